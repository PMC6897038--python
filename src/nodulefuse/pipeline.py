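"""End-to-end glue: synthetic stacks -> descriptor matrices -> grid results.

Sample convention: the classification grid runs at one sample per
five-slice stack.  Hand-crafted descriptors are computed on the centre
slice (resized to its 28x28 working size); the CNN is trained on all five
slices of every stack (each slice carries the stack's label, which both
augments the training set and exposes the through-slice structure to the
network) and then contributes the centre-slice feature vector to fusion.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .cnn import SmallCNNClassifier, TrainConfig
from .descriptors import ExHOGDescriptor, HOGDescriptor, LBPDescriptor
from .preprocess import resize
from .synthetic import SliceStack

DESCRIPTOR_WORKING_SIZE = 28
CNN_WORKING_SIZE = 50


def _resize_batch(patches: Iterable[np.ndarray], target: int) -> np.ndarray:
    return np.stack([resize(p, target) for p in patches])


def center_slices(stacks: Sequence[SliceStack], target: int) -> np.ndarray:
    """(n_stacks, target, target) array of resized centre slices."""
    return _resize_batch((s.center for s in stacks), target)


def all_slices(stacks: Sequence[SliceStack], target: int
               ) -> Tuple[np.ndarray, np.ndarray]:
    """Every slice as an individual sample with its stack's label."""
    patches = _resize_batch((sl for s in stacks for sl in s.slices), target)
    labels = np.asarray([s.label for s in stacks for _ in s.slices])
    return patches, labels


def stack_labels(stacks: Sequence[SliceStack]) -> np.ndarray:
    return np.asarray([s.label for s in stacks])


def train_cnn_on_stacks(stacks: Sequence[SliceStack],
                        config: TrainConfig | None = None) -> SmallCNNClassifier:
    """Train the CNN on all five slices of every stack."""
    config = (config or TrainConfig()).validate()
    patches, labels = all_slices(stacks, CNN_WORKING_SIZE)
    model = SmallCNNClassifier(
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_iter=config.max_iterations,
        random_state=config.seed,
    )
    return model.fit(patches, labels)


def extract_descriptors(stacks: Sequence[SliceStack],
                        which: Sequence[str] = ("HOG", "ExHOG", "LBP"),
                        cnn_model: SmallCNNClassifier | None = None,
                        ) -> Dict[str, np.ndarray]:
    """Per-stack descriptor matrices keyed by name.

    ``CNN`` requires a fitted ``cnn_model``; the remaining names are
    computed on the centre slice at the 28x28 working size.
    """
    out: Dict[str, np.ndarray] = {}
    handcrafted = [w for w in which if w != "CNN"]
    if handcrafted:
        patches28 = center_slices(stacks, DESCRIPTOR_WORKING_SIZE)
        extractors = {"HOG": HOGDescriptor(), "ExHOG": ExHOGDescriptor(),
                      "LBP": LBPDescriptor()}
        for name in handcrafted:
            if name not in extractors:
                raise ValueError(f"unknown descriptor {name!r}")
            out[name] = extractors[name].transform(patches28)
    if "CNN" in which:
        if cnn_model is None:
            raise ValueError("CNN descriptor requested but no fitted cnn_model given")
        patches50 = center_slices(stacks, CNN_WORKING_SIZE)
        out["CNN"] = cnn_model.transform(patches50)
    return out
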