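"""Synthetic nodule / non-nodule patch generator.

Emulates the structure of LIDC-style nodule patches so the full pipeline is
testable without the real CT archive: each sample is a five-slice stack
(p2, p1, n, n1, n2) of square grayscale patches.  Nodule stacks contain a
bright, roughly round or oval Gaussian blob whose amplitude peaks on the
centre slice and decays towards the outer slices, mimicking a 3-D mass
sampled by five axial slices.  Non-nodule stacks are either an elongated
vessel-like ridge or flat background noise — two confusable negative modes
that keep the classification task non-trivial.

The generator is fully deterministic under a fixed seed and all intensities
lie in [0, 1].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Tuple

import numpy as np
import pandas as pd

SLICE_NAMES = ("p2", "p1", "n", "n1", "n2")

#: per-slice blob amplitude multiplier for offsets 0, 1, 2 from the centre
SLICE_DECAY = (1.0, 0.7, 0.4)

MANIFEST_COLUMNS = [
    "patientid",
    "noduleid",
    "slicenumber",
    "zposition",
    "diameter",
    "label",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic dataset.

    Defaults mirror the study composition this package targets:
    467 nodule stacks and 131 non-nodule stacks of 50x50 patches.
    """

    n_nodule: int = 467
    n_nonnodule: int = 131
    patch_size: int = 50
    noise_sd: float = 0.05
    nodule_radius_range: Tuple[float, float] = (4.0, 10.0)
    seed: int = 0

    def validate(self) -> "SynthConfig":
        if self.n_nodule < 1:
            raise ValueError(f"n_nodule must be >= 1, got {self.n_nodule}")
        if self.n_nonnodule < 1:
            raise ValueError(f"n_nonnodule must be >= 1, got {self.n_nonnodule}")
        if self.patch_size < 16:
            raise ValueError(f"patch_size must be >= 16, got {self.patch_size}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        lo, hi = self.nodule_radius_range
        if not (0 < lo <= hi):
            raise ValueError(
                f"nodule_radius_range must satisfy 0 < lo <= hi, got {self.nodule_radius_range}"
            )
        return self


@dataclass
class SliceStack:
    """Five ordered slices (p2, p1, n, n1, n2) sharing one label.

    ``slices`` has shape (5, patch_size, patch_size); the centre slice is
    index 2.  ``meta`` carries the synthetic manifest fields.
    """

    slices: np.ndarray
    label: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=np.float64)
        if self.slices.shape[0] != 5 or self.slices.ndim != 3:
            raise ValueError(f"expected 5 equal-size slices, got shape {self.slices.shape}")
        if self.label not in ("nodule", "nonnodule"):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def center(self) -> np.ndarray:
        return self.slices[2]


def _gaussian_blob(size: int, cy: float, cx: float, ry: float, rx: float,
                   angle: float) -> np.ndarray:
    """Unit-amplitude anisotropic Gaussian, axes (ry, rx), rotated by angle."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return np.exp(-0.5 * ((u / rx) ** 2 + (v / ry) ** 2))


def _ridge(size: int, offset: float, width: float, angle: float) -> np.ndarray:
    """Unit-amplitude straight ridge of the given half-width through the patch."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    c, s = np.cos(angle), np.sin(angle)
    # signed distance from the line through centre+offset with direction angle
    d = -s * (xx - size / 2.0) + c * (yy - size / 2.0) - offset
    return np.exp(-0.5 * (d / width) ** 2)


def _nodule_stack(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    size = cfg.patch_size
    jitter = 0.10 * size
    cy = size / 2.0 + rng.uniform(-jitter, jitter)
    cx = size / 2.0 + rng.uniform(-jitter, jitter)
    radius = rng.uniform(*cfg.nodule_radius_range)
    # mild anisotropy: round-to-oval
    ratio = rng.uniform(0.7, 1.0)
    angle = rng.uniform(0.0, np.pi)
    amplitude = rng.uniform(0.5, 0.9)
    blob = _gaussian_blob(size, cy, cx, radius, radius * ratio, angle)
    stack = np.empty((5, size, size))
    for i, off in enumerate((2, 1, 0, 1, 2)):
        stack[i] = 0.2 + amplitude * SLICE_DECAY[off] * blob
    return stack


def _nonnodule_stack(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    size = cfg.patch_size
    background = np.full((5, size, size), 0.2)
    if rng.uniform() < 0.5:
        # vessel-like ridge: persists across slices with slight drift
        angle = rng.uniform(0.0, np.pi)
        width = rng.uniform(1.0, 3.0)
        offset = rng.uniform(-0.15 * size, 0.15 * size)
        amplitude = rng.uniform(0.4, 0.8)
        drift = rng.uniform(-1.0, 1.0)
        for i in range(5):
            background[i] += amplitude * _ridge(size, offset + drift * (i - 2), width, angle)
    return background


def generate_dataset(config: SynthConfig) -> Tuple[List[SliceStack], pd.DataFrame]:
    """Generate ``n_nodule + n_nonnodule`` five-slice stacks plus a manifest.

    Manifest columns: patientid, noduleid, slicenumber (centre slice),
    zposition, diameter, label — one row per stack.  Deterministic: the same
    config (including seed) yields bit-identical arrays and manifest.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    stacks: List[SliceStack] = []
    rows = []
    labels = ["nodule"] * config.n_nodule + ["nonnodule"] * config.n_nonnodule
    for idx, label in enumerate(labels):
        if label == "nodule":
            clean = _nodule_stack(rng, config)
        else:
            clean = _nonnodule_stack(rng, config)
        noisy = clean + rng.normal(0.0, config.noise_sd, clean.shape)
        noisy = np.clip(noisy, 0.0, 1.0)
        slicenumber = int(rng.integers(20, 200))
        meta = {
            "patientid": f"SYN{idx // 4 + 1:04d}",
            "noduleid": f"N{idx + 1:04d}",
            "slicenumber": slicenumber,
            "zposition": round(-float(slicenumber) * 2.5, 2),
            "diameter": round(float(rng.uniform(2.0, 3.0)), 2)
            if label == "nodule"
            else 0.0,
            "label": label,
        }
        stacks.append(SliceStack(slices=noisy, label=label, meta=meta))
        rows.append(meta)
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return stacks, manifest


def stack_filenames(meta: dict) -> List[str]:
    """Deterministic PNG filenames for the five slices of one stack."""
    return [
        f"{meta['patientid']}_{meta['noduleid']}_{name}.png" for name in SLICE_NAMES
    ]


def save_dataset(stacks: List[SliceStack], manifest: pd.DataFrame,
                 outdir: str | Path) -> Path:
    """Write slices as 8-bit grayscale PNGs plus ``manifest.csv``; returns outdir."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stack in stacks:
        for name, patch in zip(stack_filenames(stack.meta), stack.slices):
            img = np.clip(np.round(patch * 255.0), 0, 255).astype(np.uint8)
            iio.imwrite(outdir / name, img)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return outdir


def load_saved_dataset(outdir: str | Path) -> Tuple[List[SliceStack], pd.DataFrame]:
    """Inverse of :func:`save_dataset` (up to 8-bit quantisation)."""
    from .preprocess import load_patch

    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    stacks = []
    for _, row in manifest.iterrows():
        meta = row.to_dict()
        slices = np.stack(
            [load_patch(outdir / name) for name in stack_filenames(meta)]
        )
        stacks.append(SliceStack(slices=slices, label=meta["label"], meta=meta))
    return stacks, manifest
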