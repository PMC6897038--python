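"""Descriptor fusion and the 36-combination classification grid.

Feature vectors from the four extractors are fused by concatenation in the
canonical order HOG, ExHOG, CNN, LBP (restricted to the chosen subset).
Nine canonical feature sets — the four singletons plus HOG+CNN, ExHOG+CNN,
CNN+LBP, ExHOG+CNN+LBP and HOG+CNN+LBP — crossed with four classifiers
(RBF-kernel SVM, 1-nearest-neighbour, Gini decision tree, 100-tree random
forest) give the 36-combination grid.

Evaluation uses five independent stratified splits at train fractions
10/20/30/40/50 percent; each classifier is fitted on the train split (with
per-feature z-scoring fitted on the train split only) and predicts the
complement, and the five held-out prediction sets are pooled into a single
confusion matrix per combination.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

from .metrics import ConfusionCounts, MetricsReport, confusion, panel

#: concatenation order of fused descriptors
FUSION_ORDER = ("HOG", "ExHOG", "CNN", "LBP")

#: the nine canonical feature sets, keyed by their table name
CANONICAL_FEATURE_SETS: Dict[str, Tuple[str, ...]] = {
    "LBP": ("LBP",),
    "HOG": ("HOG",),
    "ExHOG": ("ExHOG",),
    "CNN": ("CNN",),
    "HOG_CNN": ("HOG", "CNN"),
    "ExHOG_CNN": ("ExHOG", "CNN"),
    "CNN_LBP": ("CNN", "LBP"),
    "ExHOG_CNN_LBP": ("ExHOG", "CNN", "LBP"),
    "HOG_CNN_LBP": ("HOG", "CNN", "LBP"),
}

CLASSIFIERS = ("SVM", "KNN", "DT", "RF")


@dataclass(frozen=True)
class ComboSpec:
    """One (feature set, classifier) cell of the experiment grid."""

    feature_sets: Tuple[str, ...]
    classifier: str

    def __post_init__(self):
        if not self.feature_sets:
            raise ValueError("feature_sets must be non-empty")
        unknown = set(self.feature_sets) - set(FUSION_ORDER)
        if unknown:
            raise ValueError(f"unknown descriptors: {sorted(unknown)}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")

    @property
    def feature_name(self) -> str:
        members = frozenset(self.feature_sets)
        for name, sets in CANONICAL_FEATURE_SETS.items():
            if frozenset(sets) == members:
                return name
        return "_".join(d for d in FUSION_ORDER if d in members)

    @property
    def name(self) -> str:
        return f"{self.classifier}_{self.feature_name}"


def canonical_combos() -> List[ComboSpec]:
    """The 36 canonical (classifier x feature set) combinations."""
    return [
        ComboSpec(feature_sets=sets, classifier=clf)
        for clf in CLASSIFIERS
        for sets in CANONICAL_FEATURE_SETS.values()
    ]


def combo_from_name(name: str) -> ComboSpec:
    """Parse a table-style name like ``SVM_ExHOG_CNN`` (case-insensitive)."""
    head, _, tail = name.partition("_")
    clf = head.upper()
    for feature_name, sets in CANONICAL_FEATURE_SETS.items():
        if tail.upper() == feature_name.upper():
            return ComboSpec(feature_sets=sets, classifier=clf)
    raise ValueError(f"cannot parse combination name {name!r}")


@dataclass(frozen=True)
class SplitScheme:
    """Five stratified train/test partitions at increasing train fractions."""

    train_fractions: Tuple[float, ...] = (0.10, 0.20, 0.30, 0.40, 0.50)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not all(0.0 < f < 1.0 for f in self.train_fractions):
            raise ValueError("train fractions must lie in (0, 1)")


@dataclass
class GridResult:
    """Per-combination pooled confusion matrices and metric panels."""

    table: pd.DataFrame
    confusions: Dict[str, ConfusionCounts]
    reports: Dict[str, MetricsReport]
    seed: int


def fuse(descriptors: Mapping[str, np.ndarray], combo: ComboSpec) -> np.ndarray:
    """Concatenate the combo's descriptors in canonical order.

    ``descriptors`` maps descriptor names to (n_samples, dim) arrays (or
    1-D single-sample vectors).  Missing members raise ``KeyError``.
    """
    missing = [d for d in combo.feature_sets if d not in descriptors]
    if missing:
        raise KeyError(f"missing descriptors for fusion: {missing}")
    parts = [np.atleast_2d(np.asarray(descriptors[d], dtype=np.float64))
             for d in FUSION_ORDER if d in combo.feature_sets]
    n = {p.shape[0] for p in parts}
    if len(n) != 1:
        raise ValueError(f"descriptor sample counts disagree: {sorted(n)}")
    fused = np.concatenate(parts, axis=1)
    return fused


def make_classifier(kind: str, seed: int = 0) -> Pipeline:
    """A train-split-scaled classifier pipeline of the requested kind.

    SVM: RBF kernel, C=1, gamma='scale'; KNN: k=1, Euclidean; DT: Gini;
    RF: 100 trees.  The z-scoring step is part of the pipeline, so its
    mean/scale are fitted on the training split only.
    """
    if kind == "SVM":
        clf = SVC(C=1.0, kernel="rbf", gamma="scale", random_state=seed)
    elif kind == "KNN":
        clf = KNeighborsClassifier(n_neighbors=1, metric="euclidean")
    elif kind == "DT":
        clf = DecisionTreeClassifier(criterion="gini", random_state=seed)
    elif kind == "RF":
        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
    else:
        raise ValueError(f"unknown classifier {kind!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def train_classifier(features: np.ndarray, labels: Sequence, kind: str,
                     seed: int = 0) -> Pipeline:
    """Fit a classifier pipeline on labelled feature vectors."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    model = make_classifier(kind, seed)
    model.fit(np.asarray(features, dtype=np.float64), labels)
    return model


def _splits(labels: np.ndarray, scheme: SplitScheme):
    """Yield (train_idx, test_idx) for each train fraction."""
    indices = np.arange(len(labels))
    for i, fraction in enumerate(scheme.train_fractions):
        stratify = labels if scheme.stratified else None
        try:
            train_idx, test_idx = train_test_split(
                indices, train_size=fraction, stratify=stratify,
                random_state=scheme.seed + i, shuffle=True,
            )
        except ValueError as exc:
            raise ValueError(
                f"train fraction {fraction} leaves an invalid split: {exc}"
            ) from exc
        if len(np.unique(labels[train_idx])) < 2:
            raise ValueError(
                f"train fraction {fraction} leaves an empty class in the train split"
            )
        yield fraction, train_idx, test_idx


def run_grid(descriptors: Mapping[str, np.ndarray], labels: Sequence,
             scheme: SplitScheme | None = None,
             combos: Sequence[ComboSpec] | None = None,
             classifier_factory: Callable[[str, int], object] | None = None,
             ) -> GridResult:
    """Evaluate combinations over the five-split scheme with pooled predictions.

    Parameters
    ----------
    descriptors : mapping of descriptor name -> (n_samples, dim) array.
    labels : per-sample labels from {"nodule", "nonnodule"}.
    scheme : split scheme; defaults to the canonical five fractions, seed 0.
    combos : combinations to run; defaults to the canonical 36.
    classifier_factory : optional replacement for :func:`make_classifier`
        (used e.g. to inject oracle classifiers in tests).

    Returns a :class:`GridResult` whose table has one row per combination
    with the pooled confusion counts, the metric panel (percent) and the
    wall time in seconds.
    """
    scheme = scheme or SplitScheme()
    combos = list(combos) if combos is not None else canonical_combos()
    if not combos:
        raise ValueError("no combinations requested")
    factory = classifier_factory or make_classifier
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("dataset must contain both classes")

    split_list = list(_splits(labels, scheme))
    rows = []
    confusions: Dict[str, ConfusionCounts] = {}
    reports: Dict[str, MetricsReport] = {}
    for combo in combos:
        start = time.perf_counter()
        fused = fuse(descriptors, combo)
        pooled_true: List[str] = []
        pooled_pred: List[str] = []
        for _, train_idx, test_idx in split_list:
            model = factory(combo.classifier, scheme.seed)
            model.fit(fused[train_idx], labels[train_idx])
            pred = model.predict(fused[test_idx])
            pooled_true.extend(labels[test_idx])
            pooled_pred.extend(pred)
        counts = confusion(pooled_true, pooled_pred)
        report = panel(counts)
        seconds = time.perf_counter() - start
        confusions[combo.name] = counts
        reports[combo.name] = report
        row = {"combo": combo.name, "classifier": combo.classifier,
               "feature_set": combo.feature_name,
               "TP": counts.tp, "FP": counts.fp, "FN": counts.fn,
               "TN": counts.tn}
        row.update(report.as_dict())
        row["seconds"] = seconds
        rows.append(row)
    table = pd.DataFrame(rows)
    return GridResult(table=table, confusions=confusions, reports=reports,
                      seed=scheme.seed)
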