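"""Confusion-matrix construction and the classification metric panel.

The counts follow the table layout used throughout this project's result
tables: row one holds the true nodules, row two the true non-nodules, and
the four cells are named

* ``tp`` — nodules predicted nodule,
* ``fp`` — nodules predicted non-nodule (row one, second entry),
* ``fn`` — non-nodules predicted nodule,
* ``tn`` — non-nodules predicted non-nodule.

Under the standard machine-learning convention ``fp`` here is the false
*negative* count and ``fn`` the false *positive* count; the
``ConfusionCounts`` properties ``fn_standard`` / ``fp_standard`` expose the
usual names.  The metric formulas below are the ones that reproduce the
published percentage panels cell-for-cell under this layout:

* accuracy   = (tp + tn) / n
* sensitivity = recall = tp / (tp + fp)        (true nodules recovered)
* specificity = tn / (fp + tn)
* precision  = tp / (tp + fn)                  (predicted nodules correct)
* F-score    = 2 P R / (P + R)
* PPV        = tp / (tp + fp),  NPV = tn / (tn + fn)
* kappa      = (p_a - p_e) / (1 - p_e), p_e from the row/column marginals

All values are reported as percentages in [0, 100]; any metric with a zero
denominator is defined as 0 and its name recorded in ``flags``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

LABELS = ("nodule", "nonnodule")


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts in the row-one-true-nodules layout described in the module docs."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_nodule(self) -> int:
        return self.tp + self.fp

    @property
    def n_nonnodule(self) -> int:
        return self.fn + self.tn

    # standard-convention aliases
    @property
    def fn_standard(self) -> int:
        """Missed nodules (standard false negatives) = ``fp`` in this layout."""
        return self.fp

    @property
    def fp_standard(self) -> int:
        """False alarms (standard false positives) = ``fn`` in this layout."""
        return self.fn

    def as_tuple(self):
        return (self.tp, self.fp, self.fn, self.tn)


@dataclass
class MetricsReport:
    """Metric panel in percent; see the module docstring for formulas."""

    accuracy: float
    sensitivity: float
    specificity: float
    kappa: float
    precision: float
    recall: float
    fscore: float
    ppv: float
    npv: float
    flags: List[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "kappa": self.kappa,
            "precision": self.precision,
            "recall": self.recall,
            "fscore": self.fscore,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def confusion(true_labels: Sequence, predicted_labels: Sequence,
              positive: str = "nodule") -> ConfusionCounts:
    """Tally a ConfusionCounts from two equal-length label sequences.

    Labels must come from {"nodule", "nonnodule"} (the positive class is
    nodule); anything else raises ``ValueError``.
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("label sequences must be 1-D and of equal length")
    negative = [l for l in LABELS if l != positive][0]
    for arr, name in ((y_true, "true"), (y_pred, "predicted")):
        bad = set(np.unique(arr)) - set(LABELS)
        if bad:
            raise ValueError(f"unknown {name} labels: {sorted(bad)}")
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fp = int(np.sum((y_true == positive) & (y_pred == negative)))
    fn = int(np.sum((y_true == negative) & (y_pred == positive)))
    tn = int(np.sum((y_true == negative) & (y_pred == negative)))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: float, den: float, name: str, flags: List[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def panel(c: ConfusionCounts) -> MetricsReport:
    """Full metric panel (percent) for one confusion matrix."""
    if c.n == 0:
        raise ValueError("confusion matrix is empty")
    flags: List[str] = []
    n = float(c.n)
    accuracy = (c.tp + c.tn) / n
    sensitivity = _ratio(c.tp, c.tp + c.fp, "sensitivity", flags)
    specificity = _ratio(c.tn, c.fp + c.tn, "specificity", flags)
    precision = _ratio(c.tp, c.tp + c.fn, "precision", flags)
    recall = sensitivity
    if precision + recall == 0:
        flags.append("fscore")
        fscore = 0.0
    else:
        fscore = 2.0 * precision * recall / (precision + recall)
    ppv = _ratio(c.tp, c.tp + c.fp, "ppv", flags)
    npv = _ratio(c.tn, c.tn + c.fn, "npv", flags)

    pred_pos = c.tp + c.fn
    pred_neg = c.fp + c.tn
    true_pos = c.tp + c.fp
    true_neg = c.fn + c.tn
    p_e = (pred_pos * true_pos + pred_neg * true_neg) / (n * n)
    if p_e >= 1.0:
        # degenerate marginals: perfect chance agreement
        kappa = 0.0
        flags.append("kappa")
    else:
        kappa = (accuracy - p_e) / (1.0 - p_e)

    return MetricsReport(
        accuracy=100.0 * accuracy,
        sensitivity=100.0 * sensitivity,
        specificity=100.0 * specificity,
        kappa=100.0 * kappa,
        precision=100.0 * precision,
        recall=100.0 * recall,
        fscore=100.0 * fscore,
        ppv=100.0 * ppv,
        npv=100.0 * npv,
        flags=flags,
    )


def matches_printed(computed: float, printed: float, tol: float = 0.02) -> bool:
    """Whether a computed percentage agrees with a printed one.

    Published tables print to varying precision and sometimes truncate
    rather than round, so a computed value counts as matching when it is
    within ``tol`` percentage points, or when truncating or rounding it to
    the printed number of decimals reproduces the printed value exactly.
    """
    if abs(computed - printed) <= tol:
        return True
    text = repr(float(printed))
    decimals = len(text.split(".")[1]) if "." in text and text.split(".")[1] != "0" else 0
    scale = 10 ** decimals
    truncated = np.floor(computed * scale) / scale
    rounded = np.round(computed * scale) / scale
    return bool(np.isclose(truncated, printed) or np.isclose(rounded, printed))
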