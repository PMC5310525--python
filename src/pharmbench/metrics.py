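"""Confusion accounting and binary-classification metrics.

Predicted-sensitive is the positive class throughout.  The degenerate-case
convention extends the usual one: whenever a metric's denominator vanishes
(e.g. no positive prediction, TP=FP=0) the metric is 0, so every drug stays
scoreable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "MetricSet", "confusion", "mcc", "precision_recall_f1"]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN for one classifier on one evaluation set."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricSet:
    """MCC, precision, recall and F1 for one evaluation."""

    mcc: float
    precision: float
    recall: float
    f1: float

    @classmethod
    def from_counts(cls, c: ConfusionCounts) -> "MetricSet":
        pr, rc, f1 = precision_recall_f1(c)
        return cls(mcc=mcc(c), precision=pr, recall=rc, f1=f1)


def confusion(predicted: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tally a 2x2 confusion matrix from boolean label vectors.

    ``True`` means sensitive (the positive class); the vectors must be
    aligned cell-for-cell and of equal length.
    """
    pred = np.asarray(predicted, dtype=bool)
    true = np.asarray(truth, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError(f"label length mismatch: {pred.shape} vs {true.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & true)),
        tn=int(np.sum(~pred & ~true)),
        fp=int(np.sum(pred & ~true)),
        fn=int(np.sum(~pred & true)),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient, in [-1, 1].

    MCC = (TP·TN − FP·FN) / √((TP+FN)(FN+TN)(TN+FP)(FP+TP)); if any factor
    of the denominator is zero the value is 0 (this subsumes the TP=FP=0
    case of a marker with no positive prediction).
    """
    tp, tn, fp, fn = (float(x) for x in (c.tp, c.tn, c.fp, c.fn))
    denom = (tp + fn) * (fn + tn) * (tn + fp) * (fp + tp)
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """PR = TP/(TP+FP), RC = TP/(TP+FN), F1 = 2·PR·RC/(PR+RC).

    Each ratio is 0 when its denominator is 0.
    """
    pr = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    rc = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = 2 * pr * rc / (pr + rc) if (pr + rc) else 0.0
    return pr, rc, f1
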