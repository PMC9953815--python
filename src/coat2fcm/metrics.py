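"""Pixel-level segmentation metrics between a predicted and a true mask.

Standard confusion-matrix rates plus the two overlap indices used
throughout medical image segmentation:

    DSC = 2|S∩G| / (|S| + |G|)        (Dice similarity coefficient)
    JSI = |S∩G| / |S∪G|               (Jaccard similarity index)

linked by the identity DSC = 2·JSI / (1 + JSI).  Metrics with a zero
denominator raise :class:`UndefinedMetricError` instead of returning a
sentinel, so batch evaluations cannot silently average garbage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "accuracy",
    "sensitivity",
    "specificity",
    "dsc",
    "jsi",
    "evaluate_masks",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    sensitivity: float
    specificity: float
    dsc: float
    jsi: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "dsc": self.dsc,
            "jsi": self.jsi,
        }


def _check_masks(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise InvalidArgumentError("mask shapes differ")
    for m in (pred, truth):
        if not np.isin(m, (0, 1)).all():
            raise InvalidArgumentError("masks must be strictly binary {0,1}")
    return pred.astype(bool), truth.astype(bool)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-level TP/TN/FP/FN between two binary masks."""
    p, g = _check_masks(pred, truth)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & g)),
        tn=int(np.count_nonzero(~p & ~g)),
        fp=int(np.count_nonzero(p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total."""
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined: no pixels compared")
    return (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN), a.k.a. recall."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive ground truth")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP)."""
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative ground truth")
    return c.tn / (c.tn + c.fp)


def dsc(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity coefficient 2|S∩G| / (|S| + |G|)."""
    p, g = _check_masks(pred, truth)
    s = int(np.count_nonzero(p)) + int(np.count_nonzero(g))
    if s == 0:
        raise UndefinedMetricError("DSC undefined: both masks empty")
    return 2.0 * np.count_nonzero(p & g) / s


def jsi(pred: np.ndarray, truth: np.ndarray) -> float:
    """Jaccard similarity index |S∩G| / |S∪G|."""
    p, g = _check_masks(pred, truth)
    union = int(np.count_nonzero(p | g))
    if union == 0:
        raise UndefinedMetricError("JSI undefined: both masks empty")
    return np.count_nonzero(p & g) / union


def evaluate_masks(pred: np.ndarray, truth: np.ndarray) -> MetricReport:
    """All five metrics for one mask pair."""
    c = confusion_counts(pred, truth)
    return MetricReport(
        accuracy=accuracy(c),
        sensitivity=sensitivity(c),
        specificity=specificity(c),
        dsc=dsc(pred, truth),
        jsi=jsi(pred, truth),
    )
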