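"""Segmentation evaluation metrics.

Per-class one-vs-rest confusion counts over label masks, and the derived
metrics used throughout the pipeline: IOU (Jaccard index) and its class mean
mIOU, precision, recall, F1 and the Matthews correlation coefficient (MCC).

Conventions for degenerate denominators (the definitions are silent there):

* IOU with empty prediction *and* empty truth is 1.0 — a vacuously perfect
  match; the same applies to precision/recall/F1.
* A zero denominator where one side is non-empty yields 0.0.
* MCC is 0.0 whenever any factor under the square root vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "iou",
    "miou",
    "precision",
    "recall",
    "f1",
    "mcc",
    "evaluate",
    "evaluate_dataset",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest pixel confusion counts for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


def confusion(pred: np.ndarray, truth: np.ndarray, class_id: int) -> ConfusionCounts:
    """One-vs-rest confusion counts of ``class_id`` between two label masks.

    FN counts truth-foreground pixels predicted as background (the standard
    definition, consistent with recall = TP/(TP+FN)).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred == class_id
    t = truth == class_id
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def iou(counts: ConfusionCounts) -> float:
    """Intersection over union TP/(TP+FP+FN); both sides empty -> 1.0."""
    denom = counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return counts.tp / denom


def miou(per_class: list[ConfusionCounts]) -> float:
    """Unweighted mean of per-class IOUs."""
    if not per_class:
        raise ValueError("miou needs at least one class")
    return float(np.mean([iou(c) for c in per_class]))


def precision(counts: ConfusionCounts) -> float:
    if counts.tp + counts.fp == 0:
        return 1.0 if counts.fn == 0 else 0.0
    return counts.tp / (counts.tp + counts.fp)


def recall(counts: ConfusionCounts) -> float:
    if counts.tp + counts.fn == 0:
        return 1.0 if counts.fp == 0 else 0.0
    return counts.tp / (counts.tp + counts.fn)


def f1(counts: ConfusionCounts) -> float:
    denom = 2 * counts.tp + counts.fn + counts.fp
    if denom == 0:
        return 1.0
    return 2 * counts.tp / denom


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0.0 if any root factor is zero."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    factors = [(tn + fn), (fp + tp), (tn + fp), (tp + fn)]
    if any(f == 0 for f in factors):
        return 0.0
    num = tp * tn - fp * fn
    # integer-exact product can overflow float64 precision; use math.prod + sqrt
    return num / math.sqrt(math.prod(factors))


@dataclass
class MetricsReport:
    """Per-class and macro-averaged metrics over foreground classes 1..K."""

    per_class: dict[int, dict[str, float]]
    counts: dict[int, ConfusionCounts] = field(repr=False, default_factory=dict)

    @property
    def miou(self) -> float:
        return float(np.mean([m["iou"] for m in self.per_class.values()]))

    def macro(self, key: str) -> float:
        return float(np.mean([m[key] for m in self.per_class.values()]))

    def to_dict(self) -> dict:
        out = {
            "per_class": {str(k): dict(v) for k, v in self.per_class.items()},
            "miou": self.miou,
        }
        for key in ("precision", "recall", "f1", "mcc"):
            out[f"macro_{key}"] = self.macro(key)
        return out


def _report_from_counts(counts: dict[int, ConfusionCounts]) -> MetricsReport:
    per_class = {
        k: {
            "iou": iou(c),
            "precision": precision(c),
            "recall": recall(c),
            "f1": f1(c),
            "mcc": mcc(c),
        }
        for k, c in counts.items()
    }
    return MetricsReport(per_class=per_class, counts=counts)


def evaluate(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> MetricsReport:
    """Full metrics report over foreground classes ``1..n_classes``.

    Background (0) participates only as the negative side of each
    one-vs-rest count; a class absent from both masks scores IOU 1.0 by the
    empty-empty convention.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    counts = {k: confusion(pred, truth, k) for k in range(1, n_classes + 1)}
    return _report_from_counts(counts)


def evaluate_dataset(
    preds: list[np.ndarray],
    truths: list[np.ndarray],
    n_classes: int,
    per_image: bool = False,
) -> MetricsReport | list[MetricsReport]:
    """Dataset-level report: confusion counts are accumulated over all images
    before any ratio is taken (so large images weigh more, per common
    practice). With ``per_image=True`` returns one report per image instead.
    """
    if len(preds) != len(truths):
        raise ValueError("preds and truths differ in length")
    if per_image:
        return [evaluate(p, t, n_classes) for p, t in zip(preds, truths)]
    totals = {k: ConfusionCounts(0, 0, 0, 0) for k in range(1, n_classes + 1)}
    for p, t in zip(preds, truths):
        for k in range(1, n_classes + 1):
            totals[k] = totals[k] + confusion(p, t, k)
    return _report_from_counts(totals)


def similarity_rate(miou_a: float, miou_b: float) -> float:
    """Similarity between two mIOUs as a percentage, 100·min/max.

    This is an interpretation: quoted "similarity rates" between label sets
    rarely state a formula; the symmetric ratio of the two mean IOUs is used
    here and flagged as such.
    """
    if miou_a == miou_b:
        return 100.0
    hi = max(miou_a, miou_b)
    if hi == 0:
        return 100.0
    return 100.0 * min(miou_a, miou_b) / hi
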