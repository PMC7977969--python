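"""Evaluation metrics: count accuracy, confusion-matrix metrics, IoU, AP/mAP.

Count accuracy compares an automatic count against the manual reference as

    accuracy(%) = 100 * (1 - |automatic - manual| / manual)

which is symmetric in the sign of the error and can go negative when the
error exceeds the reference count (clipping at zero is available but off by
default). Detector quality uses intersection-over-union of boxes and average
precision — the area under the monotone precision envelope over recall —
with mAP the arithmetic mean over classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames_io import InputError
from .roi_detection import BoundingBox

__all__ = [
    "CountComparison",
    "ConfusionCounts",
    "count_accuracy",
    "confusion_metrics",
    "iou",
    "average_precision",
    "mean_average_precision",
]


@dataclass(frozen=True)
class CountComparison:
    automatic: int
    manual: int

    @property
    def accuracy_pct(self) -> float:
        return count_accuracy(self.automatic, self.manual)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with 'bite' as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InputError("confusion counts must be nonnegative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise InputError("confusion counts are all zero")


def count_accuracy(automatic: int, manual: int, clip: bool = False) -> float:
    """Percent agreement of an automatic count with the manual reference,
    rounded to 2 decimals."""
    if manual <= 0:
        raise InputError("manual count must be positive for count accuracy")
    acc = 100.0 * (1.0 - abs(automatic - manual) / manual)
    if clip:
        acc = max(acc, 0.0)
    return round(acc, 2)


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Precision, sensitivity (recall) and F1 as fractions in [0, 1].

    A metric whose denominator is zero is reported as ``nan`` rather than
    raising, so partially degenerate folds can still be aggregated.
    """
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else np.nan
    sensitivity = c.tp / (c.tp + c.fn) if c.tp + c.fn else np.nan
    if np.isnan(precision) or np.isnan(sensitivity) or precision + sensitivity == 0:
        f1 = np.nan if np.isnan(precision) or np.isnan(sensitivity) else 0.0
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return {"precision": precision, "sensitivity": sensitivity, "f1": f1}


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two half-open boxes; 0 when disjoint."""
    ix = max(0.0, min(a.x + a.w, b.x + b.w) - max(a.x, b.x))
    iy = max(0.0, min(a.y + a.h, b.y + b.h) - max(a.y, b.y))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def average_precision(pr_points) -> float:
    """AP from (precision, recall) points by all-point interpolation.

    The precision curve is made monotone non-increasing in recall (the
    envelope), then integrated exactly with rectangles between consecutive
    recall values, starting from recall 0.
    """
    pts = list(pr_points)
    if not pts:
        raise InputError("average_precision needs at least one (precision, recall) point")
    pts = sorted(pts, key=lambda t: t[1])
    prec = np.array([p for p, _ in pts], dtype=np.float64)
    rec = np.array([r for _, r in pts], dtype=np.float64)
    if rec.min() < 0 or rec.max() > 1:
        raise InputError("recall values must lie in [0, 1]")
    # monotone non-increasing envelope from the right
    env = np.maximum.accumulate(prec[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for p, r in zip(env, rec):
        ap += p * (r - prev_r)
        prev_r = r
    return float(ap)


def mean_average_precision(ap_list) -> float:
    """Arithmetic mean of per-class AP values."""
    aps = np.asarray(list(ap_list), dtype=np.float64)
    if aps.size == 0:
        raise InputError("mean_average_precision needs at least one AP")
    return float(aps.mean())
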