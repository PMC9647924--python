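"""Evaluation metrics for segmentation, detection, numbering, staging,
and FMS placement.

Detection/numbering evaluation pairs predicted and gold boxes greedily
by descending Jaccard index; a pair with JI strictly over the threshold
(default 0.7) is a successful match.  Ratios with zero denominators are
reported as ``None`` (undefined), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "JI_THRESHOLD",
    "ConfusionMatrix",
    "DetectionEval",
    "dsc",
    "ji",
    "box_ji",
    "evaluate_detection",
    "numbering_accuracy",
    "position_accuracy",
    "sensitivity_specificity",
]

JI_THRESHOLD = 0.7


def _pixels(mask) -> np.ndarray:
    pixels = getattr(mask, "pixels", mask)
    return np.asarray(pixels).astype(bool)


def dsc(a, b) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); 1.0 when both empty."""
    a, b = _pixels(a), _pixels(b)
    if a.shape != b.shape:
        raise ValueError(f"mask dimension mismatch: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def ji(a, b) -> float:
    """Jaccard index |A∩B| / |A∪B|; 1.0 when both empty."""
    a, b = _pixels(a), _pixels(b)
    if a.shape != b.shape:
        raise ValueError(f"mask dimension mismatch: {a.shape} vs {b.shape}")
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def _extent(box) -> tuple[float, float, float, float]:
    if hasattr(box, "extent"):
        return box.extent
    return tuple(box)


def box_ji(a, b) -> float:
    """Closed-form intersection-over-union of two half-open boxes."""
    ax0, ay0, ax1, ay1 = _extent(a)
    bx0, by0, bx1, by1 = _extent(b)
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    if union <= 0:
        return 1.0
    return inter / union


@dataclass
class ConfusionMatrix:
    """K x K table of (true class, predicted class) counts."""

    counts: np.ndarray
    classes: tuple = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")
        if not self.classes:
            self.classes = tuple(range(self.counts.shape[0]))

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "ConfusionMatrix":
        classes = tuple(sorted({c for pair in records for c in pair}))
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for true, pred in records:
            counts[index[true], index[pred]] += 1
        return cls(counts=counts, classes=classes)


@dataclass
class DetectionEval:
    n_detected: int
    n_gold: int
    n_successful: int
    n_true_number: int
    detection_precision: float | None
    detection_recall: float | None
    numbering_precision: float | None
    numbering_recall: float | None

    def __post_init__(self) -> None:
        if self.n_successful > min(self.n_detected, self.n_gold):
            raise ValueError("n_successful exceeds min(n_detected, n_gold)")
        if self.n_true_number > self.n_successful:
            raise ValueError("n_true_number exceeds n_successful")


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def evaluate_detection(
    pred: Sequence[tuple],
    gold: Sequence[tuple],
    threshold: float = JI_THRESHOLD,
) -> DetectionEval:
    """Detection / numbering precision and recall under the JI rule.

    ``pred`` and ``gold`` are sequences of ``(box, fdi)`` (fdi may be
    ``None`` on predictions).  Boxes are paired one-to-one greedily by
    descending JI; pairs with JI strictly above ``threshold`` are
    successful matches, and successful pairs with equal numbers count as
    true-positive numberings.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    pairs = [(box_ji(pb, gb), i, j)
             for i, (pb, _) in enumerate(pred)
             for j, (gb, _) in enumerate(gold)]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_pred: set[int] = set()
    used_gold: set[int] = set()
    n_successful = n_true = 0
    for score, i, j in pairs:
        if score <= threshold:
            break
        if i in used_pred or j in used_gold:
            continue
        used_pred.add(i)
        used_gold.add(j)
        n_successful += 1
        if pred[i][1] is not None and pred[i][1] == gold[j][1]:
            n_true += 1
    n_detected, n_gold = len(pred), len(gold)
    return DetectionEval(
        n_detected=n_detected, n_gold=n_gold,
        n_successful=n_successful, n_true_number=n_true,
        detection_precision=_ratio(n_successful, n_detected),
        detection_recall=_ratio(n_successful, n_gold),
        numbering_precision=_ratio(n_true, n_detected),
        numbering_recall=_ratio(n_true, n_gold),
    )


def numbering_accuracy(records: Sequence[tuple[int, int]]) -> float:
    """Fraction of correctly numbered teeth."""
    if not records:
        raise ValueError("no numbering records")
    return sum(1 for true, pred in records if true == pred) / len(records)


def position_accuracy(records: Sequence[tuple]) -> float:
    """Fraction of correctly positioned radiographs."""
    if not records:
        raise ValueError("no position records")

    def norm(p):
        return getattr(p, "value", p)

    return sum(1 for true, pred in records if norm(true) == norm(pred)) / len(records)


def sensitivity_specificity(
    cm: ConfusionMatrix, positive_class,
) -> tuple[float | None, float | None]:
    """One-vs-rest sensitivity TP/(TP+FN) and specificity TN/(TN+FP)."""
    if positive_class not in cm.classes:
        raise ValueError(f"unknown class {positive_class!r}")
    k = cm.classes.index(positive_class)
    counts = cm.counts
    tp = int(counts[k, k])
    fn = int(counts[k, :].sum()) - tp
    fp = int(counts[:, k].sum()) - tp
    tn = int(counts.sum()) - tp - fn - fp
    return (_ratio(tp, tp + fn), _ratio(tn, tn + fp))
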