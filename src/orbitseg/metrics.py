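"""Overlap metrics for binary segmentation masks.

Predictions are binarized at a fixed probability threshold (foreground on
ties), reduced to pixel-wise confusion counts, and scored with the Dice
coefficient ``2TP / (2TP + FP + FN)`` and the Jaccard index (IoU)
``TP / (TP + FP + FN)``.  The two are linked by ``dice = 2*iou / (1 + iou)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "binarize", "confusion", "dice", "iou"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-wise confusion counts of a binary prediction against truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def degenerate(self) -> bool:
        """True when prediction and truth are both empty (no foreground)."""
        return self.tp + self.fp + self.fn == 0


def binarize(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold sigmoid probabilities into a {0,1} mask.

    Ties (``probs == threshold``) go to foreground.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    probs = np.asarray(probs)
    return (probs >= threshold).astype(np.uint8)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Count TP/FP/FN/TN between two binary masks of equal shape."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def dice(c: ConfusionCounts) -> float:
    """Dice coefficient 2TP / (2TP + FP + FN).

    Empty-vs-empty (tp = fp = fn = 0) is defined as 1.0 by convention.
    """
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


def iou(c: ConfusionCounts) -> float:
    """Intersection over union TP / (TP + FP + FN).

    Empty-vs-empty is defined as 1.0 by convention, matching :func:`dice`.
    """
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return c.tp / denom
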