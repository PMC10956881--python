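"""Segmentation metrics from pixel-wise confusion counts.

IoU = TP/(TP+FP+FN), Sensitivity = TP/(TP+FN), Specificity = TN/(TN+FP),
Dice = 2TP/(FP+2TP+FN); hence Dice = 2·IoU/(1+IoU) identically.

Empty-mask convention (both masks empty): Dice = IoU = Sensitivity = 1,
the standard challenge convention for images with no foreground; if exactly
one mask is empty the formulas already give Dice = IoU = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "confusion", "metrics", "evaluate_pair"]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred_binary: np.ndarray, target: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts; foreground (lesion) = 1."""
    if pred_binary.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred_binary.shape} vs {target.shape}")
    p = np.asarray(pred_binary).astype(bool)
    t = np.asarray(target).astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(counts: ConfusionCounts) -> dict:
    """Dice / IoU / sensitivity / specificity in [0, 1]."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.total == 0:
        logger.warning("metrics on zero pixels: returning convention value 1.0 for all")
        return {"iou": 1.0, "sen": 1.0, "spe": 1.0, "dice": 1.0}
    if tp + fp + fn == 0:  # both masks empty
        iou = dice = 1.0
    else:
        iou = tp / (tp + fp + fn)
        dice = 2 * tp / (fp + 2 * tp + fn)
    sen = tp / (tp + fn) if tp + fn else 1.0
    spe = tn / (tn + fp) if tn + fp else 1.0
    return {"iou": iou, "sen": sen, "spe": spe, "dice": dice}


def evaluate_pair(pred_binary: np.ndarray, target: np.ndarray) -> dict:
    """Convenience: confusion + metrics for one image pair."""
    return metrics(confusion(pred_binary, target))
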