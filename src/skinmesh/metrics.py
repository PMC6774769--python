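"""Pixel-classification evaluation: TPR/FPR, ROC sweeps, IoU and Dice.

Predicted skin masks (or probability maps swept over thresholds) are
compared against ground-truth masks by pixel-wise confusion counts.
TPR = TP/S and FPR = FP/NS where S and NS are the ground-truth skin and
non-skin pixel totals; IoU is |∩|/|∪| and Dice 2|∩|/(|A|+|B|).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "ROCCurve",
    "EvalReport",
    "confusion",
    "tpr_fpr",
    "roc",
    "iou",
    "dice",
    "evaluate_masks",
    "DEFAULT_THRESHOLD",
]

#: Fixed decision threshold used for tabulated comparisons.
DEFAULT_THRESHOLD = 0.55


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def S(self) -> int:
        """Total ground-truth skin pixels."""
        return self.TP + self.FN

    @property
    def NS(self) -> int:
        """Total ground-truth non-skin pixels."""
        return self.FP + self.TN


@dataclass
class ROCCurve:
    """(FPR, TPR) points ordered by descending threshold."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    @property
    def points(self) -> np.ndarray:
        return np.stack([self.fpr, self.tpr], axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fpr, self.tpr, **kwargs)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_xlim(-0.02, 1.02)
        ax.set_ylim(-0.02, 1.02)
        return ax


@dataclass
class EvalReport:
    tpr: float
    fpr: float
    iou: float
    dice: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "tpr": self.tpr,
            "fpr": self.fpr,
            "iou": self.iou,
            "dice": self.dice,
        }


def _pair(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    return pred, truth


def confusion(pred, truth) -> ConfusionCounts:
    """Pixel-wise confusion counts of a predicted vs ground-truth mask."""
    pred, truth = _pair(pred, truth)
    return ConfusionCounts(
        TP=int(np.count_nonzero(pred & truth)),
        FP=int(np.count_nonzero(pred & ~truth)),
        TN=int(np.count_nonzero(~pred & ~truth)),
        FN=int(np.count_nonzero(~pred & truth)),
    )


def tpr_fpr(c: ConfusionCounts) -> tuple[float, float]:
    """(TP/S, FP/NS); raises if either ground-truth class is empty."""
    if c.S == 0:
        raise ValueError("TPR undefined: ground truth contains no skin pixels")
    if c.NS == 0:
        raise ValueError("FPR undefined: ground truth contains no non-skin pixels")
    return c.TP / c.S, c.FP / c.NS


def roc(pm, truth, thresholds: np.ndarray | None = None) -> ROCCurve:
    """ROC sweep of a probability map over K thresholds (101 by default)."""
    values = np.asarray(getattr(pm, "values", pm), dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if values.shape != truth.shape:
        raise ValueError("probability map and truth mask shapes differ")
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    thresholds = np.sort(np.asarray(thresholds, dtype=float))[::-1]
    if len(thresholds) < 2:
        raise ValueError("need at least two thresholds for a ROC sweep")
    tprs, fprs = [], []
    for tau in thresholds:
        t, f = tpr_fpr(confusion(values >= tau, truth))
        tprs.append(t)
        fprs.append(f)
    return ROCCurve(thresholds, np.asarray(fprs), np.asarray(tprs))


def iou(pred, truth) -> float:
    """Intersection over union; two empty masks count as perfect agreement."""
    pred, truth = _pair(pred, truth)
    union = np.count_nonzero(pred | truth)
    if union == 0:
        logger.info("both masks empty; IoU defined as 1")
        return 1.0
    return np.count_nonzero(pred & truth) / union


def dice(pred, truth) -> float:
    """Dice coefficient 2|∩|/(|A|+|B|); empty masks agree perfectly."""
    pred, truth = _pair(pred, truth)
    total = np.count_nonzero(pred) + np.count_nonzero(truth)
    if total == 0:
        logger.info("both masks empty; Dice defined as 1")
        return 1.0
    return 2.0 * np.count_nonzero(pred & truth) / total


def evaluate_masks(pred, truth) -> EvalReport:
    """Full evaluation of one predicted mask against ground truth."""
    c = confusion(pred, truth)
    t, f = tpr_fpr(c)
    return EvalReport(tpr=t, fpr=f, iou=iou(pred, truth), dice=dice(pred, truth), counts=c)
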