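"""Segmentation and counting metrics.

Segmentation quality is scored from a C x C confusion matrix of point
counts, n_ij = points of true class i predicted as class j:

    OAcc  = sum_i n_ii / sum_ij n_ij
    Acc_i = n_ii / sum_j n_ij                mAcc = mean_i Acc_i
    IoU_i = n_ii / (sum_j n_ij + sum_j n_ji - n_ii)
    mIoU  = mean_i IoU_i

Counting quality compares predicted instance counts y_hat with ground
truth y over n plants:

    MAE  = mean |y - y_hat|
    RMSE = sqrt(mean (y - y_hat)^2)
    CA   = mean_i (y_hat_i / y_i) * 100      (mean of per-plant ratios,
                                              not the pooled ratio)
All percentages are returned on the 0-100 scale at full precision.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np


@dataclass
class ConfusionMatrix:
    """Integer point-count confusion matrix; entry (i, j): true i, predicted j."""

    counts: np.ndarray
    num_classes: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.num_classes, self.num_classes):
            raise ValueError("counts must be C x C")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts, self.num_classes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class CountReport:
    """Per-plant (actual, predicted) count pairs with summary errors."""

    pairs: List[Tuple[int, int]]
    mae: float
    rmse: float
    ca_percent: float


def accumulate_confusion(true_labels, pred_labels, num_classes: int,
                         into: ConfusionMatrix | None = None) -> ConfusionMatrix:
    """Tally a confusion matrix; accumulation over chunks equals single-pass."""
    t = np.asarray(true_labels).ravel()
    p = np.asarray(pred_labels).ravel()
    if t.shape != p.shape:
        raise ValueError("label arrays must have equal length")
    for name, arr in (("true", t), ("predicted", p)):
        if arr.size and (arr.min() < 0 or arr.max() >= num_classes):
            raise ValueError(f"{name} labels outside [0, {num_classes})")
    cm = np.bincount(t * num_classes + p,
                     minlength=num_classes * num_classes
                     ).reshape(num_classes, num_classes)
    out = ConfusionMatrix(cm, num_classes)
    return out if into is None else into + out


def segmentation_scores(cm: ConfusionMatrix) -> Dict[str, object]:
    """OAcc, per-class Acc, mAcc, per-class IoU and mIoU as percentages.

    A class absent from both truth and prediction (empty union) is excluded
    from the mAcc/mIoU averages; with two always-present classes this never
    triggers in practice.
    """
    n = cm.counts.astype(np.float64)
    total = n.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(n)
    row = n.sum(axis=1)
    col = n.sum(axis=0)
    union = row + col - diag
    present = union > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        acc = np.where(row > 0, diag / row, np.nan)
        iou = np.where(present, diag / np.where(union > 0, union, 1.0), np.nan)
    oacc = diag.sum() / total
    macc = np.nanmean(acc[present])
    miou = np.nanmean(iou[present])
    return {
        "OAcc": 100.0 * oacc,
        "Acc": 100.0 * acc,
        "mAcc": 100.0 * macc,
        "IoU": 100.0 * iou,
        "mIoU": 100.0 * miou,
    }


def mean_iou_of(per_class_ious: Sequence[float]) -> float:
    """Average per-class IoUs exactly as mIoU averages them."""
    return float(np.mean(np.asarray(per_class_ious, dtype=np.float64)))


def counting_scores(pairs: Sequence[Tuple[float, float]]) -> CountReport:
    """MAE, RMSE and counting accuracy from (actual, predicted) pairs.

    CA is the mean of per-plant ratios predicted/actual, expressed in
    percent; every actual count must therefore be positive.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("pairs must be a non-empty sequence of (actual, predicted)")
    y, yhat = arr[:, 0], arr[:, 1]
    if (y <= 0).any():
        raise ValueError("actual counts must be > 0 for CA")
    err = y - yhat
    return CountReport(
        pairs=[(a, b) for a, b in pairs],
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err ** 2))),
        ca_percent=float(np.mean(yhat / y) * 100.0),
    )
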