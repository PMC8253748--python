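"""Evaluation mathematics for segmentation and compression measurement.

Pixelwise segmentation quality is summarized by sensitivity, specificity,
accuracy and the Dice similarity coefficient computed from a pixel
confusion matrix.  Compression-measurement quality uses MAE / MSE / RMSE
against manual values, Pearson correlation, and Bland-Altman agreement
(bias and 95% limits of agreement, bias +/- 1.96 x sample SD of the
differences).

Undefined scores (zero denominators, zero variance) are reported as NaN
rather than 0 so that aggregate means stay honest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "ConfusionCounts",
    "SegScores",
    "RegressionErrors",
    "AgreementReport",
    "confusion",
    "dice",
    "seg_scores",
    "regression_errors",
    "agreement",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class SegScores:
    sensitivity: float
    specificity: float
    accuracy: float
    dsc: float


@dataclass
class RegressionErrors:
    mae: float
    mse: float
    rmse: float
    n: int


@dataclass
class AgreementReport:
    pearson_r: float
    bias: float
    loa_low: float
    loa_high: float
    inside_loa_fraction: float
    n: int


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Pixel confusion counts between a predicted and a reference mask."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValidationError(
            f"mask shapes differ: {pred.shape} vs {gt.shape}")
    p = pred > 0
    g = gt > 0
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def seg_scores(c: ConfusionCounts) -> SegScores:
    """Sensitivity, specificity, accuracy and Dice from confusion counts."""
    return SegScores(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        accuracy=_ratio(c.tp + c.tn, c.total),
        dsc=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """Convenience: Dice similarity coefficient of two binary masks."""
    return seg_scores(confusion(pred, gt)).dsc


def regression_errors(manual, predicted) -> RegressionErrors:
    """MAE, MSE and RMSE of predicted vs manually measured compressions."""
    x = np.asarray(manual, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(
            f"manual and predicted must be equal-length 1D vectors "
            f"(got {x.shape} vs {y.shape})")
    if x.size == 0:
        raise ValidationError("need at least one pair")
    err = np.abs(x - y)
    mse = float((err ** 2).mean())
    return RegressionErrors(mae=float(err.mean()), mse=mse,
                            rmse=float(np.sqrt(mse)), n=int(x.size))


def agreement(manual, predicted) -> AgreementReport:
    """Pearson correlation plus Bland-Altman agreement statistics.

    Differences are ``predicted - manual``; limits of agreement are
    bias +/- 1.96 x sample standard deviation (ddof=1).  Zero-variance
    inputs yield NaN correlation.
    """
    x = np.asarray(manual, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(
            f"manual and predicted must be equal-length 1D vectors "
            f"(got {x.shape} vs {y.shape})")
    if x.size < 3:
        raise ValidationError(f"agreement needs n >= 3, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(x, y).statistic)
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    inside = float(np.mean((d >= loa_low) & (d <= loa_high)))
    return AgreementReport(pearson_r=r, bias=bias, loa_low=loa_low,
                           loa_high=loa_high, inside_loa_fraction=inside,
                           n=int(x.size))
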