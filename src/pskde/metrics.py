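"""Segmentation evaluation metrics, training losses, and the Welch t-test.

Count-based metrics (IoU/Jaccard, Dice/F1, precision, recall, accuracy)
are computed from pixel confusion counts between a ground-truth mask and a
thresholded prediction.  Dice is the harmonic mean of precision and recall
and relates to IoU by D = 2J/(1+J).  When a metric's denominator is zero
(e.g. both masks empty) the metric is defined as 1, making every metric a
total function — a region that is correctly predicted absent is a perfect
prediction.

Soft losses operate on probability maps: binary cross-entropy with
probability clipping at 1e-7, soft-Jaccard loss 1 - soft-IoU and soft-Dice
loss 1 - soft-Dice with a 1e-7 smoothing constant, and their sum BCE+JCD.

Per-image metrics are aggregated as mean and sample standard deviation
(n-1 denominator), and two methods are compared with the unequal-variance
(Welch) two-sample t-test with Welch–Satterthwaite degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .images import validate_mask

#: Probability clipping bound for BCE and smoothing constant for soft losses.
EPS = 1e-7

METRIC_NAMES = ("Accuracy", "Dice", "IoU", "Precision", "Recall")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level confusion counts; tp+fp+fn+tn equals the pixel count."""

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


def confusion(gt: np.ndarray, pr_mask: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts between two binary masks."""
    gt = validate_mask(gt)
    pr = validate_mask(pr_mask)
    if gt.shape != pr.shape:
        raise ValueError("image/mask shape mismatch")
    gtb = gt.astype(bool)
    prb = pr.astype(bool)
    tp = int(np.count_nonzero(gtb & prb))
    fp = int(np.count_nonzero(~gtb & prb))
    fn = int(np.count_nonzero(gtb & ~prb))
    tn = int(np.count_nonzero(~gtb & ~prb))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, den: float) -> float:
    return 1.0 if den == 0 else num / den


def iou(c: ConfusionCounts) -> float:
    """Intersection over union (Jaccard index): tp / (tp + fp + fn)."""
    return _ratio(c.tp, c.tp + c.fp + c.fn)


def dice(c: ConfusionCounts) -> float:
    """Dice / F1 coefficient: 2 tp / (2 tp + fp + fn)."""
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn)


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.total)


def all_metrics(c: ConfusionCounts) -> dict[str, float]:
    """The five reported metrics keyed by their standard names."""
    return {
        "Accuracy": accuracy(c),
        "Dice": dice(c),
        "IoU": iou(c),
        "Precision": precision(c),
        "Recall": recall(c),
    }


def _check_prob_pair(gt: np.ndarray, pr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gt = validate_mask(gt).astype(np.float64)
    pr = np.asarray(pr, dtype=np.float64)
    if gt.shape != pr.shape:
        raise ValueError("image/mask shape mismatch")
    if not np.all(np.isfinite(pr)) or pr.min() < 0.0 or pr.max() > 1.0:
        raise ValueError("probability map values outside [0, 1]")
    return gt, pr


def bce_loss(gt: np.ndarray, pr: np.ndarray) -> float:
    """Mean binary cross-entropy with probabilities clipped to [1e-7, 1-1e-7]."""
    gt, pr = _check_prob_pair(gt, pr)
    p = np.clip(pr, EPS, 1.0 - EPS)
    return float(np.mean(-gt * np.log(p) - (1.0 - gt) * np.log(1.0 - p)))


def jaccard_loss(gt: np.ndarray, pr: np.ndarray) -> float:
    """1 - soft-IoU with 1e-7 smoothing in numerator and denominator."""
    gt, pr = _check_prob_pair(gt, pr)
    inter = float(np.sum(gt * pr))
    union = float(np.sum(gt) + np.sum(pr) - inter)
    return 1.0 - (inter + EPS) / (union + EPS)


def dice_loss(gt: np.ndarray, pr: np.ndarray) -> float:
    """1 - soft-Dice with 1e-7 smoothing in numerator and denominator."""
    gt, pr = _check_prob_pair(gt, pr)
    inter = float(np.sum(gt * pr))
    total = float(np.sum(gt) + np.sum(pr))
    return 1.0 - (2.0 * inter + EPS) / (total + EPS)


def bce_jcd_loss(gt: np.ndarray, pr: np.ndarray) -> float:
    """Binary cross-entropy plus soft-Jaccard loss."""
    return bce_loss(gt, pr) + jaccard_loss(gt, pr)


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns ``(t, df, p)`` with the Welch statistic, Welch–Satterthwaite
    degrees of freedom and two-sided p-value.  Requires at least two
    values and positive variance in each sample.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("degenerate sample")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va <= 0.0 or vb <= 0.0:
        raise ValueError("degenerate sample")
    na, nb = a.size, b.size
    se2a, se2b = va / na, vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def aggregate_report(
    per_image_metrics: Sequence[Mapping[str, float]],
    region_label: str,
    method_label: str,
) -> pd.DataFrame:
    """Aggregate per-image metric dicts into a mean(SD) report.

    One row per metric with columns region, method, metric, mean, sd, n;
    sd uses the n-1 denominator and is reported as 0 for a single image.
    Rows are ordered by (region, method, metric).
    """
    if len(per_image_metrics) == 0:
        raise ValueError("no images evaluated")
    frame = pd.DataFrame(list(per_image_metrics))
    rows = []
    for metric in sorted(frame.columns):
        vals = frame[metric].to_numpy(dtype=np.float64)
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        rows.append(
            {
                "region": region_label,
                "method": method_label,
                "metric": metric,
                "mean": float(vals.mean()),
                "sd": sd,
                "n": int(vals.size),
            }
        )
    report = pd.DataFrame(rows)
    return report.sort_values(["region", "method", "metric"], ignore_index=True)
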