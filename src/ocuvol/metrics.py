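"""Method-comparison statistics: Corr/MAE/MSE, Dice/IoU, Bland-Altman.

Paired comparison of estimated against reference volumes (both in cc)
reports the correlation coefficient, mean absolute error, mean squared
error, and Bland-Altman agreement: the mean difference and the 95% limits
of agreement mean +/- 1.96 * sd of the differences (sample sd, n-1).
Differences are signed estimate - reference, so a negative mean difference
means systematic underestimation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger("ocuvol")

#: Two-sided 95% normal quantile used for limits of agreement.
LOA_FACTOR = 1.96


@dataclass(frozen=True)
class EvaluationReport:
    """Paired-comparison statistics for one method over one cohort.

    ``corr`` is NaN when either vector has zero variance (correlation is
    undefined there, not zero).  Volumes in cc, so mae is cc and mse cc^2.
    """

    corr: float
    mae: float
    mse: float
    n: int
    mean_diff: float
    loa_lower: float
    loa_upper: float
    group_label: str | None = None

    def __post_init__(self) -> None:
        if not math.isnan(self.corr) and not -1.0 <= self.corr <= 1.000000001:
            raise ValueError("correlation out of [-1, 1]")
        if self.mae < 0 or self.mse < 0:
            raise ValueError("errors must be non-negative")
        if not self.loa_lower <= self.mean_diff <= self.loa_upper:
            raise ValueError("limits of agreement must bracket the mean difference")

    def to_dict(self) -> dict:
        return {
            "corr": self.corr, "mae": self.mae, "mse": self.mse, "n": self.n,
            "mean_diff": self.mean_diff,
            "loa_lower": self.loa_lower, "loa_upper": self.loa_upper,
            "group_label": self.group_label,
        }


def paired_stats(
    estimates: Sequence[float],
    references: Sequence[float],
    corr_method: str = "pearson",
    group_label: str | None = None,
) -> EvaluationReport:
    """Corr, MAE, MSE and Bland-Altman agreement for paired volumes (cc)."""
    est = np.asarray(estimates, dtype=np.float64)
    ref = np.asarray(references, dtype=np.float64)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("estimates and references must be equal-length 1-D vectors")
    n = est.size
    if n < 2:
        raise ValueError("need at least 2 pairs")

    if est.std() == 0 or ref.std() == 0:
        logger.warning("zero variance in a vector: correlation undefined, reported as NaN")
        corr = float("nan")
    elif corr_method == "pearson":
        corr = float(stats.pearsonr(est, ref).statistic)
    elif corr_method == "spearman":
        corr = float(stats.spearmanr(est, ref).statistic)
    else:
        raise ValueError(f"unknown correlation method {corr_method!r}")

    diff = est - ref
    mae = float(np.mean(np.abs(diff)))
    mse = float(np.mean(diff**2))
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return EvaluationReport(
        corr=corr, mae=mae, mse=mse, n=n,
        mean_diff=mean_diff,
        loa_lower=mean_diff - LOA_FACTOR * sd,
        loa_upper=mean_diff + LOA_FACTOR * sd,
        group_label=group_label,
    )


def dice_iou(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[float, float]:
    """Dice coefficient and intersection-over-union of two binary masks.

    Two empty masks agree perfectly on absence: both scores are 1.0 by
    convention (conventions differ across toolkits; this one is symmetric
    with the identical-nonempty case).
    """
    a = np.asarray(mask_a) > 0
    b = np.asarray(mask_b) > 0
    if a.shape != b.shape:
        raise ValueError(f"mask dimensions differ: {a.shape} vs {b.shape}")
    inter = int(np.logical_and(a, b).sum())
    size_sum = int(a.sum()) + int(b.sum())
    union = size_sum - inter
    if size_sum == 0:
        return 1.0, 1.0
    dice = 2.0 * inter / size_sum
    iou = inter / union if union else 1.0
    return dice, iou


def grouped_errors(
    errors: Sequence[float],
    labels: Sequence[str],
) -> dict[str, dict]:
    """Five-number box-plot summaries of volume errors per group (cc).

    Quartiles use linear interpolation; whiskers extend to the most extreme
    points within 1.5 * IQR of the quartiles; points beyond are listed as
    outliers.  Groups present in ``labels`` but empty of data are omitted
    with a warning.
    """
    errors = np.asarray(errors, dtype=np.float64)
    labels = list(labels)
    if len(labels) != errors.size:
        raise ValueError("labels must cover all subjects")
    out: dict[str, dict] = {}
    for group in dict.fromkeys(labels):  # preserve first-seen order
        vals = errors[[i for i, g in enumerate(labels) if g == group]]
        if vals.size == 0:
            logger.warning("group %r is empty; omitted from summary", group)
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        out[group] = {
            "n": int(vals.size),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(inside.min()),
            "whisker_high": float(inside.max()),
            "outliers": sorted(float(v) for v in vals[(vals < lo_fence) | (vals > hi_fence)]),
        }
    return out
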