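"""Downstream evaluation: SoS contrast, RMSE, ROC/AUC, and the rank-sum test.

The differential-diagnosis statistic is the SoS contrast
``delta_c = |median(c_inc) - median(c_bkg)|`` between the inclusion and the
same 5 mm background ring used for relative uncertainty; carcinoma (CA) is
the positive class and is assumed to show the larger contrast.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import scipy.stats
import sklearn.metrics

from .geometry import ImagingGrid
from .maps import SoSMap
from .selection import ring_background_mask


@dataclasses.dataclass
class ContrastResult:
    """Median-based inclusion/background SoS contrast (m/s)."""

    delta_c: float
    c_inc_median: float
    c_bkg_median: float


def sos_contrast(
    c: SoSMap, inclusion: np.ndarray, grid: ImagingGrid, ring_mm: float = 5.0
) -> ContrastResult:
    """|median inclusion SoS - median ring-background SoS|."""
    inclusion = np.asarray(inclusion, dtype=bool)
    if c.values.shape != grid.shape:
        raise ValueError("SoS map and grid shapes differ")
    ring = ring_background_mask(inclusion, grid, ring_mm)
    if not ring.any():
        raise ValueError("ring background mask is empty")
    ci = float(np.median(c.values[inclusion]))
    cb = float(np.median(c.values[ring]))
    return ContrastResult(delta_c=abs(ci - cb), c_inc_median=ci, c_bkg_median=cb)


def rmse(c_hat: SoSMap, c_gt: SoSMap) -> float:
    """Root-mean-square error over all pixels (m/s)."""
    if c_hat.values.shape != c_gt.values.shape:
        raise ValueError("SoS maps must share a grid")
    diff = c_hat.values - c_gt.values
    return float(np.sqrt(np.mean(diff * diff)))


@dataclasses.dataclass
class ClassificationReport:
    """ROC summary at the operating point maximizing sensitivity + specificity."""

    auc: float
    f1: float
    sensitivity: float
    specificity: float
    threshold: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray


def roc_auc(scores, labels) -> ClassificationReport:
    """ROC/AUC for contrast scores; higher score means more likely CA (label 1).

    AUC uses the rank statistic (ties at half credit); the operating point is
    the threshold maximizing sensitivity + specificity, lowest threshold on
    ties; predictions at the operating point are ``score >= threshold``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = sklearn.metrics.roc_curve(labels, scores)
    auc = float(sklearn.metrics.roc_auc_score(labels, scores))
    youden = tpr + (1.0 - fpr)
    # thresholds are descending; among ties pick the lowest threshold (last argmax)
    best = len(youden) - 1 - int(np.argmax(youden[::-1]))
    thr = float(thresholds[best])
    pred = scores >= thr
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    f1 = tp / (tp + 0.5 * (fp + fn)) if tp + fp + fn > 0 else 0.0
    return ClassificationReport(
        auc=auc,
        f1=float(f1),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        threshold=thr,
        roc_fpr=fpr,
        roc_tpr=tpr,
    )


@dataclasses.dataclass
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first group
    p_value: float
    method: str


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact null over all rank assignments (midranks for ties)."""
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    n1 = len(a)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    us = np.array(
        [
            sum(ranks[list(c)]) - n1 * (n1 + 1) / 2.0
            for c in itertools.combinations(range(len(pooled)), n1)
        ]
    )
    lo = float(np.mean(us <= u_obs + 1e-12))
    hi = float(np.mean(us >= u_obs - 1e-12))
    return u_obs, min(1.0, 2.0 * min(lo, hi))


def rank_sum_test(group_a, group_b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) between unpaired groups.

    Exact null (enumerated over rank assignments, handling ties by midranks)
    for combined n <= 12; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if len(a) + len(b) <= 12:
        u, p = _exact_ranksum_p(a, b)
        return RankSumResult(statistic=u, p_value=p, method="exact")
    res = scipy.stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return RankSumResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), method="asymptotic"
    )
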