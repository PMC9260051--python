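"""Evaluation metrics: nRMSE, Bland-Altman agreement, variability, regression."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["NrmseResult", "BlandAltmanResult", "nrmse", "bland_altman",
           "variability_stats", "regression"]


@dataclass
class NrmseResult:
    value_pct: float
    n_voxels: int


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float


def nrmse(estimate: np.ndarray, truth: np.ndarray, mask: np.ndarray) -> NrmseResult:
    """Normalized RMS error in percent over the masked voxels:
    100 * ||(estimate - truth)[mask]|| / ||truth[mask]||."""
    estimate = np.asarray(estimate)
    truth = np.asarray(truth)
    mask = np.asarray(mask, bool)
    if estimate.shape != truth.shape or mask.shape != truth.shape:
        raise ValueError("shape mismatch")
    if not mask.any():
        raise ValueError("empty mask")
    e = estimate[mask]
    t = truth[mask]
    denom = np.linalg.norm(t)
    if denom == 0:
        raise ValueError("all-zero truth over mask: nRMSE undefined")
    return NrmseResult(value_pct=100.0 * float(np.linalg.norm(e - t) / denom),
                       n_voxels=int(mask.sum()))


def bland_altman(a, b) -> BlandAltmanResult:
    """Agreement between two measurement series: bias = mean(b - a),
    95% limits of agreement = bias +/- 1.96 * sample SD of differences."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = b - a
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(bias=bias, loa_low=bias - 1.96 * sd,
                             loa_high=bias + 1.96 * sd)


def variability_stats(per_subject_values):
    """(intersubject, intrasubject) variability from per-subject (mean, sd)
    pairs: SD of the means over subjects, and mean of the SDs."""
    vals = list(per_subject_values)
    if len(vals) < 2:
        raise ValueError("need at least two subjects")
    means = np.array([m for m, _ in vals], float)
    sds = np.array([s for _, s in vals], float)
    return float(np.std(means, ddof=1)), float(np.mean(sds))


def regression(x, y):
    """Linear regression of ROI means: returns (slope, intercept, r_squared)."""
    res = stats.linregress(np.asarray(x, float), np.asarray(y, float))
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
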