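"""Shared statistics and imaging metrics.

Generalized polarization for ratiometric membrane-order imaging, Welch's
unequal-variance t-test, the Holm-Sidak step-down multiple-testing
correction, and Akaike/Bayesian information criteria.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def gp_image(I_low: np.ndarray, I_high: np.ndarray) -> np.ma.MaskedArray:
    """Generalized polarization map, GP = (I_L - I_H) / (I_L + I_H).

    ``I_low`` is the short-wavelength (ordered-phase) emission band and
    ``I_high`` the long-wavelength band.  Pixels where both intensities
    are zero are masked (GP undefined).  Values lie in [-1, 1] for
    non-negative inputs.
    """
    I_low = np.asarray(I_low, dtype=float)
    I_high = np.asarray(I_high, dtype=float)
    if I_low.shape != I_high.shape:
        raise ValueError("intensity arrays must share a shape")
    if (I_low < 0).any() or (I_high < 0).any():
        raise ValueError("intensities must be non-negative")
    total = I_low + I_high
    mask = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        gp = np.where(mask, 0.0, (I_low - I_high) / np.where(mask, 1.0, total))
    return np.ma.MaskedArray(gp, mask=mask)


def gp_region_mean(gp: np.ma.MaskedArray, region_mask: np.ndarray) -> float:
    """Mean GP over an externally supplied binary region mask.

    Pixels where GP is undefined (zero total intensity) are ignored.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != gp.shape:
        raise ValueError("region mask must match the GP map shape")
    vals = gp[region_mask].compressed()
    if vals.size == 0:
        raise ValueError("region contains no defined GP pixels")
    return float(vals.mean())


def welch_t(sampleA: np.ndarray, sampleB: np.ndarray) -> tuple[float, float]:
    """Welch's two-sided unequal-variance t-test: (t statistic, p-value)."""
    a = np.asarray(sampleA, dtype=float)
    b = np.asarray(sampleB, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero variance in both samples: t undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def holm_sidak(p_values, alpha: float = 0.05) -> dict:
    """Holm-Sidak step-down multiple-testing correction.

    Sorted p-values p_(1) <= ... <= p_(m) are compared in turn with the
    stage-wise levels ``1 - (1 - alpha)^(1/(m - i + 1))``; once one test
    fails, all later (larger) p-values fail too.  Returns per-hypothesis
    rejections (input order), the stage levels, and Sidak-adjusted
    p-values ``1 - (1 - p)^(m - i + 1)`` made monotone.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    levels = 1.0 - (1.0 - alpha) ** (1.0 / (m - np.arange(m)))
    reject_sorted = np.zeros(m, dtype=bool)
    failed = False
    adj_sorted = np.empty(m)
    running_max = 0.0
    for i, idx in enumerate(order):
        adj = 1.0 - (1.0 - p[idx]) ** (m - i)
        running_max = max(running_max, adj)
        adj_sorted[i] = min(running_max, 1.0)
        if not failed and p[idx] <= levels[i]:
            reject_sorted[i] = True
        else:
            failed = True
    reject = np.zeros(m, dtype=bool)
    adjusted = np.empty(m)
    reject[order] = reject_sorted
    adjusted[order] = adj_sorted
    return {"reject": reject, "adjusted_p": adjusted, "levels": levels, "alpha": alpha}


def information_criteria(log_likelihood: float, k_params: int, n_obs: int) -> tuple[float, float]:
    """(AIC, BIC) = (2k - 2 logL, k ln n - 2 logL)."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    aic = 2.0 * k_params - 2.0 * log_likelihood
    bic = k_params * np.log(n_obs) - 2.0 * log_likelihood
    return float(aic), float(bic)
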