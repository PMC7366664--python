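"""Statistical layer: two-tailed t tests with Hedges' g effect sizes,
Bonferroni thresholds, and map z-scoring."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "one_sample_t", "two_sample_t_hedges",
           "bonferroni_threshold", "zscore_map"]


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    effect_size: float  # Hedges' g where applicable
    n: tuple


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    """Two-tailed single-sample Student's t test against ``mu0``.

    Effect size is the one-sample Hedges' g, (mean - mu0)/sd corrected by
    J = 1 - 3/(4*df - 1).
    """
    x = np.asarray(values, float)
    if x.size < 2 or not np.isfinite(x).all():
        raise ValueError("need n >= 2 finite values")
    if x.std(ddof=1) == 0:
        raise ValueError("zero variance")
    res = sps.ttest_1samp(x, mu0)
    df = x.size - 1
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * (x.mean() - mu0) / x.std(ddof=1)
    return TestResult(float(res.statistic), float(df), float(res.pvalue),
                      float(g), (x.size,))


def two_sample_t_hedges(a, b, welch: bool = False) -> TestResult:
    """Unpaired two-tailed two-sample t test with Hedges' g.

    The default pooled-variance (Student) form matches the pooling used by
    g = (mean_a - mean_b)/s_pooled * J, with the small-sample correction
    J = 1 - 3/(4*(n_a + n_b) - 9); Welch's test is available via ``welch``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 in both groups")
    na, nb = a.size, b.size
    s_pooled = math.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                         / (na + nb - 2))
    if s_pooled == 0:
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = res.df if hasattr(res, "df") else na + nb - 2
    j = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    g = j * (a.mean() - b.mean()) / s_pooled
    return TestResult(float(res.statistic), float(df), float(res.pvalue),
                      float(g), (na, nb))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted significance threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def zscore_map(pixel_map: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """z-score a map over the masked finite pixels (subtract their mean,
    divide by their s.d.); used to compare maps across sessions. Zero s.d.
    yields an all-NaN map."""
    pixel_map = np.asarray(pixel_map, float)
    if mask is None:
        mask = np.ones(pixel_map.shape, bool)
    sel = mask & np.isfinite(pixel_map)
    if sel.sum() < 2:
        raise ValueError("need at least 2 finite masked values")
    mu = pixel_map[sel].mean()
    sd = pixel_map[sel].std()
    if sd == 0:
        return np.full_like(pixel_map, np.nan)
    out = np.full_like(pixel_map, np.nan)
    out[sel] = (pixel_map[sel] - mu) / sd
    return out
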