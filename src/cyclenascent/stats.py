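"""Statistical primitives: tie-aware Mann-Whitney U and BH FDR.

The exact Mann-Whitney path enumerates group labelings directly (so ties
are handled exactly, which the textbook Wilcoxon null distribution does
not); it is used whenever the smaller group has <= 8 observations and the
enumeration is affordable. Tie-free inputs of any size with a small group
fall back to the exact Wilcoxon distribution, everything else to the
tie-corrected normal approximation (both via scipy).
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_MIN_N = 8
ENUMERATION_CAP = 400_000


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample ``a``: #{pairs a > b} + 0.5 * #{ties}."""
    ranks = sps.rankdata(np.concatenate([a, b]))
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for sample a, p).

    Exact by enumeration when min(n_a, n_b) <= 8 and the number of
    labelings is manageable; exact Wilcoxon for larger tie-free inputs with
    a small group; otherwise tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney_u requires non-empty samples")
    n_a, n_b = len(a), len(b)
    u_obs = _u_statistic(a, b)
    small = min(n_a, n_b) <= EXACT_MIN_N
    if small and comb(n_a + n_b, n_a) <= ENUMERATION_CAP:
        return u_obs, _exact_p_enumeration(a, b, u_obs)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return u_obs, float(res.pvalue)


def _exact_p_enumeration(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """p = P(|U - n_a n_b / 2| >= |u_obs - n_a n_b / 2|) over all equally
    likely assignments of the pooled values to the two groups."""
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    offset = n_a * (n_a + 1) / 2
    mu = n_a * n_b / 2
    threshold = abs(u_obs - mu) - 1e-9
    total = 0
    extreme = 0
    for idx in combinations(range(n_a + n_b), n_a):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if abs(u - mu) >= threshold:
            extreme += 1
    return extreme / total


def welch_log_test(log_a: np.ndarray, log_b: np.ndarray) -> float:
    """Two-sided Welch t-test p-value on (log) replicate values.

    Degenerate zero-variance inputs return 1.0 when the means agree and
    0.0 otherwise (the test statistic is infinite).
    """
    log_a = np.asarray(log_a, dtype=float)
    log_b = np.asarray(log_b, dtype=float)
    if log_a.std(ddof=1) == 0 and log_b.std(ddof=1) == 0:
        return 1.0 if np.isclose(log_a.mean(), log_b.mean()) else 0.0
    return float(sps.ttest_ind(log_a, log_b, equal_var=False).pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up q-values: q_i = min_{j >= i} (m * p_(j) / j), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
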