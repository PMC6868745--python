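"""Rank-based two-sample testing and FDR control.

The package is deliberately rank-based throughout: every downstream decision
consumes only a direction and a significance flag, so the default two-sample
engine is a Wilcoxon rank-sum test.  For small groups the p-value is computed
by exact enumeration of group assignments (permutation null of the rank-sum
statistic, average ranks on ties); larger groups fall back to the normal
approximation with tie correction.
"""
from __future__ import annotations

import math
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

Alternative = Literal["two-sided", "greater", "less"]

#: exact enumeration is used when C(n1+n2, n1) does not exceed this
EXACT_ENUMERATION_LIMIT = 20_000

_EPS = 1e-12


def rank_sum_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """Sum of average ranks of ``x`` within the pooled sample."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ranks = rankdata(np.concatenate([x, y]))
    return float(ranks[: len(x)].sum())


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Alternative = "two-sided",
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
) -> float:
    """Wilcoxon rank-sum p-value for ``x`` vs ``y``.

    ``greater`` tests whether ``x`` tends to exceed ``y``.  Degenerate input
    (all pooled values identical) returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("rank_sum_test requires non-empty groups")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    ranks = rankdata(pooled)
    w_obs = float(ranks[:n1].sum())
    n = n1 + n2
    mean = n1 * (n + 1) / 2.0

    if math.comb(n, n1) <= exact_limit:
        return _exact_p(ranks, n1, w_obs, mean, alternative)

    # normal approximation with tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (n * (n - 1)))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (w_obs - mean) / math.sqrt(var)
    if alternative == "two-sided":
        return float(2 * norm.sf(abs(z)))
    if alternative == "greater":
        return float(norm.sf(z))
    return float(norm.cdf(z))


def _exact_p(
    ranks: np.ndarray, n1: int, w_obs: float, mean: float, alternative: Alternative
) -> float:
    total = 0
    hits = 0
    if alternative == "two-sided":
        thr = abs(w_obs - mean) - _EPS
        for idx in combinations(range(len(ranks)), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mean) >= thr:
                hits += 1
    elif alternative == "greater":
        thr = w_obs - _EPS
        for idx in combinations(range(len(ranks)), n1):
            total += 1
            if ranks[list(idx)].sum() >= thr:
                hits += 1
    else:
        thr = w_obs + _EPS
        for idx in combinations(range(len(ranks)), n1):
            total += 1
            if ranks[list(idx)].sum() <= thr:
                hits += 1
    return hits / total


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
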