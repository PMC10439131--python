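"""Shared statistical primitives.

The rank-sum test mirrors the convention used throughout the pipeline:
midranks for ties, exact enumeration of the rank-sum null when both
groups have at most eight observations, and the tie-corrected normal
approximation with continuity correction otherwise.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, floor

import numpy as np
from scipy import stats

EXACT_MAX_N = 8


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(statistic, pvalue)`` where the statistic is the rank sum
    of ``x`` in the pooled midranked sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    if np.all(pooled == pooled[0]):
        return w, 1.0
    if max(x.size, y.size) <= EXACT_MAX_N:
        return w, _exact_rank_sum_p(ranks, x.size, w)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return w, float(res.pvalue)


def _exact_rank_sum_p(ranks: np.ndarray, n_x: int, w_obs: float) -> float:
    """Exact two-sided p by enumerating all group assignments of the
    pooled midranks (valid with ties)."""
    n = ranks.size
    mu = n_x * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    hits = 0
    for idx in combinations(range(n), n_x):
        w = ranks[list(idx)].sum()
        if abs(w - mu) >= dev - 1e-12:
            hits += 1
    return hits / comb(n, n_x)


def rank_sum_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise two-sided rank-sum p-values for ``a`` (n_a x g) vs
    ``b`` (n_b x g), tie-corrected normal approximation."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", axis=0
        )
    p = np.asarray(res.pvalue, dtype=float)
    # columns that are entirely tied carry no evidence
    constant = np.ptp(np.vstack([a, b]), axis=0) == 0
    p[constant | np.isnan(p)] = 1.0
    return p


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, p * m)``; ``m`` defaults to the
    number of p-values supplied."""
    p = np.asarray(pvals, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(1.0, p * m)


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(1.0, adj)
    return out


def trimmed_mean(values, trim: float = 0.1) -> float:
    """Symmetric trimmed mean dropping ``floor(trim * n)`` values from
    each tail of the sorted sample."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    k = floor(trim * v.size)
    if 2 * k >= v.size:
        raise ValueError("trim removes every observation")
    return float(v[k : v.size - k].mean())
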