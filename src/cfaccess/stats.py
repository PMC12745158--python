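"""Exact nonparametric tests used throughout the pipeline.

The Wilcoxon signed-rank and rank-sum p-values are computed from the exact
null distribution of the rank statistic (dynamic programming over doubled
ranks, so midranks from ties stay integral) up to a size cutoff, and from a
normal approximation with tie correction and continuity correction above it.
Zero differences are dropped before ranking (Wilcoxon's original treatment),
which keeps the exact enumeration well-defined.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def _dp_signed_rank_tail(scaled_ranks: np.ndarray, w_obs: float, tail: str) -> float:
    """P(W+ >= w) or P(W+ <= w) for sign-flip null over given (doubled) ranks."""
    total = int(scaled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in scaled_ranks:
        nxt = 0.5 * dist
        nxt[r:] += 0.5 * dist[: total + 1 - r]
        dist = nxt
    w = np.arange(total + 1)
    eps = 1e-9
    if tail == "ge":
        return float(dist[w >= w_obs - eps].sum())
    return float(dist[w <= w_obs + eps].sum())


def signed_rank_test(
    diffs, alternative: str = "greater", exact_max_n: int = 200
) -> tuple[float, int]:
    """One-sample Wilcoxon signed-rank test on paired differences.

    Returns (p, n_used) where n_used counts nonzero differences. With no
    nonzero differences the test is vacuous and p = 1. `alternative`
    "greater" tests for a positive location shift (W+ large).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0, 0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        scaled = np.round(2 * ranks).astype(int)
        w2 = 2 * w_plus
        if alternative == "greater":
            p = _dp_signed_rank_tail(scaled, w2, "ge")
        elif alternative == "less":
            p = _dp_signed_rank_tail(scaled, w2, "le")
        else:
            p = min(
                1.0,
                2
                * min(
                    _dp_signed_rank_tail(scaled, w2, "ge"),
                    _dp_signed_rank_tail(scaled, w2, "le"),
                ),
            )
        return min(p, 1.0), n
    # Normal approximation with tie correction.
    mu = n * (n + 1) / 4
    tie_term = sum(t**3 - t for t in np.unique(ranks, return_counts=True)[1])
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24 - tie_term / 48)
    if alternative == "greater":
        z = (w_plus - mu - 0.5) / sigma
        return float(sps.norm.sf(z)), n
    if alternative == "less":
        z = (w_plus - mu + 0.5) / sigma
        return float(sps.norm.cdf(z)), n
    z = (w_plus - mu - np.sign(w_plus - mu) * 0.5) / sigma
    return float(min(1.0, 2 * sps.norm.sf(abs(z)))), n


def _dp_rank_sum_tail(scaled_ranks: np.ndarray, m: int, w_obs: float, tail: str) -> float:
    """Exact tail of the rank-sum of a random m-subset of the given ranks."""
    total = int(scaled_ranks.sum())
    # dp[k, s] = number of k-subsets with scaled rank sum s
    dp = np.zeros((m + 1, total + 1))
    dp[0, 0] = 1.0
    for r in scaled_ranks:
        dp[1:, r:] += dp[:-1, : total + 1 - r]
    n_subsets = dp[m].sum()
    w = np.arange(total + 1)
    eps = 1e-9
    if tail == "ge":
        return float(dp[m, w >= w_obs - eps].sum() / n_subsets)
    return float(dp[m, w <= w_obs + eps].sum() / n_subsets)


def rank_sum_test(
    x, y, alternative: str = "two-sided", exact_max_n: int = 30
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney) test of location shift between x and y.

    Exact permutation null (over which observations belong to group x) when
    n_x + n_y <= exact_max_n, ties handled with midranks; normal approximation
    with tie and continuity correction otherwise. "greater" means x tends
    larger than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    w_x = float(ranks[:n].sum())
    if n + m <= exact_max_n:
        scaled = np.round(2 * ranks).astype(int)
        w2 = 2 * w_x
        if alternative == "greater":
            return min(1.0, _dp_rank_sum_tail(scaled, n, w2, "ge"))
        if alternative == "less":
            return min(1.0, _dp_rank_sum_tail(scaled, n, w2, "le"))
        return min(
            1.0,
            2
            * min(
                _dp_rank_sum_tail(scaled, n, w2, "ge"),
                _dp_rank_sum_tail(scaled, n, w2, "le"),
            ),
        )
    mu = n * (n + m + 1) / 2
    counts = np.unique(ranks, return_counts=True)[1]
    tie_term = float(np.sum(counts**3 - counts))
    nt = n + m
    sigma = np.sqrt(n * m / 12 * (nt + 1 - tie_term / (nt * (nt - 1))))
    if alternative == "greater":
        return float(sps.norm.sf((w_x - mu - 0.5) / sigma))
    if alternative == "less":
        return float(sps.norm.cdf((w_x - mu + 0.5) / sigma))
    z = (w_x - mu - np.sign(w_x - mu) * 0.5) / sigma
    return float(min(1.0, 2 * sps.norm.sf(abs(z))))


def fisher_exact_greater(table: np.ndarray) -> tuple[float, float]:
    """One-sided (greater) Fisher exact test on a 2x2 table.

    Returns (odds_ratio, p). The odds ratio uses the Haldane-Anscombe 0.5
    correction when any cell is zero, so it is always finite.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("table must be a nonnegative 2x2 matrix")
    _, p = sps.fisher_exact(table, alternative="greater")
    t = table + 0.5 if np.any(table == 0) else table
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return float(odds), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def auc_score(scores_pos, scores_neg) -> float:
    """AUC as the rank statistic: P(random positive > random negative), ties 0.5."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def hodges_lehmann_shift(x, y) -> float:
    """Median of all pairwise differences x_i - y_j."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.median(x[:, None] - y[None, :]))
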