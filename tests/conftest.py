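"""Shared fixtures and independent brute-force oracles.

Oracles are deliberately naive (nested loops, exhaustive enumeration) and
stay independent of the library code paths they check.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import settings
from scipy.stats import rankdata

settings.register_profile("stable", derandomize=True)
settings.load_profile("stable")

from cfaccess.genomic_io import ChromSizes, GenomicInterval


@pytest.fixture
def sizes():
    return ChromSizes({"chrA": 10_000, "chrB": 5_000})


# ---------------------------------------------------------------------------
# Brute-force oracles


def oracle_count_overlaps(regions, frags, min_overlap=1):
    """All-pairs overlap count: frags is a list of (chrom, start, end, sample)."""
    samples = list(dict.fromkeys(f[3] for f in frags))
    counts = np.zeros((len(regions), len(samples)), dtype=int)
    for i, r in enumerate(regions):
        for chrom, start, end, sample in frags:
            if chrom != r.chrom:
                continue
            if min(end, r.end) - max(start, r.start) >= min_overlap:
                counts[i, samples.index(sample)] += 1
    return samples, counts


def oracle_signed_rank_p(diffs, alternative="greater"):
    """Exact signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ge = le = 0
    for signs in itertools.product([1, -1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s > 0)
        ge += w >= w_obs - 1e-9
        le += w <= w_obs + 1e-9
    total = 2**n
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2 * min(ge, le) / total)


def oracle_rank_sum_p(x, y, alternative="two-sided"):
    """Exact rank-sum p by enumerating all group assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n = len(x)
    w_obs = ranks[:n].sum()
    ge = le = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        w = ranks[list(idx)].sum()
        total += 1
        ge += w >= w_obs - 1e-9
        le += w <= w_obs + 1e-9
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2 * min(ge, le) / total)


def oracle_fisher_greater_p(table):
    """One-sided Fisher p by full hypergeometric enumeration (exact fractions)."""
    a, b = table[0]
    c, d = table[1]
    n1, k1, n = a + b, a + c, a + b + c + d
    p = Fraction(0)
    for k in range(a, min(n1, k1) + 1):
        if n1 - k > n - k1:
            continue
        p += Fraction(comb(k1, k) * comb(n - k1, n1 - k), comb(n, n1))
    return float(p)


def oracle_auc(pos, neg):
    """Concordant-pair count with half-credit ties."""
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and a.end > b.start
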