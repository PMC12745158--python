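"""Subtype-differential regions, mutation-flank comparison set, TFBS summaries.

Differential accessibility between two sample groups (e.g. low-grade glioma
vs glioblastoma plasma cfDNA) is tested per region with an exact two-sided
Wilcoxon rank-sum on log2(CPM+1), with BH adjustment across regions. A region
is significant when its raw p < alpha and |log2 fold change| exceeds the
threshold (defaults 0.05 and 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import (
    ChromSizes,
    CountMatrix,
    GenomicInterval,
    ValidationError,
)
from .stats import bh_adjust, hodges_lehmann_shift, rank_sum_test


@dataclass
class DifferentialResult:
    region: GenomicInterval
    log2fc: float  # group A over group B, on mean log2(CPM+1)
    p: float
    bh_q: float
    significant: bool


@dataclass
class TFRegionMatrix:
    """Binding-site counts: transcription factors x regions."""

    tfs: list[str]
    regions: list[GenomicInterval]
    site_counts: np.ndarray  # (n_tfs, n_regions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.site_counts,
            index=self.tfs,
            columns=[r.region_id() for r in self.regions],
        )


def normalize_cpm(matrix: CountMatrix, log2: bool = False) -> np.ndarray:
    """Counts-per-million per sample column; optionally log2(CPM + 1)."""
    totals = matrix.counts.sum(axis=0).astype(float)
    zero = [s for s, t in zip(matrix.samples, totals) if t == 0]
    if zero:
        raise ValidationError(f"all-zero count column(s) for sample(s): {zero}")
    cpm = matrix.counts / totals * 1e6
    return np.log2(cpm + 1.0) if log2 else cpm


def differential_regions(
    matrix: CountMatrix,
    groups: Mapping[str, str],
    alpha: float = 0.05,
    lfc_threshold: float = 2.0,
) -> list[DifferentialResult]:
    """Two-group differential accessibility per region.

    `groups` maps each sample to one of exactly two labels; log2fc is the
    difference of group means of log2(CPM+1) (first label minus second, labels
    sorted). p is the exact two-sided rank-sum for group sizes <= 10, else a
    normal approximation with continuity correction.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValidationError(f"need exactly 2 group labels, got {labels}")
    a_idx = [i for i, s in enumerate(matrix.samples) if groups.get(s) == labels[0]]
    b_idx = [i for i, s in enumerate(matrix.samples) if groups.get(s) == labels[1]]
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise ValidationError("each group needs >=2 samples")
    logcpm = normalize_cpm(matrix, log2=True)
    exact = max(len(a_idx), len(b_idx)) <= 10
    results: list[DifferentialResult] = []
    pvals = np.empty(len(matrix.regions))
    lfcs = np.empty(len(matrix.regions))
    for i in range(len(matrix.regions)):
        xa = logcpm[i, a_idx]
        xb = logcpm[i, b_idx]
        lfcs[i] = xa.mean() - xb.mean()
        pvals[i] = rank_sum_test(
            xa, xb, alternative="two-sided",
            exact_max_n=(len(a_idx) + len(b_idx)) if exact else 0,
        )
    qvals = bh_adjust(pvals)
    for i, region in enumerate(matrix.regions):
        sig = bool(pvals[i] < alpha and abs(lfcs[i]) > lfc_threshold)
        results.append(
            DifferentialResult(region, float(lfcs[i]), float(pvals[i]), float(qvals[i]), sig)
        )
    return results


def mutation_flank_regions(
    positions: Sequence[tuple[str, int]],
    flank: int = 90,
    sizes: ChromSizes | None = None,
    split: bool = False,
) -> list[GenomicInterval]:
    """Regions of +/- `flank` bp around point mutations.

    The default +/-90 bp gives 181-bp regions, comparable to a mono-nucleosomal
    cfDNA fragment (~167 bp). `split=True` instead emits two separate
    `flank`-bp regions, one upstream and one downstream of each position.
    """
    out: list[GenomicInterval] = []
    for chrom, pos in positions:
        length = sizes.get(chrom) if sizes else None
        if pos < 0 or (length is not None and pos >= length):
            raise ValidationError(f"position {chrom}:{pos} out of bounds")
        if split:
            if pos > 0:
                out.append(GenomicInterval(chrom, max(0, pos - flank), pos))
            end = pos + 1 + flank
            out.append(
                GenomicInterval(chrom, pos + 1, min(end, length) if length else end)
            )
        else:
            end = pos + flank + 1
            out.append(
                GenomicInterval(
                    chrom, max(0, pos - flank), min(end, length) if length else end
                )
            )
    return out


@dataclass
class RegionSetComparison:
    p: float
    median_a: float
    median_b: float
    hl_shift: float  # Hodges-Lehmann estimate of the A-minus-B shift


def compare_region_sets(counts_a, counts_b) -> RegionSetComparison:
    """Two-sided rank-sum comparison of fragment counts between two region sets."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both region-count lists must be nonempty")
    p = rank_sum_test(a, b, alternative="two-sided")
    return RegionSetComparison(
        p, float(np.median(a)), float(np.median(b)), hodges_lehmann_shift(a, b)
    )


def tfbs_region_matrix(
    tfbs: Sequence[tuple[GenomicInterval, str]],
    regions: Sequence[GenomicInterval],
) -> TFRegionMatrix:
    """Count labeled TF binding-site intervals overlapping each region (>=1 bp)."""
    for iv, label in tfbs:
        if not label:
            raise ValidationError(f"unlabeled TFBS interval {iv.region_id()}")
    tfs = sorted({label for _, label in tfbs})
    tf_idx = {t: i for i, t in enumerate(tfs)}
    counts = np.zeros((len(tfs), len(regions)), dtype=np.int64)
    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for j, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append((j, r))
    for iv, label in tfbs:
        for j, r in by_chrom.get(iv.chrom, ()):
            if iv.start < r.end and iv.end > r.start:
                counts[tf_idx[label], j] += 1
    return TFRegionMatrix(tfs, list(regions), counts)


@dataclass
class TopTFSummary:
    ranked_tfs: list[str]  # all TFs, by descending total site count
    top_k: list[str]
    per_region_fraction: np.ndarray  # NaN where a region has no sites


def top_k_tf_summary(matrix: TFRegionMatrix, k: int = 50) -> TopTFSummary:
    """Rank TFs by total binding-site count; per-region top-k site fraction.

    Ties in total count break alphabetically. Regions with zero sites have an
    undefined (NaN) fraction.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(matrix.tfs):
        warnings.warn(
            f"k={k} exceeds the {len(matrix.tfs)} available TFs; truncating",
            stacklevel=2,
        )
        k = len(matrix.tfs)
    totals = matrix.site_counts.sum(axis=1)
    order = sorted(range(len(matrix.tfs)), key=lambda i: (-totals[i], matrix.tfs[i]))
    ranked = [matrix.tfs[i] for i in order]
    top_idx = order[:k]
    all_sites = matrix.site_counts.sum(axis=0).astype(float)
    top_sites = matrix.site_counts[top_idx].sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(all_sites > 0, top_sites / all_sites, np.nan)
    return TopTFSummary(ranked, ranked[:k], frac)
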