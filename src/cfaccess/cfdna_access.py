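"""Open-chromatin calling from cfDNA fragment counts via flank-window contrast.

Bound, protein-protected open regions retain cfDNA against nuclease digestion,
so a genuinely accessible-and-protected region shows more fragments inside the
region ("Peak") than in the 500-bp windows immediately upstream ("Peak-F") and
downstream ("Peak-B"). Three layers of evidence are reported per candidate:

* a deterministic strict-dominance rule — the in-region count exceeds both
  flank counts in every sample;
* a per-region one-sided exact Wilcoxon signed-rank over the paired
  (peak, flank) counts pooled across samples, BH-adjusted across regions;
* one global pooled signed-rank over all (peak, mean-flank) pairs.

A region is *called* when the dominance rule holds and, whenever the design
permits attainable significance (>= 5 pairs, i.e. >= 3 samples), its BH q-value
is <= alpha. A Fisher exact test against a tiled-genome background quantifies
whether cfDNA support concentrates in tissue-derived peaks.
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
    FragmentsLike,
    GenomicInterval,
    ValidationError,
    count_overlaps,
    fragments_to_frame,
)
from .stats import bh_adjust, fisher_exact_greater, signed_rank_test

FLANK_WIDTH = 500


@dataclass
class FlankedRegion:
    """A candidate region plus its upstream (Peak-F) and downstream (Peak-B) windows."""

    peak: GenomicInterval
    peak_f: GenomicInterval | None
    peak_b: GenomicInterval | None
    f_ok: bool  # False when the upstream window is missing or clipped short
    b_ok: bool

    @property
    def testable(self) -> bool:
        return self.f_ok and self.b_ok


@dataclass
class OpenRegionCall:
    region: GenomicInterval
    per_sample: pd.DataFrame  # index: sample; columns: peak, flank_f, flank_b
    dominant: bool  # peak count > both flank counts in every sample
    per_region_p: float
    bh_q: float
    called: bool


@dataclass
class OpenRegionSummary:
    calls: list[OpenRegionCall]
    global_p: float
    n_pairs_global: int
    alpha: float

    @property
    def called_regions(self) -> list[GenomicInterval]:
        return [c.region for c in self.calls if c.called]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            row = {"region": c.region.region_id()}
            for sample, r in c.per_sample.iterrows():
                row[f"{sample}:peak"] = int(r["peak"])
                row[f"{sample}:flank_f"] = int(r["flank_f"])
                row[f"{sample}:flank_b"] = int(r["flank_b"])
            row.update(
                dominant=c.dominant,
                per_region_p=c.per_region_p,
                bh_q=c.bh_q,
                called=c.called,
            )
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    """Fisher 2x2 enrichment of cfDNA support among candidates vs background."""

    table: np.ndarray
    odds_ratio: float
    p: float


def make_flanks(
    region: GenomicInterval,
    flank: int = FLANK_WIDTH,
    sizes: ChromSizes | None = None,
) -> FlankedRegion:
    """Attach the immediately adjacent upstream/downstream windows of `flank` bp.

    A window clipped by a chromosome edge (or empty at flank=0) is flagged
    unusable: its counts would not be comparable at a different width, so the
    region is excluded from testing rather than tested unequally.
    """
    length = sizes.get(region.chrom) if sizes else None
    f_start = region.start - flank
    peak_f = None
    f_ok = flank > 0 and f_start >= 0
    if flank > 0 and region.start > 0:
        peak_f = GenomicInterval(region.chrom, max(0, f_start), region.start)
    if not f_ok and peak_f is not None:
        warnings.warn(
            f"upstream flank of {region.region_id()} clipped at chromosome start",
            stacklevel=2,
        )
    b_end = region.end + flank
    peak_b = None
    b_ok = flank > 0 and (length is None or b_end <= length)
    if flank > 0 and (length is None or region.end < length):
        peak_b = GenomicInterval(
            region.chrom, region.end, min(b_end, length) if length else b_end
        )
    if not b_ok and flank > 0 and peak_b is not None:
        warnings.warn(
            f"downstream flank of {region.region_id()} clipped at chromosome end",
            stacklevel=2,
        )
    return FlankedRegion(region, peak_f, peak_b, f_ok, b_ok)


def call_open_regions(
    flanked: Sequence[FlankedRegion],
    fragments: FragmentsLike,
    alpha: float = 0.05,
    samples: Sequence[str] | None = None,
) -> OpenRegionSummary:
    """Call cfDNA-supported open regions from peak-vs-flank fragment counts.

    Only regions whose flanks are full-width are tested. Counting is raw
    (not depth-normalized): the peak/flank comparison is paired within sample,
    so it is depth-invariant.
    """
    testable = [fr for fr in flanked if fr.testable]
    if not testable:
        raise ValidationError("no testable flanked regions")
    frame = fragments_to_frame(fragments)
    if len(frame) == 0:
        raise ValidationError("empty fragment input")
    if samples is None:
        samples = list(dict.fromkeys(frame["sample"]))

    # One batched count over peaks and both flanks.
    intervals: list[GenomicInterval] = []
    for fr in testable:
        intervals.extend([fr.peak, fr.peak_f, fr.peak_b])
    cm = count_overlaps(intervals, frame, samples=samples)
    counts = cm.counts.reshape(len(testable), 3, len(samples))

    pvals = []
    calls: list[OpenRegionCall] = []
    global_diffs: list[float] = []
    for i, fr in enumerate(testable):
        peak_c = counts[i, 0]
        f_c = counts[i, 1]
        b_c = counts[i, 2]
        dominant = bool(np.all(peak_c > f_c) and np.all(peak_c > b_c))
        diffs = np.concatenate([peak_c - f_c, peak_c - b_c]).astype(float)
        p, _ = signed_rank_test(diffs, alternative="greater")
        pvals.append(p)
        global_diffs.append(peak_c - (f_c + b_c) / 2.0)
        per_sample = pd.DataFrame(
            {"peak": peak_c, "flank_f": f_c, "flank_b": b_c}, index=list(samples)
        )
        calls.append(OpenRegionCall(fr.peak, per_sample, dominant, p, np.nan, False))

    qvals = bh_adjust(pvals)
    # Significance attainable when the pooled pair count can reach p <= alpha:
    # with n pairs the minimal one-sided exact p is 2^-n.
    n_pairs_design = 2 * len(samples)
    use_q_gate = 0.5**n_pairs_design <= alpha
    for c, q in zip(calls, qvals):
        c.bh_q = float(q)
        c.called = c.dominant and ((q <= alpha) if use_q_gate else True)

    pooled = np.concatenate(global_diffs)
    global_p, n_used = signed_rank_test(pooled, alternative="greater")
    return OpenRegionSummary(calls, global_p, n_used, alpha)


def background_windows(
    tiles: Sequence[GenomicInterval],
    tissue_peaks: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Genome tiles with zero overlap with any tissue-derived peak."""
    from .tissue_peaks import _interval_arrays, _overlaps_any

    arrays = _interval_arrays(tissue_peaks)
    return [t for t in tiles if not _overlaps_any(t, arrays)]


def overlap_enrichment(
    candidate_called: int,
    candidate_total: int,
    background_called: int,
    background_total: int,
) -> EnrichmentResult:
    """One-sided Fisher exact test: is cfDNA support enriched among candidates?

    The 2x2 table is [[called, not-called] x [candidate, background]]; the
    alternative is "greater" because the hypothesis — cfDNA support
    concentrates in tissue-derived open regions — is directional.
    """
    if candidate_total <= 0 or background_total <= 0:
        raise ValidationError("stratum totals must be positive")
    if candidate_called > candidate_total or background_called > background_total:
        raise ValidationError("called count exceeds stratum total")
    table = np.array(
        [
            [candidate_called, candidate_total - candidate_called],
            [background_called, background_total - background_called],
        ]
    )
    odds, p = fisher_exact_greater(table)
    return EnrichmentResult(table, odds, p)
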