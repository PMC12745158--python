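"""Unified tissue peak-set construction and cross-sample diversity measures.

The unified set follows the iterative-overlap procedure used for ATAC-seq
union peak sets: every peak is standardized to 501 bp around its summit,
blacklist overlappers are dropped, and a greedy pass retains the most
significant peak while deleting everything it overlaps, repeating until no
peaks remain. The result is a non-overlapping, fixed-width peak set in which
every deleted peak lost to an overlapping peak of at least its significance.

Diversity measures: the common/specific partition (a peak is common when any
other sample has an overlapping peak), regions shared by *all* samples, the
per-window coefficient of variation of peak counts, and genomic feature
annotation with a fixed priority order.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .genomic_io import ChromSizes, GenomicInterval, Peak, ValidationError


@dataclass
class PeakSet:
    """Non-overlapping, width-standardized peaks with contributing samples."""

    peaks: list[Peak]
    provenance: list[str] = field(default_factory=list)

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]


@dataclass
class WindowCV:
    """Per-window peak-count dispersion across samples (CV = sd / mean)."""

    window: GenomicInterval
    per_sample_counts: dict[str, int]
    cv: float  # NaN when mean count is 0


@dataclass
class RegionAnnotation:
    region: GenomicInterval
    feature: str  # Promoter | Exon | Intron | Downstream | DistalIntergenic
    nearest_gene: str


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: strand-aware TSS plus optional exon structure."""

    gene: str
    chrom: str
    strand: str
    start: int  # gene body start (0-based)
    end: int  # gene body end (exclusive)
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"unknown strand symbol {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end: last base of the gene body, strand-aware."""
        return self.end - 1 if self.strand == "+" else self.start


def read_gene_models(path: Union[str, Path]) -> list[GeneModel]:
    """Read gene models from BED12 or a minimal 5-column TSV.

    BED12 block fields become exons. The minimal TSV has columns
    gene, chrom, strand, start, end (no exon structure -> whole body exonic).
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) >= 12:  # BED12
                start, end = int(f[1]), int(f[2])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offs = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = tuple((start + o, start + o + s) for o, s in zip(offs, sizes))
                genes.append(GeneModel(f[3], f[0], f[5], start, end, exons))
            else:
                gene, chrom, strand, start, end = f[:5]
                s, e = int(start), int(end)
                genes.append(GeneModel(gene, chrom, strand, s, e, ((s, e),)))
    return genes


# ---------------------------------------------------------------------------


def extend_summits(
    peaks: Sequence[Peak], flank: int = 250, sizes: ChromSizes | None = None
) -> list[Peak]:
    """Standardize peaks to [summit - flank, summit + flank + 1), clipped.

    The default flank of 250 bp yields 501-bp peaks, wider than a typical
    mono-nucleosomal cfDNA fragment so a region can hold several fragments.
    """
    out: list[Peak] = []
    for p in peaks:
        length = sizes.get(p.interval.chrom) if sizes else None
        if length is not None and not (0 <= p.summit < length):
            raise ValidationError(
                f"summit {p.summit} outside chromosome {p.interval.chrom}"
            )
        start = max(0, p.summit - flank)
        end = p.summit + flank + 1
        if length is not None:
            end = min(end, length)
        out.append(
            Peak(
                GenomicInterval(p.interval.chrom, start, end),
                p.summit,
                p.neglog10_p,
                name=p.name,
                sample=p.sample,
            )
        )
    return out


def _interval_arrays(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        starts = np.array([p[0] for p in pairs])
        ends = np.array([p[1] for p in pairs])
        out[chrom] = (starts, np.sort(ends))
    return out


def _overlaps_any(
    iv: GenomicInterval, arrays: Mapping[str, tuple[np.ndarray, np.ndarray]]
) -> bool:
    if iv.chrom not in arrays:
        return False
    starts, ends_sorted = arrays[iv.chrom]
    n = np.searchsorted(starts, iv.end, "left") - np.searchsorted(
        ends_sorted, iv.start, "right"
    )
    return n > 0


def remove_blacklisted(
    peaks: Sequence[Peak], blacklist: Sequence[GenomicInterval]
) -> list[Peak]:
    """Drop peaks overlapping any blacklist interval by >= 1 bp."""
    arrays = _interval_arrays(blacklist)
    return [p for p in peaks if not _overlaps_any(p.interval, arrays)]


def iterative_overlap_merge(peaks: Sequence[Peak]) -> PeakSet:
    """Greedy retention by descending significance.

    Equivalent to: keep the most significant peak, delete all peaks it
    overlaps, repeat. Ties in significance break by smaller start, then
    lexicographic chromosome, then name, for determinism.
    """
    order = sorted(
        peaks,
        key=lambda p: (-p.neglog10_p, p.interval.start, p.interval.chrom, p.name),
    )
    retained: list[Peak] = []
    # per-chrom sorted lists of retained (start, end) for overlap queries
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for p in order:
        iv = p.interval
        starts, ends = by_chrom.setdefault(iv.chrom, ([], []))
        n_ov = bisect_left(starts, iv.end) - bisect_right(ends, iv.start)
        if n_ov > 0:
            continue
        retained.append(p)
        insort(starts, iv.start)
        insort(ends, iv.end)
    retained.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    provenance = sorted({p.sample for p in retained if p.sample})
    return PeakSet(retained, provenance)


def partition_common_specific(
    peaksets: Mapping[str, Sequence[Peak]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label each sample's peaks common (overlaps >=1 other sample) or specific.

    Returns (per-peak labels, per-sample common/specific fractions). The two
    fractions sum to 1 per sample.
    """
    if len(peaksets) < 2:
        raise ValidationError("common/specific partition needs >=2 samples")
    arrays = {s: _interval_arrays([p.interval for p in pk]) for s, pk in peaksets.items()}
    rows = []
    for sample, pk in peaksets.items():
        others = [a for s, a in arrays.items() if s != sample]
        for p in pk:
            common = any(_overlaps_any(p.interval, a) for a in others)
            rows.append(
                (
                    sample,
                    p.interval.chrom,
                    p.interval.start,
                    p.interval.end,
                    p.name,
                    "common" if common else "specific",
                )
            )
    labels = pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "name", "label"]
    )
    frac = (
        labels.groupby("sample")["label"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=["common", "specific"], fill_value=0.0)
    )
    return labels, frac


def shared_in_all(
    peaksets: Mapping[str, Sequence[Peak]],
    unified: Sequence[GenomicInterval] | None = None,
) -> list[GenomicInterval]:
    """Unified-set regions overlapped by a peak from *every* sample.

    When `unified` is not given it is built by pooling all samples'
    peaks through the iterative-overlap merge.
    """
    if len(peaksets) < 2:
        raise ValidationError("shared_in_all needs >=2 samples")
    if unified is None:
        pooled = [p for pk in peaksets.values() for p in pk]
        unified = iterative_overlap_merge(pooled).intervals
    arrays = {s: _interval_arrays([p.interval for p in pk]) for s, pk in peaksets.items()}
    return [
        iv for iv in unified if all(_overlaps_any(iv, a) for a in arrays.values())
    ]


def window_peak_cv(
    peaksets: Mapping[str, Sequence[Peak]],
    windows: Sequence[GenomicInterval],
) -> list[WindowCV]:
    """Coefficient of variation of per-sample peak counts in each window.

    A peak is assigned to the window containing its summit. CV uses the
    sample (n-1) standard deviation over samples; NaN when the mean is 0.
    """
    win_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, w in enumerate(windows):
        win_by_chrom.setdefault(w.chrom, []).append((w.start, w.end, i))
    for chrom, ws in win_by_chrom.items():
        ws.sort()
        for (s1, e1, _), (s2, _, _) in zip(ws, ws[1:]):
            if s2 < e1:
                raise ValidationError(f"overlapping windows on {chrom}")
    samples = list(peaksets)
    counts = np.zeros((len(windows), len(samples)), dtype=int)
    for j, sample in enumerate(samples):
        for p in peaksets[sample]:
            ws = win_by_chrom.get(p.interval.chrom)
            if not ws:
                continue
            starts = [w[0] for w in ws]
            k = bisect_right(starts, p.summit) - 1
            if k >= 0 and p.summit < ws[k][1]:
                counts[ws[k][2], j] += 1
    out = []
    for i, w in enumerate(windows):
        row = counts[i]
        mean = row.mean()
        if mean == 0:
            cv = float("nan")
        elif len(row) < 2:
            cv = 0.0
        else:
            cv = float(row.std(ddof=1) / mean)
        out.append(WindowCV(w, dict(zip(samples, row.tolist())), cv))
    return out


_FEATURE_PRIORITY = ("Promoter", "Exon", "Intron", "Downstream", "DistalIntergenic")


def annotate_regions(
    regions: Sequence[GenomicInterval],
    gene_models: Sequence[GeneModel],
    promoter_flank: int = 3000,
    downstream: int = 3000,
) -> list[RegionAnnotation]:
    """Assign each region one genomic feature, tested at the region midpoint.

    Priority: Promoter (TSS +/- promoter_flank) > Exon > Intron >
    Downstream (<= `downstream` bp past the 3' end) > DistalIntergenic.
    The midpoint rule gives 501-bp regions a unique label even when they
    straddle a feature boundary. nearest_gene is the gene with the closest TSS.
    """
    out: list[RegionAnnotation] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    for region in regions:
        mid = region.midpoint
        genes = by_chrom.get(region.chrom, [])
        if not genes:
            out.append(RegionAnnotation(region, "DistalIntergenic", ""))
            continue
        nearest = min(genes, key=lambda g: (abs(g.tss - mid), g.gene))
        feature = "DistalIntergenic"
        for g in genes:
            if abs(g.tss - mid) <= promoter_flank:
                feature = "Promoter"
                break
        if feature != "Promoter":
            best = len(_FEATURE_PRIORITY) - 1
            for g in genes:
                if g.start <= mid < g.end:
                    in_exon = any(s <= mid < e for s, e in g.exons)
                    cand = 1 if in_exon else 2
                elif g.strand == "+" and g.end <= mid < g.end + downstream:
                    cand = 3
                elif g.strand == "-" and g.start - downstream <= mid < g.start:
                    cand = 3
                else:
                    continue
                best = min(best, cand)
            feature = _FEATURE_PRIORITY[best]
        out.append(RegionAnnotation(region, feature, nearest.gene))
    return out
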