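"""Genomic data model, standard-format I/O, genome tiling and fragment counting.

Coordinates are 0-based half-open (BED convention) throughout. Chromosome
name dialects ("chr1" vs "1") are never auto-translated; `check_chrom_match`
warns on mismatches because a silent mismatch yields all-zero counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(ValueError):
    """A file line could not be parsed; the message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on chromosome `chrom`."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome identifier must be nonempty")
        if self.start < 0:
            raise ValidationError(f"negative start coordinate: {self.start}")
        if self.start >= self.end:
            raise ValidationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_overlap

    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def from_region_id(cls, rid: str) -> "GenomicInterval":
        chrom, _, rest = rid.rpartition(":")
        start, _, end = rest.partition("-")
        return cls(chrom, int(start), int(end))


@dataclass(frozen=True)
class Peak:
    """A scored peak: interval plus summit (absolute coordinate) and -log10 p."""

    interval: GenomicInterval
    summit: int
    neglog10_p: float
    name: str = ""
    sample: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError(
                f"summit {self.summit} outside interval {self.interval.region_id()}"
            )
        if self.neglog10_p < 0:
            raise ValidationError("neglog10_p must be nonnegative")


class ChromSizes(dict):
    """Mapping chromosome -> length in bases."""

    def __init__(self, sizes: Mapping[str, int]):
        for chrom, length in sizes.items():
            if length <= 0:
                raise ValidationError(f"chromosome {chrom} has nonpositive length")
        super().__init__(sizes)

    def validate_interval(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self:
            raise ValidationError(f"unknown chromosome {interval.chrom}")
        if interval.end > self[interval.chrom]:
            raise ValidationError(
                f"interval {interval.region_id()} exceeds chromosome length "
                f"{self[interval.chrom]}"
            )

    @classmethod
    def read(cls, path: Union[str, Path]) -> "ChromSizes":
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise ParseError(f"{path} line {i}: expected 2 columns")
                sizes[fields[0]] = int(fields[1])
        return cls(sizes)

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for chrom, length in self.items():
                fh.write(f"{chrom}\t{length}\n")


@dataclass(frozen=True)
class FragmentRecord:
    """One cfDNA fragment interval attributed to a sample."""

    interval: GenomicInterval
    sample: str


FRAGMENT_COLUMNS = ["chrom", "start", "end", "sample"]

# Fragments are accepted either as FragmentRecord iterables or as a DataFrame
# with columns chrom/start/end/sample; the frame form is the fast path.
FragmentsLike = Union[pd.DataFrame, Iterable[FragmentRecord]]


def fragments_to_frame(fragments: FragmentsLike) -> pd.DataFrame:
    if isinstance(fragments, pd.DataFrame):
        missing = [c for c in FRAGMENT_COLUMNS if c not in fragments.columns]
        if missing:
            raise ValidationError(f"fragment frame missing columns {missing}")
        return fragments
    rows = [
        (f.interval.chrom, f.interval.start, f.interval.end, f.sample)
        for f in fragments
    ]
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


@dataclass
class CountMatrix:
    """Fragment counts: regions x samples, nonnegative integers."""

    regions: list[GenomicInterval]
    samples: list[str]
    counts: np.ndarray  # shape (n_regions, n_samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.regions)} regions x {len(self.samples)} samples"
            )
        if np.any(self.counts < 0):
            raise ValidationError("counts must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[r.region_id() for r in self.regions],
            columns=self.samples,
        )

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="region")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        regions = [GenomicInterval.from_region_id(r) for r in df.index]
        return cls(regions, list(df.columns), df.to_numpy())


# ---------------------------------------------------------------------------
# Readers / writers


def read_narrowpeak(path: Union[str, Path], sample: str = "") -> list[Peak]:
    """Read a 10-column narrowPeak (BED6+4) file into Peak records.

    Column 8 is the -log10 p-value; column 10 is the summit offset from
    start (-1 means unknown, mapped to the interval midpoint).
    """
    peaks: list[Peak] = []
    sample = sample or Path(path).stem
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 10:
                raise ParseError(f"{path} line {i}: expected 10 narrowPeak columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                neglog10_p = float(fields[7])
                offset = int(fields[9])
            except ValueError as exc:
                raise ParseError(f"{path} line {i}: {exc}") from exc
            if start < 0:
                raise ValidationError(f"{path} line {i}: negative coordinate")
            interval = GenomicInterval(fields[0], start, end)
            summit = (start + end) // 2 if offset == -1 else start + offset
            peaks.append(
                Peak(interval, summit, neglog10_p, name=fields[3], sample=sample)
            )
    return peaks


def write_narrowpeak(peaks: Sequence[Peak], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name or '.'}\t0\t.\t"
                f"0\t{p.neglog10_p:g}\t-1\t{p.summit - iv.start}\n"
            )


def read_bed(path: Union[str, Path]) -> list[GenomicInterval]:
    """Read a BED3+ file; only the first three columns are used."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path} line {i}: expected >=3 BED columns")
            try:
                intervals.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                )
            except ValidationError as exc:
                raise ValidationError(f"{path} line {i}: {exc}") from exc
            except ValueError as exc:
                raise ParseError(f"{path} line {i}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_labeled_bed(path: Union[str, Path]) -> list[tuple[GenomicInterval, str]]:
    """Read a BED file whose 4th column labels each interval (e.g. TF name)."""
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path} line {i}: expected 4 columns (BED + label)")
            out.append(
                (GenomicInterval(fields[0], int(fields[1]), int(fields[2])), fields[3])
            )
    return out


def read_fragments_bed(path: Union[str, Path], sample: str) -> pd.DataFrame:
    """Read per-sample fragment intervals into the canonical fragment frame."""
    ivs = read_bed(path)
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in ivs],
            "start": [iv.start for iv in ivs],
            "end": [iv.end for iv in ivs],
            "sample": sample,
        }
    )


def check_chrom_match(
    intervals: Iterable[GenomicInterval], sizes: ChromSizes
) -> set[str]:
    """Warn about (and return) chromosome names absent from `sizes`."""
    unmatched = {iv.chrom for iv in intervals} - set(sizes)
    if unmatched:
        warnings.warn(
            f"chromosomes not in chrom.sizes (counts there would be zero): "
            f"{sorted(unmatched)}",
            stacklevel=2,
        )
    return unmatched


# ---------------------------------------------------------------------------
# Tiling and counting


def tile_genome(sizes: ChromSizes, width: int) -> list[GenomicInterval]:
    """Partition each chromosome into left-to-right tiles of `width` bases.

    The last tile of a chromosome is truncated at the chromosome end, so the
    union of tiles covers the genome exactly.
    """
    if width <= 0:
        raise ValidationError("tile width must be positive")
    tiles: list[GenomicInterval] = []
    for chrom, length in sizes.items():
        starts = range(0, length, width)
        tiles.extend(
            GenomicInterval(chrom, s, min(s + width, length)) for s in starts
        )
    return tiles


def count_overlaps(
    regions: Sequence[GenomicInterval],
    fragments: FragmentsLike,
    min_overlap: int = 1,
    samples: Sequence[str] | None = None,
) -> CountMatrix:
    """Count fragments overlapping each region by >= `min_overlap` bases.

    A fragment overlapping two regions increments both. `samples` fixes the
    column order (and admits all-zero columns for fragment-free samples);
    by default columns follow first appearance in the fragment input.
    """
    if min_overlap <= 0:
        raise ValidationError("min_overlap must be >= 1")
    frame = fragments_to_frame(fragments)
    if samples is None:
        samples = list(dict.fromkeys(frame["sample"]))
    else:
        samples = list(samples)
    sample_idx = {s: j for j, s in enumerate(samples)}
    counts = np.zeros((len(regions), len(samples)), dtype=np.int64)

    region_by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        region_by_chrom.setdefault(r.chrom, []).append(i)

    for (sample, chrom), sub in frame.groupby(["sample", "chrom"], sort=False):
        if sample not in sample_idx or chrom not in region_by_chrom:
            continue
        j = sample_idx[sample]
        idx = region_by_chrom[chrom]
        fs = np.sort(sub["start"].to_numpy())
        fe = np.sort(sub["end"].to_numpy())
        if min_overlap == 1:
            # overlap >= 1  <=>  f.start < r.end and f.end > r.start;
            # since f.end <= r.start implies f.start < r.end, counts subtract.
            for i in idx:
                r = regions[i]
                n = np.searchsorted(fs, r.end, "left") - np.searchsorted(
                    fe, r.start, "right"
                )
                counts[i, j] = n
        else:
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            for i in idx:
                r = regions[i]
                ov = np.minimum(ends, r.end) - np.maximum(starts, r.start)
                counts[i, j] = int(np.count_nonzero(ov >= min_overlap))
    return CountMatrix(list(regions), samples, counts)
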