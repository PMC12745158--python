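"""Seeded synthetic cohorts with planted ground truth for every pipeline stage.

The generator emulates the data structure the pipeline consumes, without any
sequence-level realism:

* per-sample tissue peak calls with regions shared by all samples (summit
  jitter of +/-25 bp) and sample-specific regions;
* cfDNA fragment files whose midpoints follow a mixture of a uniform genomic
  background and extra mass on planted "protected" open regions, so the
  in-region fragment density is `protection_enrichment` times the background;
* a two-group plasma cohort with differential regions at `differential_fold`
  higher density in one group;
* a graded cohort (WHO II/III/IV) in which the same planted marker regions
  carry the fold effect in grade-IV samples.

Fragment lengths follow a truncated normal around the mono-nucleosome size
(mean 167 bp, sd 20, minimum 50). Identical config + seed reproduce
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .genomic_io import (
    ChromSizes,
    FRAGMENT_COLUMNS,
    GenomicInterval,
    Peak,
    ValidationError,
    write_bed,
    write_narrowpeak,
)

PEAK_WIDTH = 501  # standardized width after 250-bp summit extension


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults: one 10-Mb chromosome; four tissue samples (as in the discovery
    cohort); 3x fragment-density protection in bound open regions; 16 planted
    differential/marker regions among 200 analysis regions at 8-fold effect;
    grade composition 32/15/64 for WHO II/III/IV; 50,000 fragments per sample
    (about 0.8x coverage of the synthetic genome at mono-nucleosome length).
    """

    chrom_sizes: dict = field(default_factory=lambda: {"chrS": 10_000_000})
    n_tissue_samples: int = 4
    n_shared_peaks: int = 100
    n_specific_peaks: int = 20  # per sample
    n_protected: int = 50  # protected subset of the shared regions
    protection_enrichment: float = 3.0
    n_analysis_regions: int = 200
    n_differential: int = 16
    differential_fold: float = 8.0
    n_per_subtype: int = 5
    grade_composition: dict = field(
        default_factory=lambda: {"II": 32, "III": 15, "IV": 64}
    )
    fragment_length_mean: float = 167.0
    fragment_length_sd: float = 20.0
    fragment_length_min: int = 50
    depth: int = 50_000
    summit_jitter: int = 25

    def __post_init__(self) -> None:
        if self.protection_enrichment <= 0 or self.differential_fold <= 0:
            raise ValidationError("enrichment and fold must be positive")
        if self.fragment_length_min < 1:
            raise ValidationError("fragment_length_min must be >= 1")
        if min(self.n_shared_peaks, self.n_specific_peaks, self.n_protected,
               self.n_analysis_regions, self.n_differential) < 0:
            raise ValidationError("counts must be nonnegative")
        if self.n_protected > self.n_shared_peaks:
            raise ValidationError("n_protected cannot exceed n_shared_peaks")
        if self.n_differential > self.n_analysis_regions:
            raise ValidationError("n_differential cannot exceed n_analysis_regions")

    @property
    def sizes(self) -> ChromSizes:
        return ChromSizes(self.chrom_sizes)

    def tissue_sample_names(self) -> list[str]:
        return [f"tissue_{i+1}" for i in range(self.n_tissue_samples)]

    def csf_sample_names(self) -> list[str]:
        return [f"csf_{i+1}" for i in range(self.n_tissue_samples)]


@dataclass
class SimTruth:
    """Planted ground truth the recovery tests compare against."""

    shared_regions: list[GenomicInterval]
    sample_specific_regions: dict[str, list[GenomicInterval]]
    protected_regions: list[GenomicInterval]
    analysis_regions: list[GenomicInterval]
    differential_regions: list[tuple[GenomicInterval, str, float]]  # (region, group, fold)
    grade_labels: dict[str, str]
    subtype_groups: dict[str, str]
    # per-sample fragment enrichment plan: sample -> [(region, fold), ...]
    sample_enrichment: dict[str, list[tuple[GenomicInterval, float]]]


def _plan_slots(config: SimConfig, rng: np.random.Generator) -> list[GenomicInterval]:
    """Non-overlapping 501-bp regions with >=1000 bp clearance between them.

    The clearance keeps every planted region's 500-bp flank windows free of
    any other planted signal, and >=500 bp from chromosome edges.
    """
    spacing = 2500
    slots: list[tuple[str, int]] = []
    for chrom, length in config.chrom_sizes.items():
        n = (length - 1000) // spacing
        slots.extend((chrom, 500 + i * spacing) for i in range(n))
    n_needed = (
        config.n_shared_peaks
        + config.n_specific_peaks * config.n_tissue_samples
        + config.n_analysis_regions
    )
    if n_needed > len(slots):
        raise ValidationError(
            f"genome too small for {n_needed} planted regions; "
            "increase chrom_sizes"
        )
    chosen = rng.choice(len(slots), size=n_needed, replace=False)
    return [
        GenomicInterval(slots[i][0], slots[i][1], slots[i][1] + PEAK_WIDTH)
        for i in sorted(chosen)
    ]


def plan_truth(config: SimConfig, seed: int) -> SimTruth:
    """Lay out all planted regions, cohort rosters, and enrichment plans."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    regions = _plan_slots(config, rng)
    order = rng.permutation(len(regions))
    k = 0
    shared = [regions[i] for i in sorted(order[k : k + config.n_shared_peaks])]
    k += config.n_shared_peaks
    specific: dict[str, list[GenomicInterval]] = {}
    for s in config.tissue_sample_names():
        specific[s] = [
            regions[i] for i in sorted(order[k : k + config.n_specific_peaks])
        ]
        k += config.n_specific_peaks
    analysis = [
        regions[i] for i in sorted(order[k : k + config.n_analysis_regions])
    ]
    protected = shared[: config.n_protected]
    differential = [
        (r, "GBM", config.differential_fold)
        for r in analysis[: config.n_differential]
    ]

    subtype_groups: dict[str, str] = {}
    for g in ("LGG", "GBM"):
        for i in range(config.n_per_subtype):
            subtype_groups[f"plasma_{g}_{i+1}"] = g
    grade_labels: dict[str, str] = {}
    for grade in ("II", "III", "IV"):
        for i in range(config.grade_composition.get(grade, 0)):
            grade_labels[f"grade{grade}_{i+1}"] = grade

    enrichment: dict[str, list[tuple[GenomicInterval, float]]] = {}
    for s in config.csf_sample_names():
        enrichment[s] = [(r, config.protection_enrichment) for r in protected]
    for s, g in subtype_groups.items():
        enrichment[s] = [
            (r, fold) for r, grp, fold in differential if grp == g
        ]
    for s, grade in grade_labels.items():
        if grade == "IV":
            enrichment[s] = [(r, fold) for r, _, fold in differential]
        else:
            enrichment[s] = []
    return SimTruth(
        shared_regions=shared,
        sample_specific_regions=specific,
        protected_regions=protected,
        analysis_regions=analysis,
        differential_regions=differential,
        grade_labels=grade_labels,
        subtype_groups=subtype_groups,
        sample_enrichment=enrichment,
    )


def simulate_tissue_peaks(
    config: SimConfig, seed: int, truth: SimTruth | None = None
) -> tuple[dict[str, list[Peak]], SimTruth]:
    """Per-sample raw peak calls realizing the planted shared/specific layout.

    Shared regions appear in every sample with +/-`summit_jitter` bp summit
    jitter; specific regions in exactly one sample. Raw peak intervals are
    150-400 bp on each side of the summit (the pipeline standardizes them to
    501 bp); -log10 p significance scores are drawn log-uniform in [3.16, 100].
    """
    if truth is None:
        truth = plan_truth(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    peaksets: dict[str, list[Peak]] = {}
    for s in config.tissue_sample_names():
        peaks: list[Peak] = []
        own = [(r, True) for r in truth.shared_regions] + [
            (r, False) for r in truth.sample_specific_regions[s]
        ]
        for j, (region, jittered) in enumerate(own):
            center = (region.start + region.end) // 2
            summit = center
            if jittered and config.summit_jitter > 0:
                summit = center + int(
                    rng.integers(-config.summit_jitter, config.summit_jitter + 1)
                )
            left = int(rng.integers(150, 401))
            right = int(rng.integers(150, 401))
            neglog10_p = float(10 ** rng.uniform(0.5, 2.0))
            peaks.append(
                Peak(
                    GenomicInterval(region.chrom, summit - left, summit + right + 1),
                    summit,
                    neglog10_p,
                    name=f"{s}_peak{j+1}",
                    sample=s,
                )
            )
        peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
        peaksets[s] = peaks
    return peaksets, truth


def _chrom_offsets(sizes: Mapping[str, int]) -> tuple[list[str], np.ndarray]:
    chroms = list(sizes)
    lengths = np.array([sizes[c] for c in chroms], dtype=np.int64)
    return chroms, np.concatenate([[0], np.cumsum(lengths)])


def simulate_fragments(
    config: SimConfig,
    truth: SimTruth,
    sample: str,
    seed: int,
) -> pd.DataFrame:
    """Fragment intervals for one sample as a chrom/start/end/sample frame.

    Midpoints follow a mixture: uniform background over the genome plus extra
    mass on each enriched region so its total midpoint density is `fold` times
    the background. Exactly `config.depth` fragments are drawn.
    """
    enriched = truth.sample_enrichment.get(sample, [])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2, _stable_hash(sample)]))
    return _draw_fragments(config, enriched, rng, sample)


def _stable_hash(s: str) -> int:
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def _draw_fragments(
    config: SimConfig,
    enriched: Sequence[tuple[GenomicInterval, float]],
    rng: np.random.Generator,
    sample: str,
) -> pd.DataFrame:
    sizes = config.chrom_sizes
    chroms, offsets = _chrom_offsets(sizes)
    genome_len = int(offsets[-1])
    weights = [float(genome_len)] + [
        (fold - 1.0) * r.width for r, fold in enriched
    ]
    w = np.array(weights)
    n_per = rng.multinomial(config.depth, w / w.sum())

    mids = [rng.integers(0, genome_len, size=n_per[0])]
    for (region, _), n in zip(enriched, n_per[1:]):
        off = offsets[chroms.index(region.chrom)]
        mids.append(rng.integers(off + region.start, off + region.end, size=n))
    mid = np.concatenate(mids)

    a = (config.fragment_length_min - config.fragment_length_mean) / config.fragment_length_sd
    lengths = np.round(
        truncnorm.rvs(
            a,
            np.inf,
            loc=config.fragment_length_mean,
            scale=config.fragment_length_sd,
            size=mid.size,
            random_state=rng,
        )
    ).astype(np.int64)
    lengths = np.maximum(lengths, config.fragment_length_min)

    # map flat midpoints back to chromosomes
    ci = np.searchsorted(offsets, mid, side="right") - 1
    local = mid - offsets[ci]
    clen = np.array([sizes[c] for c in chroms], dtype=np.int64)[ci]
    start = local - lengths // 2
    end = start + lengths
    shift = np.where(start < 0, -start, 0) - np.where(end > clen, end - clen, 0)
    start = start + shift
    end = end + shift
    start = np.maximum(start, 0)  # guards fragments longer than the chromosome

    df = pd.DataFrame(
        {
            "chrom": np.array(chroms, dtype=object)[ci],
            "start": start,
            "end": end,
            "sample": sample,
        }
    )
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    return df[FRAGMENT_COLUMNS]


@dataclass
class SimBundle:
    """Everything one seeded cohort produces, in memory."""

    config: SimConfig
    truth: SimTruth
    tissue_peaksets: dict[str, list[Peak]]
    csf_fragments: pd.DataFrame
    subtype_fragments: pd.DataFrame
    grade_fragments: pd.DataFrame
    seed: int


def simulate_cohort(
    config: SimConfig,
    seed: int,
    out_dir: Union[str, Path, None] = None,
    force: bool = False,
    include_grade_cohort: bool = True,
) -> SimBundle:
    """Generate the full synthetic study: peaks, cfDNA fragments, labels.

    With `out_dir`, writes per-sample narrowPeak and fragment BED files, a
    sample sheet, truth BED tables, and a JSON manifest recording config and
    seed. Refuses a non-empty output directory unless `force`.
    """
    truth = plan_truth(config, seed)
    peaksets, _ = simulate_tissue_peaks(config, seed, truth=truth)

    def frames_for(samples: Sequence[str]) -> pd.DataFrame:
        parts = [simulate_fragments(config, truth, s, seed) for s in samples]
        return (
            pd.concat(parts, ignore_index=True)
            if parts
            else pd.DataFrame(columns=FRAGMENT_COLUMNS)
        )

    csf = frames_for(config.csf_sample_names())
    subtype = frames_for(sorted(truth.subtype_groups))
    grade = (
        frames_for(sorted(truth.grade_labels))
        if include_grade_cohort
        else pd.DataFrame(columns=FRAGMENT_COLUMNS)
    )
    bundle = SimBundle(config, truth, peaksets, csf, subtype, grade, seed)
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir), force)
    return bundle


def _write_bundle(bundle: SimBundle, out_dir: Path, force: bool) -> None:
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise ValidationError(
            f"output directory {out_dir} is not empty (use force=True)"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    for sample, peaks in bundle.tissue_peaksets.items():
        write_narrowpeak(peaks, out_dir / f"{sample}.narrowPeak")
    for frame, prefix in (
        (bundle.csf_fragments, "fragments"),
        (bundle.subtype_fragments, "fragments"),
        (bundle.grade_fragments, "fragments"),
    ):
        for sample, sub in frame.groupby("sample", sort=True):
            sub[["chrom", "start", "end"]].to_csv(
                out_dir / f"{prefix}_{sample}.bed", sep="\t", header=False, index=False
            )
    truth = bundle.truth
    write_bed(truth.shared_regions, out_dir / "truth_shared.bed")
    write_bed(truth.protected_regions, out_dir / "truth_protected.bed")
    write_bed(truth.analysis_regions, out_dir / "truth_analysis.bed")
    write_bed(
        [r for r, _, _ in truth.differential_regions],
        out_dir / "truth_differential.bed",
    )
    rows = []
    for s in bundle.config.csf_sample_names():
        rows.append((s, "csf", "", ""))
    for s, g in sorted(truth.subtype_groups.items()):
        rows.append((s, "plasma", g, ""))
    for s, g in sorted(truth.grade_labels.items()):
        rows.append((s, "plasma", "", g))
    pd.DataFrame(rows, columns=["sample", "fluid", "subtype", "grade"]).to_csv(
        out_dir / "sample_sheet.tsv", sep="\t", index=False
    )
    manifest = {
        "seed": bundle.seed,
        "config": {
            k: v for k, v in dataclasses.asdict(bundle.config).items()
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
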