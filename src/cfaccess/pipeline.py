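"""End-to-end pipeline drivers and recovery evaluation against planted truth.

Each function runs one stage of the study on a seeded synthetic cohort and
scores the result against the generator's ground truth: the unified peak set
and shared-region recovery, open-region calling (sensitivity, false discovery
proportion, null false-call rate, background enrichment), subtype-differential
recovery, and grade-classifier performance under planted and permuted labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cfdna_access import (
    background_windows,
    call_open_regions,
    make_flanks,
    overlap_enrichment,
)
from .genomic_io import GenomicInterval, count_overlaps, tile_genome
from .grade_classifier import build_feature_matrix, run_grade_classifier
from .subtype_differential import differential_regions
from .synthetic_data import SimConfig, SimTruth, plan_truth, simulate_fragments, simulate_tissue_peaks
from .tissue_peaks import extend_summits, iterative_overlap_merge, shared_in_all


def _overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and a.end > b.start


def _hits(calls: Sequence[GenomicInterval], truth: Sequence[GenomicInterval]):
    tp_truth = sum(any(_overlaps(c, t) for c in calls) for t in truth)
    fp = sum(1 for c in calls if not any(_overlaps(c, t) for t in truth))
    return tp_truth, fp


def unified_shared_regions(config: SimConfig, seed: int):
    """Tissue stage: standardize, merge, and intersect across samples."""
    peaksets, truth = simulate_tissue_peaks(config, seed)
    std = {s: extend_summits(pk, 250, config.sizes) for s, pk in peaksets.items()}
    unified = iterative_overlap_merge([p for pk in std.values() for p in pk])
    shared = shared_in_all(std, unified.intervals)
    return peaksets, truth, unified, shared


def shared_region_recovery(config: SimConfig, seed: int) -> dict:
    _, truth, unified, shared = unified_shared_regions(config, seed)
    recovered, admitted_fp = _hits(shared, truth.shared_regions)
    specific = [r for regs in truth.sample_specific_regions.values() for r in regs]
    admitted_specific = sum(
        any(_overlaps(s, r) for s in shared) for r in specific
    )
    return {
        "n_unified": len(unified.peaks),
        "n_shared": len(shared),
        "recovery": recovered / max(1, len(truth.shared_regions)),
        "specific_admitted": admitted_specific,
    }


def _csf_fragments(config: SimConfig, truth: SimTruth, seed: int) -> pd.DataFrame:
    return pd.concat(
        [simulate_fragments(config, truth, s, seed) for s in config.csf_sample_names()],
        ignore_index=True,
    )


def open_region_recovery(
    config: SimConfig, seed: int, n_background: int = 2000
) -> dict:
    """Open-region calling on the shared tissue regions, scored against truth.

    Also runs the identical caller on a seeded subsample of non-peak 500-bp
    background tiles and Fisher-tests the enrichment of cfDNA support among
    tissue-derived candidates.
    """
    _, truth, unified, shared = unified_shared_regions(config, seed)
    fragments = _csf_fragments(config, truth, seed)
    flanked = [make_flanks(r, 500, config.sizes) for r in shared]
    summary = call_open_regions(flanked, fragments)
    called = summary.called_regions
    tp, fp = _hits(called, truth.protected_regions)

    tiles = tile_genome(config.sizes, 500)
    bg = background_windows(tiles, unified.intervals)
    rng = np.random.default_rng(seed)
    if len(bg) > n_background:
        bg = [bg[i] for i in sorted(rng.choice(len(bg), n_background, replace=False))]
    bg_flanked = [fr for fr in (make_flanks(t, 500, config.sizes) for t in bg) if fr.testable]
    bg_summary = call_open_regions(bg_flanked, fragments)
    enr = overlap_enrichment(
        len(called), len(summary.calls),
        len(bg_summary.called_regions), len(bg_summary.calls),
    )
    return {
        "n_candidates": len(summary.calls),
        "n_called": len(called),
        "sensitivity": tp / max(1, len(truth.protected_regions)),
        "fdp": fp / max(1, len(called)),
        "global_p": summary.global_p,
        "fisher_p": enr.p,
        "fisher_odds": enr.odds_ratio,
        "background_called": len(bg_summary.called_regions),
        "background_total": len(bg_summary.calls),
    }


def _null_truth(config: SimConfig, seed: int) -> SimTruth:
    truth = plan_truth(config, seed)
    truth.sample_enrichment = {s: [] for s in truth.sample_enrichment}
    return truth


def null_open_call_rate(config: SimConfig, seeds: Sequence[int]) -> float:
    """Mean fraction of candidates called when fragments are uniform."""
    rates = []
    for seed in seeds:
        truth = _null_truth(config, seed)
        fragments = _csf_fragments(config, truth, seed)
        flanked = [make_flanks(r, 500, config.sizes) for r in truth.shared_regions]
        summary = call_open_regions(flanked, fragments)
        rates.append(len(summary.called_regions) / len(summary.calls))
    return float(np.mean(rates))


def _subtype_fragments(config: SimConfig, truth: SimTruth, seed: int) -> pd.DataFrame:
    return pd.concat(
        [
            simulate_fragments(config, truth, s, seed)
            for s in sorted(truth.subtype_groups)
        ],
        ignore_index=True,
    )


def differential_recovery(
    config: SimConfig, seed: int, q_threshold: float = 0.1
) -> dict:
    """Subtype-differential screen on the planted analysis regions.

    Reports recovery both for the FDR-controlled selection (BH q <= 0.1 with
    the fold-change gate) and for the display thresholds (raw p < 0.05,
    |log2FC| > 2) carried by the `significant` flag.
    """
    truth = plan_truth(config, seed)
    fragments = _subtype_fragments(config, truth, seed)
    cm = count_overlaps(truth.analysis_regions, fragments)
    results = differential_regions(cm, truth.subtype_groups)
    planted = {r.region_id() for r, _, _ in truth.differential_regions}

    def score(selected):
        tp = sum(1 for r in selected if r.region.region_id() in planted)
        return {
            "n_selected": len(selected),
            "sensitivity": tp / max(1, len(planted)),
            "fdp": (len(selected) - tp) / max(1, len(selected)),
        }

    bh_sel = [r for r in results if r.bh_q <= q_threshold and abs(r.log2fc) > 2]
    raw_sel = [r for r in results if r.significant]
    return {"bh": score(bh_sel), "raw": score(raw_sel)}


def null_differential_fraction(config: SimConfig, seeds: Sequence[int]) -> float:
    """Mean fraction of regions at p < 0.05 with no planted subtype effect."""
    fracs = []
    for seed in seeds:
        truth = _null_truth(config, seed)
        fragments = _subtype_fragments(config, truth, seed)
        cm = count_overlaps(truth.analysis_regions, fragments)
        results = differential_regions(cm, truth.subtype_groups)
        fracs.append(float(np.mean([r.p < 0.05 for r in results])))
    return float(np.mean(fracs))


@dataclass
class ClassifierRecovery:
    auc_train: float
    auc_test: float
    auc_test_ci: tuple[float, float]
    planted_in_top20: int
    n_planted: int
    features: pd.DataFrame
    grades: dict[str, str]
    report_dict: dict


def classifier_recovery(
    config: SimConfig, seed: int, n_boot: int = 500
) -> ClassifierRecovery:
    """Grade classifier on the planted marker cohort."""
    truth = plan_truth(config, seed)
    samples = sorted(truth.grade_labels)
    fragments = pd.concat(
        [simulate_fragments(config, truth, s, seed) for s in samples],
        ignore_index=True,
    )
    features = build_feature_matrix(truth.analysis_regions, fragments, samples=samples)
    report = run_grade_classifier(
        features, truth.grade_labels, seed=seed, n_boot=n_boot
    )
    planted = {r.region_id() for r, _, _ in truth.differential_regions}
    top20 = set(report.importance.index[:20])
    return ClassifierRecovery(
        auc_train=report.auc_train,
        auc_test=report.auc_test,
        auc_test_ci=report.auc_test_ci,
        planted_in_top20=len(planted & top20),
        n_planted=len(planted),
        features=features,
        grades=dict(truth.grade_labels),
        report_dict=report.to_dict(),
    )


def permuted_label_auc(
    features: pd.DataFrame,
    grades: Mapping[str, str],
    seeds: Sequence[int],
    n_boot: int = 200,
) -> float:
    """Mean test AUC after randomly permuting grade labels across samples."""
    samples = sorted(grades)
    values = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        permuted = dict(
            zip(samples, rng.permutation([grades[s] for s in samples]).tolist())
        )
        report = run_grade_classifier(features, permuted, seed=seed, n_boot=n_boot)
        values.append(report.auc_test)
    return float(np.mean(values))
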