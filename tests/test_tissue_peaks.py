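"""tissue_peaks: summit extension, blacklist, iterative merge, diversity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cfaccess.genomic_io import ChromSizes, GenomicInterval, Peak, ValidationError
from cfaccess.tissue_peaks import (
    GeneModel,
    annotate_regions,
    extend_summits,
    iterative_overlap_merge,
    partition_common_specific,
    read_gene_models,
    remove_blacklisted,
    shared_in_all,
    window_peak_cv,
)
from conftest import intervals_overlap


def peak(chrom, start, end, summit=None, p=1.0, name="", sample=""):
    if summit is None:
        summit = (start + end) // 2
    return Peak(GenomicInterval(chrom, start, end), summit, p, name, sample)


class TestExtendSummits:
    def test_standard_width_501(self, sizes):
        (out,) = extend_summits([peak("chrA", 900, 1100, summit=1000)], 250, sizes)
        assert (out.interval.start, out.interval.end) == (750, 1251)
        assert out.interval.width == 501

    def test_clipped_at_zero(self, sizes):
        (out,) = extend_summits([peak("chrA", 50, 200, summit=100)], 250, sizes)
        assert (out.interval.start, out.interval.end) == (0, 351)

    def test_flank_zero_single_base(self, sizes):
        (out,) = extend_summits([peak("chrA", 900, 1100, summit=1000)], 0, sizes)
        assert (out.interval.start, out.interval.end) == (1000, 1001)

    def test_summit_outside_chromosome_rejected(self):
        small = ChromSizes({"chrA": 500})
        with pytest.raises(ValidationError):
            extend_summits([peak("chrA", 400, 600, summit=550)], 250, small)


class TestBlacklist:
    def test_overlap_removed_adjacency_kept(self):
        peaks = [peak("chrA", 750, 1251)]
        assert remove_blacklisted(peaks, [GenomicInterval("chrA", 1200, 1300)]) == []
        assert (
            remove_blacklisted(peaks, [GenomicInterval("chrA", 1251, 1300)]) == peaks
        )
        assert remove_blacklisted(peaks, []) == peaks


class TestIterativeMerge:
    def test_greedy_example(self):
        a = peak("chrA", 100, 600, p=10, name="A")
        b = peak("chrA", 400, 900, p=5, name="B")
        c = peak("chrA", 800, 1300, p=8, name="C")
        kept = iterative_overlap_merge([a, b, c]).peaks
        assert sorted(k.name for k in kept) == ["A", "C"]

    def test_disjoint_all_retained(self):
        peaks = [peak("chrA", i * 1000, i * 1000 + 501, p=i + 1) for i in range(5)]
        assert len(iterative_overlap_merge(peaks).peaks) == 5

    def test_identical_intervals_keep_more_significant(self):
        lo = peak("chrA", 100, 601, p=7, name="lo")
        hi = peak("chrA", 100, 601, p=9, name="hi")
        kept = iterative_overlap_merge([lo, hi]).peaks
        assert [k.name for k in kept] == ["hi"]

    def test_tie_broken_by_start(self):
        right = peak("chrA", 300, 801, p=5, name="right")
        left = peak("chrA", 100, 601, p=5, name="left")
        kept = iterative_overlap_merge([right, left]).peaks
        assert [k.name for k in kept] == ["left"]

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_idempotent_nonoverlapping_and_greedy_dominant(self, seed):
        rng = np.random.default_rng(seed)
        peaks = []
        for i in range(int(rng.integers(1, 60))):
            start = int(rng.integers(0, 5000))
            peaks.append(
                peak("chrA", start, start + 501, p=float(rng.integers(1, 20)), name=f"p{i}")
            )
        merged = iterative_overlap_merge(peaks)
        kept = merged.peaks
        # non-overlapping output
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert not intervals_overlap(kept[i].interval, kept[j].interval)
        # idempotence
        again = iterative_overlap_merge(kept).peaks
        assert [(k.interval, k.name) for k in again] == [
            (k.interval, k.name) for k in kept
        ]
        # every deleted peak overlaps a retained peak of >= its significance
        kept_set = {k.name for k in kept}
        for p_ in peaks:
            if p_.name in kept_set:
                continue
            assert any(
                intervals_overlap(p_.interval, k.interval)
                and k.neglog10_p >= p_.neglog10_p
                for k in kept
            )


class TestPartitionAndShared:
    def test_mutual_overlap_both_common(self):
        sets = {
            "s1": [peak("chrA", 0, 501, name="a", sample="s1")],
            "s2": [peak("chrA", 400, 901, name="b", sample="s2")],
        }
        labels, frac = partition_common_specific(sets)
        assert set(labels["label"]) == {"common"}
        assert np.allclose(frac.sum(axis=1), 1.0)

    def test_isolated_peak_specific(self):
        sets = {
            "s1": [peak("chrA", 0, 501), peak("chrA", 5000, 5501)],
            "s2": [peak("chrA", 400, 901)],
        }
        labels, _ = partition_common_specific(sets)
        lab = labels.set_index("start")["label"]
        assert lab[5000] == "specific" and lab[0] == "common"

    def test_requires_two_samples(self):
        with pytest.raises(ValidationError):
            partition_common_specific({"s1": [peak("chrA", 0, 501)]})

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_labels_match_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sets = {}
        for s in ["s1", "s2", "s3"]:
            sets[s] = [
                peak("chrA", int(st_ := rng.integers(0, 4000)), int(st_) + 501,
                     name=f"{s}_{i}", sample=s)
                for i in range(int(rng.integers(1, 15)))
            ]
        labels, _ = partition_common_specific(sets)
        for _, row in labels.iterrows():
            iv = GenomicInterval(row["chrom"], row["start"], row["end"])
            expected = any(
                intervals_overlap(iv, q.interval)
                for s2, pk in sets.items()
                if s2 != row["sample"]
                for q in pk
            )
            assert (row["label"] == "common") == expected

    def test_shared_in_all_requires_every_sample(self):
        # region at 0 covered by 4/4 samples, region at 5000 by 3/4
        sets = {}
        for i, s in enumerate(["s1", "s2", "s3", "s4"]):
            pk = [peak("chrA", 0, 501, name="shared", sample=s)]
            if s != "s4":
                pk.append(peak("chrA", 5000, 5501, name="partial", sample=s))
            sets[s] = pk
        unified = [GenomicInterval("chrA", 0, 501), GenomicInterval("chrA", 5000, 5501)]
        shared = shared_in_all(sets, unified)
        assert shared == [GenomicInterval("chrA", 0, 501)]

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_shared_matches_coverage_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sets = {
            s: [
                peak("chrA", int(st_ := rng.integers(0, 3000)), int(st_) + 501, sample=s)
                for i in range(int(rng.integers(1, 10)))
            ]
            for s in ["s1", "s2", "s3"]
        }
        unified = [GenomicInterval("chrA", i * 600, i * 600 + 501) for i in range(6)]
        shared = shared_in_all(sets, unified)
        expected = [
            u
            for u in unified
            if all(
                any(intervals_overlap(u, q.interval) for q in pk)
                for pk in sets.values()
            )
        ]
        assert shared == expected


class TestWindowCV:
    def test_no_variation(self):
        windows = [GenomicInterval("chrA", 0, 1000)]
        sets = {
            s: [peak("chrA", i * 100, i * 100 + 50) for i in range(5)]
            for s in ["s1", "s2", "s3", "s4"]
        }
        (wcv,) = window_peak_cv(sets, windows)
        assert wcv.cv == 0.0

    def test_undefined_when_no_peaks(self):
        windows = [GenomicInterval("chrA", 0, 1000)]
        sets = {"s1": [], "s2": []}
        (wcv,) = window_peak_cv(sets, windows)
        assert np.isnan(wcv.cv)

    def test_hand_computed_cv(self):
        windows = [GenomicInterval("chrA", 0, 10_000)]
        sets = {
            f"s{k}": [peak("chrA", 100 * i, 100 * i + 50) for i in range(n)]
            for k, n in enumerate([2, 4, 6, 8])
        }
        (wcv,) = window_peak_cv(sets, windows)
        assert wcv.cv == pytest.approx(2.581988897 / 5, abs=1e-8)

    def test_peak_assigned_by_summit(self):
        windows = [GenomicInterval("chrA", 0, 500), GenomicInterval("chrA", 500, 1000)]
        sets = {
            "s1": [peak("chrA", 400, 700, summit=450)],
            "s2": [peak("chrA", 400, 700, summit=600)],
        }
        w1, w2 = window_peak_cv(sets, windows)
        assert w1.per_sample_counts == {"s1": 1, "s2": 0}
        assert w2.per_sample_counts == {"s1": 0, "s2": 1}

    def test_overlapping_windows_rejected(self):
        windows = [GenomicInterval("chrA", 0, 600), GenomicInterval("chrA", 500, 1000)]
        with pytest.raises(ValidationError):
            window_peak_cv({"s1": [], "s2": []}, windows)


class TestAnnotation:
    @pytest.fixture
    def genes(self):
        # '+' gene with two exons and one intron; '-' gene far away
        return [
            GeneModel("G1", "chrA", "+", 10_000, 20_000,
                      exons=((10_000, 12_000), (18_000, 20_000))),
            GeneModel("G2", "chrA", "-", 60_000, 70_000,
                      exons=((60_000, 70_000),)),
        ]

    def region(self, mid, half=250):
        return GenomicInterval("chrA", mid - half, mid + half + 1)

    def test_promoter_upstream_of_tss(self, genes):
        (ann,) = annotate_regions([self.region(9_900)], genes)
        assert ann.feature == "Promoter" and ann.nearest_gene == "G1"

    def test_intron_outside_promoter_window(self, genes):
        (ann,) = annotate_regions([self.region(15_000)], genes)
        assert ann.feature == "Intron"

    def test_exon_beats_intron(self, genes):
        (ann,) = annotate_regions([self.region(19_000)], genes)
        assert ann.feature == "Exon"

    def test_downstream_strand_aware(self, genes):
        (ann,) = annotate_regions([self.region(21_500)], genes, promoter_flank=1000)
        assert ann.feature == "Downstream"
        (ann2,) = annotate_regions([self.region(58_500)], genes, promoter_flank=1000)
        assert ann2.feature == "Downstream"

    def test_distal_intergenic(self, genes):
        (ann,) = annotate_regions([self.region(40_000)], genes)
        assert ann.feature == "DistalIntergenic"

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValidationError):
            GeneModel("G", "chrA", "*", 0, 10)

    def test_read_gene_models_bed12_and_tsv(self, tmp_path):
        bed12 = tmp_path / "g.bed"
        bed12.write_text(
            "chrA\t10000\t20000\tG1\t0\t+\t10000\t20000\t0\t2\t2000,2000\t0,8000\n"
        )
        (g,) = read_gene_models(bed12)
        assert g.exons == ((10_000, 12_000), (18_000, 20_000))
        tsv = tmp_path / "g.tsv"
        tsv.write_text("G2\tchrA\t-\t60000\t70000\n")
        (g2,) = read_gene_models(tsv)
        assert g2.tss == 69_999 and g2.strand == "-"
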