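"""subtype_differential: CPM, rank-sum differential, mutation flanks, TFBS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cfaccess.genomic_io import ChromSizes, CountMatrix, GenomicInterval, ValidationError
from cfaccess.subtype_differential import (
    compare_region_sets,
    differential_regions,
    mutation_flank_regions,
    normalize_cpm,
    tfbs_region_matrix,
    top_k_tf_summary,
)
from conftest import oracle_rank_sum_p


def matrix(counts, samples=None):
    counts = np.asarray(counts)
    regions = [
        GenomicInterval("chrA", i * 1000, i * 1000 + 501)
        for i in range(counts.shape[0])
    ]
    samples = samples or [f"s{j+1}" for j in range(counts.shape[1])]
    return CountMatrix(regions, samples, counts)


class TestNormalizeCPM:
    def test_unit_scaling(self):
        cm = matrix([[10], [999_990]])
        assert normalize_cpm(cm)[0, 0] == pytest.approx(10.0)

    def test_depth_correction(self):
        cm = matrix([[10, 10], [99_990, 999_990]])
        cpm = normalize_cpm(cm)
        assert cpm[0, 0] == pytest.approx(100.0)
        assert cpm[0, 1] == pytest.approx(10.0)

    def test_all_zero_column_named(self):
        cm = matrix([[1, 0], [2, 0]], samples=["ok", "empty"])
        with pytest.raises(ValidationError, match="empty"):
            normalize_cpm(cm)


class TestDifferentialRegions:
    def test_identical_groups_not_significant(self):
        cm = matrix(np.tile([[7, 7, 7, 7, 7, 7]], (3, 1)))
        groups = {f"s{i+1}": ("A" if i < 3 else "B") for i in range(6)}
        res = differential_regions(cm, groups)
        assert all(r.log2fc == 0 and not r.significant for r in res)

    def test_exact_two_sided_p(self):
        # second region balances column totals so CPM ranks follow raw counts
        cm = matrix([[1, 2, 3, 40, 50, 60], [99, 98, 97, 60, 50, 40]])
        groups = {f"s{i+1}": ("A" if i < 3 else "B") for i in range(6)}
        r = differential_regions(cm, groups)[0]
        assert r.p == pytest.approx(0.1, abs=1e-12)
        assert r.log2fc < 0  # A below B

    def test_label_symmetry(self):
        rng = np.random.default_rng(3)
        cm = matrix(rng.poisson(20, size=(30, 10)))
        g1 = {f"s{i+1}": ("A" if i < 5 else "B") for i in range(10)}
        g2 = {s: ("B" if g == "A" else "A") for s, g in g1.items()}
        r1 = differential_regions(cm, g1)
        r2 = differential_regions(cm, g2)
        for a, b in zip(r1, r2):
            assert a.log2fc == pytest.approx(-b.log2fc, abs=1e-12)
            assert a.p == pytest.approx(b.p, abs=1e-12)
            assert a.significant == b.significant

    def test_group_size_validation(self):
        cm = matrix([[1, 2, 3]])
        with pytest.raises(ValidationError):
            differential_regions(cm, {"s1": "A", "s2": "A", "s3": "B"})


class TestMutationFlanks:
    def test_width_181(self, sizes):
        (r,) = mutation_flank_regions([("chrA", 1000)], 90, sizes)
        assert (r.start, r.end) == (910, 1091) and r.width == 181

    def test_boundary_clip(self, sizes):
        (r,) = mutation_flank_regions([("chrA", 50)], 90, sizes)
        assert (r.start, r.end) == (0, 141)

    def test_flank_zero_single_base(self, sizes):
        (r,) = mutation_flank_regions([("chrA", 1000)], 0, sizes)
        assert (r.start, r.end) == (1000, 1001)

    def test_out_of_bounds_rejected(self, sizes):
        with pytest.raises(ValidationError):
            mutation_flank_regions([("chrA", 10_000)], 90, sizes)

    def test_split_mode_two_regions(self, sizes):
        up, down = mutation_flank_regions([("chrA", 1000)], 90, sizes, split=True)
        assert (up.start, up.end) == (910, 1000)
        assert (down.start, down.end) == (1001, 1091)

    def test_constant_width_away_from_edges(self, sizes):
        regions = mutation_flank_regions(
            [("chrA", p) for p in range(100, 9_000, 137)], 90, sizes
        )
        assert {r.width for r in regions} == {181}


class TestCompareRegionSets:
    def test_identical_lists_p_one(self):
        res = compare_region_sets([1, 2, 3], [1, 2, 3])
        assert res.p == 1.0

    def test_small_example(self):
        res = compare_region_sets([1, 2, 3], [4, 5, 6])
        assert res.p == pytest.approx(0.1, abs=1e-12)

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(4)
        a = rng.normal(10, 1, 300)
        b = rng.normal(7, 1, 300)
        res = compare_region_sets(a, b)
        assert res.p < 1e-6
        assert res.hl_shift == pytest.approx(3.0, abs=0.3)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            compare_region_sets([], [1.0])


class TestTFBS:
    def regions(self, n=3):
        return [GenomicInterval("chrA", i * 1000, i * 1000 + 501) for i in range(n)]

    def test_single_site(self):
        m = tfbs_region_matrix(
            [(GenomicInterval("chrA", 100, 120), "MAZ")], self.regions(1)
        )
        assert m.tfs == ["MAZ"]
        np.testing.assert_array_equal(m.site_counts, [[1]])

    def test_site_spanning_two_regions_counted_in_both(self):
        regions = [GenomicInterval("chrA", 0, 500), GenomicInterval("chrA", 500, 1000)]
        m = tfbs_region_matrix([(GenomicInterval("chrA", 480, 520), "SP1")], regions)
        np.testing.assert_array_equal(m.site_counts, [[1, 1]])

    def test_unlabeled_rejected(self):
        with pytest.raises(ValidationError):
            tfbs_region_matrix([(GenomicInterval("chrA", 0, 10), "")], self.regions(1))

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_nested_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        regions = [
            GenomicInterval("chrA", int(s := rng.integers(0, 2000)), int(s) + int(rng.integers(1, 400)))
            for _ in range(int(rng.integers(1, 10)))
        ]
        tfbs = [
            (
                GenomicInterval("chrA", int(s := rng.integers(0, 2300)), int(s) + int(rng.integers(1, 40))),
                str(rng.choice(["A", "B", "C"])),
            )
            for _ in range(int(rng.integers(1, 50)))
        ]
        m = tfbs_region_matrix(tfbs, regions)
        for ti, tf in enumerate(m.tfs):
            for ri, r in enumerate(regions):
                expected = sum(
                    1
                    for iv, lab in tfbs
                    if lab == tf and iv.start < r.end and iv.end > r.start
                )
                assert m.site_counts[ti, ri] == expected


class TestTopKTF:
    def test_single_tf_fraction_one(self):
        m = tfbs_region_matrix(
            [(GenomicInterval("chrA", 100, 120), "MAZ")],
            [GenomicInterval("chrA", 0, 501), GenomicInterval("chrA", 1000, 1501)],
        )
        with pytest.warns(UserWarning, match="truncating"):
            summ = top_k_tf_summary(m, k=50)
        assert summ.per_region_fraction[0] == 1.0
        assert np.isnan(summ.per_region_fraction[1])  # region with no sites

    def test_ranking_and_fraction(self):
        regions = [GenomicInterval("chrA", 0, 501)]
        tfbs = (
            [(GenomicInterval("chrA", 10 + i, 30 + i), "X") for i in range(10)]
            + [(GenomicInterval("chrA", 10 + i, 30 + i), "Y") for i in range(5)]
            + [(GenomicInterval("chrA", 10, 30), "Z")]
        )
        m = tfbs_region_matrix(tfbs, regions)
        summ = top_k_tf_summary(m, k=2)
        assert summ.ranked_tfs == ["X", "Y", "Z"]
        assert summ.top_k == ["X", "Y"]
        assert summ.per_region_fraction[0] == pytest.approx(15 / 16)

    def test_all_sites_in_top_k(self):
        regions = [GenomicInterval("chrA", 0, 501)]
        tfbs = [(GenomicInterval("chrA", 10, 30), t) for t in ["A", "B"]]
        m = tfbs_region_matrix(tfbs, regions)
        summ = top_k_tf_summary(m, k=2)
        assert summ.per_region_fraction[0] == 1.0

    def test_k_validation(self):
        m = tfbs_region_matrix(
            [(GenomicInterval("chrA", 0, 10), "A")], [GenomicInterval("chrA", 0, 501)]
        )
        with pytest.raises(ValidationError):
            top_k_tf_summary(m, k=0)
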