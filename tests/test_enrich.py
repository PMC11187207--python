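"""Random-region nulls, OE ratios, compartment labels, rank/ANOVA tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from embryort.enrich import (
    compartment_at_sites,
    derive_region_sets,
    enrichment_test,
    lamina_oe,
    mann_whitney,
    one_way_anova,
    sample_random_regions,
    value_at_sites,
)
from embryort.errors import (
    InvalidArgumentError,
    SamplingFailureError,
    UndefinedStatisticError,
)
from embryort.genome import IntervalTrack, partition_genome


def track(*rows):
    return IntervalTrack(pd.DataFrame(list(rows), columns=["chrom", "start", "end"]))


class TestRandomRegions:
    def test_count_and_lengths_matched(self, toy_bins):
        out = sample_random_regions([100, 2000, 50_000], toy_bins, seed=1)
        assert len(out) == 3
        assert sorted(out.track.lengths) == [100, 2000, 50_000]

    def test_same_seed_identical(self, toy_bins):
        a = sample_random_regions([500] * 5, toy_bins, seed=3)
        b = sample_random_regions([500] * 5, toy_bins, seed=3)
        assert a.track.df.equals(b.track.df)

    def test_fully_masked_genome_fails(self, toy_bins):
        masked = toy_bins.with_mask(np.ones(toy_bins.n_bins, dtype=bool))
        with pytest.raises(SamplingFailureError):
            sample_random_regions([100], masked, seed=0)

    def test_regions_avoid_masked_territory(self):
        bins = partition_genome({"c1": 1_000_000}, 100_000)
        mask = np.zeros(10, dtype=bool)
        mask[4:6] = True  # 400-600 kb masked
        bins = bins.with_mask(mask)
        out = sample_random_regions([50_000] * 200, bins, seed=2)
        for s, e in zip(out.track.df["start"], out.track.df["end"]):
            assert e <= 400_000 or s >= 600_000

    def test_oversized_length_fails_with_length_in_message(self, toy_bins):
        with pytest.raises(SamplingFailureError, match="2000000"):
            sample_random_regions([2_000_000], toy_bins, seed=0)


class TestValueAtSites:
    def test_single_bin_site(self, toy_bins):
        vals = np.arange(10, dtype=float)
        out = value_at_sites(track(("c1", 150_000, 160_000)), vals, toy_bins)
        assert out[0] == 1.0

    def test_spanning_site_averages(self, toy_bins):
        vals = np.zeros(10)
        vals[1], vals[2] = 2.0, 4.0
        out = value_at_sites(track(("c1", 150_000, 250_000)), vals, toy_bins)
        assert out[0] == 3.0

    def test_fully_masked_site_missing(self):
        bins = partition_genome({"c1": 1_000_000}, 100_000)
        bins = bins.with_mask(np.array([True] * 2 + [False] * 8))
        out = value_at_sites(track(("c1", 0, 150_000)), np.ones(10), bins)
        assert np.isnan(out[0])

    def test_window_extends_site(self, toy_bins):
        vals = np.zeros(10)
        vals[0], vals[1], vals[2] = 3.0, 0.0, 3.0
        out = value_at_sites(track(("c1", 110_000, 120_000)), vals, toy_bins, window_bins=1)
        assert out[0] == 2.0


class TestLaminaOE:
    def test_all_sites_in_half_covered_genome(self, toy_bins):
        lads = track(("c1", 0, 500_000))
        sites = track(("c1", 10_000, 20_000), ("c1", 200_000, 210_000))
        assert lamina_oe(sites, lads, toy_bins) == pytest.approx(2.0)

    def test_no_overlap_gives_zero(self, toy_bins):
        lads = track(("c1", 0, 500_000))
        sites = track(("c1", 700_000, 710_000))
        assert lamina_oe(sites, lads, toy_bins) == 0.0

    def test_zero_coverage_undefined(self, toy_bins):
        lads = IntervalTrack(pd.DataFrame(columns=["chrom", "start", "end"]))
        with pytest.raises((UndefinedStatisticError, InvalidArgumentError)):
            lamina_oe(track(("c1", 0, 10)), lads, toy_bins)

    def test_uniform_point_sites_calibrate_to_one(self, desk_bins, rt_truth):
        lads = rt_truth.lad_track()
        oes = [
            lamina_oe(s.track, lads, desk_bins)
            for s in sample_random_regions([1] * 50, desk_bins, n_sets=100, seed=5)
        ]
        assert 0.9 < np.mean(oes) < 1.1


class TestCompartment:
    def test_sign_labels(self, toy_bins):
        ev = np.zeros(10)
        ev[1], ev[3] = 0.8, -0.3
        sites = track(
            ("c1", 100_000, 200_000), ("c1", 300_000, 400_000), ("c1", 500_000, 600_000)
        )
        out = compartment_at_sites(sites, ev, toy_bins)
        assert out["label"].tolist() == ["A", "B", "unassigned"]
        assert out["value"].tolist() == [0.8, -0.3, 0.0]


class TestRegionSets:
    def test_long_gene_selected(self):
        genes = track(("c1", 0, 600_000), ("c1", 700_000, 750_000))
        long_genes, _ = derive_region_sets(genes)
        assert long_genes.df[["start", "end"]].values.tolist() == [[0, 600_000]]

    def test_adjacent_genes_leave_no_gap(self):
        genes = track(("c1", 0, 2_000_000), ("c1", 2_000_100, 4_000_000))
        _, intergenic = derive_region_sets(genes)
        assert len(intergenic) == 0

    def test_gene_free_chromosome_is_one_intergenic_interval(self):
        genes = track(("c1", 0, 1_000_000))
        _, intergenic = derive_region_sets(
            genes, chrom_lengths={"c1": 1_000_000, "c2": 2_000_000}
        )
        # c2 carries no genes; with chromosome lengths supplied the whole
        # of c2 would appear only if it had a merged-gene anchor; the gap
        # after the last c1 gene is below threshold
        assert len(intergenic) == 0
        genes2 = track(("c1", 0, 1_000_000), ("c2", 0, 100))
        _, intergenic2 = derive_region_sets(
            genes2, chrom_lengths={"c1": 1_000_000, "c2": 2_100_000}
        )
        assert intergenic2.df[["chrom", "start", "end"]].values.tolist() == [
            ["c2", 100, 2_100_000]
        ]

    def test_outputs_disjoint_within_sets(self, rt_truth):
        long_genes, intergenic = derive_region_sets(rt_truth.genes)
        for t in (long_genes, intergenic):
            df = t.sort().df
            for chrom, sub in df.groupby("chrom"):
                assert (sub["start"].values[1:] >= sub["end"].values[:-1]).all()

    def test_empty_gene_track_warns(self):
        empty = IntervalTrack(pd.DataFrame(columns=["chrom", "start", "end"]))
        with pytest.warns(UserWarning):
            lg, ig = derive_region_sets(empty)
        assert len(lg) == 0 and len(ig) == 0


def enumeration_mwu(a, b):
    """Independent oracle: exact two-sided MWU by full labeling enumeration."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    na = len(a)

    def ustat(x, y):
        return sum(float(xi > yi) + 0.5 * float(xi == yi) for xi in x for yi in y)

    u_obs = ustat(a, b)
    us = np.array(
        [
            ustat(pooled[list(ix)], np.delete(pooled, list(ix)))
            for ix in combinations(range(len(pooled)), na)
        ]
    )
    p_low = (us <= u_obs + 1e-12).mean()
    p_high = (us >= u_obs - 1e-12).mean()
    return u_obs, min(1.0, 2 * min(p_low, p_high))


class TestMannWhitney:
    def test_textbook_example(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(8)
        a = rng.normal(5, 1, 50)
        b = rng.normal(0, 1, 50)
        _, p = mann_whitney(a, b)
        assert p < 1e-6

    def test_exact_branch_equals_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            na, nb = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            vals = rng.choice(1000, size=na + nb, replace=False).astype(float)
            u1, p1 = mann_whitney(vals[:na], vals[na:])
            u2, p2 = enumeration_mwu(vals[:na], vals[na:])
            assert u1 == pytest.approx(u2)
            assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mann_whitney([], [1.0])

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(21)
        rej = sum(
            mann_whitney(rng.normal(size=30), rng.normal(size=30))[1] < 0.05
            for _ in range(2000)
        )
        assert 0.03 < rej / 2000 < 0.07


class TestANOVA:
    def test_equal_groups_f_zero_p_one(self):
        f, p = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert f == 0.0
        assert p == 1.0

    def test_two_groups_f_is_t_squared(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        f, p_f = one_way_anova([a, b])
        t, p_t = sps.ttest_ind(a, b)
        assert f == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)

    def test_hand_computed_sums_of_squares(self):
        # groups {1,2,3},{7,8,9}: ss_between 54, ss_within 4, F = 54
        f, p = one_way_anova([[1, 2, 3], [7, 8, 9]])
        assert f == pytest.approx(54.0)
        assert p == pytest.approx(float(sps.f.sf(54.0, 1, 4)))

    def test_degenerate_constant_everything(self):
        with pytest.raises(UndefinedStatisticError):
            one_way_anova([[1.0, 1.0], [1.0, 1.0]])

    def test_single_group_rejected(self):
        with pytest.raises(InvalidArgumentError):
            one_way_anova([[1, 2, 3]])


def test_enrichment_result_summary_fields():
    rng = np.random.default_rng(2)
    res = enrichment_test(
        rng.normal(2, 1, 40), rng.normal(0, 1, 360),
        statistic_name="gene_density", oe_ratio=1.8,
    )
    assert res.n_sites == 40 and res.n_null == 360
    assert res.p_two_sided < 1e-6
    assert "gene_density" in res.summary()
    row = res.to_frame().iloc[0]
    assert row["oe_ratio"] == 1.8
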