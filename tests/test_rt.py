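"""Binarisation, aggregation, early/late classification, profile ordering."""

import numpy as np
import pandas as pd
import pytest

from embryort.errors import (
    DegenerateInputError,
    InsufficientDataError,
    UndefinedStatisticError,
)
from embryort.rt import (
    ReplicationTimingModel,
    _best_1d_split,
    aggregate_profile,
    binarize_cell,
    classify_early_late,
    correlate_profiles,
    order_cells,
)


def exhaustive_sse_split(values):
    """Oracle: best threshold by brute-force within-cluster SSE scan."""
    v = np.sort(values)
    best = (np.inf, None, None)
    for k in range(1, len(v)):
        lo, hi = v[:k], v[k:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if sse < best[0]:
            best = (sse, lo.mean(), hi.mean())
    return best[1], best[2]


class TestBinarize:
    def test_noise_free_two_level_profile_exact(self, rt_truth):
        x = np.where(rt_truth.t <= 0.5, 2.0, 1.0)
        states, pct = binarize_cell(x)
        np.testing.assert_array_equal(states, (rt_truth.t <= 0.5).astype(float))
        assert pct == pytest.approx((rt_truth.t <= 0.5).mean())

    def test_sse_method_matches_em_on_clean_data(self, rt_truth):
        x = np.where(rt_truth.t <= 0.3, 2.0, 1.0)
        s_em, _ = binarize_cell(x, method="em")
        s_sse, _ = binarize_cell(x, method="sse")
        np.testing.assert_array_equal(s_em, s_sse)

    def test_flat_profile_non_informative(self):
        assert binarize_cell(np.ones(500)) is None

    def test_too_few_bins_rejected(self):
        with pytest.raises(InsufficientDataError):
            binarize_cell(np.array([1.0, 2.0] * 10))

    def test_missing_bins_propagate(self):
        x = np.array([1.0] * 100 + [2.0] * 100 + [np.nan] * 20)
        states, pct = binarize_cell(x)
        assert np.isnan(states[-20:]).all()
        assert pct == pytest.approx(0.5)

    def test_two_means_split_equals_exhaustive_sse_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            n = int(rng.integers(10, 200))
            v = np.concatenate(
                [rng.normal(1, 0.2, n // 2), rng.normal(2, 0.3, n - n // 2)]
            )
            got = _best_1d_split(v)
            want = exhaustive_sse_split(v)
            assert got[0] == pytest.approx(want[0])
            assert got[1] == pytest.approx(want[1])

    def test_default_accuracy_floor_at_study_noise(self, cohort_profiles, cohort):
        accs = []
        for p, c in zip(cohort_profiles, cohort.cells):
            if c.phase != "S":
                continue
            out = binarize_cell(p.copy_ratio)
            if out is None:
                continue
            states, _ = out
            sel = np.isfinite(states)
            accs.append((states[sel] == c.states[sel]).mean())
        assert np.mean(accs) >= 0.8


class TestAggregate:
    def test_fraction_over_cells(self):
        binary = pd.DataFrame([[1, 0], [1, 0], [0, 0]], dtype=float)
        agg = aggregate_profile(binary)
        assert agg.replication_percentage[0] == pytest.approx(2 / 3)
        assert agg.replication_percentage[1] == 0.0

    def test_single_cell_identity(self):
        binary = pd.DataFrame([[1.0, 0.0, 1.0]])
        agg = aggregate_profile(binary)
        np.testing.assert_array_equal(agg.replication_percentage, [1, 0, 1])

    def test_missing_states_shrink_denominator(self):
        binary = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]])
        agg = aggregate_profile(binary)
        assert agg.replication_percentage[1] == 1.0
        assert agg.n_informative.tolist() == [2, 1]

    def test_empty_cohort_degenerate(self):
        with pytest.raises(DegenerateInputError):
            aggregate_profile(pd.DataFrame(columns=[0, 1]))

    def test_cell_relabeling_leaves_aggregate_unchanged(self):
        rng = np.random.default_rng(4)
        binary = pd.DataFrame(
            rng.integers(0, 2, size=(10, 50)).astype(float),
            index=[f"c{i}" for i in range(10)],
        )
        shuffled = binary.sample(frac=1, random_state=1)
        a = aggregate_profile(binary)
        b = aggregate_profile(shuffled)
        np.testing.assert_array_equal(a.replication_percentage, b.replication_percentage)


class TestEarlyLate:
    @pytest.mark.parametrize(
        "states,expected",
        [
            ([1, 1, 1, 0, 0], "early"),  # 0.6
            ([1, 1, 0, 0, 0], "late"),  # 0.4
            ([1, 1, 0, 0], "boundary"),  # exactly 0.5
        ],
    )
    def test_strict_half_rule(self, states, expected):
        # one bin, aggregated over len(states) cells
        binary = pd.DataFrame(np.array(states, dtype=float)[:, None])
        agg = aggregate_profile(binary)
        assert classify_early_late(agg)[0] == expected

    def test_conservation_over_unmasked_bins(self, cohort_profiles, cohort):
        s_profiles = {
            p.cell_id: p.copy_ratio for p, c in zip(cohort_profiles, cohort.cells)
            if p.phase == "S"
        }
        res = ReplicationTimingModel(s_profiles, cohort.bins).fit()
        classes = res.aggregate.classes
        informative = res.aggregate.n_informative > 0
        n_classified = sum(res.aggregate.class_counts().values())
        assert n_classified == int((informative & cohort.bins.unmasked).sum())


class TestCorrelate:
    def test_identical_profiles(self):
        p = np.linspace(0, 1, 50)
        r, n = correlate_profiles(p, p)
        assert r == pytest.approx(1.0)
        assert n == 50

    def test_mirrored_profiles(self):
        p = np.linspace(0, 1, 50)
        r, _ = correlate_profiles(p, 1 - p)
        assert r == pytest.approx(-1.0)

    def test_independent_truths_uncorrelated(self, desk_bins):
        import embryort as ert

        # short correlation length -> many effective degrees of freedom,
        # so the sampling noise of r is well below the 0.1 band
        a = ert.make_rt_truth(desk_bins, 5, 0.0, seed=101)
        b = ert.make_rt_truth(desk_bins, 5, 0.0, seed=202)
        r, _ = correlate_profiles(a.t, b.t, bins=desk_bins)
        assert abs(r) < 0.1

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            correlate_profiles(np.ones(20), np.linspace(0, 1, 20))

    def test_too_few_shared_bins(self):
        a = np.array([1.0, 2.0, np.nan, np.nan])
        with pytest.raises(InsufficientDataError):
            correlate_profiles(a, a)


class TestOrderCells:
    def test_ascending_by_percent(self):
        pct = pd.Series({"cell1": 0.8, "cell2": 0.2, "cell3": 0.5})
        assert list(order_cells(pct)) == ["cell2", "cell3", "cell1"]

    def test_ties_broken_by_cell_id(self):
        pct = pd.Series({"b": 0.5, "a": 0.5, "c": 0.5})
        assert list(order_cells(pct)) == ["a", "b", "c"]

    def test_empty_input(self):
        assert list(order_cells(pd.Series(dtype=float))) == []


class TestModelResults:
    def test_fit_recovers_truth_implied_profile(self, cohort_profiles, cohort, rt_truth):
        s_profiles = {
            p.cell_id: p.copy_ratio for p, c in zip(cohort_profiles, cohort.cells)
            if p.phase == "S"
        }
        res = ReplicationTimingModel(s_profiles, cohort.bins).fit()
        f_values = np.array([c.s_fraction for c in cohort.cells if c.phase == "S"])
        expected = rt_truth.expected_fraction(f_values)
        sel = np.isfinite(res.aggregate.replication_percentage) & cohort.bins.unmasked
        r = np.corrcoef(res.aggregate.replication_percentage[sel], expected[sel])[0, 1]
        assert r > 0.9

    def test_summary_mentions_key_counts(self, cohort_profiles, cohort):
        s_profiles = {
            p.cell_id: p.copy_ratio for p, c in zip(cohort_profiles, cohort.cells)
            if p.phase == "S"
        }
        res = ReplicationTimingModel(s_profiles, cohort.bins).fit()
        text = res.summary()
        assert "informative S cells" in text and "early bins" in text

    def test_bedgraph_roundtrip(self, cohort_profiles, cohort, tmp_path):
        from embryort.genome import bin_track, read_interval_track

        s_profiles = {
            p.cell_id: p.copy_ratio for p, c in zip(cohort_profiles, cohort.cells)
            if p.phase == "S"
        }
        res = ReplicationTimingModel(s_profiles, cohort.bins).fit()
        path = tmp_path / "profile.bedgraph"
        res.to_bedgraph(path)
        back = bin_track(read_interval_track(path), cohort.bins, "mean_score")
        sel = np.isfinite(back)
        np.testing.assert_allclose(
            back[sel], res.aggregate.replication_percentage[sel], atol=1e-5
        )
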