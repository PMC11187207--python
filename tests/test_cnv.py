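"""Copy-number segmentation, break-site annotation, karyotype summaries."""

import numpy as np
import pandas as pd
import pytest

from embryort.cnv import (
    CopyNumberModel,
    SegmentedCN,
    _robust_noise_var,
    _segment_values,
    annotate_breakpoints,
    call_copy_number,
    segment_cell,
    summarize_karyotypes,
)
from embryort.errors import DegenerateInputError, InvalidArgumentError
from embryort.genome import partition_genome


@pytest.fixture(scope="module")
def flat_bins():
    return partition_genome({"c1": 10_000_000}, 100_000)  # 100 bins


def make_segmented(levels_and_lengths, bins, cell_id="cell"):
    """Construct a SegmentedCN with exactly known mean ratios."""
    rows = []
    start_bin = 0
    for level, n in levels_and_lengths:
        rows.append(
            {
                "chrom": "c1",
                "start": start_bin * 100_000,
                "end": (start_bin + n) * 100_000,
                "start_bin": start_bin,
                "end_bin": start_bin + n,
                "n_bins": n,
                "mean_ratio": level,
            }
        )
        start_bin += n
    return SegmentedCN(cell_id=cell_id, segments=pd.DataFrame(rows))


class TestSegmentation:
    def test_noise_free_step_found_exactly(self, flat_bins):
        x = np.where(np.arange(100) < 40, 1.0, 2.0)
        seg = segment_cell(x, flat_bins).segments
        assert len(seg) == 2
        assert seg.iloc[0]["end_bin"] == 40
        assert seg.iloc[0]["mean_ratio"] == pytest.approx(1.0)
        assert seg.iloc[1]["mean_ratio"] == pytest.approx(2.0)

    def test_constant_profile_single_segment(self, flat_bins):
        seg = segment_cell(np.ones(100), flat_bins).segments
        assert len(seg) == 1
        assert seg.iloc[0]["n_bins"] == 100

    def test_min_seg_bins_enforced_for_close_changes(self, flat_bins):
        x = np.ones(100)
        x[45:55] = 2.0  # two true changes only 10 bins apart
        seg = segment_cell(x, flat_bins, min_seg_bins=20).segments
        # the 10-bin event cannot be isolated: every reported segment
        # respects the minimum length, so the true pair of boundaries
        # (45, 55) is never fully resolved
        assert (seg["n_bins"] >= 20).all()
        assert not {45, 55} <= set(seg["start_bin"])

    def test_short_chromosome_single_segment_with_warning(self):
        bins = partition_genome({"c1": 500_000}, 100_000)
        with pytest.warns(UserWarning):
            seg = segment_cell(np.ones(5), bins, min_seg_bins=5).segments
        assert len(seg) == 1

    def test_segments_partition_unmasked_bins(self, cohort_profiles, cohort):
        p = cohort_profiles[0]
        seg = segment_cell(p.copy_ratio, cohort.bins).segments
        for chrom in cohort.bins.chrom_names:
            sub = seg[seg.chrom == chrom]
            sl = cohort.bins.chrom_slice(chrom)
            usable = (
                cohort.bins.unmasked[sl] & np.isfinite(p.copy_ratio[sl])
            ).sum()
            assert sub["n_bins"].sum() == usable
            # contiguous, non-overlapping bin spans
            assert (sub["start_bin"].values[1:] == sub["end_bin"].values[:-1]).all()

    def test_interior_event_isolated(self, flat_bins):
        rng = np.random.default_rng(0)
        x = 1.0 + rng.normal(0, 0.1, 100)
        x[30:55] += 1.0
        seg = segment_cell(x, flat_bins).segments
        assert len(seg) == 3
        assert seg.iloc[1]["start_bin"] == 30
        assert seg.iloc[1]["end_bin"] == 55

    def test_capped_dp_equals_exhaustive_enumeration(self):
        def oracle(v, min_seg, beta):
            n = len(v)
            cs = np.concatenate([[0.0], np.cumsum(v)])
            css = np.concatenate([[0.0], np.cumsum(v * v)])

            def sse(i, j):
                s = cs[j] - cs[i]
                return (css[j] - css[i]) - s * s / (j - i)

            best = (sse(0, n), [])
            for k in range(min_seg, n - min_seg + 1):
                c = sse(0, k) + sse(k, n) + beta
                if c < best[0]:
                    best = (c, [k])
            for k1 in range(min_seg, n - 2 * min_seg + 1):
                for k2 in range(k1 + min_seg, n - min_seg + 1):
                    c = sse(0, k1) + sse(k1, k2) + sse(k2, n) + 2 * beta
                    if c < best[0]:
                        best = (c, [k1, k2])
            return best[1]

        rng = np.random.default_rng(42)
        for _ in range(30):
            n = 60
            v = np.zeros(n)
            k = rng.integers(0, 3)
            if k == 1:
                v[rng.integers(10, 50):] += rng.choice([-1.0, 1.0])
            elif k == 2:
                b1 = int(rng.integers(8, 30))
                b2 = b1 + int(rng.integers(10, min(25, 52 - b1)))
                v[b1:b2] += rng.choice([-1.0, 1.0])
            v += rng.normal(0, 0.1, n)
            beta = 3.0 * np.log(n) * _robust_noise_var(v)
            assert _segment_values(v, 5, beta, max_changepoints=2) == oracle(v, 5, beta)


class TestCopyNumber:
    def test_unit_ratio_maps_to_baseline(self, flat_bins):
        seg = make_segmented([(1.0, 100)], flat_bins)
        out = call_copy_number(seg)
        assert out.segments["cn_continuous"].iloc[0] == pytest.approx(2.0)
        assert out.segments["cn_integer"].iloc[0] == 2

    def test_minority_doubled_segment_called_four(self, flat_bins):
        seg = make_segmented([(1.0, 80), (2.0, 20)], flat_bins)
        out = call_copy_number(seg).segments
        assert out["cn_continuous"].iloc[1] == pytest.approx(4.0)

    def test_half_ratio_called_one(self, flat_bins):
        seg = make_segmented([(1.0, 80), (0.5, 20)], flat_bins)
        out = call_copy_number(seg).segments
        assert out["cn_continuous"].iloc[1] == pytest.approx(1.0)
        assert out["cn_integer"].iloc[1] == 1

    def test_round_half_up(self, flat_bins):
        seg = make_segmented([(1.0, 80), (1.25, 20)], flat_bins)
        out = call_copy_number(seg).segments
        assert out["cn_continuous"].iloc[1] == pytest.approx(2.5)
        assert out["cn_integer"].iloc[1] == 3

    def test_zero_ratio_degenerate(self, flat_bins):
        with pytest.raises(DegenerateInputError):
            call_copy_number(make_segmented([(0.0, 100)], flat_bins))


class TestBreakpoints:
    def test_two_copy_jump_annotated(self, flat_bins):
        seg = call_copy_number(make_segmented([(1.0, 60), (2.0, 40)], flat_bins))
        bp = annotate_breakpoints(seg)
        assert len(bp) == 1
        assert bp.iloc[0]["position"] == 60 * 100_000
        assert bp.iloc[0]["delta_cn"] == pytest.approx(2.0)

    def test_exactly_one_copy_jump_not_annotated(self, flat_bins):
        # cn 2 -> 3 transition: delta exactly 1 fails the strict rule
        seg = make_segmented([(1.0, 90), (1.5, 10)], flat_bins)
        seg = call_copy_number(seg)
        deltas = np.diff(seg.segments["cn_continuous"])
        assert deltas[0] == pytest.approx(1.0)
        assert len(annotate_breakpoints(seg)) == 0

    def test_fractional_loss_annotated(self, flat_bins):
        seg = call_copy_number(make_segmented([(1.0, 80), (0.25, 20)], flat_bins))
        bp = annotate_breakpoints(seg)
        assert len(bp) == 1
        assert bp.iloc[0]["delta_cn"] == pytest.approx(-1.5)

    def test_chromosome_ends_never_emit(self, flat_bins):
        seg = call_copy_number(make_segmented([(1.0, 100)], flat_bins))
        assert len(annotate_breakpoints(seg)) == 0

    def test_delta_one_events_on_correct_segments_are_silent(self, flat_bins):
        # many exact one-copy steps; the strict > 1 rule ignores all of them
        seg = call_copy_number(
            make_segmented([(1.0, 30), (1.5, 20), (1.0, 30), (1.5, 20)], flat_bins)
        )
        assert len(annotate_breakpoints(seg)) == 0

    def test_requires_called_copy_number(self, flat_bins):
        with pytest.raises(InvalidArgumentError):
            annotate_breakpoints(make_segmented([(1.0, 100)], flat_bins))


class TestKaryotype:
    def test_whole_chromosome_loss_called(self, flat_bins):
        seg = call_copy_number(make_segmented([(1.0, 100)], flat_bins), baseline_cn=2)
        seg.segments["cn_integer"] = 1  # whole chromosome at cn 1
        seg.segments["cn_continuous"] = 1.0
        summary = summarize_karyotypes([seg], annotate_breakpoints(seg))
        assert summary.calls.iloc[0]["call"] == "loss"

    def test_no_events_all_euploid(self, flat_bins):
        seg = call_copy_number(make_segmented([(1.0, 100)], flat_bins))
        summary = summarize_karyotypes([seg], annotate_breakpoints(seg))
        assert summary.calls.iloc[0]["call"] == "euploid"
        assert summary.aneuploidy_fraction == 0.0

    def test_segmental_event_called(self, flat_bins):
        seg = call_copy_number(make_segmented([(1.0, 60), (2.0, 40)], flat_bins))
        summary = summarize_karyotypes([seg], annotate_breakpoints(seg))
        assert summary.calls.iloc[0]["call"] == "segmental"

    def test_cohort_aneuploidy_fraction(self, flat_bins):
        cells = []
        for i in range(20):
            seg = call_copy_number(make_segmented([(1.0, 100)], flat_bins), baseline_cn=2)
            if i < 10:
                seg.segments["cn_integer"] = 1
            seg.cell_id = f"c{i}"
            seg.segments["cell_id"] = f"c{i}"
            cells.append(seg)
        summary = summarize_karyotypes(cells, pd.DataFrame(columns=["cell_id", "chrom"]))
        assert summary.aneuploidy_fraction == pytest.approx(0.5)


class TestModel:
    def test_model_recovers_injected_event(self, desk_bins, rt_truth):
        import embryort as ert
        from embryort.qc import qc_cells

        sim = ert.simulate_cells(
            rt_truth, n_g1=3, n_s=0, gc_coeff=0.3, nb_dispersion=100, seed=44
        )
        sim = ert.inject_cn_event(sim, "G1_001", ("chr1", 30_000_000, 34_000_000), +2, seed=1)
        ref = ert.simulate_cells(rt_truth, n_g1=10, n_s=0, gc_coeff=0.3, seed=45)
        profiles = qc_cells(sim.counts, sim.cell_ids, desk_bins, reference_counts=ref.counts)
        res = CopyNumberModel({p.cell_id: p.copy_ratio for p in profiles}, desk_bins).fit()
        bp = res.breakpoints()
        hits = bp[(bp.cell_id == "G1_001") & (bp.chrom == "chr1")]
        assert any(abs(hits.position - 30_000_000) <= 100_000)
        assert any(abs(hits.position - 34_000_000) <= 100_000)

    def test_results_deterministic_tables(self, flat_bins, tmp_path):
        rng = np.random.default_rng(9)
        x = 1.0 + rng.normal(0, 0.1, 100)
        res = CopyNumberModel({"c0": x}, flat_bins).fit()
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        res.segments_tsv(p1)
        res.segments_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()
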