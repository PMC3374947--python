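"""Window binning, pooled reference, log2 ratios and deletion calling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from panelscreen.coverage_cnv import (
    ExonSummary,
    Window,
    WindowCountMatrix,
    WindowRatioTrack,
    aggregate_exons,
    bin_depth,
    build_count_matrix,
    build_reference,
    call_deletions,
    estimate_mosaic_fraction,
    library_size_normalize,
    log2_ratio_track,
    make_windows,
    mean_shift_normalize,
    project_orf,
)
from panelscreen.formats_io import DepthTrack, GeneModel, TargetRegion


def uniform_track(sample_id, chrom, start, end, depth):
    return DepthTrack.from_pairs(sample_id, [(chrom, p, depth) for p in range(start + 1, end + 1)])


class TestMakeWindows:
    def test_exact_tiling(self):
        ws = make_windows([TargetRegion("chr1", 0, 300)], 100, 100)
        assert [(w.start, w.end) for w in ws] == [(0, 100), (100, 200), (200, 300)]

    def test_overlapping_windows_truncate_at_target_end(self):
        ws = make_windows([TargetRegion("chr1", 0, 250)], 100, 50)
        assert [(w.start, w.end) for w in ws] == [
            (0, 100), (50, 150), (100, 200), (150, 250), (200, 250),
        ]

    def test_empty_targets(self):
        assert make_windows([], 100, 100) == []

    def test_windows_never_span_targets(self):
        ws = make_windows([TargetRegion("chr1", 0, 150), TargetRegion("chr1", 500, 650)], 100, 100)
        assert [(w.start, w.end) for w in ws] == [(0, 100), (100, 150), (500, 600), (600, 650)]

    def test_step_larger_than_size_rejected(self):
        with pytest.raises(ValueError):
            make_windows([TargetRegion("chr1", 0, 300)], 100, 150)

    def test_indices_are_ordinal(self):
        ws = make_windows([TargetRegion("chr1", 0, 500)], 100, 100)
        assert [w.index for w in ws] == list(range(5))


class TestBinDepth:
    def test_uniform_depth(self):
        track = uniform_track("s", "chr1", 0, 100, 100)
        ws = make_windows([TargetRegion("chr1", 0, 100)], 100, 100)
        assert bin_depth(track, ws)[0] == pytest.approx(100.0)

    def test_half_covered_window(self):
        track = uniform_track("s", "chr1", 0, 50, 100)
        ws = make_windows([TargetRegion("chr1", 0, 100)], 100, 100)
        assert bin_depth(track, ws)[0] == pytest.approx(50.0)

    def test_window_without_positions_is_zero(self):
        track = DepthTrack("s")
        ws = make_windows([TargetRegion("chr1", 0, 100)], 100, 100)
        assert bin_depth(track, ws)[0] == 0.0

    def test_conservation_with_non_overlapping_windows(self, rng):
        """step = size: window sums partition the targets and conserve total
        depth exactly (integer arithmetic)."""
        targets = [TargetRegion("chr1", 0, 730), TargetRegion("chr1", 1000, 1250)]
        rows = []
        for t in targets:
            for p in range(t.start + 1, t.end + 1):
                rows.append(("chr1", p, int(rng.integers(0, 200))))
        track = DepthTrack.from_pairs("s", rows)
        ws = make_windows(targets, 100, 100)
        sums = bin_depth(track, ws, stat="sum")
        assert int(sums.sum()) == track.total_depth()
        means = bin_depth(track, ws)
        widths = np.array([w.width for w in ws])
        assert np.allclose(means * widths, sums, rtol=0, atol=1e-9)


class TestLibraryNormalization:
    def test_identical_samples_unchanged(self):
        ws = make_windows([TargetRegion("chr1", 0, 300)], 100, 100)
        counts = np.array([[10.0, 20.0, 30.0]] * 2)
        m = library_size_normalize(WindowCountMatrix(ws, ["a", "b"], counts))
        assert m.library_factors == {"a": 1.0, "b": 1.0}
        assert np.allclose(m.counts, counts)

    def test_double_depth_sample_scaled_down(self):
        ws = make_windows([TargetRegion("chr1", 0, 200)], 100, 100)
        counts = np.array([[10.0, 10.0], [20.0, 20.0], [10.0, 10.0]])
        m = library_size_normalize(WindowCountMatrix(ws, ["a", "b", "c"], counts))
        assert m.library_factors["b"] == pytest.approx(0.5)
        assert np.allclose(m.counts[1], [10.0, 10.0])

    def test_single_sample_factor_one(self):
        ws = make_windows([TargetRegion("chr1", 0, 100)], 100, 100)
        m = library_size_normalize(WindowCountMatrix(ws, ["a"], np.array([[5.0]])))
        assert m.library_factors == {"a": 1.0}

    def test_all_zero_sample_rejected(self):
        ws = make_windows([TargetRegion("chr1", 0, 100)], 100, 100)
        with pytest.raises(ValueError, match="zero"):
            library_size_normalize(WindowCountMatrix(ws, ["a", "b"], np.array([[5.0], [0.0]])))


class TestReference:
    def test_identical_samples(self):
        ws = make_windows([TargetRegion("chr1", 0, 200)], 100, 100)
        m = WindowCountMatrix(ws, ["a", "b", "c"], np.array([[7.0, 9.0]] * 3))
        assert np.allclose(build_reference(m), [7.0, 9.0])

    def test_median_is_robust_to_one_deleted_sample(self):
        ws = make_windows([TargetRegion("chr1", 0, 100)], 100, 100)
        m = WindowCountMatrix(ws, ["a", "b", "c"], np.array([[100.0], [100.0], [50.0]]))
        assert build_reference(m)[0] == pytest.approx(100.0)

    def test_exclude_self_on_two_samples(self):
        ws = make_windows([TargetRegion("chr1", 0, 100)], 100, 100)
        m = WindowCountMatrix(ws, ["a", "b"], np.array([[10.0], [30.0]]))
        assert build_reference(m, exclude_self=True, test_sample="a")[0] == pytest.approx(30.0)

    def test_exclude_self_needs_two_samples(self):
        ws = make_windows([TargetRegion("chr1", 0, 100)], 100, 100)
        m = WindowCountMatrix(ws, ["a"], np.array([[10.0]]))
        with pytest.raises(ValueError):
            build_reference(m, exclude_self=True, test_sample="a")


class TestLog2Ratio:
    WS = make_windows([TargetRegion("chr1", 0, 100)], 100, 100)

    def test_equal_counts_give_zero(self):
        t = log2_ratio_track(np.array([100.0]), np.array([100.0]), self.WS)
        assert t.M[0] == 0.0

    def test_half_depth_with_pseudocount(self):
        t = log2_ratio_track(np.array([50.0]), np.array([100.0]), self.WS, pseudocount=0.5)
        assert t.M[0] == pytest.approx(np.log2(50.5 / 100.5))

    def test_zero_count_clamped(self):
        # log2(0.5/200.5) ~ -8.65 clamps to -5
        t = log2_ratio_track(np.array([0.0]), np.array([200.0]), self.WS)
        assert t.M[0] == -5.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            log2_ratio_track(np.array([1.0, 2.0]), np.array([1.0]), self.WS)


class TestMeanShift:
    WS3 = make_windows([TargetRegion("chr1", 0, 300)], 100, 100)
    WS2 = make_windows([TargetRegion("chr1", 0, 200)], 100, 100)

    @pytest.mark.parametrize(
        "M, expected",
        [([0.0, 0.0, 0.0], [0.0, 0.0, 0.0]), ([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])],
    )
    def test_constant_tracks(self, M, expected):
        t = mean_shift_normalize(WindowRatioTrack("s", self.WS3, np.array(M)))
        assert np.allclose(t.M, expected)
        assert t.normalized

    def test_two_window_example(self):
        t = mean_shift_normalize(WindowRatioTrack("s", self.WS2, np.array([0.0, -1.0])))
        assert np.allclose(t.M, [0.5, -0.5])

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            mean_shift_normalize(WindowRatioTrack("s", [], np.array([])))

    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=200))
    def test_mean_is_zero_for_any_track(self, values):
        ws = make_windows([TargetRegion("chr1", 0, 100 * len(values))], 100, 100)
        t = mean_shift_normalize(WindowRatioTrack("s", ws, np.array(values)))
        assert abs(t.M.mean()) < 1e-9


GENE2 = GeneModel("G", "TX", "chr1", "+", (100, 300), (200, 400), 100, 400)


def _track(M, targets=None):
    ws = make_windows(targets or [TargetRegion("chr1", 0, 100 * len(M))], 100, 100)
    return WindowRatioTrack("s", ws, np.array(M, dtype=float), normalized=True)


class TestAggregateExons:
    def test_uniform_exon(self):
        track = _track([-1.0, -1.0, -1.0, 0.0], [TargetRegion("chr1", 100, 500)])
        # exon1 [100,200) gets window [100,200) only
        s = aggregate_exons(track, GENE2)
        assert (s[0].mean_M, s[0].q25_M, s[0].q75_M, s[0].n_windows) == (-1.0, -1.0, -1.0, 1)

    def test_single_window_exon(self):
        track = _track([-0.4], [TargetRegion("chr1", 100, 200)])
        s = aggregate_exons(track, GENE2)
        assert (s[0].mean_M, s[0].q25_M, s[0].q75_M) == (-0.4, -0.4, -0.4)

    def test_linear_interpolated_quartiles(self):
        model = GeneModel("G", "TX", "chr1", "+", (0,), (200,), 0, 200)
        track = _track([0.0, -2.0])
        (s,) = aggregate_exons(track, model)
        assert s.mean_M == pytest.approx(-1.0)
        assert s.q25_M == pytest.approx(-1.5)
        assert s.q75_M == pytest.approx(-0.5)

    def test_uncovered_exon_reported_empty(self):
        track = _track([0.0], [TargetRegion("chr1", 100, 200)])
        s = aggregate_exons(track, GENE2)
        assert s[1].n_windows == 0 and s[1].mean_M is None

    def test_requires_normalized_track(self):
        t = WindowRatioTrack("s", make_windows([TargetRegion("chr1", 0, 100)], 100, 100), np.array([0.0]))
        with pytest.raises(ValueError, match="normalized"):
            aggregate_exons(t, GENE2)

    def test_one_bp_overlap_assigns_window(self):
        # window [0,100) overlaps exon [99,150) by exactly 1 bp
        model = GeneModel("G", "TX", "chr1", "+", (99,), (150,), 99, 150)
        track = _track([-0.7, 0.0])
        (s,) = aggregate_exons(track, model)
        assert s.n_windows == 2  # both windows overlap by >=1 bp


class TestMosaicFraction:
    def test_zero_ratio_zero_fraction(self):
        assert estimate_mosaic_fraction(0.0) == 0.0

    def test_constitutional_het(self):
        assert estimate_mosaic_fraction(-1.0) == pytest.approx(1.0)

    def test_four_copy_background(self):
        # one allele lost among four copies: depth ratio 3/4 -> f = 0.5
        assert estimate_mosaic_fraction(np.log2(3 / 4)) == pytest.approx(0.5)

    def test_forward_inverse_identity(self):
        for f in np.arange(0.0, 1.0001, 0.1):
            M = np.log2(1 - f / 2)
            assert abs(estimate_mosaic_fraction(M) - f) < 1e-9

    def test_gain_rejected(self):
        with pytest.raises(ValueError):
            estimate_mosaic_fraction(0.2)


def summaries_for(gene, values, q75=None):
    out = []
    for i, v in enumerate(values, start=1):
        out.append(ExonSummary(gene, i, v, v - 0.2, q75 if q75 is not None else v + 0.2, 3))
    return out


class TestCallDeletions:
    def test_het_run_15_to_23(self):
        values = [0.0] * 43
        for i in range(14, 23):
            values[i] = -1.0
        s = []
        for i, v in enumerate(values, start=1):
            s.append(ExonSummary("FANCA", i, v, v - 0.2, -0.8 if v < 0 else v + 0.1, 3))
        calls = call_deletions(s)
        assert len(calls) == 1
        c = calls[0]
        assert (c.first_exon, c.last_exon, c.zygosity_class) == (15, 23, "het")
        assert c.mean_M == pytest.approx(-1.0)
        assert c.mosaic_fraction == pytest.approx(1.0)

    def test_single_last_exon_call(self):
        values = [0.0] * 38
        values[37] = -0.95
        s = [
            ExonSummary("FANCI", i, v, v - 0.1, -0.8 if v < 0 else 0.1, 2)
            for i, v in enumerate(values, start=1)
        ]
        calls = call_deletions(s)
        assert [(c.first_exon, c.last_exon, c.zygosity_class) for c in calls] == [(38, 38, "het")]

    def test_no_calls_on_flat_track(self):
        s = summaries_for("G", [0.01, -0.02, 0.0, 0.03])
        assert call_deletions(s) == []

    def test_hom_class(self):
        s = [ExonSummary("G", 1, -4.5, -4.8, -4.2, 5)]
        (c,) = call_deletions(s)
        assert c.zygosity_class == "hom" and c.mosaic_fraction is None

    def test_mosaic_mode_lowers_threshold_and_classifies(self):
        s = [ExonSummary("G", 1, -0.4, -0.5, -0.3, 5)]
        assert call_deletions(s) == []  # -0.4 above het threshold
        (c,) = call_deletions(s, mosaic_mode=True)
        assert c.zygosity_class == "mosaic"
        assert c.mosaic_fraction == pytest.approx(2 * (1 - 2**-0.4))

    def test_q75_guard_blocks_noisy_exon(self):
        # mean is low but upper quartile shows most windows are normal
        s = [ExonSummary("G", 1, -0.7, -2.0, 0.3, 5)]
        assert call_deletions(s) == []

    def test_mixed_genes_rejected(self):
        s = [ExonSummary("A", 1, 0.0, 0.0, 0.0, 1), ExonSummary("B", 1, 0.0, 0.0, 0.0, 1)]
        with pytest.raises(ValueError, match="mix"):
            call_deletions(s)

    def test_two_separate_runs(self):
        values = [0.0] * 10
        for i in (1, 2, 6):
            values[i] = -1.0
        s = [
            ExonSummary("G", i, v, v - 0.1, -0.8 if v < 0 else 0.1, 2)
            for i, v in enumerate(values, start=1)
        ]
        calls = call_deletions(s)
        assert [(c.first_exon, c.last_exon) for c in calls] == [(2, 3), (7, 7)]


class TestSelfReferenceNull:
    def test_identical_copies_give_zero_M(self, rng):
        """A sample against a reference of its own copies: pseudocount cancels
        and M is identically zero after normalization."""
        targets = [TargetRegion("chr1", 0, 1000)]
        rows = [("chr1", p, int(rng.integers(0, 300))) for p in range(1, 1001)]
        tracks = [DepthTrack.from_pairs(f"s{i}", rows) for i in range(3)]
        ws = make_windows(targets, 100, 100)
        matrix = library_size_normalize(build_count_matrix(tracks, ws))
        ref = build_reference(matrix)
        t = mean_shift_normalize(log2_ratio_track(matrix.row("s0"), ref, ws))
        assert np.all(np.abs(t.M) < 1e-9)


class TestProjectOrf:
    def test_series_lengths_and_flags(self):
        # 5 windows across the transcript span; exons [100,200) and [300,400)
        track = _track([0.0] * 5, [TargetRegion("chr1", 0, 500)])
        s = aggregate_exons(track, GENE2)
        orf, exon = project_orf(track, s, GENE2)
        assert len(orf) == 3  # windows [100,200),[200,300),[300,400) overlap tx span
        assert orf["exonic"].tolist() == [True, False, True]
        assert len(exon) == GENE2.n_exons

    def test_intron_only_windows_unflagged(self):
        model = GeneModel("G", "TX", "chr1", "+", (0, 900), (50, 1000), 0, 1000)
        track = _track([0.0] * 4, [TargetRegion("chr1", 200, 600)])
        orf, _ = project_orf(track, aggregate_exons(track, model), model)
        assert not orf["exonic"].any()
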