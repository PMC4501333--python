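"""Coverage binning, normalization, masking, smoothing and slope scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import polprime as pp
from polprime.tracks import VALID, MASKED, INTERPOLATED, BLACKLISTED

from _oracles import pileup_oracle, binned_mean_oracle, smooth_oracle
from conftest import make_track


def small_layout(length=2000, bin_size=20):
    return pp.GenomeLayout((("chr1", length),), bin_size=bin_size)


class TestBinCoverage:
    def test_stacked_reads_fill_one_bin(self):
        layout = small_layout()
        reads = pp.ReadSet.from_records(
            [("chr1", 100, 120, "+")] * 3, layout, dedup=False)
        track = pp.bin_coverage(reads, layout)
        assert track.values["chr1"][5] == 3.0
        assert track.values["chr1"].sum() == 3.0

    def test_identical_reads_collapse_to_one_stack(self):
        layout = small_layout()
        reads = pp.ReadSet.from_records([("chr1", 100, 120, "+")] * 3, layout)
        assert reads.total_unique_reads == 1
        track = pp.bin_coverage(reads, layout)
        assert track.values["chr1"][5] == 1.0

    def test_empty_readset_gives_zero_track(self):
        layout = small_layout()
        track = pp.bin_coverage(pp.ReadSet.from_records([], layout), layout)
        assert all(track.values[c].sum() == 0 for c in layout.names)

    def test_matches_per_base_pileup_oracle(self):
        rng = np.random.default_rng(42)
        layout = small_layout(2000)
        starts = rng.integers(0, 2000 - 36, size=50)
        recs = [("chr1", int(s), int(s) + 36, "+" if i % 2 else "-")
                for i, s in enumerate(starts)]
        reads = pp.ReadSet.from_records(recs, layout)
        track = pp.bin_coverage(reads, layout)
        iv = reads.intervals["chr1"]
        depth = pileup_oracle(list(zip(iv["start"], iv["end"])), 2000)
        expected = binned_mean_oracle(depth, 20)
        np.testing.assert_allclose(track.values["chr1"], expected)

    def test_read_beyond_end_rejected(self):
        layout = small_layout(100)
        with pytest.raises(ValueError, match="beyond chromosome end"):
            pp.ReadSet.from_records([("chr1", 90, 130, "+")], layout)

    def test_unknown_chromosome_named_in_error(self):
        layout = small_layout()
        with pytest.raises(KeyError, match="chrX"):
            pp.ReadSet.from_records([("chrX", 0, 36, "+")], layout)


class TestNormalizeRpm:
    def test_scales_by_library_size(self):
        track = make_track([5.0, 0.0])
        track.library_size = 2_000_000
        out = pp.normalize_rpm(track)
        assert out.values["chrT"][0] == 2.5
        assert out.normalization == "rpm"

    def test_million_read_library_is_identity(self):
        track = make_track([5.0, 7.0])
        track.library_size = 1_000_000
        np.testing.assert_array_equal(pp.normalize_rpm(track).values["chrT"], [5.0, 7.0])

    def test_double_library_halves_rpm(self):
        a = make_track([4.0]); a.library_size = 1_000_000
        b = make_track([4.0]); b.library_size = 2_000_000
        assert pp.normalize_rpm(a).values["chrT"][0] == 2 * pp.normalize_rpm(b).values["chrT"][0]

    def test_zero_library_and_double_normalization_error(self):
        track = make_track([1.0])
        with pytest.raises(ValueError):
            pp.normalize_rpm(track)
        track.library_size = 10
        once = pp.normalize_rpm(track)
        with pytest.raises(ValueError, match="already"):
            pp.normalize_rpm(once)


class TestMaskingAndInterpolation:
    def test_zero_mappability_zero_signal_masked(self):
        track = make_track([0.0, 1.0, 0.0])
        out = pp.mask_low_mappability(track, {"chrT": np.array([0.0, 1.0, 1.0])})
        assert out.mask["chrT"][0] == MASKED
        assert out.mask["chrT"][1] == VALID

    def test_full_mappability_masks_nothing(self):
        track = make_track([0.0, 0.0, 0.0])
        out = pp.mask_low_mappability(track, {"chrT": np.ones(3)})
        assert (out.mask["chrT"] == VALID).all()

    def test_mismatched_layout_errors(self):
        track = make_track([0.0, 0.0])
        with pytest.raises(ValueError, match="bins"):
            pp.mask_low_mappability(track, {"chrT": np.ones(5)})

    def test_enriched_signal_not_masked_despite_low_mappability(self):
        track = make_track([9.0, 1.0])
        out = pp.mask_low_mappability(track, {"chrT": np.zeros(2)})
        assert out.mask["chrT"][0] == VALID

    def test_interpolation_averages_flanking_bins(self):
        track = make_track([4.0, 0.0, 8.0, 1.0, 1.0, 1.0])
        track.mask["chrT"][1] = MASKED
        out = pp.interpolate_masked(track)
        assert out.values["chrT"][1] == 6.0
        assert out.mask["chrT"][1] == INTERPOLATED

    def test_masked_chromosome_start_stays_masked(self):
        track = make_track([0.0, 4.0, 4.0])
        track.mask["chrT"][0] = MASKED
        out = pp.interpolate_masked(track)
        assert out.mask["chrT"][0] == MASKED

    def test_low_signal_gaps_not_interpolated(self):
        # flanking bins below the 2x-genome-mean floor: gap stays masked
        track = make_track([1.0, 0.0, 1.0, 1.0, 1.0, 1.0])
        track.mask["chrT"][1] = MASKED
        out = pp.interpolate_masked(track)
        assert out.mask["chrT"][1] == MASKED

    def test_masked_run_inside_peak_filled_with_flank_mean(self):
        vals = np.array([1.0, 1.0, 10.0, 0.0, 0.0, 0.0, 14.0, 1.0, 1.0, 1.0])
        track = make_track(vals)
        track.mask["chrT"][3:6] = MASKED
        out = pp.interpolate_masked(track)
        np.testing.assert_array_equal(out.values["chrT"][3:6], 12.0)
        assert (out.mask["chrT"][3:6] == INTERPOLATED).all()


class TestSmooth:
    def test_three_bin_mean(self):
        out = pp.smooth(make_track([0.0, 3.0, 6.0]))
        assert out.values["chrT"][1] == 3.0

    def test_constant_track_unchanged(self):
        out = pp.smooth(make_track([4.0] * 10))
        np.testing.assert_array_equal(out.values["chrT"], 4.0)

    def test_matches_bruteforce_windowed_mean(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0, 10, size=50)
        out = pp.smooth(make_track(vals))
        np.testing.assert_allclose(out.values["chrT"], smooth_oracle(list(vals)))

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_interior_signal_conserved_on_padded_track(self, core):
        vals = np.array([0.0] * 3 + core + [0.0] * 3)
        out = pp.smooth(make_track(vals))
        assert abs(out.values["chrT"][1:-1].sum() - vals.sum()) <= 1e-6 * max(1.0, vals.sum())


class TestBlacklistInput:
    def test_input_spike_blacklists_bin(self):
        track = make_track([1.0] * 100, normalization="rpm")
        inp = make_track([1.0] * 100, normalization="rpm")
        inp.values["chrT"][40] = 50.0
        out = pp.blacklist_input(track, inp)
        assert out.mask["chrT"][40] == BLACKLISTED
        assert (out.mask["chrT"] != BLACKLISTED).sum() == 99

    def test_flat_input_blacklists_nothing(self):
        track = make_track([1.0] * 20, normalization="rpm")
        inp = make_track([2.0] * 20, normalization="rpm")
        assert (pp.blacklist_input(track, inp).mask["chrT"] == VALID).all()

    def test_layout_mismatch_errors(self):
        with pytest.raises(ValueError, match="layout"):
            pp.blacklist_input(make_track([1.0] * 4), make_track([1.0] * 8))


class TestSlopeScores:
    def test_stated_difference_quotient(self):
        vals = np.zeros(9)
        vals[0], vals[6] = 10.0, 30.0
        slopes = pp.slope_scores(make_track(vals))
        assert slopes.slopes["chrT"][3] == pytest.approx((30.0 - 10.0) / 100.0)

    def test_constant_track_zero_slope(self):
        slopes = pp.slope_scores(make_track([5.0] * 20))
        assert (slopes.slopes["chrT"][slopes.defined["chrT"]] == 0).all()

    def test_undefined_near_ends_and_masked_bins(self):
        track = make_track([1.0] * 30)
        track.mask["chrT"][15] = MASKED
        slopes = pp.slope_scores(track)
        d = slopes.defined["chrT"]
        assert not d[:3].any() and not d[-3:].any()
        assert not d[12:19].any()      # ±3-bin support touches the masked bin
        assert d[11] and d[19]

    def test_mirrored_track_negates_slopes(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 5, size=40)
        fwd = pp.slope_scores(make_track(vals))
        rev = pp.slope_scores(make_track(vals[::-1]))
        np.testing.assert_allclose(
            rev.slopes["chrT"][::-1][fwd.defined["chrT"]],
            -fwd.slopes["chrT"][fwd.defined["chrT"]],
        )

    @given(st.lists(st.floats(0, 50, allow_nan=False), min_size=8, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_track_has_nonnegative_slopes(self, raw):
        vals = np.sort(np.asarray(raw))
        slopes = pp.slope_scores(make_track(vals))
        d = slopes.defined["chrT"]
        assert (slopes.slopes["chrT"][d] >= 0).all()


def test_rpm_scale_equivariance():
    """Doubling every read doubles raw values but leaves RPM unchanged."""
    layout = pp.GenomeLayout((("chr1", 2000),), bin_size=20)
    rng = np.random.default_rng(11)
    starts = rng.integers(0, 2000 - 36, size=80)
    recs = [("chr1", int(s), int(s) + 36, "+") for s in starts]
    single = pp.ReadSet.from_records(recs, layout, dedup=False)
    double = pp.ReadSet.from_records(recs * 2, layout, dedup=False)
    t1, t2 = pp.bin_coverage(single, layout), pp.bin_coverage(double, layout)
    np.testing.assert_allclose(t2.values["chr1"], 2 * t1.values["chr1"])
    np.testing.assert_allclose(
        pp.normalize_rpm(t2).values["chr1"], pp.normalize_rpm(t1).values["chr1"])
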