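"""Slope-run pairing, multiplet merging, background and signal filters."""

import dataclasses

import numpy as np
import pytest

import polprime as pp
from polprime.features import (DetectionConfig, RNAPIIFeature, annotate_signal,
                               annotate_tags, find_slope_runs, merge_multiplets,
                               local_background_filter, pair_runs,
                               signal_threshold_filter, union_features)

from conftest import make_track, triangle, random_fixture


CFG = DetectionConfig(slope_threshold=0.02)


def runs_of(values, thr=0.02):
    track = make_track(values)
    slopes = pp.slope_scores(track)
    return find_slope_runs(slopes, DetectionConfig(slope_threshold=thr)), track


class TestSlopeRuns:
    def test_triangular_peak_gives_one_rise_and_one_fall(self):
        vals = triangle(60, center=30, half_width=12, height=30.0, base=1.0)
        runs, _ = runs_of(vals)
        assert [r.sign for r in runs] == [1, -1]

    def test_constant_track_has_no_runs(self):
        runs, _ = runs_of(np.full(50, 7.0))
        assert runs == []

    def test_two_peak_fixture_gives_four_runs_at_expected_bins(self):
        vals = np.maximum(triangle(120, 30, 10, 20.0), triangle(120, 80, 10, 20.0))
        runs, track = runs_of(vals)
        assert [r.sign for r in runs] == [1, -1, 1, -1]
        # hand-computed for the first peak (apex bin 30, flank slope 2/bin):
        # v[i+3]-v[i-3] > 2 holds for i = 19..29, < -2 for i = 31..41
        assert (runs[0].start_bin, runs[0].end_bin) == (19, 30)
        assert (runs[1].start_bin, runs[1].end_bin) == (31, 42)
        assert runs[0].extremum_slope == pytest.approx(0.12)

    def test_nonpositive_threshold_rejected(self):
        track = make_track(np.zeros(20))
        slopes = pp.slope_scores(track)
        with pytest.raises(ValueError):
            find_slope_runs(slopes, DetectionConfig())  # unresolved auto threshold


class TestPairing:
    def layout(self, n=200):
        return pp.GenomeLayout((("chrT", n * 20),), bin_size=20)

    def mkrun(self, s, e, sign):
        return pp.SlopeRun("chrT", s, e, sign, 0.1 * sign)

    def test_gap_over_cutoff_not_paired(self):
        runs = [self.mkrun(40, 50, 1), self.mkrun(75, 85, -1)]  # gap 500 bp
        assert pair_runs(runs, CFG, self.layout()) == []

    def test_gap_within_cutoff_paired(self):
        runs = [self.mkrun(40, 50, 1), self.mkrun(65, 85, -1)]  # gap 300 bp
        feats = pair_runs(runs, CFG, self.layout())
        assert [(f.start, f.end) for f in feats] == [(800, 1700)]

    def test_nearest_downstream_fall_wins(self):
        runs = [self.mkrun(40, 50, 1), self.mkrun(55, 60, -1), self.mkrun(65, 70, -1)]
        feats = pair_runs(runs, CFG, self.layout())
        assert [(f.start, f.end) for f in feats] == [(800, 1200)]

    def test_each_fall_consumed_once(self):
        # both rises are within range of the single fall; the upstream one
        # claims it and the second stays unpaired
        runs = [self.mkrun(10, 20, 1), self.mkrun(21, 24, 1), self.mkrun(25, 30, -1)]
        feats = pair_runs(runs, CFG, self.layout())
        assert [(f.start, f.end) for f in feats] == [(200, 600)]


def doublet_track(max_left, max_right, trough, base=0.1):
    """Noise-free two-summit profile with controlled peak/trough levels."""
    left = triangle(120, 35, 12, max_left - base, base)
    right = triangle(120, 65, 12, max_right - base, base)
    vals = np.maximum(left, right)
    # floor the whole inter-summit valley at the requested trough level
    vals[36:65] = np.maximum(vals[36:65], trough)
    return make_track(vals)


class TestMerging:
    def features(self):
        return [RNAPIIFeature("chrT", 23 * 20, 48 * 20), RNAPIIFeature("chrT", 52 * 20, 78 * 20)]

    def test_poorly_resolved_doublet_merges(self):
        track = doublet_track(10.0, 8.0, trough=5.0)   # ratio 8/5 = 1.6 < 2.5
        merged = merge_multiplets(self.features(), track, CFG)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (23 * 20, 78 * 20)

    def test_resolved_doublet_stays_separate(self):
        track = doublet_track(10.0, 9.0, trough=2.0)   # ratio 9/2 = 4.5
        assert len(merge_multiplets(self.features(), track, CFG)) == 2

    def test_zero_trough_never_merges(self):
        track = doublet_track(10.0, 8.0, trough=0.0, base=0.0)
        assert len(merge_multiplets(self.features(), track, CFG)) == 2

    def test_chain_of_three_merges_to_fixpoint(self):
        base = 1.0
        vals = np.maximum.reduce([
            triangle(160, 30, 10, 9.0, base),
            triangle(160, 55, 10, 9.0, base),
            triangle(160, 80, 10, 9.0, base),
        ])
        # valley floor 7 between the outer summits: both pairwise
        # peak-to-trough ratios are 10/7 ≈ 1.43 < 2.5
        vals[31:80] = np.maximum(vals[31:80], 7.0)
        track = make_track(vals)
        feats = [RNAPIIFeature("chrT", 20 * 20, 41 * 20),
                 RNAPIIFeature("chrT", 44 * 20, 66 * 20),
                 RNAPIIFeature("chrT", 69 * 20, 91 * 20)]
        merged = merge_multiplets(feats, track, CFG)
        assert len(merged) == 1
        assert len(merged[0].merged_from) == 3
        assert (merged[0].start, merged[0].end) == (20 * 20, 91 * 20)


class TestBackgroundFilter:
    def test_boundary_inclusive_acceptance(self):
        vals = np.full(300, 10.0)
        track = make_track(vals)
        f = RNAPIIFeature("chrT", 100 * 20, 110 * 20)
        annotate_signal([f], track)
        f.max_ushp = 35.0
        out = local_background_filter([f], track, CFG)
        assert out[0].status == "candidate"          # 35 >= 3.5 × 10, inclusive

    def test_below_threshold_rejected(self):
        track = make_track(np.full(300, 10.0))
        f = RNAPIIFeature("chrT", 100 * 20, 110 * 20)
        annotate_signal([f], track)
        f.max_ushp = 30.0
        assert local_background_filter([f], track, CFG)[0].status == "background_filtered"

    def test_two_features_share_domain_background(self):
        vals = np.full(400, 2.0)
        vals[100:110] = 40.0
        vals[160:170] = 8.0   # centers 1.2 kb apart -> same domain
        track = make_track(vals)
        f1 = RNAPIIFeature("chrT", 100 * 20, 110 * 20)
        f2 = RNAPIIFeature("chrT", 160 * 20, 170 * 20)
        annotate_signal([f1, f2], track)
        out = local_background_filter([f1, f2], track, CFG)
        # shared background = 2.0 (non-peak bins): 40 >= 7 accepted, 8 >= 7 accepted
        assert [f.status for f in out] == ["candidate", "candidate"]

    def test_no_background_bins_accepts_with_warning(self):
        vals = np.full(50, 30.0)
        track = make_track(vals)
        f = RNAPIIFeature("chrT", 0, 50 * 20)
        annotate_signal([f], track)
        with pytest.warns(UserWarning, match="background"):
            out = local_background_filter([f], track, CFG)
        assert out[0].status == "candidate"


class TestSignalFilter:
    @pytest.mark.parametrize("tags,length,expected", [
        (25, 500, "accepted"),       # count rule
        (10, 1, "signal_filtered"),  # density 10/bp < 14.5, count 10 < 20
        (15, 1, "accepted"),         # density 15/bp >= 14.5
        (10, 500, "signal_filtered"),
    ])
    def test_count_or_density_rule(self, tags, length, expected):
        f = RNAPIIFeature("chrT", 0, length, tag_count=tags,
                          tag_density=tags / length, status="candidate")
        assert signal_threshold_filter([f], CFG)[0].status == expected


class TestDetectComposition:
    def test_single_condition_union_is_that_condition(self, mini, mini_tracks):
        fs = pp.detect({"HD": (mini_tracks["HD"], mini.readsets["HD"])})
        accepted = [f for f in fs.per_track["HD"] if f.status == "accepted"]
        assert [(u.chrom, u.start, u.end) for u in fs.union] == \
            [(f.chrom, f.start, f.end) for f in accepted]

    def test_union_never_larger_than_per_track_sum(self, mini_detection):
        total = sum(sum(f.status == "accepted" for f in feats)
                    for feats in mini_detection.per_track.values())
        assert 0 < len(mini_detection.union) <= total

    def test_accepted_features_non_overlapping_within_track(self, mini_detection):
        for feats in mini_detection.per_track.values():
            acc = sorted((f for f in feats if f.status == "accepted"),
                         key=lambda f: (f.chrom, f.start))
            for a, b in zip(acc, acc[1:]):
                assert a.chrom != b.chrom or a.end <= b.start


class TestInvariances:
    def test_translation_by_whole_bins(self):
        layout = pp.GenomeLayout((("chrF", 8000),), bin_size=20)
        rng = np.random.default_rng(5)
        starts = np.concatenate([
            rng.integers(0, 8000 - 36, size=1500),
            np.clip(rng.normal(3000, 150, size=1200).astype(np.int64), 0, 8000 - 36),
        ])
        strands = rng.integers(0, 2, size=len(starts)) * 2 - 1
        shift = 40 * 20
        layout2 = pp.GenomeLayout((("chrF", 8000 + shift),), bin_size=20)
        r1 = pp.ReadSet.from_arrays({"chrF": (starts, starts + 36, strands)}, layout=layout)
        r2 = pp.ReadSet.from_arrays({"chrF": (starts + shift, starts + shift + 36, strands)}, layout=layout2)
        cfg = DetectionConfig(slope_threshold=0.1)
        f1 = pp.detect_track(pp.process_track(r1, layout, rpm=False), r1, cfg)
        f2 = pp.detect_track(pp.process_track(r2, layout2, rpm=False), r2, cfg)
        a1 = [(f.start, f.end, f.status) for f in f1 if f.status == "accepted"]
        a2 = [(f.start - shift, f.end - shift, f.status) for f in f2 if f.status == "accepted"]
        assert a1 == a2 and a1

    def test_chromosome_order_invariance(self, mini):
        sub = {c: rs for c, rs in mini.readsets.items() if c == "HD"}
        layout_fwd = mini.layout
        layout_rev = pp.GenomeLayout(tuple(reversed(layout_fwd.chromosomes)), bin_size=20)
        t_fwd = pp.process_track(sub["HD"], layout_fwd)
        t_rev = pp.process_track(sub["HD"], layout_rev)
        f_fwd = pp.detect_track(t_fwd, sub["HD"])
        f_rev = pp.detect_track(t_rev, sub["HD"])
        key = lambda fs: sorted((f.chrom, f.start, f.end, f.status) for f in fs)
        assert key(f_fwd) == key(f_rev)

    def test_raising_thresholds_never_adds_features(self):
        track, reads, _ = random_fixture(seed=12)
        def n_accepted(cfg):
            return sum(f.status == "accepted" for f in pp.detect_track(track, reads, cfg))
        base = DetectionConfig().resolved(track)
        higher = dataclasses.replace(base, slope_threshold=2 * base.slope_threshold)
        assert n_accepted(higher) <= n_accepted(base)
        assert n_accepted(dataclasses.replace(base, enrichment_fold=7.0)) <= n_accepted(base)

    def test_flat_track_any_level_yields_nothing(self):
        for level in (0.0, 1.0, 250.0):
            track = make_track(np.full(500, level))
            reads = pp.ReadSet.from_records([], track.layout)
            feats = pp.detect_track(track, reads)
            assert feats == []
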