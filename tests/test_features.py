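import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragsite import features, simulate
from fragsite.features import FeatureTrack, Locus, LocusSet, WindowStat


def _track(intervals):
    """intervals: list of (chrom, start, end, value)"""
    data = {}
    for chrom in {iv[0] for iv in intervals}:
        rows = [iv for iv in intervals if iv[0] == chrom]
        data[chrom] = (np.array([r[1] for r in rows]),
                       np.array([r[2] for r in rows]),
                       np.array([r[3] for r in rows], dtype=float))
    return FeatureTrack(data)


def per_bp_mean_oracle(intervals, chrom, lo, hi):
    """Brute-force per-base enumeration of the window mean."""
    vals = []
    for c, s, e, v in intervals:
        if c != chrom:
            continue
        for bp in range(max(s, lo), min(e, hi)):
            vals.append(v)
    return float(np.mean(vals)) if vals else math.nan


class TestWindowAggregate:
    def test_constant_track_gives_constant_mean(self):
        track = _track([("chr1", 0, 1_000_000, 3.5)])
        loci = LocusSet([Locus("chr1", 500_000, 500_100, "l")])
        (stat,) = features.window_aggregate(track, loci, 50_000)
        assert stat.value == pytest.approx(3.5)

    def test_signal_outside_window_gives_zero(self):
        track = _track([("chr1", 0, 10_000, 9.0), ("chr1", 10_000, 900_000, 0.0)])
        loci = LocusSet([Locus("chr1", 500_000, 500_100, "l")])
        (stat,) = features.window_aggregate(track, loci, 50_000)
        assert stat.value == pytest.approx(0.0)

    def test_piecewise_track_matches_per_bp_oracle(self):
        intervals = [("chr1", 0, 300, 1.0), ("chr1", 300, 700, 4.0),
                     ("chr1", 900, 1500, -2.0)]
        track = _track(intervals)
        loci = LocusSet([Locus("chr1", 495, 505, "l")])  # center 500
        (stat,) = features.window_aggregate(track, loci, 450)  # window [50, 950)
        assert stat.value == pytest.approx(per_bp_mean_oracle(intervals, "chr1", 50, 950))

    def test_uncovered_chromosome_gives_nan(self):
        track = _track([("chr1", 0, 100, 1.0)])
        loci = LocusSet([Locus("chr2", 500, 600, "l")])
        (stat,) = features.window_aggregate(track, loci, 100)
        assert math.isnan(stat.value)

    def test_count_mode_uses_midpoints(self):
        track = _track([("chr1", 480, 520, 1.0), ("chr1", 940, 1040, 1.0)])
        loci = LocusSet([Locus("chr1", 495, 505, "l")])  # window [250, 750)
        (stat,) = features.window_aggregate(track, loci, 250, mode="count")
        assert stat.value == 1.0  # second feature's midpoint (990) is outside

    @given(split_at=st.integers(min_value=101, max_value=899))
    @settings(max_examples=40, deadline=None)
    def test_invariant_to_splitting_equal_valued_intervals(self, split_at):
        whole = _track([("chr1", 100, 900, 2.5)])
        split = _track([("chr1", 100, split_at, 2.5), ("chr1", split_at, 900, 2.5)])
        loci = LocusSet([Locus("chr1", 400, 420, "l")])
        a = features.window_aggregate(whole, loci, 350)[0].value
        b = features.window_aggregate(split, loci, 350)[0].value
        assert a == pytest.approx(b)


class TestSelectControls:
    def _pool(self, units):
        return LocusSet([Locus("chr1", 1000 * i + 100, 1000 * i + 200, f"c{i}",
                               repeat_units=u) for i, u in enumerate(units)])

    def test_all_below_threshold_errors(self):
        with pytest.raises(ValueError, match="no candidates"):
            features.select_controls(self._pool([2.0, 4.0, 4.5]))

    def test_filter_and_median(self):
        kept, median = features.select_controls(self._pool([4.0, 5.0, 6.0, 7.0]))
        assert [l.repeat_units for l in kept.loci] == [5.0, 6.0, 7.0]
        assert median == 6.0

    def test_engineered_pool_gives_planted_median(self):
        units = [3.0, 4.0, 5.0, 8.7, 100.0]  # filtered: 5.0, 8.7, 100.0
        _, median = features.select_controls(self._pool(units))
        assert median == pytest.approx(8.7)

    def test_subsampling_is_seeded_and_sized(self):
        pool = self._pool(list(np.linspace(5, 50, 200)))
        a, _ = features.select_controls(pool, n_target=30, seed=4)
        b, _ = features.select_controls(pool, n_target=30, seed=4)
        assert len(a) == 30
        assert [l.id for l in a.loci] == [l.id for l in b.loci]

    def test_generator_default_pool_median_near_target(self):
        pool = simulate.simulate_control_loci(944, seed=0)
        _, median = features.select_controls(pool, min_units=4.5)
        assert median == pytest.approx(8.7, abs=0.5)


class TestCompareSets:
    def _stats(self, values):
        return [WindowStat(f"l{i}", 50_000, v) for i, v in enumerate(values)]

    def test_identical_multisets_give_p_one(self):
        s = self._stats([1.0, 2.0, 3.0])
        res = features.compare_sets(s, list(s))
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_3v3_exact_p(self):
        """All 3 fragile-site values above all 3 controls: exact two-sided
        rank-sum p = 2/20 = 0.1 (enumeration of the 20 rank assignments)."""
        res = features.compare_sets(self._stats([10.0, 11.0, 12.0]),
                                    self._stats([1.0, 2.0, 3.0]))
        assert res.p_value == pytest.approx(0.1)
        assert res.direction == 1

    def test_nan_windows_dropped_and_counted(self):
        res = features.compare_sets(self._stats([1.0, float("nan"), 3.0, 4.0]),
                                    self._stats([2.0, 5.0, 6.0]))
        assert res.n_dropped == 1
        assert res.n_fsfs == 3

    def test_planted_shift_detected_with_high_power(self):
        """Effect far above noise: rejection at 0.01 in >99% of replicates."""
        fsfs = LocusSet([Locus("chrA", 150_000 * i + 60_000, 150_000 * i + 60_100,
                               f"f{i}") for i in range(20)])
        ctrl = LocusSet([Locus("chrB", 150_000 * i + 60_000, 150_000 * i + 60_100,
                               f"c{i}", repeat_units=6.0) for i in range(20)])
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            track = simulate.simulate_feature_tracks(fsfs, ctrl, effect=5.0,
                                                     half_width=50_000, seed=seed)
            fs = features.window_aggregate(track, fsfs, 50_000)
            cs = features.window_aggregate(track, ctrl, 50_000)
            if features.compare_sets(fs, cs).p_value < 0.01:
                rejections += 1
        assert rejections / n_rep > 0.99


class TestBoundaryDensity:
    def test_no_features_gives_zero_counts(self):
        loci = LocusSet([Locus("chr1", 1_000_000, 1_000_100, "l")])
        empty = LocusSet([])
        assert features.boundary_density(empty, empty, loci) == [("l", 0, 0)]

    def test_site_at_center_counted_once(self):
        loci = LocusSet([Locus("chr1", 1_000_000, 1_000_100, "l")])
        ctcf = LocusSet([Locus("chr1", 1_000_040, 1_000_060, "s")])
        assert features.boundary_density(ctcf, LocusSet([]), loci) == [("l", 1, 0)]

    def test_straddling_features_follow_midpoint_rule(self):
        loci = LocusSet([Locus("chr1", 1_000_000, 1_000_002, "l")])  # center 1_000_001
        half = 50_000
        # midpoints at exactly lo-1, lo, hi-1, hi of window [950_001, 1_050_001)
        mids = [950_000, 950_001, 1_050_000, 1_050_001]
        sites = LocusSet([Locus("chr1", m - 10, m + 10, f"s{i}")
                          for i, m in enumerate(mids)])
        (result,) = features.boundary_density(sites, LocusSet([]), loci, window=2 * half)
        expected = sum(1 for m in mids if 950_001 <= m < 1_050_001)
        assert result[1] == expected == 2


def test_bh_adjustment_emitted_alongside_raw():
    raw = [0.001, 0.02, 0.8, 0.04]
    adj = features.bh_adjust(raw)
    assert all(a >= r for a, r in zip(adj, raw))
    assert adj[2] == pytest.approx(0.8)
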