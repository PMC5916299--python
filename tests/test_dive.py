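"""Dive detection, bouts, trips, classifications, and track filtering."""

import numpy as np
import pytest

from divefmr import dive as dv
from divefmr.simulate import SimConfig, apply_drift, simulate_dive_record
from divefmr.solar import solar_elevation

T0 = np.datetime64("2014-11-20T00:00:00", "s")


def make_trace(depths, dt=1.0, animal="A"):
    depths = np.asarray(depths, dtype=float)
    times = T0 + (np.arange(len(depths)) * dt).astype("timedelta64[s]")
    return dv.DepthTrace(animal, times, depths, dt)


def square_dive(depth, n_samples, lead=5, trail=5):
    return np.concatenate([np.zeros(lead), np.full(n_samples, depth), np.zeros(trail)])


def brute_force_dives(trace, depth_min=4.0, duration_min=16.0, surface=1.0):
    """Independent threshold-scan oracle: plain loop over samples."""
    out = []
    run = []
    depths = list(trace.depth_m) + [0.0]
    for i, d in enumerate(depths):
        if d > surface:
            run.append(i)
        elif run:
            dur = (run[-1] - run[0] + 1) * trace.sampling_interval_s
            max_d = max(trace.depth_m[run[0] : run[-1] + 1])
            if max_d >= depth_min and dur >= duration_min:
                out.append((run[0], run[-1], max_d, dur))
            run = []
    return out


class TestZeroOffset:
    def test_constant_offset_removed(self):
        trace = make_trace(square_dive(50.0, 60, lead=100, trail=100) + 1.5)
        corr = dv.zero_offset_correct(trace)
        surface = corr.depth_m[:90]
        assert np.all(np.abs(surface) <= 0.1)

    def test_drift_free_trace_unchanged(self):
        trace = make_trace(square_dive(50.0, 60, lead=100, trail=100))
        corr = dv.zero_offset_correct(trace)
        assert np.allclose(corr.depth_m, trace.depth_m, atol=1e-9)

    def test_linear_drift_recovers_planted_depths(self):
        cfg = SimConfig(seed=21, sampling_interval_s=2.0, n_trips_range=(1, 1),
                        trip_duration_days_range=(1.0, 1.0))
        trace, _, truth = simulate_dive_record(cfg, 0)
        drifted = apply_drift(trace, kind="linear", magnitude_m=2.0)
        corr = dv.zero_offset_correct(drifted)
        clean = dv.detect_dives(trace)
        recovered = dv.detect_dives(corr)
        assert len(recovered) == len(clean) == truth.n_valid_dives
        for a, b in zip(clean, recovered):
            assert b.max_depth == pytest.approx(a.max_depth, abs=0.2)


class TestDetectDives:
    def test_below_depth_threshold_ignored(self):
        trace = make_trace(square_dive(3.9, 120))
        assert dv.detect_dives(trace) == []

    def test_square_wave_dive(self):
        trace = make_trace(square_dive(50.0, 60))
        dives = dv.detect_dives(trace)
        assert len(dives) == 1
        assert dives[0].max_depth == 50.0
        assert dives[0].duration_s == 60.0

    def test_too_brief_submergence_ignored(self):
        trace = make_trace(square_dive(50.0, 10))
        assert dv.detect_dives(trace) == []

    def test_empty_trace(self):
        assert dv.detect_dives(make_trace([])) == []

    @pytest.mark.parametrize("dt", [1.0, 2.0, 5.0, 10.0])
    def test_census_matches_planted_truth(self, dt):
        cfg = SimConfig(seed=13, sampling_interval_s=dt, n_trips_range=(1, 1),
                        trip_duration_days_range=(0.5, 0.5))
        trace, _, truth = simulate_dive_record(cfg, 1)
        dives = dv.detect_dives(trace)
        assert len(dives) == truth.n_valid_dives

    def test_agrees_with_brute_force_oracle(self):
        cfg = SimConfig(seed=17, sampling_interval_s=2.0, n_trips_range=(1, 1),
                        trip_duration_days_range=(0.5, 0.5))
        trace, _, _ = simulate_dive_record(cfg, 2)
        dives = dv.detect_dives(trace)
        oracle = brute_force_dives(trace)
        assert len(dives) == len(oracle)
        for d, (i0, i1, max_d, dur) in zip(dives, oracle):
            assert d.start == trace.times[i0]
            assert d.max_depth == pytest.approx(max_d)
            assert d.duration_s == pytest.approx(dur)

    def test_thresholds_hold_for_every_detected_dive(self):
        cfg = SimConfig(seed=19, sampling_interval_s=2.0, n_trips_range=(1, 1),
                        trip_duration_days_range=(0.5, 0.5))
        trace, _, _ = simulate_dive_record(cfg, 3)
        for d in dv.detect_dives(trace):
            assert d.max_depth >= 4.0
            assert d.duration_s >= 16.0
            assert 0 < d.descent_rate <= 3.0
            assert 0 < d.ascent_rate <= 3.0

    def test_counts_invariant_to_added_surface_time(self):
        base = np.concatenate([square_dive(30.0, 60), square_dive(80.0, 90)])
        n0 = len(dv.detect_dives(make_trace(base)))
        padded = np.concatenate(
            [square_dive(30.0, 60), np.zeros(7200), square_dive(80.0, 90)]
        )
        assert len(dv.detect_dives(make_trace(padded))) == n0


def dives_with_gaps(gaps_s, duration=60.0):
    """Synthetic dive list with specified surface intervals between dives."""
    dives, t = [], T0
    for g in [0.0] + list(gaps_s):
        t = t + np.timedelta64(int(g), "s")
        dives.append(
            dv.Dive(start=t, end=t + np.timedelta64(int(duration), "s"),
                    max_depth=50.0, duration_s=duration, descent_rate=1.2,
                    ascent_rate=1.2, bottom_time_s=20.0)
        )
        t = dives[-1].end
    return dives


class TestBouts:
    def test_all_short_gaps_one_bout(self):
        dives = dives_with_gaps([30.0] * 9)
        bouts = dv.detect_bouts(dives, criterion=300.0)
        assert len(bouts) == 1
        assert len(bouts[0].dives) == 10

    def test_alternating_gaps_split_into_pairs(self):
        dives = dives_with_gaps([30.0, 7200.0, 30.0, 7200.0, 30.0])
        bouts = dv.detect_bouts(dives, criterion=300.0)
        assert [len(b.dives) for b in bouts] == [2, 2, 2]

    def test_single_dive_single_bout(self):
        dives = dives_with_gaps([])
        assert len(dv.detect_bouts(dives)) == 1

    def test_partition_is_exhaustive_and_disjoint(self):
        cfg = SimConfig(seed=23, sampling_interval_s=2.0, n_trips_range=(1, 1),
                        trip_duration_days_range=(1.0, 1.0))
        trace, _, truth = simulate_dive_record(cfg, 4)
        dives = dv.detect_dives(trace)
        bouts = dv.detect_bouts(dives, criterion=600.0)
        assert sum(len(b.dives) for b in bouts) == len(dives)
        assert len(bouts) == truth.n_bouts

    def test_survivorship_criterion_separates_bimodal_gaps(self):
        # planted structure: ~1 min within bouts, ~45-90 min between
        cfg = SimConfig(seed=29, sampling_interval_s=2.0, n_trips_range=(1, 1),
                        trip_duration_days_range=(2.0, 2.0))
        trace, _, truth = simulate_dive_record(cfg, 5)
        dives = dv.detect_dives(trace)
        gaps = np.array(
            [(b.start - a.end).astype("timedelta64[s]").astype(float)
             for a, b in zip(dives[:-1], dives[1:])]
        )
        crit = dv.bout_criterion_survivorship(gaps)
        assert 120.0 < crit < 2700.0
        bouts = dv.detect_bouts(dives, dv.BoutCriterionSpec(mode="survivorship"))
        assert len(bouts) == truth.n_bouts

    def test_survivorship_falls_back_when_underdetermined(self):
        assert dv.bout_criterion_survivorship(np.array([60.0, 60.0, 60.0])) == 600.0


class TestTrips:
    def test_continuous_wet_record_is_one_trip(self):
        cycle = square_dive(30.0, 60, lead=30, trail=30)
        depths = np.tile(cycle, 3 * 86400 // len(cycle))
        trace = make_trace(depths)
        trips = dv.segment_trips(trace, dv.detect_dives(trace))
        assert len(trips) == 1

    def test_short_excursion_is_not_a_trip(self):
        # 5 hr of diving bounded by long haul-outs
        cycle = square_dive(30.0, 60, lead=30, trail=30)
        wet = np.tile(cycle, 5 * 3600 // len(cycle))
        depths = np.concatenate([np.zeros(3600 * 2), wet, np.zeros(3600 * 2)])
        trace = make_trace(depths)
        trips = dv.segment_trips(trace, dv.detect_dives(trace))
        assert trips == []

    def test_simulator_trip_boundaries_recovered(self):
        cfg = SimConfig(seed=31, sampling_interval_s=2.0, n_trips_range=(3, 3),
                        trip_duration_days_range=(1.0, 2.0))
        trace, _, truth = simulate_dive_record(cfg, 6)
        dives = dv.detect_dives(trace)
        trips = dv.segment_trips(trace, dives)
        assert len(trips) == 3
        for trip, (t_start, t_end) in zip(trips, truth.trip_bounds):
            assert abs((trip.start - t_start).astype(float)) <= cfg.sampling_interval_s
            assert abs((trip.end - t_end).astype(float)) <= 2 * cfg.sampling_interval_s


class TestDayNight:
    LAT, LON = 33.25, -119.5

    def test_local_noon_is_day_midnight_is_night(self):
        # local solar time at 119.5W trails UTC by ~8 hr
        noon = np.datetime64("2014-11-20T20:00:00")
        midnight = np.datetime64("2014-11-20T08:00:00")
        assert dv.classify_day_night(np.array([noon]), self.LAT, self.LON)[0]
        assert not dv.classify_day_night(np.array([midnight]), self.LAT, self.LON)[0]

    def test_exactly_two_transitions_per_day(self):
        times = np.datetime64("2014-11-20T00:00:00") + np.arange(0, 86400, 60).astype(
            "timedelta64[s]"
        )
        elev = solar_elevation(times, self.LAT, self.LON)
        crossings = np.sum(np.diff(np.sign(elev)) != 0)
        assert crossings == 2

    def test_missing_location_uses_fallback_with_warning(self):
        t = np.array([np.datetime64("2014-11-20T20:00:00")])
        with pytest.warns(UserWarning, match="fallback"):
            out = dv.classify_day_night(t, None, None, fallback=(self.LAT, self.LON))
        assert out[0]
        with pytest.raises(ValueError):
            dv.classify_day_night(t, None, None)


def make_dive(depth, duration=120.0, bottom=60.0, start=T0):
    return dv.Dive(start=start, end=start + np.timedelta64(int(duration), "s"),
                   max_depth=depth, duration_s=duration, descent_rate=1.2,
                   ascent_rate=1.2, bottom_time_s=bottom)


class TestBenthicClassification:
    def test_identical_flat_dives_all_benthic(self):
        dives = [make_dive(100.0, bottom=70.0) for _ in range(10)]
        assert dv.classify_benthic(dives).all()

    def test_random_v_dives_mostly_pelagic(self, rng):
        dives = [
            make_dive(d, duration=200.0, bottom=20.0)
            for d in rng.uniform(30, 180, size=60)
        ]
        frac = dv.classify_benthic(dives).mean()
        assert frac < 0.3

    def test_single_dive_benthic_by_convention(self):
        assert dv.classify_benthic([make_dive(55.0, bottom=10.0)])[0]

    def test_agreement_with_simulator_labels(self):
        cfg = SimConfig(seed=37, sampling_interval_s=2.0, n_trips_range=(1, 1),
                        trip_duration_days_range=(1.5, 1.5))
        agree = []
        for i in range(4):
            trace, _, truth = simulate_dive_record(cfg, i, strategy="mixed")
            dives = dv.detect_dives(trace)
            pred = dv.classify_benthic(dives)
            true = np.array([t == "benthic" for t in truth.dive_types])
            agree.append(np.mean(pred == true))
        assert np.mean(agree) >= 0.9


class TestTripSummaries:
    def _trip(self, dives, hours=10.0):
        trip = dv.Trip("A", T0, T0 + np.timedelta64(int(hours * 3600), "s"), dives)
        trip.bouts = dv.detect_bouts(dives, criterion=600.0)
        return trip

    def test_mean_depth_and_duration(self):
        d1 = make_dive(50.0, duration=100.0)
        d2 = make_dive(150.0, duration=200.0, start=T0 + np.timedelta64(600, "s"))
        m = dv.trip_metrics(self._trip([d1, d2]))
        assert m["mean_depth_m"] == 100.0
        assert m["mean_duration_s"] == 150.0
        assert m["n_dives"] == 2
        assert 0 <= m["percent_time_diving"] <= 100

    def test_no_dives_gives_all_missing(self):
        m = dv.trip_metrics(self._trip([]))
        assert all(np.isnan(v) for v in m.values())
        assert set(m) == set(dv.TRIP_METRIC_NAMES)

    def test_water_column_partition_sums_to_100(self):
        dives = [make_dive(d) for d in (50.0, 120.0, 250.0, 300.0, 80.0)]
        for i, d in enumerate(dives):
            d.is_day = i % 2 == 0
            d.is_benthic = i == 0
        sv = dv.strategy_variables(self._trip(dives))
        total = sv["percent_benthic"] + sv["percent_epipelagic"] + sv["percent_mesopelagic"]
        assert total == pytest.approx(100.0)

    def test_all_day_trip_has_missing_night_entries(self):
        dives = [make_dive(60.0), make_dive(70.0, start=T0 + np.timedelta64(900, "s"))]
        for d in dives:
            d.is_day, d.is_benthic = True, False
        sv = dv.strategy_variables(self._trip(dives))
        assert np.isnan(sv["mean_night_depth_m"])
        assert sv["mean_day_depth_m"] == pytest.approx(65.0)
        assert sv["percent_day_dives"] == 100.0

    def test_unlabeled_dives_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            dv.strategy_variables(self._trip([make_dive(60.0)]))


def walk_fixes(n=24, lat0=33.0, lon0=-119.0, dlat=0.01):
    return [
        dv.TrackFix(time=T0 + np.timedelta64(i * 3600, "s"), lat=lat0 + i * dlat, lon=lon0)
        for i in range(n)
    ]


class TestTrackFilter:
    def test_spike_removed(self):
        fixes = walk_fixes()
        spiked = list(fixes)
        spiked[10] = dv.TrackFix(time=fixes[10].time, lat=fixes[10].lat + 1.0, lon=-119.0)
        kept = dv.filter_track(spiked)
        assert len(kept) == len(fixes) - 1
        assert all(f.lat < 34.0 for f in kept)

    def test_smooth_track_unchanged(self):
        fixes = walk_fixes()
        assert dv.filter_track(fixes) == fixes

    def test_planted_violators_exactly_removed(self):
        fixes = walk_fixes(n=60)
        bad_idx = set(range(4, 54, 5))  # 10 isolated erroneous fixes
        spiked = [
            dv.TrackFix(time=f.time, lat=f.lat + (1.2 if i in bad_idx else 0.0), lon=f.lon)
            for i, f in enumerate(fixes)
        ]
        kept = dv.filter_track(spiked)
        kept_lats = {round(f.lat, 6) for f in kept}
        assert len(kept) == 50
        for i, f in enumerate(fixes):
            if i in bad_idx:
                assert round(f.lat + 1.2, 6) not in kept_lats
            else:
                assert round(f.lat, 6) in kept_lats

    def test_short_tracks_returned_unchanged(self):
        fixes = walk_fixes(n=2)
        assert dv.filter_track(fixes) == fixes


class TestInterpolation:
    def test_midpoint_at_intermediate_hour(self):
        f0 = dv.TrackFix(time=T0, lat=33.0, lon=-119.0)
        f1 = dv.TrackFix(time=T0 + np.timedelta64(7200, "s"), lat=34.0, lon=-118.0)
        out = dv.interpolate_hourly([f0, f1])
        assert len(out) == 3
        assert out[1].lat == pytest.approx(33.5)
        assert out[1].lon == pytest.approx(-118.5)

    def test_hourly_fixes_are_fixed_points(self):
        fixes = walk_fixes(n=6)
        out = dv.interpolate_hourly(fixes)
        assert len(out) == 6
        for a, b in zip(fixes, out):
            assert b.lat == pytest.approx(a.lat)

    def test_interpolants_within_segment_bounds(self, rng):
        fixes = [
            dv.TrackFix(time=T0 + np.timedelta64(int(i * 5400), "s"),
                        lat=33.0 + float(rng.uniform(0, 0.5)),
                        lon=-119.0 + float(rng.uniform(0, 0.5)))
            for i in range(8)
        ]
        lats = [f.lat for f in fixes]
        lons = [f.lon for f in fixes]
        for f in dv.interpolate_hourly(fixes):
            assert min(lats) - 1e-9 <= f.lat <= max(lats) + 1e-9
            assert min(lons) - 1e-9 <= f.lon <= max(lons) + 1e-9
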