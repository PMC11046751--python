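"""Segmentation, strategy classification, migration timing, and seasons."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from migoverlap import classification as cls
from migoverlap.classification import (
    ClusterParams,
    MigrationEvent,
    MovementStatus,
    RangeSegment,
    SeasonWindows,
    define_seasons,
    detect_segments,
    displacement,
    displacement_km,
    nsd,
    timing_table,
)
from migoverlap.synthetic import (
    AgentSpec,
    PopulationConfig,
    simulate_population,
    simulate_track,
)
from migoverlap.tracks import study_day

from conftest import T0, make_track, regular_track
from test_synthetic import migratory_spec, resident_spec


class TestNSD:
    def test_first_fix_zero(self):
        tr = regular_track([[5, 5], [8, 9]])
        assert nsd(tr)[0] == 0.0

    def test_straight_path_quadratic(self):
        th = np.arange(50) * 4.0
        tr = make_track(th, np.column_stack([th * 700.0, th * 300.0]))
        vals = nsd(tr)
        coef = np.polyfit(th, np.sqrt(vals), 1)  # sqrt(NSD) linear in t
        fitted = np.polyval(coef, th) ** 2
        ss = 1 - np.sum((vals - fitted) ** 2) / np.sum((vals - vals.mean()) ** 2)
        assert ss > 0.999

    def test_stationary_ou_plateau(self):
        # track starts at the center, so NSD fluctuates about 2 * range_sd^2
        spec = resident_spec(monitor_end="2019-05-10T00:00:00")  # ~510 fixes
        tr = simulate_track(spec, 2)
        plateau = nsd(tr)[50:].mean() * 1e6  # m^2
        assert plateau == pytest.approx(2 * 500.0**2, rel=0.25)


class TestDetectSegments:
    def test_migratory_two_ranges_recovered(self):
        spec = migratory_spec()
        tr = simulate_track(spec, 5)
        segs = cls.home_segments(detect_segments(tr))
        clusters = {s.cluster for s in segs}
        assert len(clusters) == 2
        # recovered centers near the generating centers
        for truth in [(0.0, 0.0), (0.0, 16000.0)]:
            best = min(
                segs, key=lambda s: np.hypot(s.center[0] - truth[0], s.center[1] - truth[1])
            )
            n_fix = best.last_fix - best.first_fix + 1
            bound = 3 * 2 * 500.0 / np.sqrt(n_fix)
            assert np.hypot(best.center[0] - truth[0], best.center[1] - truth[1]) < bound

    def test_resident_single_segment(self):
        tr = simulate_track(resident_spec(monitor_end="2019-08-13T00:00:00"), 1)
        segs = cls.home_segments(detect_segments(tr))
        assert len({s.cluster for s in segs}) == 1
        assert segs[0].first_fix == 0

    def test_stopover_attached_to_migration_event(self):
        # hand-built track: 40 d at A, 10 d pause at P, 40 d at B
        rng = np.random.default_rng(3)
        blocks = [
            ((0.0, 0.0), 240),
            ((0.0, 8000.0), 60),
            ((0.0, 16000.0), 240),
        ]
        xy = np.vstack([
            np.asarray(c) + rng.normal(0, 150.0, (n, 2)) for c, n in blocks
        ])
        tr = regular_track(xy)
        params = ClusterParams(min_separation=2500.0)
        segs = detect_segments(tr, params)
        events = cls.extract_events(segs, params)
        assert len(events) == 1
        assert len(events[0].stopovers) == 1
        assert events[0].stopovers[0].center[1] == pytest.approx(8000.0, abs=200)
        # the stopover is not a home range
        assert len(cls.home_segments(segs, params)) == 2


class TestClassify:
    def test_short_monitoring_unknown(self):
        tr = simulate_track(resident_spec(monitor_end="2019-02-23T00:00:00"), 0)
        st = cls.classify(detect_segments(tr), 10.0)
        assert st.status == "unknown"

    def test_five_center_switcher_nomadic(self):
        rng = np.random.default_rng(7)
        centers = [(0, 0), (8000, 0), (8000, 8000), (0, 8000), (-8000, 8000)]
        xy = np.vstack([
            np.asarray(c, float) + rng.normal(0, 200.0, (300, 2)) for c in centers
        ])
        tr = regular_track(xy)
        st = cls.classify(detect_segments(tr), float(tr.hours()[-1] / 24))
        assert st.status == "nomadic"

    def test_rigid_motion_invariance(self):
        tr = simulate_track(migratory_spec(), 9)
        st0 = cls.classify(detect_segments(tr), 365.0)
        ang = 0.65
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = tr.subset(np.arange(tr.n))
        moved.xy[:] = tr.xy @ R.T + np.array([1e5, -2e5])
        st1 = cls.classify(detect_segments(moved), 365.0)
        assert st0.status == st1.status == "migratory"


class TestDisplacement:
    def _seg(self, cluster, center, day0, day1):
        return RangeSegment(
            center=center,
            start=T0 + np.timedelta64(day0 * 86400, "s"),
            end=T0 + np.timedelta64(day1 * 86400, "s"),
            first_fix=day0 * 6,
            last_fix=day1 * 6,
            cluster=cluster,
        )

    def test_three_four_five(self):
        segs = [
            self._seg(0, (0.0, 0.0), 0, 60),
            self._seg(1, (3000.0, 4000.0), 63, 150),
        ]
        assert displacement_km(segs) == pytest.approx(5.0)

    def test_identical_centroids_zero(self):
        segs = [
            self._seg(0, (100.0, 100.0), 0, 60),
            self._seg(1, (100.0, 100.0), 63, 150),
        ]
        assert displacement_km(segs) == 0.0

    def test_two_years_averaged(self):
        # no range fidelity: winter <-> summer A (10 km), winter <-> summer B (14 km)
        segs = [
            self._seg(0, (0.0, 0.0), 0, 50),
            self._seg(1, (10000.0, 0.0), 55, 170),
            self._seg(0, (0.0, 0.0), 175, 300),
            self._seg(2, (0.0, 14000.0), 305, 420),
        ]
        assert displacement_km(segs) == pytest.approx(12.0)

    def test_rejects_non_migratory(self):
        with pytest.raises(ValueError):
            displacement(MovementStatus("resident"), [])


def _event(season, depart_day, arrive_day):
    seg = RangeSegment((0.0, 0.0), T0, T0 + np.timedelta64(40, "D"), 0, 10, 0)
    seg2 = RangeSegment(
        (0.0, 9000.0),
        T0 + np.timedelta64(int(arrive_day * 86400), "s"),
        T0 + np.timedelta64(int((arrive_day + 60) * 86400), "s"),
        20,
        40,
        1,
    )
    return MigrationEvent(
        depart=T0 + np.timedelta64(int(depart_day * 86400), "s"),
        arrive=T0 + np.timedelta64(int(arrive_day * 86400), "s"),
        from_segment=seg,
        to_segment=seg2,
        season_label=season,
    )


class TestTimingTable:
    def test_degenerate_single_day(self):
        events = [_event("spring", 100.0, 101.0) for _ in range(5)]
        row = timing_table(events).loc["spring"]
        assert row["start_05"] == row["start_25"] == row["mean_start"] == 100.0

    def test_hand_computed_quantile(self):
        # arrivals {110, 112, 118, 140}: linear-interpolation 75% quantile
        arr = [110.0, 112.0, 118.0, 140.0]
        events = [_event("fall", 100.0, a) for a in arr]
        got = timing_table(events).loc["fall", "finish_75"]
        # hand computation: position (4-1)*0.75 = 2.25 -> 118 + 0.25*(140-118)
        assert got == pytest.approx(118 + 0.25 * (140 - 118))

    def test_normal_sample_quantile(self):
        rng = np.random.default_rng(42)
        deps = rng.normal(105.0, 2.0, 60)
        events = [_event("spring", d, d + 2) for d in deps]
        q25 = timing_table(events).loc["spring", "start_25"]
        assert q25 == pytest.approx(103.65, abs=1.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            timing_table([])


class TestDefineSeasons:
    def test_quartile_dates_become_window_bounds(self):
        events = [_event("spring", d, d + 4) for d in (50.0, 52.0, 54.0, 56.0)]
        events += [_event("fall", d, d + 4) for d in (250.0, 254.0, 258.0, 262.0)]
        tt = timing_table(events)
        sw = define_seasons(tt)
        exp_spring_start = cls.study_day_to_date(tt.loc["spring", "start_25"])
        assert sw.spring[0] == (exp_spring_start.month, exp_spring_start.day)

    def test_partition_complete(self):
        sw = define_seasons(
            {
                "spring": (dt.date(2021, 4, 4), dt.date(2021, 5, 2)),
                "fall": (dt.date(2021, 10, 10), dt.date(2021, 11, 28)),
            }
        )
        # construction of SeasonWindows verifies the partition invariant for
        # both common and leap years; also check a few labels directly
        assert sw.season_of([np.datetime64("2020-10-09T12:00")])[0] == "summer"
        assert sw.season_of([np.datetime64("2020-10-10T00:00")])[0] == "fall"
        assert sw.season_of([np.datetime64("2021-01-15T00:00")])[0] == "winter"

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            define_seasons(
                {
                    "spring": (dt.date(2021, 4, 4), dt.date(2021, 11, 1)),
                    "fall": (dt.date(2021, 10, 10), dt.date(2021, 11, 28)),
                }
            )

    def test_winter_season_year_wraps(self):
        sw = define_seasons(
            {
                "spring": (dt.date(2021, 4, 4), dt.date(2021, 5, 2)),
                "fall": (dt.date(2021, 10, 10), dt.date(2021, 11, 28)),
            }
        )
        s, y = sw.season_year(
            [np.datetime64("2019-12-05T00:00"), np.datetime64("2020-01-20T00:00")]
        )
        assert list(s) == ["winter", "winter"]
        assert list(y) == [2019, 2019]


class TestPopulationRecovery:
    def test_small_population_agreement(self):
        cfg = PopulationConfig(
            counts={"deer": {"migratory": 6, "resident": 3, "nomadic": 2}}
        )
        tracks, ledger = simulate_population(cfg, 21)
        hits = 0
        for tr in tracks:
            segs = detect_segments(tr)
            st = cls.classify(segs, float(tr.hours()[-1] / 24))
            hits += st.status == ledger.agents[tr.id].strategy
        assert hits == len(tracks)
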