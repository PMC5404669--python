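"""Colony attendance, foraging-event detection and trip segmentation."""
import numpy as np
import pandas as pd
import pytest

from cpforage import (
    Site,
    Track,
    attendance_mask,
    complete_days,
    detect_foraging_events,
    foraging_trips,
    geodesic_distance,
    segment_trips,
    solar_times,
)
from cpforage.trip_segmentation import ForagingEventParams
from conftest import COLONY, make_track, xy_to_lonlat

CLUSTER_SPEEDS = [0, 6, 1, 7, 0, 5, 2, 8]  # highly variable: hover/strike mix


def cluster_xy(center_x, rng=None, n=8, spread=30.0):
    rng = rng or np.random.default_rng(1)
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = spread * (0.5 + 0.5 * rng.random(n))
    return np.column_stack([center_x + r * np.cos(ang), r * np.sin(ang)])


class TestAttendanceMask:
    def test_buffer_membership(self):
        track = make_track([[10, 0], [300, 0], [45, 20]])
        assert attendance_mask(track, COLONY).tolist() == [True, False, True]

    def test_boundary_is_inside(self):
        # a fix at exactly the buffer radius counts as at the colony
        lon, lat = xy_to_lonlat([[50.0, 0.0]])
        d = geodesic_distance((lon[0], lat[0]), (COLONY.lon, COLONY.lat))
        site_eq = Site("c", COLONY.lon, COLONY.lat, attendance_radius=d)
        site_lt = Site("c", COLONY.lon, COLONY.lat, attendance_radius=d - 1e-6)
        track = make_track([[50.0, 0.0]])
        assert attendance_mask(track, site_eq)[0]
        assert not attendance_mask(track, site_lt)[0]


class TestAnchorSites:
    def test_roost_counts_as_attendance(self):
        lon, lat = xy_to_lonlat([[5000.0, 0.0]])
        roost = Site("roost", float(lon[0]), float(lat[0]), 50.0)
        track = make_track([[5000.0, 10.0]])
        assert not attendance_mask(track, COLONY)[0]
        assert attendance_mask(track, [COLONY, roost])[0]


class TestForagingEvents:
    def test_straight_transit_has_no_event(self):
        xy = np.column_stack([np.arange(10) * 600.0, np.zeros(10)])
        track = make_track(xy, speeds=np.full(10, 10.0))
        assert detect_foraging_events(track.fixes) == []

    def test_hover_cluster_is_one_event(self):
        track = make_track(cluster_xy(2000.0), speeds=CLUSTER_SPEEDS)
        events = detect_foraging_events(track.fixes)
        assert len(events) == 1
        assert events[0].speed_cv >= 0.5
        assert events[0].radius <= 100.0

    def test_constant_speed_cluster_is_rejected(self):
        track = make_track(cluster_xy(2000.0), speeds=np.full(8, 5.0))
        assert detect_foraging_events(track.fixes) == []

    def test_two_clusters_split_by_transit_give_two_events(self):
        xy = np.vstack(
            [
                cluster_xy(0.0),
                np.column_stack([400 + np.arange(5) * 400.0, np.zeros(5)]),
                cluster_xy(2400.0),
            ]
        )
        speeds = CLUSTER_SPEEDS + [10.0] * 5 + CLUSTER_SPEEDS
        track = make_track(xy, speeds=speeds)
        events = detect_foraging_events(track.fixes)
        assert len(events) == 2

    def test_min_fixes_respected(self):
        track = make_track(cluster_xy(0.0, n=2), speeds=[0, 8])
        assert detect_foraging_events(track.fixes) == []

    def test_altitude_criterion_applies_with_ground_reference(self):
        track = make_track(
            cluster_xy(2000.0), speeds=CLUSTER_SPEEDS, altitudes=np.full(8, 200.0)
        )
        p = ForagingEventParams(ground_ref=10.0)  # median AGL 190 m > 50 m
        assert detect_foraging_events(track.fixes, p) == []
        p_off = ForagingEventParams()
        assert len(detect_foraging_events(track.fixes, p_off)) == 1


def toy_day_track():
    """Colony -> 2 km foraging trip -> colony -> 250 m excursion with a
    foraging clump -> colony -> second 2 km trip -> colony."""
    parts, speeds = [], []

    def colony(n=2):
        parts.append(np.tile([[5.0, 5.0]], (n, 1)))
        speeds.extend([0.3] * n)

    def commute(xs):
        parts.append(np.column_stack([xs, np.zeros(len(xs))]))
        speeds.extend([10.0] * len(xs))

    def clump(x):
        parts.append(cluster_xy(x))
        speeds.extend(CLUSTER_SPEEDS)

    colony(3)
    commute([600, 1200, 1900]); clump(2000.0); commute([1200, 600])
    colony(2)
    parts.append(cluster_xy(250.0, spread=20)); speeds.extend(CLUSTER_SPEEDS)
    colony(2)
    commute([700, 1400, 2100]); clump(2200.0); commute([1400, 700])
    colony(2)
    return make_track(np.vstack(parts), speeds=speeds)


class TestSegmentTrips:
    def test_toy_day_yields_two_complete_foraging_trips(self):
        track = toy_day_track()
        trips = segment_trips(track, COLONY)
        ftr = foraging_trips(trips)
        assert len(ftr) == 2
        for t in ftr:
            assert t.complete and t.max_distance_m > 300

    def test_excursion_within_300m_is_not_a_trip(self):
        track = toy_day_track()
        trips = segment_trips(track, COLONY)
        near = [t for t in trips if t.max_distance_m <= 300]
        assert len(near) == 1
        assert near[0].has_foraging_event  # clump found, but range too small
        assert not near[0].is_foraging_trip

    def test_track_inside_buffer_has_no_trips(self):
        track = make_track(np.tile([[10.0, -5.0]], (20, 1)) + np.arange(20)[:, None] % 3)
        assert segment_trips(track, COLONY) == []

    def test_track_starting_mid_excursion_is_incomplete(self):
        track = toy_day_track()
        clipped = Track(
            individual_id="x",
            fixes=track.fixes.iloc[4:].reset_index(drop=True),
            sex="female",
        )
        trips = segment_trips(clipped, COLONY)
        assert trips[0].complete is False
        assert foraging_trips(trips, complete_only=True)[0].departure is not None

    def test_departure_is_last_inside_fix_and_arrival_first_inside(self):
        track = toy_day_track()
        trip = foraging_trips(segment_trips(track, COLONY))[0]
        inside = attendance_mask(track, COLONY)
        assert inside[trip.start_idx] and inside[trip.end_idx]
        assert not inside[trip.start_idx + 1]
        assert not inside[trip.end_idx - 1]

    def test_trips_are_disjoint_and_ordered(self, cohort42):
        track = cohort42["tracks"][0]
        trips = segment_trips(track, cohort42["colony"])
        for a, b in zip(trips, trips[1:]):
            assert a.end_idx <= b.start_idx


class TestCompleteDays:
    @staticmethod
    def _full_day_fixes(date="2013-05-10"):
        sr, ss = solar_times(date, COLONY.lon, COLONY.lat)
        t0 = sr.ceil("60s")
        n = int((ss - t0).total_seconds() // 60) + 1
        return t0, n

    def test_sunrise_to_sunset_coverage_is_complete(self):
        t0, n = self._full_day_fixes()
        track = make_track(np.tile([[5.0, 5.0]], (n, 1)), t0=t0, dt_s=60)
        (day,) = complete_days(track, COLONY)
        assert day.complete

    def test_late_start_is_incomplete(self):
        t0, n = self._full_day_fixes()
        track = make_track(
            np.tile([[5.0, 5.0]], (n - 120, 1)), t0=t0 + pd.Timedelta(hours=2), dt_s=60
        )
        (day,) = complete_days(track, COLONY)
        assert not day.complete

    def test_internal_gap_breaks_completeness(self):
        t0, n = self._full_day_fixes()
        track = make_track(np.tile([[5.0, 5.0]], (n, 1)), t0=t0, dt_s=60)
        fixes = pd.concat(
            [track.fixes.iloc[: n // 2], track.fixes.iloc[n // 2 + 60 :]]
        ).reset_index(drop=True)
        gappy = Track(individual_id="x", fixes=fixes, sex="male")
        (day,) = complete_days(gappy, COLONY)
        assert not day.complete


def test_coarsening_cadence_never_increases_trip_count():
    """Subsampling the same underlying 1-s path to coarser cadences can only
    merge or lose trips, never create new ones."""
    from cpforage import published_summary_preset, simulate_day, Period

    params = published_summary_preset(1)
    rng = np.random.default_rng([99, 0, 1])
    fixes, truth = simulate_day(
        params, "male", Period.courtship, "2013-04-20", COLONY, 1, rng=rng
    )
    counts = {}
    for step, si in [(1, 1), (60, 60), (180, 180), (600, 600)]:
        sub = fixes.iloc[::step].reset_index(drop=True).assign(sampling_interval=si)
        track = Track(individual_id="x", fixes=sub, sex="male")
        counts[si] = len(foraging_trips(segment_trips(track, COLONY)))
    assert counts[1] == truth["n_trips"]
    assert counts[1] >= counts[60] >= counts[180] >= counts[600]
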