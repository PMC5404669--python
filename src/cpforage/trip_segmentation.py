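"""Segment tracks into colony-attendance bouts, foraging trips and complete days.

A *foraging trip* is an excursion that leaves the anchor buffer (colony or
roost, 50 m by default), reaches more than 300 m from the colony, and
contains at least one identifiable *foraging event*: a clump of fixes with
highly variable instantaneous speed (and optionally low altitude above a
ground reference).  Excursions beyond 300 m with no foraging event are kept
as "non-foraging excursions" but excluded from trip statistics; trips whose
departure or return was not observed are flagged incomplete and likewise
excluded downstream.

A *complete tracking day* covers sunrise to sunset for one individual-date
with no internal gap larger than ``gap_factor`` sampling intervals.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .track_model import Site, Track, distances_to, haversine, solar_times

TRIP_MIN_RANGE_M = 300.0  # a trip must extend beyond 300 m from the colony


@dataclass
class ForagingEventParams:
    """Operational thresholds for the clumped-fix foraging-event heuristic.

    The source criteria are qualitative ("clumped locations at low altitude
    with highly variable speed"); these numeric defaults are package choices
    exposed here rather than field-measured constants.
    """

    clump_radius: float = 100.0  # m, max fix distance to window centroid
    min_fixes: int = 3
    speed_cv_min: float = 0.5  # sample coefficient of variation of speed
    max_altitude_agl: float = 50.0  # m, applied only with a ground reference
    ground_ref: float | None = None  # median colony-attendance altitude, if used


@dataclass
class ForagingEvent:
    start_idx: int  # positional index into the fix slice searched
    end_idx: int  # inclusive
    centroid_lon: float
    centroid_lat: float
    radius: float
    speed_cv: float
    median_altitude_agl: float | None = None


@dataclass
class Trip:
    """One colony-to-colony excursion.

    ``start_idx``/``end_idx`` are positional indices into the parent track's
    fixes, inclusive, and include the anchor fixes bounding the excursion
    when observed (departure = last fix inside the buffer before exit,
    arrival = first fix inside after return).
    """

    individual_id: str
    start_idx: int
    end_idx: int
    departure: pd.Timestamp | None
    arrival: pd.Timestamp | None
    complete: bool
    max_distance_m: float
    has_foraging_event: bool
    sampling_interval: int
    sex: str | None = None
    period: object | None = None
    events: list = field(default_factory=list)

    @property
    def is_foraging_trip(self) -> bool:
        return self.max_distance_m > TRIP_MIN_RANGE_M and self.has_foraging_event

    def fixes(self, track: Track) -> pd.DataFrame:
        return track.fixes.iloc[self.start_idx : self.end_idx + 1]


@dataclass
class TrackDay:
    individual_id: str
    date: pd.Timestamp
    start_idx: int
    end_idx: int  # inclusive
    complete: bool
    sunrise: pd.Timestamp
    sunset: pd.Timestamp
    sex: str | None = None
    period: object | None = None

    @property
    def day_length_s(self) -> float:
        return (self.sunset - self.sunrise).total_seconds()

    def fixes(self, track: Track) -> pd.DataFrame:
        return track.fixes.iloc[self.start_idx : self.end_idx + 1]


def attendance_mask(track_or_fixes, sites) -> np.ndarray:
    """True where a fix lies within the attendance buffer of any anchor site.

    The buffer test is inclusive (distance <= radius)."""
    fixes = track_or_fixes.fixes if isinstance(track_or_fixes, Track) else track_or_fixes
    if isinstance(sites, Site):
        sites = [sites]
    mask = np.zeros(len(fixes), dtype=bool)
    for s in sites:
        mask |= distances_to(fixes, s) <= s.attendance_radius
    return mask


def _speed_cv(speeds: np.ndarray) -> float:
    m = speeds.mean()
    if m <= 0:
        return 0.0
    return float(speeds.std(ddof=1) / m)


def detect_foraging_events(
    fixes: pd.DataFrame, params: ForagingEventParams | None = None
) -> list[ForagingEvent]:
    """Greedy maximal clump windows within one excursion's fixes.

    A window qualifies when every fix lies within ``clump_radius`` of the
    window centroid, it has at least ``min_fixes`` fixes, and the sample CV
    of instantaneous speed is at least ``speed_cv_min``.  With a configured
    ground reference the median altitude above it must not exceed
    ``max_altitude_agl``; without one the altitude criterion is skipped.
    """
    p = params or ForagingEventParams()
    n = len(fixes)
    lon = fixes["lon"].to_numpy()
    lat = fixes["lat"].to_numpy()
    speed = fixes["speed"].to_numpy(float)
    alt = fixes["altitude"].to_numpy(float)

    events: list[ForagingEvent] = []
    i = 0
    while i <= n - p.min_fixes:
        # grow the longest clump starting at i
        j = i + 1
        best_j = -1
        while j < n:
            clon, clat = lon[i : j + 1].mean(), lat[i : j + 1].mean()
            d = haversine(lon[i : j + 1], lat[i : j + 1], clon, clat)
            if d.max() > p.clump_radius:
                break
            best_j = j
            j += 1
        if best_j - i + 1 >= p.min_fixes:
            sl = slice(i, best_j + 1)
            clon, clat = lon[sl].mean(), lat[sl].mean()
            d = haversine(lon[sl], lat[sl], clon, clat)
            cv = _speed_cv(speed[sl])
            med_agl = None
            alt_ok = True
            if p.ground_ref is not None:
                med_agl = float(np.median(alt[sl]) - p.ground_ref)
                alt_ok = med_agl <= p.max_altitude_agl
            if cv >= p.speed_cv_min and alt_ok:
                events.append(
                    ForagingEvent(
                        start_idx=i,
                        end_idx=best_j,
                        centroid_lon=float(clon),
                        centroid_lat=float(clat),
                        radius=float(d.max()),
                        speed_cv=cv,
                        median_altitude_agl=med_agl,
                    )
                )
                i = best_j + 1
                continue
        i += 1
    return events


def segment_trips(
    track: Track,
    sites,
    event_params: ForagingEventParams | None = None,
    colony: Site | None = None,
) -> list[Trip]:
    """Split a track into excursions between anchor-buffer visits.

    Returns one :class:`Trip` per excursion; filter with ``is_foraging_trip``
    (range > 300 m and at least one foraging event) and ``complete``.  The
    maximum range is measured from ``colony`` (first site by default).
    """
    if isinstance(sites, Site):
        sites = [sites]
    colony = colony or sites[0]
    inside = attendance_mask(track, sites)
    n = len(inside)
    trips: list[Trip] = []
    if n == 0:
        return trips

    dist_colony = distances_to(track.fixes, colony)
    ts = track.fixes["timestamp"]

    i = 0
    while i < n:
        if inside[i]:
            i += 1
            continue
        # run of outside fixes [i, j]
        j = i
        while j + 1 < n and not inside[j + 1]:
            j += 1
        dep_idx = i - 1 if i > 0 else None  # last fix inside before exit
        arr_idx = j + 1 if j + 1 < n else None  # first fix inside after return
        start = dep_idx if dep_idx is not None else i
        end = arr_idx if arr_idx is not None else j
        excursion = track.fixes.iloc[i : j + 1]
        events = detect_foraging_events(excursion, event_params)
        trips.append(
            Trip(
                individual_id=track.individual_id,
                start_idx=start,
                end_idx=end,
                departure=ts.iloc[dep_idx] if dep_idx is not None else None,
                arrival=ts.iloc[arr_idx] if arr_idx is not None else None,
                complete=dep_idx is not None and arr_idx is not None,
                max_distance_m=float(dist_colony[i : j + 1].max()),
                has_foraging_event=len(events) > 0,
                sampling_interval=track.sampling_interval,
                sex=track.sex,
                events=events,
            )
        )
        i = j + 1
    return trips


def foraging_trips(trips: list[Trip], complete_only: bool = True) -> list[Trip]:
    """The trips that enter statistics: foraging excursions, complete ones."""
    out = [t for t in trips if t.is_foraging_trip]
    if complete_only:
        out = [t for t in out if t.complete]
    return out


def complete_days(
    track: Track,
    colony: Site,
    tolerance_s: float = 900.0,
    gap_factor: float = 3.0,
) -> list[TrackDay]:
    """One :class:`TrackDay` per calendar date with a completeness flag.

    A day is complete when the first fix is no later than sunrise +
    ``tolerance_s``, the last no earlier than sunset - ``tolerance_s``, and
    no internal gap exceeds ``gap_factor`` sampling intervals.
    """
    days: list[TrackDay] = []
    if len(track) == 0:
        return days
    ts = track.fixes["timestamp"]
    dates = ts.dt.normalize()
    pos = np.arange(len(ts))
    for date, idx in pd.Series(pos, index=ts.index).groupby(dates):
        first, last = int(idx.iloc[0]), int(idx.iloc[-1])
        sunrise, sunset = solar_times(date, colony.lon, colony.lat)
        sub = ts.iloc[first : last + 1]
        gaps = sub.diff().dt.total_seconds().dropna()
        si = track.fixes["sampling_interval"].iloc[first]
        ok = (
            sub.iloc[0] <= sunrise + pd.Timedelta(seconds=tolerance_s)
            and sub.iloc[-1] >= sunset - pd.Timedelta(seconds=tolerance_s)
            and (len(gaps) == 0 or gaps.max() <= gap_factor * si)
        )
        days.append(
            TrackDay(
                individual_id=track.individual_id,
                date=pd.Timestamp(date).tz_localize(None),
                start_idx=first,
                end_idx=last,
                complete=bool(ok),
                sunrise=sunrise,
                sunset=sunset,
                sex=track.sex,
            )
        )
    return days
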