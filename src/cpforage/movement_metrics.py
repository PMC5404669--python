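"""Trip-level and daily movement variables.

Trip level: duration (h), accumulated distance between consecutive fixes
(km) and maximum distance from the colony (km).  Daily level, for complete
tracking days: daily accumulated distance (km), number of foraging trips
departing that day, and colony attendance as the percentage of daylight
spent within the anchor buffer.

Attendance accrues per inter-fix interval: full credit when both endpoint
fixes are inside the buffer, half credit when exactly one is — unbiased for
symmetric buffer crossings.  Trips are assigned to their departure date, so
a dusk trip returning after midnight counts once.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .track_model import Site, Track, path_length, distances_to
from .trip_segmentation import TrackDay, Trip, attendance_mask


@dataclass
class TripMetrics:
    duration_h: float
    distance_km: float
    max_distance_km: float


@dataclass
class DailyMetrics:
    daily_distance_km: float
    n_trips: int
    colony_attendance_pct: float


def trip_metrics(trip: Trip, track: Track, colony: Site) -> TripMetrics:
    """Metrics for one complete foraging trip; incomplete trips are refused
    so the statistics layer can never see them."""
    if not trip.complete:
        raise ValueError("trip metrics are defined only for complete trips")
    fixes = trip.fixes(track)
    duration_h = (trip.arrival - trip.departure).total_seconds() / 3600.0
    distance_km = path_length(fixes) / 1000.0
    max_km = float(distances_to(fixes, colony).max()) / 1000.0
    return TripMetrics(duration_h, distance_km, max_km)


def attended_seconds(fixes: pd.DataFrame, sites) -> float:
    """Interval-weighted time (s) spent inside the anchor buffer."""
    if len(fixes) < 2:
        return 0.0
    inside = attendance_mask(fixes, sites).astype(float)
    dt = fixes["timestamp"].diff().dt.total_seconds().to_numpy()[1:]
    credit = (inside[:-1] + inside[1:]) / 2.0  # 1, 0.5 or 0 per interval
    return float((credit * dt).sum())


def daily_metrics(
    day: TrackDay,
    track: Track,
    trips: list[Trip],
    sites,
) -> DailyMetrics:
    """Daily movement variables for one complete tracking day."""
    if not day.complete:
        raise ValueError("daily metrics are defined only for complete days")
    fixes = day.fixes(track)
    distance_km = path_length(fixes) / 1000.0
    date = day.date
    n_trips = sum(
        1
        for t in trips
        if t.is_foraging_trip
        and t.complete
        and t.departure is not None
        and t.departure.tz_localize(None).normalize() == date
    )
    att = attended_seconds(fixes, sites)
    pct = 100.0 * att / day.day_length_s
    return DailyMetrics(distance_km, int(n_trips), float(np.clip(pct, 0.0, 100.0)))


def trips_table(trips, track, colony) -> pd.DataFrame:
    """Tidy per-trip table (complete foraging trips only)."""
    rows = []
    for t in trips:
        if not (t.is_foraging_trip and t.complete):
            continue
        m = trip_metrics(t, track, colony)
        rows.append(
            {
                "individual_id": t.individual_id,
                "sex": t.sex,
                "period": str(t.period) if t.period is not None else None,
                "departure": t.departure,
                "arrival": t.arrival,
                "sampling_interval": t.sampling_interval,
                "duration_h": m.duration_h,
                "distance_km": m.distance_km,
                "max_distance_km": m.max_distance_km,
            }
        )
    return pd.DataFrame(rows)


def days_table(days, track, trips, sites) -> pd.DataFrame:
    """Tidy per-day table (complete days only)."""
    rows = []
    for d in days:
        if not d.complete:
            continue
        m = daily_metrics(d, track, trips, sites)
        rows.append(
            {
                "individual_id": d.individual_id,
                "sex": d.sex,
                "period": str(d.period) if d.period is not None else None,
                "date": d.date,
                "day_length_h": d.day_length_s / 3600.0,
                "daily_distance_km": m.daily_distance_km,
                "n_trips": m.n_trips,
                "colony_attendance_pct": m.colony_attendance_pct,
            }
        )
    return pd.DataFrame(rows)
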