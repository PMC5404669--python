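"""End-to-end convenience pipeline: tracks -> trips/days tables.

Glue over the stage modules so the analysis scripts, the tests and the
acceptance script all run the identical chain: segmentation, completeness
flags, phenology labels, movement metrics and perch-hunting summaries.
"""
from __future__ import annotations

import pandas as pd

from .movement_metrics import daily_metrics, trip_metrics
from .perch_hunting import detect_perch_bouts, summarize_perching
from .phenology import BreedingRecord, assign_period
from .track_model import Site, Track
from .trip_segmentation import (
    ForagingEventParams,
    complete_days,
    foraging_trips,
    segment_trips,
)


def analyze_tracks(
    tracks: list[Track],
    colony: Site,
    records: dict[str, BreedingRecord] | None = None,
    sites: list[Site] | None = None,
    event_params: ForagingEventParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the full movement pipeline.

    Returns (trips, days, bouts): one row per complete foraging trip with
    its metrics and perch summary, one row per complete tracking day with
    daily metrics, and one row per detected perching bout.  Incomplete
    trips/days and non-foraging excursions are excluded here; use the stage
    functions directly to inspect them.
    """
    sites = sites or [colony]
    trip_rows, day_rows, bout_rows = [], [], []
    for track in tracks:
        rec = records.get(track.individual_id) if records else None
        trips = segment_trips(track, sites, event_params, colony=colony)
        for trip in foraging_trips(trips):
            m = trip_metrics(trip, track, colony)
            bouts = detect_perch_bouts(trip, track, sites)
            perch = summarize_perching(trip, bouts)
            period = None
            if rec is not None:
                try:
                    period = str(assign_period(trip.departure, rec))
                except ValueError:
                    period = None
            trip_rows.append(
                {
                    "individual_id": track.individual_id,
                    "sex": track.sex,
                    "period": period,
                    "departure": trip.departure,
                    "arrival": trip.arrival,
                    "sampling_interval": trip.sampling_interval,
                    "duration_h": m.duration_h,
                    "distance_km": m.distance_km,
                    "max_distance_km": m.max_distance_km,
                    "has_perching": perch.has_perching,
                    "total_perch_time_min": perch.total_perch_time_min,
                    "n_perch_bouts": perch.n_bouts,
                }
            )
            for b in bouts:
                bout_rows.append(
                    {
                        "individual_id": track.individual_id,
                        "departure": trip.departure,
                        "start": b.start,
                        "end": b.end,
                        "duration_s": b.duration_s,
                    }
                )
        for day in complete_days(track, colony):
            if not day.complete:
                continue
            dm = daily_metrics(day, track, trips, sites)
            period = None
            if rec is not None:
                try:
                    period = str(assign_period(day.date, rec))
                except ValueError:
                    period = None
            day_rows.append(
                {
                    "individual_id": track.individual_id,
                    "sex": track.sex,
                    "period": period,
                    "date": day.date,
                    "day_length_h": day.day_length_s / 3600.0,
                    "daily_distance_km": dm.daily_distance_km,
                    "n_trips": dm.n_trips,
                    "colony_attendance_pct": dm.colony_attendance_pct,
                }
            )
    return pd.DataFrame(trip_rows), pd.DataFrame(day_rows), pd.DataFrame(bout_rows)


def pooled_summary(trips: pd.DataFrame, days: pd.DataFrame) -> dict:
    """Pooled means of the six movement variables plus the perch summary,
    on their conventional reporting scales (h, km, %, counts, min)."""
    perching = trips[trips["has_perching"] == 1]
    return {
        "trip_duration_h": float(trips["duration_h"].mean()),
        "trip_distance_km": float(trips["distance_km"].mean()),
        "max_distance_km": float(trips["max_distance_km"].mean()),
        "trips_per_day": float(days["n_trips"].mean()),
        "daily_distance_km": float(days["daily_distance_km"].mean()),
        "attendance_pct": float(days["colony_attendance_pct"].mean()),
        "perch_time_min": float(perching["total_perch_time_min"].mean())
        if len(perching)
        else float("nan"),
        "n_trips": int(len(trips)),
        "n_days": int(len(days)),
    }
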