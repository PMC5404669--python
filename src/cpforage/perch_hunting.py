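"""Perching-bout detection within foraging trips.

A perching bout is a maximal run of consecutive fixes whose successive
displacements are all strictly below a cadence-specific threshold: 1 m at
1-s sampling, 5 m at 1-min, 15 m at 3-min, 25 m at 5-min and 50 m at
10-min (the threshold grows because GPS spatial accuracy degrades at lower
sampling frequencies).  Bout duration is the span between the first and
last fix of the run.  Bouts shorter than 30 s are discarded as they could
be hovering flights rather than perching — a filter that can only bite at
1-s cadence, since at any cadence of 60 s or more a single sub-threshold
step already spans a full minute.  Runs are broken at colony-buffer
entries: near-stationary fixes at the colony are attendance, not hunting.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .track_model import Site, Track, step_distances
from .trip_segmentation import Trip, attendance_mask

MIN_BOUT_DURATION_S = 30.0

#: displacement threshold (m) below which consecutive fixes count as perched
PERCH_THRESHOLDS_M = {1: 1.0, 60: 5.0, 180: 15.0, 300: 25.0, 600: 50.0}


@dataclass
class PerchBout:
    start: pd.Timestamp
    end: pd.Timestamp
    n_fixes: int
    max_step_m: float

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class TripPerchSummary:
    has_perching: int  # 0/1
    total_perch_time_min: float
    n_bouts: int


def perch_threshold(sampling_interval: int) -> float:
    """Cadence-specific displacement threshold in metres."""
    try:
        return PERCH_THRESHOLDS_M[int(sampling_interval)]
    except KeyError:
        raise ValueError(
            f"no perch threshold for sampling interval {sampling_interval}s; "
            f"legal cadences: {sorted(PERCH_THRESHOLDS_M)}"
        ) from None


def detect_perch_bouts(
    trip: Trip,
    track: Track,
    sites,
    min_duration_s: float = MIN_BOUT_DURATION_S,
) -> list[PerchBout]:
    """Perching bouts within one trip, searched outside the colony buffer."""
    fixes = trip.fixes(track)
    thr = perch_threshold(trip.sampling_interval)
    steps = step_distances(fixes)
    if len(steps) == 0:
        return []
    outside = ~attendance_mask(fixes, sites)
    # a step qualifies when below threshold and both endpoints off-colony
    ok = (steps < thr) & outside[:-1] & outside[1:]

    ts = fixes["timestamp"].reset_index(drop=True)
    bouts: list[PerchBout] = []
    i = 0
    n = len(ok)
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1]:
            j += 1
        start, end = ts.iloc[i], ts.iloc[j + 1]
        if (end - start).total_seconds() >= min_duration_s:
            bouts.append(
                PerchBout(
                    start=start,
                    end=end,
                    n_fixes=j - i + 2,
                    max_step_m=float(steps[i : j + 1].max()),
                )
            )
        i = j + 1
    return bouts


def summarize_perching(trip: Trip, bouts: list[PerchBout]) -> TripPerchSummary:
    """Per-trip summary: binary perching flag, total perch time (min), bout count."""
    total_min = sum(b.duration_s for b in bouts) / 60.0
    return TripPerchSummary(
        has_perching=int(len(bouts) > 0),
        total_perch_time_min=total_min,
        n_bouts=len(bouts),
    )


def bouts_table(trip_bouts: list[tuple[Trip, list[PerchBout]]]) -> pd.DataFrame:
    rows = []
    for trip, bouts in trip_bouts:
        for b in bouts:
            rows.append(
                {
                    "individual_id": trip.individual_id,
                    "departure": trip.departure,
                    "start": b.start,
                    "end": b.end,
                    "duration_s": b.duration_s,
                    "n_fixes": b.n_fixes,
                    "max_step_m": b.max_step_m,
                }
            )
    return pd.DataFrame(rows)
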