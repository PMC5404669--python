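"""Shared fixtures: hand-built tracks on a local tangent plane and the
seed-42 synthetic cohort (simulated once per session, reused by the
pipeline-level and acceptance tests)."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from cpforage import Site, Track, analyze_tracks, simulate_cohort
from cpforage.track_model import EARTH_RADIUS_M

COLONY = Site("colony", lon=-6.05, lat=37.40, attendance_radius=50.0)


def xy_to_lonlat(xy_m, site: Site = COLONY):
    """Local-tangent-plane metres -> (lon, lat), inverse small-offset map."""
    xy = np.atleast_2d(np.asarray(xy_m, float))
    lat = site.lat + np.degrees(xy[:, 1] / EARTH_RADIUS_M)
    lon = site.lon + np.degrees(
        xy[:, 0] / (EARTH_RADIUS_M * math.cos(math.radians(site.lat)))
    )
    return lon, lat


def make_track(
    xy_m,
    t0="2013-05-10 08:00:00",
    dt_s=60,
    speeds=None,
    altitudes=None,
    individual_id="bird00",
    sex="female",
    site: Site = COLONY,
) -> Track:
    """Build a Track from planar metre offsets around the colony."""
    xy = np.atleast_2d(np.asarray(xy_m, float))
    n = len(xy)
    lon, lat = xy_to_lonlat(xy, site)
    start = pd.Timestamp(t0)
    start = start.tz_localize("UTC") if start.tzinfo is None else start
    fixes = pd.DataFrame(
        {
            "timestamp": start + pd.to_timedelta(np.arange(n) * dt_s, unit="s"),
            "lon": lon,
            "lat": lat,
            "altitude": np.full(n, 20.0) if altitudes is None else np.asarray(altitudes, float),
            "speed": np.full(n, 5.0) if speeds is None else np.asarray(speeds, float),
            "sampling_interval": int(dt_s) if dt_s in (1, 60, 180, 300, 600) else 60,
        }
    )
    return Track(individual_id=individual_id, fixes=fixes, sex=sex, colony=site)


@pytest.fixture(scope="session")
def colony():
    return COLONY


@pytest.fixture(scope="session")
def cohort42():
    """The calibrated 30-individual x 10-day cohort at 1-min cadence,
    seed 42, with generator ground truth."""
    tracks, trip_truth, day_truth, records, col, params = simulate_cohort(seed=42)
    return {
        "tracks": tracks,
        "trip_truth": trip_truth,
        "day_truth": day_truth,
        "records": records,
        "colony": col,
        "params": params,
    }


@pytest.fixture(scope="session")
def cohort42_pipeline(cohort42):
    """Movement pipeline output on the seed-42 cohort."""
    trips, days, bouts = analyze_tracks(
        cohort42["tracks"], cohort42["colony"], cohort42["records"]
    )
    return {"trips": trips, "days": days, "bouts": bouts, **cohort42}
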