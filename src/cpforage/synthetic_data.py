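"""Synthetic GPS tracks, breeding records, body masses and habitat counts.

The generator emulates a central-place forager's tracking day: colony
residency bouts (jittered fixes inside the 50 m buffer), K ~ Poisson
foraging trips (straight outbound commute, a clumped foraging phase with
highly variable speed and optional near-stationary perching runs, straight
return), and low-tempo "loafing" excursions that carry the remaining
daylight budget.  Every fix set satisfies the track-model invariants and a
truth sidecar records, per simulated day and trip, exactly the quantities
the analysis pipeline is supposed to recover.

Calibration.  ``published_summary_preset`` encodes sex-by-period relative
patterns (males: many short trips; females: few long ones; no contrast
before pair formation) and normalizes them in closed form so that the
implied *pooled* means equal the published pooled summary statistics:
trip duration 1.16 h, trips/day 6.67, daily distance 97.82 km, colony
attendance 19.41 % of daylight, trip distance 10.98 km, trip max range
3.68 km, and 21.79 min total perching among trips with perching.  Two
second-order corrections are part of the closed-form calibration, never
tuned against pipeline output: (a) the foraging-clump radius is solved so
that commute legs plus clump wandering reproduce the pooled trip distance,
and (b) a normal-approximation inflation compensates the truncation bias
introduced when infeasible days (scheduled trips exceeding daylight) are
resampled.

Randomness: one RNG stream per individual-day derived from
(master seed, individual index, date ordinal), so any day is reproducible
in isolation and cohorts are byte-identical across runs.
"""
from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate

from .phenology import BreedingRecord, Period
from .track_model import EARTH_RADIUS_M, Site, Track, haversine, solar_times

# pooled published summary statistics used as calibration targets
POOLED_TARGETS = {
    "trip_duration_h": 1.16,
    "trips_per_day": 6.67,
    "daily_distance_km": 97.82,
    "attendance_pct": 19.41,
    "trip_distance_km": 10.98,
    "max_distance_km": 3.68,
    "perch_time_min": 21.79,  # among trips with >= 1 perching bout
    "perch_trip_fraction": 908.0 / 2171.0,
}

#: habitat classes and their pooled use percentages (shared by both sexes)
HABITAT_CLASSES = [
    "stubble", "cereal", "seedlings", "pastures", "ploughed",
    "sunflower", "others", "vineyards", "tree_groves",
]
HABITAT_PCT = np.array([25.05, 18.26, 12.42, 11.18, 9.01, 7.76, 7.14, 5.90, 3.10])

DEFAULT_COLONY = Site("colony", lon=-6.05, lat=37.40, attendance_radius=50.0)

#: complete-day plan per individual: period -> day offsets (establishment and
#: courtship relative to laying, incubation relative to laying, nestling
#: relative to hatching); weights 2/2/3/3 out of 10 days
DAY_PLAN = {
    Period.establishment: (-27, -24),
    Period.courtship: (-16, -9),
    Period.incubation: (4, 12, 20),
    Period.nestling: (6, 14, 22),
}
PERIOD_WEIGHTS = {p: len(v) / 10.0 for p, v in DAY_PLAN.items()}

INCUBATION_DAYS = 30
NESTLING_DAYS = 36
NOMINAL_LAYING = pd.Timestamp("2013-04-28")
SEXES = ("female", "male")


@dataclass
class GroupParams:
    """Movement-strategy parameters for one sex x period cell."""

    trips_per_day: float
    trip_duration_h: float
    trip_duration_cv: float
    max_range_km: float
    max_range_cv: float
    perch_prob: float
    perch_time_min: float
    perch_time_cv: float
    attendance_frac: float  # planted target, including the squeeze compensation
    attendance_sd: float
    inflation_trips: float = 1.0  # planted trips/day = calibrated * inflation
    inflation_duration: float = 1.0  # planted duration = calibrated * inflation
    perch_inflation: float = 1.0  # planted perch time = calibrated * inflation
    attendance_shortfall: float = 0.0  # squeeze compensation added to the target

    def __post_init__(self):
        if min(self.trips_per_day, self.trip_duration_h, self.max_range_km,
               self.perch_time_min) <= 0:
            raise ValueError("strategy means must be positive")
        if not 0.0 <= self.perch_prob <= 1.0:
            raise ValueError("perch_prob must lie in [0, 1]")


@dataclass
class StrategyParams:
    """Full simulator parameterization: per-group strategies + shared movement
    constants (commute speed, clump geometry, loafing speed, colony jitter)."""

    groups: dict
    commute_speed: float = 10.0  # m/s
    loaf_speed: float = 2.0  # m/s, displacement tempo of non-trip excursions
    clump_radius_m: float = 85.0
    colony_jitter_m: float = 20.0
    copula_rho: float = 0.5  # rank correlation of duration with range / perch
    cadence_s: int = 60

    def group(self, sex: str, period: Period) -> GroupParams:
        return self.groups[(sex, Period(period))]

    def implied_pooled(self) -> dict:
        """Pooled means the calibration encodes (inflation divided out):
        trip-weighted for per-trip quantities, day-weighted for attendance."""
        wk, wkt, wkr, wkp, wkpt, wa = 0.0, 0.0, 0.0, 0.0, 0.0, 0.0
        for (sex, period), g in self.groups.items():
            w = 0.5 * PERIOD_WEIGHTS[period]
            kap = g.trips_per_day / g.inflation_trips
            tau = g.trip_duration_h / g.inflation_duration
            rho = g.max_range_km / g_range_inflation(g, self.copula_rho)
            mu_p = g.perch_time_min / g.perch_inflation
            wk += w * kap
            wkt += w * kap * tau
            wkr += w * kap * rho
            wkp += w * kap * g.perch_prob
            wkpt += w * kap * g.perch_prob * mu_p
            wa += w * (g.attendance_frac - g.attendance_shortfall)
        return {
            "trips_per_day": wk,
            "trip_duration_h": wkt / wk,
            "max_distance_km": wkr / wk,
            "perch_trip_fraction": wkp / wk,
            "perch_time_min": wkpt / wkp,
            "attendance_pct": 100.0 * wa,
        }


def g_range_inflation(g: GroupParams, rho: float) -> float:
    """Inflation applied to duration-correlated quantities (range, perch)."""
    return 1.0 + rho * (g.inflation_duration - 1.0)


# ---------------------------------------------------------------------------
# closed-form calibration helpers
# ---------------------------------------------------------------------------

def _lognormal_pars(mean: float, cv: float) -> tuple[float, float]:
    s2 = math.log(1.0 + cv * cv)
    return math.log(mean) - 0.5 * s2, math.sqrt(s2)


def _disc_step_mean(radius: float, min_step: float) -> float:
    """E[distance | distance >= min_step] between two uniform points in a
    disc — the expected clump wandering step length."""

    def dens(d):
        u = d / (2.0 * radius)
        return (2.0 * d / radius ** 2) * (2.0 / math.pi) * (
            math.acos(u) - u * math.sqrt(max(0.0, 1.0 - u * u))
        )

    num, _ = integrate.quad(lambda d: d * dens(d), min_step, 2 * radius)
    den, _ = integrate.quad(dens, min_step, 2 * radius)
    return num / den


def default_day_lengths(colony: Site = DEFAULT_COLONY) -> dict:
    """Mean sunrise-to-sunset span (h) per period under the default plan."""
    out = {}
    for period, offsets in DAY_PLAN.items():
        lens = []
        for jitter in range(-3, 4):  # the deterministic laying-date spread
            laying = NOMINAL_LAYING + pd.Timedelta(days=jitter)
            anchor = laying if period != Period.nestling else laying + pd.Timedelta(
                days=INCUBATION_DAYS
            )
            for off in offsets:
                d = anchor + pd.Timedelta(days=off)
                sr, ss = solar_times(d, colony.lon, colony.lat)
                lens.append((ss - sr).total_seconds() / 3600.0)
        out[period] = float(np.mean(lens))
    return out


# relative sex-by-period patterns (qualitative structure of the findings:
# sexes alike before pair formation, then males = many short close trips,
# females = few long far ones with more perch-hunting)
_REL = {
    # (trips/day, duration, range, perch_prob, perch_time, attendance)
    ("female", Period.establishment): (4.5, 1.35, 4.2, 0.45, 25.0, 15.0),
    ("male", Period.establishment): (4.5, 1.35, 4.2, 0.45, 25.0, 15.0),
    ("female", Period.courtship): (4.5, 1.50, 4.6, 0.55, 30.0, 25.0),
    ("male", Period.courtship): (8.0, 0.90, 3.2, 0.30, 15.0, 18.0),
    ("female", Period.incubation): (3.5, 1.80, 5.5, 0.60, 35.0, 35.0),
    ("male", Period.incubation): (6.5, 1.00, 3.6, 0.30, 15.0, 25.0),
    ("female", Period.nestling): (8.0, 0.95, 3.6, 0.40, 20.0, 18.0),
    ("male", Period.nestling): (11.5, 0.70, 2.6, 0.35, 10.0, 8.0),
}

_DURATION_CV = 0.35
_RANGE_CV = 0.5
_PERCH_CV = 0.7
_ATTENDANCE_SD = 6.0  # percentage points, within group
_RETURN_FLOOR_M = 70.0  # last off-colony fix of a trip stays outside the buffer


@functools.lru_cache(maxsize=8)
def published_summary_preset(
    cadence_s: int = 60, colony: Site = DEFAULT_COLONY
) -> StrategyParams:
    """Strategy parameters moment-matched to the published pooled summaries.

    All normalizations are closed-form functions of the printed pooled
    targets, the relative sex-by-period pattern and the default day plan;
    nothing here depends on pipeline output.
    """
    w = {k: 0.5 * PERIOD_WEIGHTS[k[1]] for k in _REL}
    t = POOLED_TARGETS

    # trips/day, duration, range, perch probability, perch time, attendance
    kap = {k: v[0] for k, v in _REL.items()}
    s = t["trips_per_day"] / sum(w[k] * kap[k] for k in kap)
    kap = {k: v * s for k, v in kap.items()}

    tau = {k: v[1] for k, v in _REL.items()}
    s = (t["trips_per_day"] * t["trip_duration_h"]) / sum(
        w[k] * kap[k] * tau[k] for k in tau
    )
    tau = {k: v * s for k, v in tau.items()}

    rng_km = {k: v[2] for k, v in _REL.items()}
    s = (t["trips_per_day"] * t["max_distance_km"]) / sum(
        w[k] * kap[k] * rng_km[k] for k in rng_km
    )
    rng_km = {k: v * s for k, v in rng_km.items()}

    pp = {k: v[3] for k, v in _REL.items()}
    s = (t["trips_per_day"] * t["perch_trip_fraction"]) / sum(
        w[k] * kap[k] * pp[k] for k in pp
    )
    pp = {k: min(0.95, v * s) for k, v in pp.items()}

    mup = {k: v[4] for k, v in _REL.items()}
    s = t["perch_time_min"] * sum(w[k] * kap[k] * pp[k] for k in pp) / sum(
        w[k] * kap[k] * pp[k] * mup[k] for k in mup
    )
    mup = {k: v * s for k, v in mup.items()}

    att = {k: v[5] for k, v in _REL.items()}
    s = t["attendance_pct"] / sum(w[k] / (0.5 * PERIOD_WEIGHTS[k[1]]) * 0 + w[k] * att[k] for k in att) * \
        sum(w[k] for k in att)
    # day-weighted mean over groups: sum w*att / sum w, with sum w == 1
    s = t["attendance_pct"] / sum(w[k] * att[k] for k in att)
    att = {k: v * s / 100.0 for k, v in att.items()}

    # (a) clump radius solved so commute + wandering give the pooled trip
    # distance at the calibration cadence.  At 1-s cadence the clump model
    # is a hover/flight mix (not per-tick hops), so the distance identity
    # does not apply and a fixed geometry is used; the printed distance
    # summaries are calibrated at the 1-min cadence.
    v_commute = 10.0
    pooled_perch_s = t["perch_trip_fraction"] * t["perch_time_min"] * 60.0
    if cadence_s == 1:
        r_c = 85.0
    else:
        r_c = 80.0
        min_step = max(10.0, 1.2 * _perch_threshold(cadence_s))
        for _ in range(30):
            center = t["max_distance_km"] * 1000.0 - 0.8 * r_c
            forage_s = t["trip_duration_h"] * 3600.0 - 2.0 * center / v_commute
            n_steps = max(1.0, (forage_s - pooled_perch_s) / cadence_s)
            needed = (t["trip_distance_km"] * 1000.0 - 2.0 * center) / n_steps
            # invert E[step] ~= 0.9054 * r_c, then refine with the density
            r_new = max(min_step / 0.9054 * 1.2, needed / 0.9054)
            r_new *= needed / _disc_step_mean(r_new, min_step)
            r_c = float(np.clip(0.5 * r_c + 0.5 * r_new, 40.0, 95.0))

    # (b) feasibility calibration: a deterministic pilot of the scheduler
    # arithmetic (no track generation, no pipeline output) measures how the
    # infeasible-day truncation, the busy-day attendance squeeze and the
    # perch-window clipping deform the realized moments; planted parameters
    # are inflated until the pilot's realized means equal the calibrated
    # targets, and the clump radius is re-solved so commute legs plus
    # wandering reproduce the pooled trip distance.
    day_len = default_day_lengths(colony)
    rho_cop = 0.5
    min_step = max(10.0, 1.2 * _perch_threshold(cadence_s))
    groups = {}
    loaf_h_pool = 0.0
    n_outer = 1 if cadence_s == 1 else 2
    for outer in range(n_outer):
        groups = {}
        loaf_h_pool = 0.0
        # mean per-tick displacement in the clump: uniform hops at coarse
        # cadences, the hover/flight mix tempo at 1 s
        step_mean = 2.6 if cadence_s == 1 else _disc_step_mean(r_c, min_step)
        acc_K, acc_dist, acc_steps = 0.0, 0.0, 0.0
        for gi, key in enumerate(sorted(_REL, key=str)):
            period = key[1]
            L_s = day_len[period] * 3600.0
            u_k, u_t, att_pl, mup_pl = 1.0, 1.0, att[key], mup[key]
            pilot = None
            for it in range(3):
                trial = GroupParams(
                    trips_per_day=kap[key] * u_k,
                    trip_duration_h=tau[key] * u_t,
                    trip_duration_cv=_DURATION_CV,
                    max_range_km=rng_km[key],
                    max_range_cv=_RANGE_CV,
                    perch_prob=pp[key],
                    perch_time_min=mup_pl,
                    perch_time_cv=_PERCH_CV,
                    attendance_frac=att_pl,
                    attendance_sd=_ATTENDANCE_SD / 100.0,
                )
                pilot = _schedule_pilot(
                    trial, rho_cop, L_s, cadence_s, r_c, v_commute, step_mean,
                    seed=973101 + 100 * outer + 13 * gi + it,
                )
                u_k = float(np.clip(u_k * kap[key] / pilot["K"], 1.0, 1.8))
                u_t = float(np.clip(u_t * tau[key] / pilot["dur"], 1.0, 1.8))
                att_pl = float(np.clip(att_pl + (att[key] - pilot["att"]), 0.03, 0.8))
                mup_pl = float(np.clip(mup_pl * mup[key] / pilot["perch"],
                                       mup[key], 3.0 * mup[key]))
            corr = 1.0 + rho_cop * (u_t - 1.0)
            groups[key] = GroupParams(
                trips_per_day=kap[key] * u_k,
                trip_duration_h=tau[key] * u_t,
                trip_duration_cv=_DURATION_CV,
                max_range_km=rng_km[key] * corr,
                max_range_cv=_RANGE_CV,
                perch_prob=pp[key],
                perch_time_min=mup_pl,
                perch_time_cv=_PERCH_CV,
                attendance_frac=att_pl,
                attendance_sd=_ATTENDANCE_SD / 100.0,
                inflation_trips=u_k,
                inflation_duration=u_t,
                perch_inflation=mup_pl / mup[key],
                attendance_shortfall=att_pl - att[key],
            )
            w_key = 0.5 * PERIOD_WEIGHTS[period]
            loaf_h_pool += w_key * (
                day_len[period] * (1.0 - pilot["att"]) - pilot["trip_h"]
            )
            acc_K += w_key * pilot["K"]
            acc_dist += w_key * pilot["K"] * pilot["dist"]
            acc_steps += w_key * pilot["K"] * pilot["active_steps"]
        if cadence_s != 1:
            pooled_dist = acc_dist / acc_K
            steps_per_trip = acc_steps / acc_K
            # re-solve the clump radius from the distance shortfall
            need_step = step_mean + (
                t["trip_distance_km"] - pooled_dist
            ) * 1000.0 / max(steps_per_trip, 1.0)
            for _ in range(10):
                r_c += 0.5 * (need_step - _disc_step_mean(r_c, min_step)) / 0.9054
            r_c = float(np.clip(r_c, 40.0, 95.0))

    # loafing tempo closes the daily-distance budget
    mean_L = sum(PERIOD_WEIGHTS[p] * day_len[p] for p in day_len)
    # mean colony hop: iid draws in the jitter disc at coarse cadences, a
    # slow resting walk (~0.3 m/s) at 1-s cadence
    jitter_step = 0.9054 * 20.0 if cadence_s >= 60 else 0.3 * cadence_s
    att_pool = t["attendance_pct"] / 100.0
    jitter_km = att_pool * mean_L * 3600.0 / cadence_s * jitter_step / 1000.0
    loaf_speed = max(
        0.5,
        (t["daily_distance_km"] - t["trips_per_day"] * t["trip_distance_km"] - jitter_km)
        / loaf_h_pool * 1000.0 / 3600.0,
    )
    return StrategyParams(
        groups=groups,
        commute_speed=v_commute,
        loaf_speed=float(loaf_speed),
        clump_radius_m=r_c,
        colony_jitter_m=20.0,
        copula_rho=rho_cop,
        cadence_s=cadence_s,
    )


# ---------------------------------------------------------------------------
# geometry helpers (local tangent plane around the colony)
# ---------------------------------------------------------------------------

def _xy_to_lonlat(xy: np.ndarray, site: Site) -> tuple[np.ndarray, np.ndarray]:
    lat = site.lat + np.degrees(xy[:, 1] / EARTH_RADIUS_M)
    lon = site.lon + np.degrees(
        xy[:, 0] / (EARTH_RADIUS_M * math.cos(math.radians(site.lat)))
    )
    return lon, lat


def _perch_threshold(cadence: int) -> float:
    return {1: 1.0, 60: 5.0, 180: 15.0, 300: 25.0, 600: 50.0}[cadence]


# ---------------------------------------------------------------------------
# one simulated day
# ---------------------------------------------------------------------------

_COPULA_CHOL = None


def _draw_trip_set(g: GroupParams, rho: float, rng, min_ticks: int, dt: int):
    """Correlated draws of (duration ticks, range m, perch s) for one day."""
    K = int(rng.poisson(g.trips_per_day))
    if K == 0:
        return []
    cov = np.array([[1, rho, rho], [rho, 1, 0.25], [rho, 0.25, 1]])
    z = rng.standard_normal((K, 3)) @ np.linalg.cholesky(cov).T
    mu_t, s_t = _lognormal_pars(g.trip_duration_h * 3600.0, g.trip_duration_cv)
    mu_r, s_r = _lognormal_pars(g.max_range_km * 1000.0, g.max_range_cv)
    mu_p, s_p = _lognormal_pars(g.perch_time_min * 60.0, g.perch_time_cv)
    ticks = np.maximum(min_ticks, np.round(np.exp(mu_t + s_t * z[:, 0]) / dt)).astype(int)
    rng_m = np.exp(mu_r + s_r * z[:, 1])
    perch_s = np.where(
        rng.random(K) < g.perch_prob, np.exp(mu_p + s_p * z[:, 2]), 0.0
    )
    return [[int(t), float(r), float(p)] for t, r, p in zip(ticks, rng_m, perch_s)]


def _draw_day_schedule(g: GroupParams, rho: float, rng, n_ticks: int, day_len_s: float, dt: int):
    """Draw one day's trip set, attendance target and colony allocation.

    Shared by :func:`simulate_day` and the preset's calibration pilot so that
    the schedule-level truncation corrections stay exact by construction.
    Feasibility concerns the trips alone (plus a minimal colony/excursion
    overhead); the attendance allocation is squeezed on busy days.
    """
    min_trip_ticks = max(7, 540 // dt)
    n_resample = 0
    for attempt in range(60):
        trips = _draw_trip_set(g, rho, rng, min_trip_ticks, dt)
        trip_inner = sum(t[0] - 1 for t in trips)
        if trip_inner + 2 * (len(trips) + 3) + 8 <= n_ticks:
            break
        n_resample += 1
        if attempt >= 40 and trips:
            trips.sort(key=lambda t: t[0])
            trips = trips[:-1]  # drop the longest trip as a last resort
            trip_inner = sum(t[0] - 1 for t in trips)
            if trip_inner + 2 * (len(trips) + 3) + 8 <= n_ticks:
                break
    K = len(trips)
    trip_inner = sum(t[0] - 1 for t in trips)
    att = float(np.clip(rng.normal(g.attendance_frac, g.attendance_sd), 0.025, 0.85))
    n_exc = int(rng.integers(1, 3))
    # measured interval-weighted colony credit of a day is (colony_fixes-1)*dt
    colony_target = att * day_len_s / dt + 1.0
    avail = n_ticks - trip_inner - 4 * n_exc
    colony_fixes = int(round(np.clip(colony_target, 2 * (K + n_exc + 1), avail)))
    exc_total = n_ticks - colony_fixes - trip_inner
    return {
        "trips": trips,
        "att": att,
        "n_exc": n_exc,
        "colony_fixes": colony_fixes,
        "exc_total": exc_total,
        "n_resample": n_resample,
    }


def _trip_layout(ticks: int, range_m: float, perch_s: float, r_c: float,
                 v: float, dt: int):
    """Tick budget of one trip: (patch center distance, outbound fixes,
    forage fixes, clipped perch ticks).  Mirrors `_trip_positions`."""
    center = max(300.0 + r_c + 50.0, range_m - 0.8 * r_c)
    n_out = max(1, math.ceil(center / (v * dt)))
    n_inner = ticks - 1
    while 2 * n_out + 4 > n_inner and n_out > 1:
        center *= 0.75
        n_out = max(1, math.ceil(center / (v * dt)))
    n_forage = n_inner - 2 * n_out
    perch_ticks = min(int(round(perch_s / dt)), max(0, n_forage - 4))
    return center, n_out, n_forage, perch_ticks


def _schedule_pilot(g: GroupParams, rho: float, day_len_s: float, dt: int,
                    r_c: float, v: float, step_mean: float,
                    n_days: int = 2500, seed: int = 973101):
    """Deterministic pilot of the scheduler arithmetic: realized trips/day,
    trip duration, attendance, trip distance and clipped perch time under
    truncation and squeezing.  Pure calibration of the generator's own
    construction — no track is generated and no pipeline output is used."""
    rng = np.random.default_rng([seed])
    n_ticks = int(day_len_s // dt) + 1
    tot_K = 0
    tot_dur_h = 0.0
    tot_att = 0.0
    tot_trip_h = 0.0
    tot_dist_km = 0.0
    tot_steps = 0
    perch_sum_min = 0.0
    n_perch_trips = 0
    for _ in range(n_days):
        s = _draw_day_schedule(g, rho, rng, n_ticks, day_len_s, dt)
        day_h = sum(t[0] * dt for t in s["trips"]) / 3600.0
        tot_K += len(s["trips"])
        tot_dur_h += day_h
        tot_trip_h += day_h
        tot_att += (s["colony_fixes"] - 1) * dt / day_len_s
        for ticks, range_m, perch_s in s["trips"]:
            center, n_out, n_forage, perch_ticks = _trip_layout(
                ticks, range_m, perch_s, r_c, v, dt
            )
            kept = perch_ticks if perch_ticks * dt >= 30.0 else 0
            active = max(0, n_forage - kept)
            tot_dist_km += (2.0 * center + active * step_mean) / 1000.0
            tot_steps += active
            if kept:
                perch_sum_min += kept * dt / 60.0
                n_perch_trips += 1
    n_trips = max(tot_K, 1)
    return {
        "K": tot_K / n_days,
        "dur": tot_dur_h / n_trips,
        "trip_h": tot_trip_h / n_days,
        "att": tot_att / n_days,
        "dist": tot_dist_km / n_trips,
        "active_steps": tot_steps / n_trips,
        "perch": perch_sum_min / max(n_perch_trips, 1),
        "perch_frac": n_perch_trips / n_trips,
    }


def _clump_positions(rng, n, center_xy, r_c, min_step, prev_xy):
    """Sequential uniform-in-disc positions with a minimum hop length."""
    pts = np.empty((n, 2))
    cur = prev_xy
    for i in range(n):
        for _ in range(200):
            r = r_c * math.sqrt(rng.random())
            th = rng.uniform(0, 2 * math.pi)
            cand = center_xy + np.array([r * math.cos(th), r * math.sin(th)])
            if np.hypot(*(cand - cur)) >= min_step:
                break
        pts[i] = cand
        cur = cand
    return pts


def _trip_positions(rng, ticks, range_m, perch_s, params, dt, bearing):
    """xy positions for a trip's interior ticks (ticks - 1 fixes outside the
    colony) plus the planted perch windows (start_tick, end_tick)."""
    v = params.commute_speed
    r_c = params.clump_radius_m
    center, n_out, n_forage, perch_ticks = _trip_layout(
        ticks, range_m, perch_s, r_c, v, dt
    )
    n_inner = ticks - 1
    u = np.array([math.cos(bearing), math.sin(bearing)])
    # strictly increasing commute distances (no duplicate fixes that could
    # masquerade as perching)
    out_d = center * np.arange(1, n_out + 1) / n_out
    outbound = out_d[:, None] * u[None, :]
    min_step = max(10.0, 1.2 * _perch_threshold(dt))
    center_xy = center * u

    if dt == 1:
        forage, perch_runs = _forage_1s(
            rng, n_forage, perch_ticks, center_xy, r_c, outbound[-1]
        )
    else:
        forage, perch_runs = _forage_coarse(
            rng, n_forage, perch_ticks, center_xy, r_c, min_step, outbound[-1]
        )

    # return commute: strictly decreasing toward the buffer edge; the next
    # colony-bout fix is the arrival fix
    start = forage[-1] if len(forage) else outbound[-1]
    d0 = max(np.hypot(*start), _RETURN_FLOOR_M + 1.0)
    n_ret = n_inner - n_out - n_forage
    if n_ret > 0:
        ret_d = d0 - (d0 - _RETURN_FLOOR_M) * np.arange(1, n_ret + 1) / n_ret
        inbound = (ret_d[:, None] / d0) * start[None, :]
    else:
        inbound = np.zeros((0, 2))
    xy = np.concatenate([outbound, forage, inbound], axis=0)
    offset = n_out
    runs = [(offset + a, offset + b) for a, b in perch_runs]
    return xy, runs, n_forage


def _forage_coarse(rng, n_forage, perch_ticks, center_xy, r_c, min_step, prev_xy):
    """Cadence >= 60 s: independent clump hops with a floor on hop length so
    active movement can never mimic a perching run."""
    if n_forage <= 0:
        return np.zeros((0, 2)), []
    runs = []
    if perch_ticks >= 1:
        start = int(rng.integers(1, max(2, n_forage - perch_ticks)))
        runs.append((start, start + perch_ticks))
    xy = np.empty((n_forage, 2))
    perch_pt = None
    cur = prev_xy
    i = 0
    while i < n_forage:
        in_perch = any(a <= i <= b for a, b in runs)
        if in_perch:
            if perch_pt is None:
                # perch point well separated from the previous active fix
                perch_pt = _clump_positions(rng, 1, center_xy, r_c, min_step, cur)[0]
            xy[i] = perch_pt + rng.normal(0, 0.15, 2)
        else:
            ref = perch_pt if (perch_pt is not None and any(b == i - 1 for _, b in runs)) else cur
            xy[i] = _clump_positions(rng, 1, center_xy, r_c, min_step, ref)[0]
        cur = xy[i]
        i += 1
    return xy, [(a, min(b, n_forage - 1)) for a, b in runs]


def _forage_1s(rng, n_forage, perch_ticks, center_xy, r_c, prev_xy):
    """1-s cadence: hover (near-stationary, < 30 s) / relocation-flight mix,
    plus the planted perch run.  Hover micro-steps fall below the 1 m perch
    threshold but every hover is shorter than the 30 s filter."""
    if n_forage <= 0:
        return np.zeros((0, 2)), []
    xy = np.empty((n_forage, 2))
    runs = []
    perch_start = None
    if perch_ticks >= 1:
        perch_start = int(rng.integers(1, max(2, n_forage - perch_ticks)))
        runs.append((perch_start, perch_start + perch_ticks))
    cur = np.array(prev_xy, float)
    i = 0
    # strict hover/flight alternation: a hover (sub-threshold micro-steps,
    # always < 30 s) is never adjacent to another hover or to the perch run,
    # so only the planted perch can form a filtered bout
    hover_next = False
    while i < n_forage:
        if perch_start is not None and i == perch_start:
            pt = cur + rng.normal(0, 1.0, 2) + np.array([8.0, 0.0])
            end = min(perch_start + perch_ticks, n_forage - 1)
            for j in range(i, end + 1):
                xy[j] = pt + rng.normal(0, 0.1, 2)
            cur = xy[end]
            i = end + 1
            hover_next = False  # leave the perch with a flight
            continue
        if hover_next:  # hover: < 30 s by construction
            dur = int(rng.integers(8, 26))
            dur = min(dur, n_forage - i)
            drift = rng.normal(0, 0.25, (dur, 2))
            seg = cur + np.cumsum(drift, axis=0)
            if perch_start is not None and i < perch_start <= i + dur:
                dur = perch_start - i
                seg = seg[:dur]
        else:  # relocation flight at ~8 m/s toward a fresh clump point
            tgt = _clump_positions(rng, 1, center_xy, r_c, 30.0, cur)[0]
            dist = np.hypot(*(tgt - cur))
            dur = max(3, int(dist / 8.0))
            dur = min(dur, n_forage - i)
            frac = np.arange(1, dur + 1) / dur
            seg = cur[None, :] + frac[:, None] * (tgt - cur)[None, :]
            if perch_start is not None and i < perch_start <= i + dur:
                dur = perch_start - i
                seg = seg[:dur]
        if len(seg) == 0:
            hover_next = not hover_next
            continue
        xy[i : i + len(seg)] = seg
        cur = xy[i + len(seg) - 1]
        i += len(seg)
        hover_next = not hover_next
    return xy, [(a, min(b, n_forage - 1)) for a, b in runs]


def simulate_day(
    params: StrategyParams,
    sex: str,
    period: Period,
    date,
    colony: Site = DEFAULT_COLONY,
    cadence_s: int | None = None,
    rng=None,
    seed: int | None = None,
):
    """Simulate one individual-day; returns (fixes DataFrame, truth dict).

    The truth dict carries the planted ground truth measured on the emitted
    fixes themselves: per-trip duration/range/distance/perch windows, the
    interval-weighted attendance, and the daily accumulated distance.
    Infeasible schedules (trips exceeding daylight) are resampled, counted
    in ``truth['n_resample']``.
    """
    dt = int(cadence_s or params.cadence_s)
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else 0)
    g = params.group(sex, period)
    date = pd.Timestamp(date)
    sunrise, sunset = solar_times(date, colony.lon, colony.lat)
    day_len_s = (sunset - sunrise).total_seconds()
    t0 = sunrise.ceil(f"{dt}s")
    n_ticks = int((sunset - t0).total_seconds() // dt) + 1

    sched = _draw_day_schedule(g, params.copula_rho, rng, n_ticks, day_len_s, dt)
    trips = sched["trips"]
    n_exc = sched["n_exc"]
    exc_ticks_total = sched["exc_total"]
    n_resample = sched["n_resample"]

    # interleave away segments (trips + loafing excursions), colony bouts
    # in between
    away = [("trip", t) for t in trips]
    if n_exc == 1 or exc_ticks_total < 8:
        away += [("exc", max(exc_ticks_total, 0))]
    else:
        half = int(exc_ticks_total * rng.uniform(0.3, 0.7))
        away += [("exc", half), ("exc", exc_ticks_total - half)]
    order = rng.permutation(len(away))
    away = [away[i] for i in order]
    away = [a for a in away if not (a[0] == "exc" and a[1] < 4)]
    n_bouts = len(away) + 1
    used_away = sum(a[1][0] - 1 if a[0] == "trip" else a[1] for a in away)
    colony_fixes = n_ticks - used_away
    shares = rng.dirichlet(np.ones(n_bouts))
    bout_len = np.maximum(2, np.floor(shares * (colony_fixes - 2 * n_bouts)).astype(int) + 2)
    while bout_len.sum() > colony_fixes:
        bout_len[np.argmax(bout_len)] -= 1
    bout_len[-1] += colony_fixes - bout_len.sum()

    # --- emit fixes segment by segment -------------------------------------
    xy = np.empty((n_ticks, 2))
    speed = np.empty(n_ticks)
    alt = np.empty(n_ticks)
    pos = 0
    trip_truth = []
    perch_windows = []
    colony_tick_mask = np.zeros(n_ticks, bool)

    def emit_colony(n):
        nonlocal pos
        if n <= 0:
            return
        if dt >= 60:
            r = params.colony_jitter_m * np.sqrt(rng.random(n))
            th = rng.uniform(0, 2 * math.pi, n)
            xy[pos : pos + n, 0] = r * np.cos(th)
            xy[pos : pos + n, 1] = r * np.sin(th)
        else:
            # slow resting walk confined to the jitter disc
            steps = rng.normal(0.0, 0.25 * dt, (n, 2))
            walk = np.cumsum(steps, axis=0)
            rad = np.hypot(walk[:, 0], walk[:, 1])
            over = rad > params.colony_jitter_m
            if over.any():
                walk[over] *= (params.colony_jitter_m / rad[over])[:, None]
            xy[pos : pos + n] = walk
        speed[pos : pos + n] = np.abs(rng.normal(0.3, 0.2, n))
        alt[pos : pos + n] = rng.normal(10, 3, n)
        colony_tick_mask[pos : pos + n] = True
        pos += n

    emit_colony(int(bout_len[0]))
    for seg_i, seg in enumerate(away):
        if seg[0] == "trip":
            ticks, rng_m, perch_s = seg[1]
            bearing = rng.uniform(0, 2 * math.pi)
            dep_tick = pos - 1
            pts, runs, n_forage = _trip_positions(
                rng, ticks, rng_m, perch_s, params, dt, bearing
            )
            n_inner = len(pts)
            xy[pos : pos + n_inner] = pts
            d_steps = np.diff(
                np.vstack([xy[pos - 1], pts, [0.0, 0.0]]), axis=0
            )
            # speeds: commute fast, forage hover/flight mix, perch ~0
            sp = np.empty(n_inner)
            n_out = (n_inner - n_forage + 1) // 2 if n_forage else n_inner // 2
            sp[:] = np.abs(rng.normal(params.commute_speed, 1.0, n_inner))
            fstart = n_out
            for j in range(n_forage):
                k = fstart + j
                in_perch = any(a <= k <= b for a, b in runs)
                if in_perch:
                    sp[k] = abs(rng.normal(0.05, 0.05))
                elif j % 2 == 0:
                    sp[k] = 0.4 + abs(rng.normal(0, 0.25))
                else:
                    sp[k] = 7.0 + abs(rng.normal(0, 1.5))
            speed[pos : pos + n_inner] = sp
            a_ = np.full(n_inner, 60.0)
            a_[fstart : fstart + n_forage] = 15.0
            alt[pos : pos + n_inner] = a_ + rng.normal(0, 4, n_inner)
            for a, b in runs:
                alt[pos + a : pos + b + 1] = rng.normal(3, 1)
            arr_tick = pos + n_inner
            perch_spans = [
                ((pos + a), (pos + min(b, n_inner - 1))) for a, b in runs
            ]
            kept = [
                (a, b) for a, b in perch_spans if (b - a) * dt >= 30.0
            ]
            trip_truth.append(
                {
                    "trip_index": len(trip_truth),
                    "departure_tick": dep_tick,
                    "arrival_tick": arr_tick,
                    "duration_h": (arr_tick - dep_tick) * dt / 3600.0,
                    "perch_time_min": sum((b - a) * dt for a, b in kept) / 60.0,
                    "n_perch_bouts": len(kept),
                }
            )
            perch_windows.extend(kept)
            pos = arr_tick
        else:  # loafing excursion: out and back at the loafing tempo
            n = seg[1]
            bearing = rng.uniform(0, 2 * math.pi)
            u = np.array([math.cos(bearing), math.sin(bearing)])
            half = n // 2
            d_out = np.arange(1, half + 1) * params.loaf_speed * dt
            d_back = d_out[::-1][: n - 1 - half]
            dists = np.concatenate([d_out, d_back])
            pts = dists[:, None] * u[None, :]
            n_inner = len(pts)
            xy[pos : pos + n_inner] = pts
            speed[pos : pos + n_inner] = np.abs(
                rng.normal(params.loaf_speed, 0.15 * params.loaf_speed, n_inner)
            )
            alt[pos : pos + n_inner] = rng.normal(80, 15, n_inner)
            pos += n_inner
        emit_colony(int(bout_len[seg_i + 1]))
    # absorb any rounding remainder in a final colony stretch
    if pos < n_ticks:
        emit_colony(n_ticks - pos)

    lon, lat = _xy_to_lonlat(xy, colony)
    times = t0 + pd.to_timedelta(np.arange(n_ticks) * dt, unit="s")
    fixes = pd.DataFrame(
        {
            "timestamp": times,
            "lon": lon,
            "lat": lat,
            "altitude": alt,
            "speed": np.maximum(speed, 0.0),
            "sampling_interval": dt,
        }
    )

    # truth quantities measured on the emitted fixes
    inside = colony_tick_mask
    credit = (inside[:-1].astype(float) + inside[1:]) / 2.0
    attendance_s = float(credit.sum() * dt)
    daily_dist = float(np.sum(np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1])))) / 1000.0
    for t in trip_truth:
        a, b = t.pop("departure_tick"), t.pop("arrival_tick")
        seg = xy[a : b + 1]
        t["max_distance_km"] = float(np.hypot(seg[:, 0], seg[:, 1]).max()) / 1000.0
        t["distance_km"] = float(
            np.sum(np.hypot(np.diff(seg[:, 0]), np.diff(seg[:, 1])))
        ) / 1000.0
        t["departure"] = times[a]
        t["arrival"] = times[b]
    truth = {
        "date": date,
        "sex": sex,
        "period": period,
        "n_trips": len(trip_truth),
        "trips": trip_truth,
        "perch_windows": [(times[a], times[b]) for a, b in perch_windows],
        "attendance_pct": 100.0 * attendance_s / day_len_s,
        "daily_distance_km": daily_dist,
        "day_length_h": day_len_s / 3600.0,
        "n_resample": n_resample,
    }
    return fixes, truth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def make_breeding_records(n_individuals: int = 30) -> dict[str, BreedingRecord]:
    """Deterministic pair-year records: laying spread over one week around
    the nominal date, 30 d incubation, 36 d to fledging."""
    records = {}
    for i in range(n_individuals):
        laying = NOMINAL_LAYING + pd.Timedelta(days=(i % 7) - 3)
        hatching = laying + pd.Timedelta(days=INCUBATION_DAYS)
        records[f"bird{i:02d}"] = BreedingRecord(
            pair_id=f"bird{i:02d}",
            arrival_date=laying - pd.Timedelta(days=35),
            laying_date=laying,
            hatching_date=hatching,
            fledging_date=hatching + pd.Timedelta(days=NESTLING_DAYS),
            brood_size_by_date={hatching: 4},
        )
    return records


def individual_sex(index: int) -> str:
    return SEXES[index % 2]


def simulate_cohort(
    params: StrategyParams | None = None,
    n_individuals: int = 30,
    cadence_s: int = 60,
    seed: int = 42,
    colony: Site = DEFAULT_COLONY,
):
    """Simulate the full cohort under the default day plan (10 complete days
    per individual: 2 establishment, 2 courtship, 3 incubation, 3 nestling).

    Returns (tracks, trip_truth, day_truth, records, colony, params).
    """
    params = params or published_summary_preset(cadence_s, colony)
    records = make_breeding_records(n_individuals)
    tracks, trip_rows, day_rows = [], [], []
    for i, (ind, rec) in enumerate(records.items()):
        sex = individual_sex(i)
        frames = []
        for period, offsets in DAY_PLAN.items():
            anchor = rec.laying_date if period != Period.nestling else rec.hatching_date
            for off in offsets:
                date = anchor + pd.Timedelta(days=off)
                rng = np.random.default_rng([seed, i, date.toordinal()])
                fixes, truth = simulate_day(
                    params, sex, period, date, colony, cadence_s, rng=rng
                )
                frames.append(fixes)
                for t in truth["trips"]:
                    trip_rows.append(
                        {"individual_id": ind, "sex": sex, "period": str(period),
                         "date": truth["date"], **t}
                    )
                day_rows.append(
                    {
                        "individual_id": ind,
                        "sex": sex,
                        "period": str(period),
                        "date": truth["date"],
                        "n_trips": truth["n_trips"],
                        "attendance_pct": truth["attendance_pct"],
                        "daily_distance_km": truth["daily_distance_km"],
                        "day_length_h": truth["day_length_h"],
                        "n_resample": truth["n_resample"],
                    }
                )
        fixes = pd.concat(frames, ignore_index=True)
        tracks.append(Track(individual_id=ind, fixes=fixes, sex=sex, colony=colony))
    return (
        tracks,
        pd.DataFrame(trip_rows),
        pd.DataFrame(day_rows),
        records,
        colony,
        params,
    )


# ---------------------------------------------------------------------------
# body mass and habitat counts
# ---------------------------------------------------------------------------

@dataclass
class BodyMassParams:
    """Gaussian body-mass process: female baseline + additive male offset +
    shared smooth seasonal curve + individual intercept + noise."""

    baseline_g: float = 140.0
    sex_offset_g: float = -18.28  # male - female
    curve_amplitude_g: float = 10.0
    residual_sd_g: float = 5.0
    individual_sd_g: float = 7.0

    def curve(self, day_of_year):
        """Smooth seasonal trend: rise to a peak near incubation, then a
        decline through the nestling period."""
        d = np.asarray(day_of_year, float)
        return self.curve_amplitude_g * np.sin((d - 55.0) / 145.0 * math.pi)


def simulate_body_mass(
    params: BodyMassParams | None = None,
    n_individuals: int = 30,
    n_per_individual: int = 9,
    seed: int = 42,
) -> pd.DataFrame:
    """Body-mass measurements over the season (weekly captures, March-July)."""
    p = params or BodyMassParams()
    rng = np.random.default_rng([seed, 7001])
    rows = []
    for i in range(n_individuals):
        sex = individual_sex(i)
        b_i = rng.normal(0.0, p.individual_sd_g)
        doys = np.sort(rng.uniform(62, 196, n_per_individual))
        for d in doys:
            mass = (
                p.baseline_g
                + (p.sex_offset_g if sex == "male" else 0.0)
                + float(p.curve(d))
                + b_i
                + rng.normal(0.0, p.residual_sd_g)
            )
            rows.append(
                {
                    "individual_id": f"bird{i:02d}",
                    "sex": sex,
                    "day_of_year": float(d),
                    "mass_g": mass,
                    "year": 2013,
                    "colony": "colonyA",
                }
            )
    return pd.DataFrame(rows)


def habitat_probabilities() -> np.ndarray:
    """The nine printed habitat-use percentages, renormalized to sum to 1."""
    return HABITAT_PCT / HABITAT_PCT.sum()


def simulate_habitat_counts(
    p_female=None, p_male=None, n_per_sex: int = 161, seed: int = 42
) -> pd.DataFrame:
    """2 x 9 multinomial habitat-count table (default: identical use)."""
    pf = np.asarray(p_female if p_female is not None else habitat_probabilities())
    pm = np.asarray(p_male if p_male is not None else pf)
    for q in (pf, pm):
        if abs(q.sum() - 1.0) > 1e-8:
            raise ValueError("habitat probabilities must sum to 1")
    rng = np.random.default_rng([seed, 7002])
    return pd.DataFrame(
        [rng.multinomial(n_per_sex, pf), rng.multinomial(n_per_sex, pm)],
        index=["female", "male"],
        columns=HABITAT_CLASSES[: len(pf)],
    )
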