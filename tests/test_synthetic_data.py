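"""Synthetic-data generator: determinism, calibration and truth integrity."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from cpforage import (
    BodyMassParams,
    ModelSpec,
    Period,
    Track,
    chisq_homogeneity,
    fit_smooth,
    published_summary_preset,
    simulate_body_mass,
    simulate_cohort,
    simulate_day,
    simulate_habitat_counts,
)
from cpforage.synthetic_data import (
    DAY_PLAN,
    HABITAT_PCT,
    POOLED_TARGETS,
    habitat_probabilities,
    make_breeding_records,
)
from conftest import COLONY


class TestDeterminism:
    def test_same_seed_gives_identical_day(self):
        p = published_summary_preset()
        out = []
        for _ in range(2):
            rng = np.random.default_rng([17, 3, 735000])
            fixes, truth = simulate_day(
                p, "female", Period.courtship, "2013-04-15", COLONY, 60, rng=rng
            )
            out.append((fixes, truth))
        pd.testing.assert_frame_equal(out[0][0], out[1][0])
        assert out[0][1]["attendance_pct"] == out[1][1]["attendance_pct"]

    def test_cohort_day_streams_are_independent(self):
        """Each individual-day derives its RNG from (seed, individual, date),
        so regenerating one day in isolation reproduces the cohort's."""
        tracks, trip_truth, day_truth, records, colony, params = simulate_cohort(
            n_individuals=2, seed=5
        )
        rec = records["bird01"]
        date = rec.laying_date + pd.Timedelta(days=4)  # first incubation day
        rng = np.random.default_rng([5, 1, date.toordinal()])
        fixes, truth = simulate_day(
            params, "male", Period.incubation, date, colony, 60, rng=rng
        )
        row = day_truth[(day_truth.individual_id == "bird01") & (day_truth.date == date)]
        assert row["n_trips"].iloc[0] == truth["n_trips"]
        assert row["daily_distance_km"].iloc[0] == pytest.approx(
            truth["daily_distance_km"]
        )


class TestCalibration:
    def test_implied_pooled_means_equal_published_targets(self):
        p = published_summary_preset()
        implied = p.implied_pooled()
        assert implied["trips_per_day"] == pytest.approx(6.67, abs=1e-9)
        assert implied["trip_duration_h"] == pytest.approx(1.16, abs=1e-9)
        assert implied["max_distance_km"] == pytest.approx(3.68, abs=1e-9)
        assert implied["perch_time_min"] == pytest.approx(21.79, abs=1e-9)
        assert implied["attendance_pct"] == pytest.approx(19.41, abs=1e-9)
        assert implied["perch_trip_fraction"] == pytest.approx(908 / 2171, abs=1e-9)

    def test_moment_match_on_ten_thousand_trips(self):
        """A large simulated cohort reproduces every calibrated pooled mean
        within 3% (Monte-Carlo error included)."""
        tracks, trip_truth, day_truth, *_ = simulate_cohort(n_individuals=150, seed=7)
        assert len(trip_truth) >= 9000
        perching = trip_truth[trip_truth.n_perch_bouts > 0]
        measured = {
            "trip_duration_h": trip_truth.duration_h.mean(),
            "trip_distance_km": trip_truth.distance_km.mean(),
            "max_distance_km": trip_truth.max_distance_km.mean(),
            "trips_per_day": day_truth.n_trips.mean(),
            "attendance_pct": day_truth.attendance_pct.mean(),
            "daily_distance_km": day_truth.daily_distance_km.mean(),
            "perch_time_min": perching.perch_time_min.mean(),
        }
        for key, value in measured.items():
            assert value == pytest.approx(POOLED_TARGETS[key], rel=0.03), key

    def test_sexes_differ_in_strategy_after_pair_formation(self):
        """Males take many short trips, females few long ones — but not in
        the establishment period, when the pair does not yet exist."""
        p = published_summary_preset()
        est_f = p.group("female", Period.establishment)
        est_m = p.group("male", Period.establishment)
        # calibrated (pre-inflation) targets are identical; planted values
        # differ only by the per-group feasibility-pilot correction
        assert est_f.trips_per_day / est_f.inflation_trips == pytest.approx(
            est_m.trips_per_day / est_m.inflation_trips, rel=1e-9
        )
        for period in (Period.courtship, Period.incubation, Period.nestling):
            f, m = p.group("female", period), p.group("male", period)
            assert m.trips_per_day > f.trips_per_day
            assert m.trip_duration_h < f.trip_duration_h
            assert m.max_range_km < f.max_range_km


class TestGeneratedTracks:
    def test_fixes_satisfy_track_invariants(self):
        p = published_summary_preset()
        rng = np.random.default_rng([2, 0, 1])
        fixes, _ = simulate_day(
            p, "male", Period.nestling, "2013-06-10", COLONY, 60, rng=rng
        )
        track = Track(individual_id="x", fixes=fixes, sex="male")  # validates
        assert track.fixes["timestamp"].is_monotonic_increasing
        assert (track.fixes["speed"] >= 0).all()
        assert (track.fixes["sampling_interval"] == 60).all()

    def test_day_plan_weights_are_2233(self):
        assert {p: len(v) for p, v in DAY_PLAN.items()} == {
            Period.establishment: 2,
            Period.courtship: 2,
            Period.incubation: 3,
            Period.nestling: 3,
        }

    def test_breeding_records_are_internally_consistent(self):
        for rec in make_breeding_records(10).values():
            assert rec.arrival_date <= rec.courtship_start < rec.laying_date
            assert rec.laying_date < rec.hatching_date < rec.fledging_date

    def test_truth_sidecar_roundtrips_through_csv(self, tmp_path, cohort42):
        path = tmp_path / "truth.csv"
        cohort42["trip_truth"].to_csv(path, index=False)
        back = pd.read_csv(path, parse_dates=["date", "departure", "arrival"])
        np.testing.assert_allclose(
            back["duration_h"], cohort42["trip_truth"]["duration_h"]
        )
        np.testing.assert_allclose(
            back["max_distance_km"], cohort42["trip_truth"]["max_distance_km"]
        )


class TestBodyMass:
    def test_zero_noise_flat_curve_gives_exact_offset(self):
        p = BodyMassParams(
            sex_offset_g=-18.28, curve_amplitude_g=0.0, residual_sd_g=1e-12,
            individual_sd_g=1e-12,
        )
        tab = simulate_body_mass(p, n_individuals=10, seed=1)
        means = tab.groupby("sex")["mass_g"].mean()
        assert means["male"] - means["female"] == pytest.approx(-18.28, abs=1e-6)

    def test_smooth_fit_recovers_planted_offset(self):
        tab = simulate_body_mass(seed=42)
        spec = ModelSpec(
            "mass_g", fixed=["sex"], smooth="day_of_year", random=["individual_id"]
        )
        fit = fit_smooth(spec, tab)
        sex_hat = fit.fit.beta[fit.fit.names.index("sex[T.male]")]
        sex_se = fit.fit.se[fit.fit.names.index("sex[T.male]")]
        assert abs(sex_hat - (-18.28)) <= 2 * sex_se

    def test_doubling_residual_sd_inflates_the_standard_error(self):
        spec = ModelSpec(
            "mass_g", fixed=["sex"], smooth="day_of_year", random=["individual_id"]
        )
        ses = []
        for sd in (4.0, 8.0):
            p = BodyMassParams(residual_sd_g=sd, individual_sd_g=1.0)
            tab = simulate_body_mass(p, seed=9)
            fit = fit_smooth(spec, tab)
            ses.append(fit.fit.se[fit.fit.names.index("sex[T.male]")])
        assert ses[1] > ses[0]


class TestHabitatCounts:
    def test_default_probabilities_renormalize_printed_percentages(self):
        p = habitat_probabilities()
        assert p.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(p, HABITAT_PCT / HABITAT_PCT.sum())

    def test_null_rejection_rate_is_nominal(self):
        """Identical use by both sexes: the chi-squared test rejects at
        ~5% across replicates."""
        p = habitat_probabilities()
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            table = np.vstack(
                [rng.multinomial(161, p), rng.multinomial(161, p)]
            )
            if table.min(axis=0).sum() == 0 or (table.sum(axis=0) == 0).any():
                continue
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, _, pval, _ = chisq_homogeneity(table)
            rejections += pval < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_disjoint_supports_are_detected(self):
        pf = np.array([0.5, 0.5, 0, 0, 0, 0, 0, 0, 0.0])
        pm = np.array([0, 0, 0.5, 0.5, 0, 0, 0, 0, 0.0])
        counts = simulate_habitat_counts(pf, pm, seed=3)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            keep = counts.values.sum(axis=0) > 0
            _, _, pval, _ = chisq_homogeneity(counts.values[:, keep])
        assert pval < 0.001

    def test_counts_table_shape_and_margins(self):
        counts = simulate_habitat_counts(n_per_sex=161, seed=42)
        assert counts.shape == (2, 9)
        assert (counts.sum(axis=1) == 161).all()
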