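"""Transforms, model comparison, stepwise selection, post-hoc contrasts and
the habitat-use chi-squared test."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cpforage import (
    ModelSpec,
    aic_weights,
    backward_stepwise,
    chisq_homogeneity,
    fit_mixed,
    holm_adjust,
    posthoc_contrasts,
    transform,
)
from cpforage.stats_layer import aic_table, drop1, inverse_transform, lrt

BODY_MASS_AICS = [2115.84, 2104.63, 2165.91, 2159.92, 2126.28, 2181.33, 2229.88]


class TestTransforms:
    def test_arcsine_sqrt_endpoints_and_quarter(self):
        assert transform(0.0, "arcsine_sqrt") == 0.0
        assert transform(1.0, "arcsine_sqrt") == pytest.approx(np.pi / 2)
        assert transform(0.25, "arcsine_sqrt") == pytest.approx(np.pi / 6)

    @given(st.floats(1e-6, 1.0 - 1e-6))
    @settings(max_examples=100, deadline=None)
    def test_arcsine_roundtrip(self, p):
        assert inverse_transform(transform(p, "arcsine_sqrt"), "arcsine_sqrt") == pytest.approx(
            p, abs=1e-12
        )

    @given(st.floats(1e-6, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_log_roundtrip(self, x):
        assert inverse_transform(transform(x, "log"), "log") == pytest.approx(x, rel=1e-12)

    @pytest.mark.parametrize("bad,kind", [(-0.1, "arcsine_sqrt"), (1.1, "arcsine_sqrt"), (0.0, "log"), (-2.0, "log")])
    def test_domain_violations_error(self, bad, kind):
        with pytest.raises(ValueError):
            transform(bad, kind)


class TestHolm:
    @staticmethod
    def holm_oracle(p):
        """Hand step-down: sort ascending, multiply by (m - rank), running max."""
        p = np.asarray(p, float)
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * p[idx]))
            adj[idx] = running
        return adj

    def test_single_p_unchanged(self):
        assert holm_adjust([0.03])[0] == pytest.approx(0.03)

    def test_worked_example(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04]
        )

    def test_matches_hand_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 12))
            np.testing.assert_allclose(holm_adjust(p), self.holm_oracle(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.random(20)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_pvalues_error(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestAicWeights:
    def test_body_mass_model_table(self):
        """The printed AIC column of the body-mass model set yields Akaike
        weights 0.996 / 0.004 for the two best models."""
        w = aic_weights(BODY_MASS_AICS)
        order = np.argsort(BODY_MASS_AICS)
        assert w[order[0]] == pytest.approx(0.996, abs=5e-4)
        assert w[order[1]] == pytest.approx(0.004, abs=5e-4)
        assert all(w[i] < 1e-3 for i in order[2:])

    def test_single_model_gets_weight_one(self):
        assert aic_weights([123.4])[0] == 1.0

    def test_equal_aics_split_evenly(self):
        np.testing.assert_allclose(aic_weights([10.0, 10.0]), [0.5, 0.5])

    @given(st.lists(st.floats(0, 1e4), min_size=1, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_sum_to_one_and_permutation_equivariance(self, aics):
        w = aic_weights(aics)
        assert w.sum() == pytest.approx(1.0)
        perm = np.random.default_rng(0).permutation(len(aics))
        np.testing.assert_allclose(aic_weights(np.asarray(aics)[perm]), w[perm], atol=1e-12)


class TestChisqHomogeneity:
    def test_identical_rows_give_zero(self):
        chi2, df, p, _ = chisq_homogeneity([[10, 20, 30], [10, 20, 30]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 2

    def test_hand_computed_2x2(self):
        chi2, df, p, exp = chisq_homogeneity([[10, 20], [20, 10]])
        assert chi2 == pytest.approx(20 / 3)
        assert df == 1
        np.testing.assert_allclose(exp, [[15, 15], [15, 15]])

    def test_published_statistic_consistent_with_nine_habitats(self):
        """chi2 = 9.49 with 9 habitat classes (df = 8) corresponds to
        p ~= 0.30, the pair of values the habitat analysis reports."""
        assert sps.chi2.sf(9.49, 8) == pytest.approx(0.30, abs=0.01)

    def test_small_expected_counts_warn(self):
        with pytest.warns(UserWarning, match="expected counts"):
            chisq_homogeneity([[1, 30], [2, 28]])

    def test_degenerate_tables_error(self):
        with pytest.raises(ValueError):
            chisq_homogeneity([[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            chisq_homogeneity([[1, 2, 3]])


def simulate_mixed_table(
    seed=0,
    n_ind=16,
    days_per=8,
    sex_effect=0.0,
    period_effects=(0.0, 0.0, 0.0, 0.0),
    interaction=None,
    noise_sd=1.0,
    ind_sd=0.8,
    response="y",
):
    """Balanced sex x period design with individual random intercepts.
    ``interaction[(sex, period_idx)]`` adds cell-specific shifts."""
    rng = np.random.default_rng(seed)
    periods = ["establishment", "courtship", "incubation", "nestling"]
    rows = []
    b = rng.normal(0, ind_sd, n_ind)
    for i in range(n_ind):
        sex = "female" if i % 2 == 0 else "male"
        for d in range(days_per):
            period = periods[d % 4]
            mu = (
                10.0
                + (sex_effect if sex == "male" else 0.0)
                + period_effects[d % 4]
                + (interaction or {}).get((sex, d % 4), 0.0)
                + b[i]
            )
            rows.append(
                {
                    response: mu + rng.normal(0, noise_sd),
                    "sex": sex,
                    "period": period,
                    "individual_id": f"i{i:02d}",
                    "year": 2011 + (i % 3),
                    "colony": "A" if i < n_ind // 2 else "B",
                }
            )
    return pd.DataFrame(rows)


class TestFitMixedAndStepwise:
    def test_single_level_correction_factor_dropped_with_warning(self):
        tab = simulate_mixed_table(sex_effect=1.0).assign(sampling_frequency="60s")
        spec = ModelSpec(
            "y",
            fixed=["sex", "sampling_frequency"],
            random=["individual_id"],
            correction=["sampling_frequency"],
        )
        with pytest.warns(UserWarning, match="single level"):
            fit = fit_mixed(spec, tab)
        assert fit.converged

    def test_lrt_detects_a_strong_effect(self):
        tab = simulate_mixed_table(seed=3, sex_effect=2.0)
        spec = ModelSpec("y", fixed=["sex"], random=["individual_id"])
        tests = drop1(spec, tab)
        assert tests.loc[tests.term == "sex", "p"].iloc[0] < 0.01

    def test_marginality_protects_main_effects(self):
        inter = {("male", 3): 3.0}
        tab = simulate_mixed_table(seed=5, interaction=inter)
        spec = ModelSpec(
            "y", fixed=["sex", "period", "sex:period"], random=["individual_id"]
        )
        final, trail = backward_stepwise(spec, tab)
        assert set(final.spec.fixed) == {"sex", "period", "sex:period"}

    def test_pure_noise_predictors_all_dropped(self):
        tab = simulate_mixed_table(seed=9, n_ind=32, days_per=12)
        spec = ModelSpec(
            "y", fixed=["sex", "period", "sex:period"], random=["individual_id"]
        )
        final, trail = backward_stepwise(spec, tab)
        assert final.spec.fixed == []
        assert list(trail["term"])[-1] in {"sex", "period"}

    def test_planted_interaction_retained_in_most_replicates(self):
        kept = 0
        for r in range(20):
            tab = simulate_mixed_table(seed=100 + r, interaction={("male", 3): 2.5})
            spec = ModelSpec(
                "y", fixed=["sex", "period", "sex:period"], random=["individual_id"]
            )
            final, _ = backward_stepwise(spec, tab)
            kept += "sex:period" in final.spec.fixed
        assert kept / 20 >= 0.9

    def test_aic_prefers_no_sex_model_when_truth_has_none(self):
        """For a nested 1-df comparison AIC picks the smaller model iff
        2*dlogLik < 2, i.e. with probability ~P(chi2_1 < 2) ~ 0.84 under the
        null (simulation oracle: 27/30 at these seeds)."""
        prefer = 0
        for r in range(30):
            rng = np.random.default_rng(500 + r)
            n_ind, per = 30, 9
            ind = np.repeat(np.arange(n_ind), per)
            sex = np.where(ind % 2 == 0, "female", "male")
            doy = rng.uniform(60, 200, n_ind * per)
            y = (
                130
                + 10 * np.sin((doy - 60) / 140 * np.pi)
                + rng.normal(0, 7, n_ind)[ind]
                + rng.normal(0, 5, len(ind))
            )
            tab = pd.DataFrame(
                {"mass_g": y, "sex": sex, "day_of_year": doy, "individual_id": ind}
            )
            with_sex = ModelSpec(
                "mass_g", fixed=["sex"], smooth="day_of_year", random=["individual_id"]
            )
            without = ModelSpec(
                "mass_g", fixed=[], smooth="day_of_year", random=["individual_id"]
            )
            f1 = fit_mixed(with_sex, tab, method="ML")
            f0 = fit_mixed(without, tab, method="ML")
            prefer += f0.aic < f1.aic
        assert prefer / 30 >= 0.75

    def test_log_transform_drops_nonpositive_with_warning(self):
        tab = simulate_mixed_table(seed=1)
        tab.loc[tab.index[:3], "y"] = -1.0
        spec = ModelSpec("y", fixed=["sex"], transform="log", random=["individual_id"])
        with pytest.warns(UserWarning, match="non-positive"):
            fit = fit_mixed(spec, tab)
        assert fit.n_dropped == 3

    def test_aic_table_is_sorted_with_weights(self):
        tab = simulate_mixed_table(seed=2, sex_effect=1.5)
        f1 = fit_mixed(ModelSpec("y", fixed=["sex"], random=["individual_id"]), tab)
        f0 = fit_mixed(ModelSpec("y", fixed=[], random=["individual_id"]), tab)
        out = aic_table({"sex": f1, "null": f0})
        assert out.iloc[0]["model"] == "sex"
        assert out["weight"].sum() == pytest.approx(1.0)


class TestPosthocContrasts:
    def _fit(self, tab):
        spec = ModelSpec(
            "y", fixed=["sex", "period", "sex:period"], random=["individual_id"]
        )
        return fit_mixed(spec, tab, method="REML"), tab

    def test_male_only_nestling_effect_found_in_the_right_cell(self):
        hits, false_hits = 0, 0
        for r in range(10):
            fit, tab = self._fit(
                simulate_mixed_table(seed=300 + r, interaction={("male", 3): 3.0})
            )
            contrasts, _ = posthoc_contrasts(fit, tab)
            between = contrasts[contrasts.family == "between"].set_index("contrast")
            nest = between.loc["male-female | nestling"]
            others = between.drop("male-female | nestling")
            hits += nest["p_holm"] < 0.05
            false_hits += (others["p_holm"] < 0.05).sum()
        assert hits >= 9
        assert false_hits <= 2

    def test_null_model_rarely_flags_contrasts(self):
        fit, tab = self._fit(simulate_mixed_table(seed=77, n_ind=40, days_per=12))
        contrasts, letters = posthoc_contrasts(fit, tab)
        assert (contrasts["p_holm"] < 0.05).sum() <= 1
        # all periods share a letter within each sex under the null
        for sex in ("female", "male"):
            assert len(set(letters[sex].values())) >= 1
            common = set.intersection(*[set(v) for v in letters[sex].values()])
            assert common

    def test_compact_letters_separate_a_distinct_group(self):
        inter = {("male", 3): 6.0, ("female", 3): 6.0}
        fit, tab = self._fit(
            simulate_mixed_table(seed=55, interaction=inter, noise_sd=0.5)
        )
        _, letters = posthoc_contrasts(fit, tab)
        for sex in ("female", "male"):
            nest = set(letters[sex]["nestling"])
            rest = [set(letters[sex][p]) for p in ("establishment", "courtship", "incubation")]
            assert all(not (nest & r) for r in rest)
            assert set.intersection(*rest)

    def test_lrt_helper_counts_df(self):
        tab = simulate_mixed_table(seed=4, sex_effect=1.0)
        f1 = fit_mixed(ModelSpec("y", fixed=["sex", "period"], random=["individual_id"]), tab)
        f0 = fit_mixed(ModelSpec("y", fixed=["sex"], random=["individual_id"]), tab)
        chi2, df, p = lrt(f1, f0)
        assert df == 3  # period has four levels
        assert chi2 >= 0
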