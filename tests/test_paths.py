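"""Path analysis: ML estimation, fit indices, mediation, moderation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from discountlab.paths import (
    NO_MEDIATION,
    WITH_MEDIATION,
    PathSpec,
    fit_indices,
    fit_path,
    indirect_effect,
    moderation_regression,
    split_half_groups,
)


def simulate_structural(rng, n, state_to_rs=-0.44, trait_to_rs=0.22,
                        rs_to_exp=0.53, state_to_exp=0.0, trait_to_exp=0.36,
                        state_to_hyp=-0.06, trait_to_hyp=-0.27, r_st=0.59):
    state = rng.normal(0, 1, n)
    trait = r_st * state + np.sqrt(1 - r_st ** 2) * rng.normal(0, 1, n)
    rs = state_to_rs * state + trait_to_rs * trait + rng.normal(0, 0.85, n)
    e_exp = rng.normal(0, 0.7, n)
    e_hyp = 0.3 * e_exp + rng.normal(0, 0.9, n)  # correlated outcome residuals
    auc_e = rs_to_exp * rs + state_to_exp * state + trait_to_exp * trait + e_exp
    auc_h = state_to_hyp * state + trait_to_hyp * trait + e_hyp
    return pd.DataFrame({"state_anxiety": state, "trait_anxiety": trait,
                         "reward_sensitivity": rs, "auc_experiential": auc_e,
                         "auc_hypothetical": auc_h})


class TestFitPath:
    def test_known_paths_recovered_at_large_n(self):
        rng = np.random.default_rng(0)
        df = simulate_structural(rng, 5000)
        fit = fit_path(df, WITH_MEDIATION)
        truth = {
            ("reward_sensitivity", "state_anxiety"): -0.44,
            ("reward_sensitivity", "trait_anxiety"): 0.22,
            ("auc_experiential", "reward_sensitivity"): 0.53,
            ("auc_experiential", "state_anxiety"): 0.0,
            ("auc_experiential", "trait_anxiety"): 0.36,
            ("auc_hypothetical", "state_anxiety"): -0.06,
            ("auc_hypothetical", "trait_anxiety"): -0.27,
        }
        for key, val in truth.items():
            assert fit.estimates[key] == pytest.approx(val, abs=0.05)

    def test_standardized_signs_match_published_pattern(self):
        rng = np.random.default_rng(1)
        fit = fit_path(simulate_structural(rng, 5000), WITH_MEDIATION)
        assert fit.std_estimates[("reward_sensitivity", "state_anxiety")] < -0.3
        assert fit.std_estimates[("auc_experiential", "reward_sensitivity")] > 0.3
        assert abs(fit.std_estimates[("auc_experiential", "state_anxiety")]) < 0.05

    def test_independent_data_gives_null_paths(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(0, 1, (2000, 5)), columns=[
            "state_anxiety", "trait_anxiety", "reward_sensitivity",
            "auc_experiential", "auc_hypothetical"])
        fit = fit_path(df, NO_MEDIATION)
        for key, est in fit.estimates.items():
            assert abs(est) < 2.5 * fit.se[key] + 1e-9

    def test_ml_equals_equationwise_least_squares(self):
        rng = np.random.default_rng(3)
        df = simulate_structural(rng, 300)
        fit = fit_path(df, NO_MEDIATION)
        for outcome in ("auc_experiential", "auc_hypothetical"):
            X = sm.add_constant(df[["state_anxiety", "trait_anxiety"]].to_numpy())
            ols = sm.OLS(df[outcome].to_numpy(), X).fit()
            assert fit.estimates[(outcome, "state_anxiety")] == pytest.approx(
                ols.params[1], abs=1e-6)
            assert fit.estimates[(outcome, "trait_anxiety")] == pytest.approx(
                ols.params[2], abs=1e-6)

    def test_saturated_model_reproduces_sample_covariance(self):
        rng = np.random.default_rng(4)
        fit = fit_path(simulate_structural(rng, 200), NO_MEDIATION)
        frob = np.linalg.norm(fit.implied_cov.to_numpy()
                              - fit.sample_cov.to_numpy())
        assert frob < 1e-8

    def test_standardized_recovery_unbiased_over_replications(self):
        rng = np.random.default_rng(5)
        ests = []
        for _ in range(100):
            fit = fit_path(simulate_structural(rng, 200), NO_MEDIATION)
            ests.append(fit.estimates[("auc_hypothetical", "trait_anxiety")])
        assert np.mean(ests) == pytest.approx(-0.27, abs=0.02)

    def test_too_few_cases_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            fit_path(simulate_structural(rng, 8), WITH_MEDIATION)


class TestFitIndices:
    def test_saturated_model_forces_cfi_one_rmsea_zero(self):
        rng = np.random.default_rng(7)
        fit = fit_path(simulate_structural(rng, 150), NO_MEDIATION)
        cfi, rmsea, srmr = fit_indices(fit)
        assert cfi == 1.0 and rmsea == 0.0 and srmr < 0.05

    def test_correctly_specified_restricted_model_fits_well(self):
        rng = np.random.default_rng(8)
        fit = fit_path(simulate_structural(rng, 5000), WITH_MEDIATION)
        cfi, rmsea, srmr = fit_indices(fit)
        assert fit.df == 1
        assert cfi > 0.99 and srmr < 0.02

    def test_gross_misspecification_raises_rmsea(self):
        rng = np.random.default_rng(9)
        df = simulate_structural(rng, 2000, rs_to_exp=1.2, state_to_rs=-0.9)
        # model that forbids the dominant mediator path
        spec = PathSpec(
            exogenous=("state_anxiety", "trait_anxiety"),
            equations={"reward_sensitivity": ("trait_anxiety",),
                       "auc_experiential": ("trait_anxiety",),
                       "auc_hypothetical": ("trait_anxiety",)},
        )
        fit = fit_path(df, spec)
        _, rmsea, _ = fit_indices(fit)
        assert rmsea > 0.10


class TestIndirectEffect:
    def test_product_rule(self):
        rng = np.random.default_rng(10)
        fit = fit_path(simulate_structural(rng, 5000), WITH_MEDIATION)
        est, se, p = indirect_effect(fit, "state_anxiety", "reward_sensitivity",
                                     "auc_experiential")
        a = fit.estimates[("reward_sensitivity", "state_anxiety")]
        b = fit.estimates[("auc_experiential", "reward_sensitivity")]
        assert est == pytest.approx(a * b)
        assert est == pytest.approx(-0.44 * 0.53, abs=0.03)
        assert se > 0 and p < 0.001

    def test_complete_mediation_pattern(self):
        """Zero direct effect in truth: the fitted direct path is null while
        the indirect path is clearly nonzero."""
        rng = np.random.default_rng(11)
        fit = fit_path(simulate_structural(rng, 5000, state_to_exp=0.0),
                       WITH_MEDIATION)
        direct = fit.estimates[("auc_experiential", "state_anxiety")]
        assert abs(direct) < 2 * fit.se[("auc_experiential", "state_anxiety")]
        est, se, _ = indirect_effect(fit, "state_anxiety", "reward_sensitivity",
                                     "auc_experiential")
        assert abs(est) > 4 * se

    def test_missing_mediator_rejected(self):
        rng = np.random.default_rng(12)
        fit = fit_path(simulate_structural(rng, 200), NO_MEDIATION)
        with pytest.raises(ValueError):
            indirect_effect(fit, "state_anxiety", "reward_sensitivity",
                            "auc_experiential")


class TestModeration:
    def test_interaction_coefficient_recovered_on_raw_scales(self):
        rng = np.random.default_rng(13)
        n = 5000
        state = rng.normal(34.3, 10.1, n)
        trait = rng.normal(43.0, 10.8, n)
        auc = 0.4 + 0.0005 * state * trait - 0.01 * state + rng.normal(0, 0.15, n)
        table = moderation_regression(auc, state, trait)
        row = table.set_index("term").loc["state_x_trait"]
        assert abs(row["coef"] - 0.0005) < 2 * row["se"]
        assert row["p"] < 0.001

    def test_null_interaction_not_detected(self):
        rng = np.random.default_rng(14)
        n = 500
        state = rng.normal(34.3, 10.1, n)
        trait = rng.normal(43.0, 10.8, n)
        auc = 0.5 - 0.002 * state + rng.normal(0, 0.1, n)
        row = moderation_regression(auc, state, trait).set_index("term").loc[
            "state_x_trait"]
        assert abs(row["coef"]) < 2.5 * row["se"]

    def test_collinear_regressors_rejected(self):
        x = np.arange(20.0)
        with pytest.raises(ValueError):
            moderation_regression(x, x, x * 0 + 1.0)


class TestSplitHalf:
    def test_sign_pattern_under_moderated_structure(self):
        rng = np.random.default_rng(15)
        n = 400
        state = rng.normal(0, 1, n)
        trait = rng.normal(0, 1, n)
        auc = np.where(trait < 0, -0.5 * state, 0.0) + rng.normal(0, 0.6, n)
        res = split_half_groups(trait, auc, state).set_index("group")
        assert res.loc["low_trait", "r"] < -0.2
        assert abs(res.loc["high_trait", "r"]) < 0.15

    def test_null_structure_gives_null_correlations(self):
        rng = np.random.default_rng(16)
        res = split_half_groups(rng.normal(0, 1, 300), rng.normal(0, 1, 300),
                                rng.normal(0, 1, 300))
        assert (res["r"].abs() < 0.2).all()

    def test_deterministic_construction(self):
        rng = np.random.default_rng(17)
        n = 100
        trait = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
        state = rng.normal(0, 1, n)
        auc = np.where(trait == 0, -state, rng.normal(0, 1, n))
        res = split_half_groups(trait, auc, state).set_index("group")
        assert res.loc["low_trait", "r"] == pytest.approx(-1.0)
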