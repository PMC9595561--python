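"""Choice-regression family, stepwise selection, CV and BMS."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import dirichlet

import distractnorm as dn
from distractnorm.choice_models import (CONSISTENCY_REPORT_DIVISOR,
                                        STEPWISE_CANDIDATES, build_design)


def simulate_from_design(trials, beta, formula="consistency_bias", seed=0):
    """Bernoulli choices from a linear-logit generator on a named design."""
    X = build_design(trials, formula)
    eta = X.to_numpy() @ np.asarray(beta, dtype=float)
    rng = np.random.default_rng(seed)
    out = trials.copy()
    out["choice"] = (rng.random(len(trials)) < expit(eta)).astype(int)
    return out


class TestDesign:
    def test_consistency_and_congruency_columns(self):
        trials = pd.DataFrame({"theta_T": [5.0, 3.0, 3.0, 4.0],
                               "theta_D": [-5.0, -2.0, 2.0, 4.0]})
        X = build_design(trials, "consistency_bias")
        np.testing.assert_allclose(X["consistency"],
                                   [50.0, 15.0, 3.0, 0.0])
        Xc = build_design(trials, ["congruency"])
        np.testing.assert_array_equal(Xc["congruency"], [0, 0, 1, 1])

    def test_reporting_divisor_applies_to_consistency_only(self):
        trials = dn.generate_trials("exp1", 3000, rng=61)
        sim = simulate_from_design(trials, [0, 0.3, -0.05, -0.02], seed=62)
        fit = dn.fit_choice_glm(sim)
        rep = fit.reported_params()
        assert rep["consistency"] == pytest.approx(
            fit.params["consistency"] * CONSISTENCY_REPORT_DIVISOR)
        assert rep["theta_T"] == fit.params["theta_T"]

    def test_attention_formula_requires_cue_info(self):
        trials = dn.generate_trials("exp1", 100, rng=63).drop(columns=["A"])
        trials["cue_condition"] = "none"
        with pytest.raises(ValueError, match="valid/neutral/invalid"):
            build_design(trials, "attention")


class TestGlmFit:
    def test_generator_coefficients_recovered_within_2se(self):
        true = [0.0, 0.5, -0.05, -0.02]
        trials = dn.generate_trials("exp1", 20_000, rng=64)
        sim = simulate_from_design(trials, true, seed=65)
        fit = dn.fit_choice_glm(sim)
        for est, se, tr in zip(fit.params, fit.bse, true):
            assert abs(est - tr) < 2 * se

    def test_coinflip_choices_give_null_coefficients(self):
        trials = dn.generate_trials("exp1", 8000, rng=66)
        rng = np.random.default_rng(67)
        fit = dn.fit_choice_glm(trials, choices=rng.integers(0, 2, 8000))
        # 3-sigma joint bound: ~1% familywise false-alarm over 4 terms
        assert (np.abs(fit.params) < 3.0 * fit.bse).all()
        assert fit.loglik <= 0

    def test_nested_model_loglik_monotone(self):
        trials = dn.generate_trials("exp1", 5000, rng=68)
        sim = simulate_from_design(trials, [0, 0.4, -0.03, -0.015], seed=69)
        full = dn.fit_choice_glm(sim, formula_id="consistency_bias").loglik
        for sub in ("independent", "interaction", "target_only"):
            assert full >= dn.fit_choice_glm(sim, formula_id=sub).loglik

    def test_probit_link_supported(self):
        trials = dn.generate_trials("exp1", 2000, rng=70)
        sim = simulate_from_design(trials, [0, 0.4, 0, 0], seed=71)
        fit = dn.fit_choice_glm(sim, formula_id="target_only", link="probit")
        assert fit.link == "probit"
        assert fit.params["theta_T"] > 0

    def test_collinear_design_rejected(self):
        trials = dn.generate_trials("exp1", 200, rng=72)
        trials["theta_D"] = trials["theta_T"]  # duplicate column content
        sim = simulate_from_design(trials, [0, 0.4, 0, 0], seed=73)
        with pytest.raises(ValueError, match="collinear"):
            dn.fit_choice_glm(sim, formula_id=["theta_T", "theta_D"])


class TestStepwise:
    def test_recovers_generating_predictor_set(self):
        """Data generated from the consistency-bias regression yields
        exactly its three predictors at n = 50,000."""
        trials = dn.generate_trials("exp1", 50_000, rng=74)
        sim = simulate_from_design(trials, [0, 0.5, -0.05, -0.02], seed=75)
        assert dn.stepwise_select(sim) == ["theta_T", "theta_D", "consistency"]

    def test_independent_generator_drops_consistency(self):
        trials = dn.generate_trials("exp1", 50_000, rng=76)
        sim = simulate_from_design(trials, [0, 0.5, -0.05],
                                   formula="independent", seed=77)
        sel = dn.stepwise_select(sim)
        assert "consistency" not in sel
        assert "theta_T" in sel and "theta_D" in sel

    def test_pure_noise_stays_near_intercept_only(self):
        """Coin-flip choices retain (almost) nothing: with seven candidates
        screened at the 5% entry level, a single chance inclusion is within
        the algorithm's nominal false-entry rate, two or more are not."""
        trials = dn.generate_trials("exp1", 5000, rng=78)
        rng = np.random.default_rng(79)
        sel = dn.stepwise_select(trials, choices=rng.integers(0, 2, 5000))
        assert len(sel) <= 1

    def test_candidate_list_matches_published_candidates(self):
        assert set(STEPWISE_CANDIDATES) == {
            "theta_T", "theta_D", "abs_theta_D", "congruency",
            "theta_T_x_theta_D", "theta_T_x_abs_theta_D", "consistency"}


class TestBinnedSensitivity:
    def test_six_equal_bins(self):
        trials = dn.generate_trials("exp1", 6000, rng=80)
        sim = simulate_from_design(trials, [0, 0.3, 0, 0], seed=81)
        table = dn.binned_sensitivity(sim)
        assert len(table) == 6
        np.testing.assert_allclose(table["hi"] - table["lo"], 20 / 6)

    def test_extreme_distracters_reduce_target_slope(self):
        """Under contextual normalization, target sensitivity is weakest in
        the outermost distracter bins, and the model-predicted slopes
        reproduce the pattern."""
        trials = dn.generate_trials("exp1", 60_000, rng=82)
        sim = dn.simulate_parametric_observer(
            trials, dn.ObserverParams(r=2.0, tau=0.3), rng=83)
        glm = dn.ChoiceGLM(formula="consistency_bias").fit(sim, sim["choice"])
        table = dn.binned_sensitivity(sim, glm)
        outer = table["slope_obs"].iloc[[0, 5]].mean()
        inner = table["slope_obs"].iloc[[2, 3]].mean()
        assert inner > outer
        assert table["slope_model"].iloc[[2, 3]].mean() > \
            table["slope_model"].iloc[[0, 5]].mean()

    def test_flat_profile_without_normalization(self):
        """Without contextual normalization the per-bin slopes are
        homogeneous: a chi-square test against a common slope does not
        reject."""
        from scipy.stats import chi2
        trials = dn.generate_trials("exp1", 30_000, rng=84)
        sim = dn.simulate_parametric_observer(
            trials, dn.ObserverParams(r=3.0), rng=85)
        table = dn.binned_sensitivity(sim)
        w = 1.0 / table["se_obs"] ** 2
        pooled = np.sum(w * table["slope_obs"]) / np.sum(w)
        q = np.sum(w * (table["slope_obs"] - pooled) ** 2)
        assert chi2.sf(q, df=len(table) - 1) > 0.001


class TestCrossValidation:
    def test_deterministic_under_seed(self):
        trials = dn.generate_trials("exp1", 2000, rng=86)
        sim = simulate_from_design(trials, [0, 0.4, 0, -0.01], seed=87)
        a = dn.crossval_loglik(sim, "consistency_bias", k_folds=5, seed=3)
        b = dn.crossval_loglik(sim, "consistency_bias", k_folds=5, seed=3)
        assert a == b
        assert a <= 0

    def test_generating_model_wins_across_subjects(self):
        """The generating formula attains the higher mean held-out
        log-likelihood over 20 simulated subjects."""
        wins = 0
        for s in range(20):
            trials = dn.generate_trials("exp1", 900, rng=880 + s)
            sim = simulate_from_design(trials, [0, 0.5, -0.05, -0.02],
                                       seed=900 + s)
            full = dn.crossval_loglik(sim, "consistency_bias", k_folds=5, seed=s)
            indep = dn.crossval_loglik(sim, "independent", k_folds=5, seed=s)
            wins += full > indep
        assert wins >= 14

    def test_bad_k_rejected(self):
        trials = dn.generate_trials("exp1", 100, rng=88)
        with pytest.raises(ValueError):
            dn.crossval_loglik(trials, "consistency_bias", choices=np.zeros(100), k_folds=1)


class TestBms:
    def test_symmetric_evidences_give_uniform_exceedance(self):
        res = dn.bms_exceedance(np.zeros((12, 4)), seed=1)
        np.testing.assert_allclose(res.exceedance, 0.25, atol=0.01)
        assert res.exceedance.sum() == pytest.approx(1.0)
        assert res.expected_freq.sum() == pytest.approx(1.0)

    def test_dominant_model_matches_dirichlet_oracle(self):
        """A 10-nat advantage for all 20 subjects drives exceedance above
        0.99, agreeing with a direct Dirichlet Monte-Carlo computation on
        the converged concentration parameters."""
        lme = np.zeros((20, 2))
        lme[:, 0] = 10.0
        res = dn.bms_exceedance(lme, seed=2)
        assert res.exceedance[0] > 0.99
        rng = np.random.default_rng(99)
        draws = dirichlet.rvs(res.alpha, size=200_000, random_state=rng)
        oracle = np.mean(np.argmax(draws, axis=1) == 0)
        assert res.exceedance[0] == pytest.approx(oracle, abs=0.01)
        # posterior counts concentrate on the winner
        assert res.alpha[0] == pytest.approx(21.0, abs=0.01)

    def test_shift_invariance(self):
        rng = np.random.default_rng(89)
        lme = rng.normal(size=(15, 3))
        a = dn.bms_exceedance(lme, seed=4)
        b = dn.bms_exceedance(lme + 123.4, seed=4)
        np.testing.assert_allclose(a.exceedance, b.exceedance, atol=1e-12)

    def test_non_finite_evidence_rejected(self):
        with pytest.raises(ValueError):
            dn.bms_exceedance(np.array([[0.0, np.inf]]))
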