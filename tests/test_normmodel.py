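"""Normalization transducer: mechanics, fitting, model comparison."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import distractnorm as dn
from distractnorm import normmodel


def cohort(n_subjects, n_trials, params, base_seed):
    subs = []
    for s in range(n_subjects):
        tr = dn.generate_trials("exp1", n_trials, rng=base_seed + s)
        subs.append(dn.simulate_parametric_observer(
            tr, params, rng=base_seed + 10_000 + s))
    return subs


class TestTransducer:
    def test_reduces_to_plain_logistic(self):
        state = dn.transduce([4.0], [-7.0], {"r": 2.0, "tau": 0.0, "rho": 0.0})
        assert state.y[0] == pytest.approx(2.0)
        # identical distracter: sigma = 0, slope stays at baseline
        state = dn.transduce([4.0], [4.0], {"r": 2.0, "tau": 0.5, "rho": 0.0})
        assert state.y[0] == pytest.approx(2.0)

    def test_positive_rho_repels_from_distracter(self):
        base = dn.transduce([2.0], [8.0], {"r": 3.0, "tau": 0.0, "rho": 0.0})
        rep = dn.transduce([2.0], [8.0], {"r": 3.0, "tau": 0.0, "rho": 0.4})
        assert rep.p_cw[0] < base.p_cw[0]

    def test_slope_decreases_with_context_variability(self):
        """d y / d theta_T at fixed theta_T falls monotonically as the
        target-distracter disparity grows (tau > 0)."""
        params = {"r": 2.0, "tau": 0.3, "rho": 0.0}
        slopes = []
        for tD in [3.0, 0.0, -4.0, -9.0]:  # increasing sigma at theta_T=3
            eps = 1e-5
            lo = dn.transduce([3.0 - eps], [tD], params).y[0]
            hi = dn.transduce([3.0 + eps], [tD], params).y[0]
            slopes.append((hi - lo) / (2 * eps))
        assert all(a > b for a, b in zip(slopes, slopes[1:]))

    def test_invalid_denominator_raises(self):
        with pytest.raises(ValueError, match="non-positive"):
            dn.transduce([5.0], [-9.0], {"r": 1.0, "tau": -0.2, "rho": 0.0})


class TestNll:
    def test_closed_form_at_chance(self):
        trials = pd.DataFrame({"theta_T": np.zeros(64),
                               "theta_D": np.zeros(64),
                               "choice": np.tile([0, 1], 32)})
        val = dn.nll({"r": 1.0, "tau": 0.0, "rho": 0.0}, trials)
        assert val == pytest.approx(64 * np.log(2))

    def test_clipping_keeps_value_finite(self):
        trials = pd.DataFrame({"theta_T": [10.0], "theta_D": [10.0],
                               "choice": [0]})
        assert np.isfinite(dn.nll({"r": 0.01, "tau": 0.0, "rho": 0.0}, trials))

    def test_invalid_params_return_inf(self):
        trials = pd.DataFrame({"theta_T": [5.0], "theta_D": [-9.0],
                               "choice": [1]})
        assert dn.nll({"r": 1.0, "tau": -0.2, "rho": 0.0}, trials) == np.inf

    def test_truth_beats_perturbations_on_average(self):
        """On large simulated data, the generating parameters have lower
        negative log-likelihood than random perturbations of them."""
        true = {"r": 1.2, "tau": 0.2, "rho": 0.5}
        tr = dn.generate_trials("exp1", 50_000, rng=91)
        sim = dn.simulate_parametric_observer(
            tr, dn.ObserverParams(**true), rng=92)
        base = dn.nll(true, sim)
        rng = np.random.default_rng(93)
        worse = 0
        for _ in range(20):
            pert = {"r": true["r"] * np.exp(rng.normal(0, 0.2)),
                    "tau": true["tau"] + rng.normal(0, 0.05),
                    "rho": true["rho"] + rng.normal(0, 0.1)}
            worse += dn.nll(pert, sim) > base
        assert worse >= 17


class TestFit:
    def test_reduced_variant_matches_logistic_glm(self):
        """The tau = rho = 0 model is numerically a logistic regression on
        theta_T with slope 1/r (no intercept)."""
        tr = dn.generate_trials("exp1", 4000, rng=94)
        sim = dn.simulate_parametric_observer(
            tr, dn.ObserverParams(r=3.0), rng=95)
        f = normmodel.fit(sim, variant="reduced", n_restarts=4, seed=0)
        glm = sm.GLM(sim["choice"].to_numpy(),
                     sim[["theta_T"]].to_numpy(),
                     family=sm.families.Binomial()).fit()
        assert 1.0 / f.params["r"] == pytest.approx(glm.params[0], abs=1e-4)
        assert f.nll == pytest.approx(-glm.llf, abs=1e-3)

    def test_null_data_recovers_null_context_terms(self):
        tr = dn.generate_trials("exp1", 8000, rng=96)
        sim = dn.simulate_parametric_observer(
            tr, dn.ObserverParams(r=3.0), rng=97)
        f = normmodel.fit(sim, n_restarts=5, seed=1)
        assert abs(f.params["tau"]) < 0.06
        assert abs(f.params["rho"]) < 0.12
        assert f.nll <= min(f.restart_nlls) + 1e-9

    def test_recovery_median_error_under_20pct(self):
        """Median absolute parameter-recovery error across a simulated
        cohort stays below 20% per parameter."""
        true = {"r": 1.2, "tau": 0.2, "rho": 0.5}
        errs = {k: [] for k in true}
        for s, sim in enumerate(cohort(24, 900, dn.ObserverParams(**true),
                                       base_seed=1000)):
            f = normmodel.fit(sim, n_restarts=5, seed=s)
            for k in true:
                errs[k].append(abs(f.params[k] - true[k]) / true[k])
        for k in true:
            assert np.median(errs[k]) < 0.20, k

    def test_attention_variant_recovers_r_ordering(self):
        """With condition-specific baselines r_valid < r_neutral <
        r_invalid, the fitted ordering is preserved for >= 80% of
        subjects."""
        r_map = {"valid": 1.5, "neutral": 3.0, "invalid": 6.0}
        gen = dn.ObserverParams(r=r_map, tau=0.15, rho=0.1)
        ok = 0
        for s in range(10):
            cued = dn.generate_trials("exp3_cued", 700, rng=1500 + s)
            neut = dn.generate_trials("exp3_neutral", 200, rng=1700 + s)
            tr = pd.concat([cued, neut], ignore_index=True)
            sim = dn.simulate_parametric_observer(tr, gen, rng=1900 + s)
            f = normmodel.fit(sim, variant="attention", n_restarts=5, seed=s)
            r = f.params["r"]
            ok += r["valid"] < r["neutral"] < r["invalid"]
        assert ok >= 8

    def test_attention_variant_requires_all_conditions(self):
        tr = dn.generate_trials("exp3_cued", 200, rng=98)
        tr["choice"] = 0
        with pytest.raises(ValueError, match="missing"):
            normmodel.fit(tr, variant="attention", n_restarts=2, seed=0)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            normmodel.fit(pd.DataFrame({"theta_T": [1.0], "theta_D": [0.0],
                                        "choice": [1]}))


class TestPatternSimulation:
    def test_null_parameters_give_null_distracter_terms(self):
        tr = dn.generate_trials("exp1", 40_000, rng=99)
        fit = normmodel.simulate_pattern({"r": 3.0, "tau": 0.0, "rho": 0.0},
                                         tr, rng=100)
        assert abs(fit.params["theta_D"]) < 2 * fit.bse["theta_D"]
        assert abs(fit.params["consistency"]) < 2 * fit.bse["consistency"]
        assert fit.params["theta_T"] > 0

    def test_sweep_returns_tidy_grid(self):
        tr = dn.generate_trials("exp1", 4000, rng=101)
        table = normmodel.sweep_pattern(tr, r=3.0, tau_grid=[0.0, 0.3],
                                        rho_grid=[0.0, 0.4], rng=102)
        assert len(table) == 4
        assert {"tau", "rho", "theta_T", "theta_D",
                "consistency"} <= set(table.columns)


class TestModelComparison:
    def test_single_subject_exceedance_well_defined(self):
        tr = dn.generate_trials("exp1", 400, rng=103)
        sim = dn.simulate_parametric_observer(
            tr, dn.ObserverParams(r=1.2, tau=0.2, rho=0.5), rng=104)
        res = normmodel.compare_models([sim], k_folds=4, seed=0, n_restarts=2)
        assert res.exceedance.sum() == pytest.approx(1.0)

    def test_exclusion_rule_drops_one_sided_subjects(self):
        good = dn.simulate_parametric_observer(
            dn.generate_trials("exp1", 600, rng=105),
            dn.ObserverParams(r=2.0), rng=106)
        lazy = good.copy()
        guess = lazy["probe_side"] == "left"
        rng = np.random.default_rng(107)
        lazy.loc[guess, "choice"] = rng.integers(0, 2, int(guess.sum()))
        lazy["correct"] = (lazy["choice"]
                           == (lazy["theta_T"] > 0)).astype(int)
        keep = normmodel.exclude_chance_subjects([good, lazy])
        assert keep == [0]
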