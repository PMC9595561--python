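"""Contextual-normalization transducer model of distracter influence.

The model maps the target tilt onto a decision variable through

    y = (theta_T - rho * mu) / (r + tau * sigma),

where ``mu = (theta_T + theta_D) / 2`` is the contextual expectation and
``sigma = |theta_T - theta_D|`` the contextual variability, and choices are
Bernoulli(sigmoid(y)).  ``rho`` shifts the transducer along the input axis
(positive rho = repulsion from the distracter), ``tau`` flattens its slope
as target and distracter grow apart (the consistency bias), and ``r`` sets
the baseline slope.  The attention variant frees ``r`` per cueing condition
(valid / neutral / invalid) while sharing ``tau`` and ``rho``: spatial
attention changes overall target sensitivity, not the strength of
contextual normalization.

Fitting is maximum likelihood at the single-trial level via quasi-Newton
minimization from multiple seeded restarts, on transformed parameters that
keep ``r`` positive and the denominator bounded away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator

from .observers import ObserverParams, simulate_parametric_observer
from .choice_models import (ChoiceGLM, GlmFit, BmsResult, bms_exceedance,
                            crossval_loglik)
from .stimgen import THETA_RANGE_DEG

__all__ = [
    "TransducerState",
    "NormModelFit",
    "NormalizationModel",
    "transduce",
    "nll",
    "fit",
    "simulate_pattern",
    "sweep_pattern",
    "compare_models",
    "exclude_chance_subjects",
]

#: hard floor on the transducer denominator r + tau * sigma
DENOM_FLOOR = 1e-3

#: probability clipping bound for the Bernoulli log-likelihood
P_CLIP = 1e-9

CUE_LEVELS = ("valid", "neutral", "invalid")


@dataclass
class TransducerState:
    """Intermediate quantities of the transducer on a set of trials."""

    x: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    y: np.ndarray
    p_cw: np.ndarray


def transduce(theta_T, theta_D, params: dict | ObserverParams,
              cue_condition=None) -> TransducerState:
    """Apply the normalization transducer to trial tilts.

    ``params`` supplies ``r`` (scalar, or mapping cue condition -> r for the
    attention variant), ``tau`` and ``rho``.
    """
    if isinstance(params, ObserverParams):
        r, tau, rho = params.r, params.tau, params.rho
    else:
        r, tau, rho = params["r"], params["tau"], params["rho"]
    x = np.asarray(theta_T, dtype=float)
    theta_D = np.asarray(theta_D, dtype=float)
    mu = 0.5 * (x + theta_D)
    sigma = np.abs(x - theta_D)
    if isinstance(r, dict):
        if cue_condition is None:
            raise ValueError("condition-specific r requires cue_condition")
        r = np.asarray([r[c] for c in cue_condition], dtype=float)
    denom = r + tau * sigma
    if np.any(denom <= 0):
        raise ValueError("transducer denominator r + tau*sigma is non-positive")
    y = (x - rho * mu) / denom
    p = expit(y)
    return TransducerState(x=x, mu=mu, sigma=sigma, y=y, p_cw=p)


def nll(params: dict | ObserverParams, trials: pd.DataFrame,
        choices=None) -> float:
    """Negative Bernoulli log-likelihood of choices under the transducer.

    Probabilities are clipped to [1e-9, 1 - 1e-9] so the value stays finite
    for extreme decision variables; invalid parameters return +inf, which is
    safe inside optimizers.
    """
    y = np.asarray(trials["choice"] if choices is None else choices,
                   dtype=float)
    cue = trials["cue_condition"] if "cue_condition" in trials.columns else None
    try:
        state = transduce(trials["theta_T"].to_numpy(),
                          trials["theta_D"].to_numpy(), params,
                          cue_condition=cue)
    except ValueError:
        return float("inf")
    p = np.clip(state.p_cw, P_CLIP, 1.0 - P_CLIP)
    return float(-np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


@dataclass
class NormModelFit:
    """Best-of-restarts maximum-likelihood fit of the transducer."""

    params: dict
    nll: float
    variant: str
    n_restarts: int
    converged: bool
    seed: int
    restart_nlls: np.ndarray = field(default_factory=lambda: np.empty(0))
    cv_loglik: float | None = None


class NormalizationModel(BaseEstimator):
    """scikit-learn-style estimator for the normalization transducer.

    Variants
    --------
    ``base``
        3 free parameters (r, tau, rho).
    ``attention``
        5 free parameters (r per cue condition, shared tau, rho); requires a
        ``cue_condition`` column with valid/neutral/invalid levels.
    ``reduced``
        1 free parameter (r) with tau = rho = 0 — a plain logistic
        psychometric function of theta_T with slope 1/r.

    ``fit(trials, choices)`` minimizes the negative log-likelihood with
    L-BFGS-B from ``n_restarts`` seeded starting points on transformed
    parameters: ``r = exp(lr)`` enforces positivity and
    ``tau = (floor - r_min) / sigma_max + exp(u)`` keeps the denominator
    above its floor over the attainable sigma range.  Fitted attributes:
    ``r_`` (scalar or dict), ``tau_``, ``rho_``, ``nll_``, ``converged_``.
    """

    def __init__(self, variant: str = "base", n_restarts: int = 10,
                 random_state: int = 0):
        self.variant = variant
        self.n_restarts = n_restarts
        self.random_state = random_state

    # ---- parameter transform -------------------------------------------
    def _n_r(self) -> int:
        return 3 if self.variant == "attention" else 1

    def _unpack(self, z: np.ndarray, sigma_max: float) -> dict:
        n_r = self._n_r()
        r_vals = np.exp(np.clip(z[:n_r], -20.0, 20.0))
        if self.variant == "reduced":
            tau, rho = 0.0, 0.0
        else:
            u, rho = z[n_r], z[n_r + 1]
            tau_lo = (DENOM_FLOOR - float(r_vals.min())) / max(sigma_max, 1e-9)
            tau = tau_lo + float(np.exp(np.clip(u, -20.0, 20.0)))
        if self.variant == "attention":
            r = dict(zip(CUE_LEVELS, (float(v) for v in r_vals)))
        else:
            r = float(r_vals[0])
        return {"r": r, "tau": float(tau), "rho": float(rho)}

    def _start_points(self, rng: np.random.Generator) -> np.ndarray:
        n_r = self._n_r()
        starts = []
        for _ in range(self.n_restarts):
            lr = rng.normal(np.log(3.0), 0.7, size=n_r)
            if self.variant == "reduced":
                starts.append(lr)
            else:
                u = rng.normal(np.log(0.15), 1.0)
                rho = rng.normal(0.0, 0.3)
                starts.append(np.concatenate([lr, [u, rho]]))
        return np.asarray(starts)

    # ---- estimator API --------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "NormalizationModel":
        trials = X
        choices = np.asarray(trials["choice"] if y is None else y, dtype=float)
        if len(choices) < 2:
            raise ValueError("need at least 2 trials")
        if self.variant == "attention":
            missing = set(CUE_LEVELS) - set(trials["cue_condition"])
            if missing:
                raise ValueError(
                    f"attention variant requires all cue conditions; "
                    f"missing {sorted(missing)}")
        sigma = np.abs(trials["theta_T"].to_numpy()
                       - trials["theta_D"].to_numpy())
        sigma_max = float(max(sigma.max(), 2 * THETA_RANGE_DEG))

        def objective(z):
            return nll(self._unpack(z, sigma_max), trials, choices)

        rng = np.random.default_rng(self.random_state)
        best = None
        restart_nlls = []
        any_converged = False
        for z0 in self._start_points(rng):
            res = minimize(objective, z0, method="L-BFGS-B",
                           options={"maxiter": 500})
            restart_nlls.append(float(res.fun))
            any_converged = any_converged or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        if not any_converged and not np.isfinite(best.fun):
            raise RuntimeError(
                f"normalization-model fit failed to converge from "
                f"{self.n_restarts} restarts (best nll {best.fun})")
        params = self._unpack(best.x, sigma_max)
        self.r_ = params["r"]
        self.tau_ = params["tau"]
        self.rho_ = params["rho"]
        self.params_ = params
        self.nll_ = float(best.fun)
        self.converged_ = any_converged
        self.restart_nlls_ = np.asarray(restart_nlls)
        self.sigma_max_ = sigma_max
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        cue = X["cue_condition"] if isinstance(self.r_, dict) else None
        state = transduce(X["theta_T"].to_numpy(), X["theta_D"].to_numpy(),
                          self.params_, cue_condition=cue)
        p = np.clip(state.p_cw, P_CLIP, 1.0 - P_CLIP)
        return np.column_stack([1.0 - p, p])

    def to_fit(self) -> NormModelFit:
        return NormModelFit(params=self.params_, nll=self.nll_,
                            variant=self.variant, n_restarts=self.n_restarts,
                            converged=self.converged_, seed=self.random_state,
                            restart_nlls=self.restart_nlls_)


def fit(trials: pd.DataFrame, choices=None, variant: str = "base",
        n_restarts: int = 10, seed: int = 0) -> NormModelFit:
    """Fit the transducer on one subject's trials (estimator wrapper)."""
    est = NormalizationModel(variant=variant, n_restarts=n_restarts,
                             random_state=seed)
    return est.fit(trials, choices).to_fit()


def simulate_pattern(params: dict | ObserverParams, trials: pd.DataFrame,
                     formula_id: str = "consistency_bias",
                     rng: np.random.Generator | int | None = None) -> GlmFit:
    """Regression signature of model-simulated choices.

    Simulates choices from the transducer on the given trial set and fits
    the named choice regression, returning its coefficients — the bridge
    from model parameters (tau, rho) to regression effects (b3, b2).
    """
    if not isinstance(params, ObserverParams):
        params = ObserverParams(r=params["r"], tau=params["tau"],
                                rho=params["rho"])
    sim = simulate_parametric_observer(trials, params, rng=rng)
    return ChoiceGLM(formula=formula_id).fit(sim, sim["choice"]).to_fit()


def sweep_pattern(trials: pd.DataFrame, r: float = 3.0,
                  tau_grid=(0.0,), rho_grid=(0.0,),
                  formula_id: str = "consistency_bias",
                  rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Coefficient patterns over a (tau, rho) parameter grid (tidy frame)."""
    rng = np.random.default_rng(rng)
    rows = []
    for tau in tau_grid:
        for rho in rho_grid:
            fit_ = simulate_pattern({"r": r, "tau": tau, "rho": rho},
                                    trials, formula_id, rng=rng)
            row = {"r": r, "tau": tau, "rho": rho}
            for name, val in fit_.params.items():
                row[name] = val
            for name, val in fit_.bse.items():
                row[f"se_{name}"] = val
            rows.append(row)
    return pd.DataFrame(rows)


def compare_models(subject_trials: list[pd.DataFrame],
                   variants=("base", "reduced"), k_folds: int = 10,
                   seed: int = 0, n_restarts: int = 3) -> BmsResult:
    """Random-effects BMS between transducer variants.

    Computes each subject's cross-validated log-likelihood under every
    variant and feeds the evidence matrix to
    :func:`distractnorm.choice_models.bms_exceedance`.
    """
    if len(variants) < 2:
        raise ValueError("need at least 2 variants to compare")
    lme = np.empty((len(subject_trials), len(variants)))
    for i, trials in enumerate(subject_trials):
        for j, variant in enumerate(variants):
            est = NormalizationModel(variant=variant, n_restarts=n_restarts,
                                     random_state=seed + i)
            lme[i, j] = crossval_loglik(trials, est, k_folds=k_folds,
                                        seed=seed + i)
    return bms_exceedance(lme, seed=seed)


def exclude_chance_subjects(subject_trials: list[pd.DataFrame],
                            threshold: float = 0.55) -> list[int]:
    """Indices of subjects performing above chance on both probe sides.

    Mirrors the cohort exclusion rule: a subject is dropped when accuracy
    falls below ``threshold`` for either of the two stimulus locations
    (guarding against observers that attend one side only).
    """
    keep = []
    for i, trials in enumerate(subject_trials):
        by_side = trials.groupby("probe_side")["correct"].mean()
        if (by_side >= threshold).all():
            keep.append(i)
    return keep
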