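"""Logistic choice-regression family, stepwise selection, CV and BMS.

The central regression expresses the decision variable on each trial as

    y = b0 + b1*theta_T + b2*theta_D + b3*(theta_T * |theta_T - theta_D|)

with choices Bernoulli(sigmoid(y)).  The b3 ("consistency") term carries the
interactive effect of the distracter: a negative b3 means the target weighs
more on choice when target and distracter are similar.  The attention
variant adds interactions of the first three regressors with the cue
indicator A (+1 valid, 0 neutral, -1 invalid).

Also here: forward/backward stepwise predictor selection over the seven
candidate regressors, distracter-binned target sensitivity, stratified
cross-validated log-likelihoods, and random-effects Bayesian model
selection (variational Dirichlet posterior over model frequencies with
Monte-Carlo exceedance probabilities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import digamma
from scipy.stats import chi2
from sklearn.base import BaseEstimator, clone
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "PREDICTORS",
    "FORMULAS",
    "GlmFit",
    "BmsResult",
    "ChoiceGLM",
    "build_design",
    "fit_choice_glm",
    "stepwise_select",
    "binned_sensitivity",
    "crossval_loglik",
    "bms_exceedance",
]

#: the seven candidate predictors considered in stepwise selection,
#: plus the attention interactions used by the cued-experiment model
PREDICTORS = {
    "theta_T": lambda d: d["theta_T"].to_numpy(float),
    "theta_D": lambda d: d["theta_D"].to_numpy(float),
    "abs_theta_D": lambda d: np.abs(d["theta_D"].to_numpy(float)),
    "congruency": lambda d: (np.sign(d["theta_T"].to_numpy(float))
                             == np.sign(d["theta_D"].to_numpy(float))
                             ).astype(float),
    "theta_T_x_theta_D": lambda d: (d["theta_T"] * d["theta_D"]).to_numpy(float),
    "theta_T_x_abs_theta_D": lambda d: (d["theta_T"]
                                        * d["theta_D"].abs()).to_numpy(float),
    "consistency": lambda d: (d["theta_T"]
                              * (d["theta_T"] - d["theta_D"]).abs()
                              ).to_numpy(float),
    "A_x_theta_T": lambda d: (_attention(d) * d["theta_T"]).to_numpy(float),
    "A_x_theta_D": lambda d: (_attention(d) * d["theta_D"]).to_numpy(float),
    "A_x_consistency": lambda d: (_attention(d) * d["theta_T"]
                                  * (d["theta_T"] - d["theta_D"]).abs()
                                  ).to_numpy(float),
}

STEPWISE_CANDIDATES = ["theta_T", "theta_D", "abs_theta_D", "congruency",
                       "theta_T_x_theta_D", "theta_T_x_abs_theta_D",
                       "consistency"]

#: named regression formulas (predictor lists exclude the intercept,
#: which is always included)
FORMULAS = {
    "consistency_bias": ["theta_T", "theta_D", "consistency"],
    "attention": ["theta_T", "theta_D", "consistency",
            "A_x_theta_T", "A_x_theta_D", "A_x_consistency"],
    "independent": ["theta_T", "theta_D"],
    "interaction": ["theta_T", "consistency"],
    "target_only": ["theta_T"],
}

#: consistency-type columns are divided by this when *reporting*
#: coefficients, so unit changes are on a comparable footing with the
#: main effects; fitting always uses the raw columns
CONSISTENCY_REPORT_DIVISOR = 10.0


def _attention(d: pd.DataFrame) -> pd.Series:
    """Attention indicator A from the cue-condition column (or A directly)."""
    if "A" in d.columns and d["A"].notna().all():
        return d["A"].astype(float)
    if "cue_condition" not in d.columns:
        raise ValueError("attention formula requires an A or cue_condition column")
    coding = {"valid": 1.0, "neutral": 0.0, "invalid": -1.0}
    bad = set(d["cue_condition"]) - set(coding)
    if bad:
        raise ValueError(
            f"attention formula requires valid/neutral/invalid cues, got {bad}")
    return d["cue_condition"].map(coding)


def build_design(trials: pd.DataFrame, formula_id) -> pd.DataFrame:
    """Design matrix (with intercept) for a named formula or predictor list."""
    names = FORMULAS[formula_id] if isinstance(formula_id, str) else list(formula_id)
    cols = {"intercept": np.ones(len(trials))}
    for name in names:
        cols[name] = PREDICTORS[name](trials)
    return pd.DataFrame(cols, index=trials.index)


@dataclass
class GlmFit:
    """Coefficients, standard errors and log-likelihood of one choice GLM."""

    formula_id: object
    params: pd.Series
    bse: pd.Series
    loglik: float
    n: int
    link: str = "logit"
    flagged: bool = False

    def reported_params(self) -> pd.Series:
        """Coefficients with consistency-type terms rescaled (x10) so a
        unit step of the reported predictor matches the main effects."""
        out = self.params.copy()
        for name in out.index:
            if "consistency" in name:
                out[name] *= CONSISTENCY_REPORT_DIVISOR
        return out


class ChoiceGLM(BaseEstimator):
    """Binomial GLM of binary choices on a named trial-table design.

    scikit-learn-style estimator: ``fit(trials, choices)`` builds the design
    matrix from the trial table and fits a maximum-likelihood binomial GLM
    (logit link by default).  Fitted attributes: ``params_``, ``bse_``,
    ``loglik_``, ``result_``.
    """

    def __init__(self, formula: object = "consistency_bias", link: str = "logit"):
        self.formula = formula
        self.link = link

    def _family(self):
        link = {"logit": sm.families.links.Logit(),
                "probit": sm.families.links.Probit()}[self.link]
        return sm.families.Binomial(link=link)

    def fit(self, X: pd.DataFrame, y) -> "ChoiceGLM":
        y = np.asarray(y, dtype=float)
        design = build_design(X, self.formula)
        if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
            raise ValueError(
                f"collinear design for formula {self.formula!r}: "
                f"columns {list(design.columns)}")
        res = sm.GLM(y, design, family=self._family()).fit()
        self.flagged_ = bool(np.any(np.abs(res.params) > 1e3))
        if self.flagged_:  # (near-)separation: ridge-penalized refit
            res = sm.GLM(y, design, family=self._family()).fit_regularized(
                alpha=1e-4, L1_wt=0.0)
            params = pd.Series(np.asarray(res.params), index=design.columns)
            self.params_, self.bse_ = params, pd.Series(np.nan, index=design.columns)
            eta = design.to_numpy() @ params.to_numpy()
            p = _sigmoid(eta) if self.link == "logit" else _probit_cdf(eta)
            self.loglik_ = float(np.sum(y * np.log(np.clip(p, 1e-12, 1))
                                        + (1 - y) * np.log(np.clip(1 - p, 1e-12, 1))))
        else:
            self.params_ = res.params
            self.bse_ = res.bse
            self.loglik_ = float(res.llf)
        self.result_ = res
        self.n_ = len(y)
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        design = build_design(X, self.formula)
        eta = design.to_numpy() @ self.params_.to_numpy()
        p = _sigmoid(eta) if self.link == "logit" else _probit_cdf(eta)
        return np.column_stack([1.0 - p, p])

    def to_fit(self) -> GlmFit:
        return GlmFit(self.formula, self.params_, self.bse_, self.loglik_,
                      self.n_, self.link, self.flagged_)


def _sigmoid(x):
    from scipy.special import expit
    return expit(np.asarray(x, dtype=float))


def _probit_cdf(x):
    from scipy.stats import norm
    return norm.cdf(x)


def fit_choice_glm(trials: pd.DataFrame, choices=None,
                   formula_id: object = "consistency_bias", link: str = "logit") -> GlmFit:
    """Fit a named choice GLM on a trial table (thin estimator wrapper)."""
    y = trials["choice"] if choices is None else choices
    return ChoiceGLM(formula=formula_id, link=link).fit(trials, y).to_fit()


def _deviance_pvalue(trials, y, base_names, full_names) -> float:
    """Likelihood-ratio p-value for the terms in full beyond base."""
    ll0 = fit_choice_glm(trials, y, list(base_names)).loglik
    ll1 = fit_choice_glm(trials, y, list(full_names)).loglik
    df = len(full_names) - len(base_names)
    stat = max(0.0, 2.0 * (ll1 - ll0))
    return float(chi2.sf(stat, df))


def stepwise_select(trials: pd.DataFrame, choices=None,
                    candidates=None, p_enter: float = 0.05,
                    p_remove: float = 0.10) -> list[str]:
    """Forward/backward stepwise predictor selection (knock-in / knock-out).

    Starting from an intercept-only model, repeatedly add the candidate with
    the smallest deviance-test p-value if it is below ``p_enter``, then drop
    any retained term whose removal p-value exceeds ``p_remove``, iterating
    to a fixpoint.  Returns the retained predictor names (canonical order).
    """
    y = (trials["choice"] if choices is None else choices)
    candidates = list(STEPWISE_CANDIDATES if candidates is None else candidates)
    included: list[str] = []
    while True:
        changed = False
        # knock in
        remaining = [c for c in candidates if c not in included]
        if remaining:
            pvals = {c: _deviance_pvalue(trials, y, included, included + [c])
                     for c in remaining}
            best = min(pvals, key=pvals.get)
            if pvals[best] < p_enter:
                included.append(best)
                changed = True
        # knock out
        if included:
            pvals = {c: _deviance_pvalue(
                trials, y, [k for k in included if k != c], included)
                for c in included}
            worst = max(pvals, key=pvals.get)
            if pvals[worst] > p_remove:
                included.remove(worst)
                changed = True
        if not changed:
            return [c for c in candidates if c in included]


def binned_sensitivity(trials: pd.DataFrame, fitted_model: ChoiceGLM | None = None,
                       n_bins: int = 6) -> pd.DataFrame:
    """Target-orientation sensitivity within equal-width distracter bins.

    The distracter range [-10, 10] is split into ``n_bins`` equal bins;
    within each, choice is regressed on theta_T alone and the slope (with
    SE) is returned.  If a fitted consistency-regression model is supplied, parallel
    slopes are computed with its predicted choice probabilities as the
    outcome, tracing the model's account of the same binned pattern.
    """
    edges = np.linspace(-10.0, 10.0, n_bins + 1)
    p_model = (fitted_model.predict_proba(trials)[:, 1]
               if fitted_model is not None else None)
    rows = []
    for i in range(n_bins):
        lo, hi = edges[i], edges[i + 1]
        mask = ((trials["theta_D"] >= lo) & (trials["theta_D"] < hi)
                if i < n_bins - 1 else
                (trials["theta_D"] >= lo) & (trials["theta_D"] <= hi))
        sub = trials.loc[mask]
        row = {"bin": i, "lo": lo, "hi": hi, "n": int(mask.sum()),
               "slope_obs": np.nan, "se_obs": np.nan,
               "slope_model": np.nan, "se_model": np.nan}
        if row["n"] == 0:
            row["flag"] = "empty"
            rows.append(row)
            continue
        row["flag"] = ""
        fit = fit_choice_glm(sub, formula_id="target_only")
        row["slope_obs"], row["se_obs"] = fit.params["theta_T"], fit.bse["theta_T"]
        if p_model is not None:
            fitm = fit_choice_glm(sub, choices=p_model[mask.to_numpy()],
                                  formula_id="target_only")
            row["slope_model"] = fitm.params["theta_T"]
            row["se_model"] = fitm.bse["theta_T"]
        rows.append(row)
    return pd.DataFrame(rows)


def crossval_loglik(trials: pd.DataFrame, model, choices=None,
                    k_folds: int = 10, seed: int = 0,
                    max_refolds: int = 20) -> float:
    """Summed held-out log-likelihood under stratified k-fold CV.

    ``model`` is either a formula id (fitted as a logit :class:`ChoiceGLM`)
    or any estimator with ``fit(trials, choices)`` and ``predict_proba``.
    Folds are stratified by choice and deterministic under ``seed``; if a
    training fold ends up single-class the data are refolded with the next
    seed (logged via a UserWarning).
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    proto = ChoiceGLM(formula=model) if isinstance(model, str) else model
    y = np.asarray(trials["choice"] if choices is None else choices, dtype=float)
    for attempt in range(max_refolds):
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                              random_state=seed + attempt)
        total = 0.0
        ok = True
        for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
            if len(np.unique(y[train_idx])) < 2:
                ok = False
                break
            est = clone(proto)
            est.fit(trials.iloc[train_idx], y[train_idx])
            p = est.predict_proba(trials.iloc[test_idx])[:, 1]
            p = np.clip(p, 1e-12, 1 - 1e-12)
            yt = y[test_idx]
            total += float(np.sum(yt * np.log(p) + (1 - yt) * np.log(1 - p)))
        if ok:
            return total
        import warnings
        warnings.warn(f"single-class fold at seed {seed + attempt}; refolding")
    raise RuntimeError("could not build folds with both classes in training")


@dataclass
class BmsResult:
    """Random-effects Bayesian model selection posterior."""

    alpha: np.ndarray
    expected_freq: np.ndarray
    exceedance: np.ndarray
    n_samples: int


def bms_exceedance(lme: np.ndarray, alpha0: float = 1.0,
                   n_samples: int = 100_000, seed: int = 0,
                   tol: float = 1e-8, max_iter: int = 10_000) -> BmsResult:
    """Random-effects BMS over per-subject model evidences.

    ``lme`` is (n_subjects, n_models) of log model evidences (here:
    cross-validated log-likelihoods).  Variational updates follow the
    standard Dirichlet-multinomial scheme: subject-level responsibilities
    ``u_nk proportional to exp(lme_nk + psi(alpha_k) - psi(sum alpha))`` and
    ``alpha_k = alpha0 + sum_n u_nk``, iterated to convergence.  Exceedance
    probabilities (probability each model is the most frequent in the
    population) are estimated by Monte-Carlo sampling of Dirichlet(alpha).
    """
    lme = np.atleast_2d(np.asarray(lme, dtype=float))
    if not np.all(np.isfinite(lme)):
        raise ValueError("model evidences must be finite")
    n, K = lme.shape
    alpha = np.full(K, float(alpha0))
    for _ in range(max_iter):
        log_u = lme + digamma(alpha) - digamma(alpha.sum())
        log_u -= log_u.max(axis=1, keepdims=True)
        u = np.exp(log_u)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    exceedance = np.bincount(winners, minlength=K) / n_samples
    return BmsResult(alpha=alpha, expected_freq=alpha / alpha.sum(),
                     exceedance=exceedance, n_samples=n_samples)
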