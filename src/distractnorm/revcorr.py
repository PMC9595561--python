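"""Psychophysical reverse correlation: decision kernels and SVD scores.

A *decision kernel* is the profile, across orientation bins, of probit
regression coefficients linking trial-to-trial fluctuations of z-scored
stimulus energy to the binary choice: one independent binomial probit per
bin, optionally with the distracter's energy as a competitive regressor.
Kernels can also be computed against the ground-truth CW/CCW label instead
of choices.

Because per-bin kernel tests are not independent (the kernel is smooth),
the energy profiles of all stimuli are additionally decomposed by an
*uncentred* SVD; the tilt-informative component (the one whose scores
correlate with the sign of the true tilt — in practice an antisymmetric
profile) yields per-stimulus scalar scores that replace the raw tilts in
the consistency-bias regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin

from .energy import ORIENTATIONS_DEG
from .choice_models import ChoiceGLM, GlmFit

__all__ = [
    "DecisionKernel",
    "EnergySVD",
    "decision_kernel",
    "svd_profiles",
    "select_tilt_component",
    "component_regression",
]


@dataclass
class DecisionKernel:
    """Per-orientation probit coefficients (and SEs) of a choice regression."""

    orientations_deg: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    beta_distracter: np.ndarray | None = None
    se_distracter: np.ndarray | None = None
    outcome: str = "choices"
    regressors: str = "target_only"
    link: str = "probit"
    flagged_bins: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"orientation_deg": self.orientations_deg,
             "beta": self.beta, "se": self.se}
        if self.beta_distracter is not None:
            d["beta_distracter"] = self.beta_distracter
            d["se_distracter"] = self.se_distracter
        if self.flagged_bins is not None:
            d["flagged"] = self.flagged_bins
        return pd.DataFrame(d)


def _penalized_probit(X: np.ndarray, y: np.ndarray,
                      alpha: float = 1e-2) -> tuple[np.ndarray, np.ndarray]:
    """Ridge-penalized probit via Fisher scoring; fallback for separation.

    Returns (params, se) with SEs from the penalized Fisher information.
    """
    from scipy.stats import norm
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(100):
        eta = X @ beta
        pdf = norm.pdf(eta)
        cdf = np.clip(norm.cdf(eta), 1e-10, 1 - 1e-10)
        w = pdf**2 / (cdf * (1 - cdf))
        score_eta = pdf * (y - cdf) / (cdf * (1 - cdf))
        grad = X.T @ score_eta - alpha * beta
        hess = X.T @ (w[:, None] * X) + alpha * np.eye(p)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    pdf = norm.pdf(eta)
    cdf = np.clip(norm.cdf(eta), 1e-10, 1 - 1e-10)
    w = pdf**2 / (cdf * (1 - cdf))
    info = X.T @ (w[:, None] * X) + alpha * np.eye(p)
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se


def decision_kernel(choices, z_energy_target: np.ndarray,
                    z_energy_distracter: np.ndarray | None = None,
                    outcome: str = "choices") -> DecisionKernel:
    """Estimate a decision kernel by parallel per-bin probit regressions.

    ``choices`` is the binary outcome per trial (participant/observer
    choices or ground-truth CW labels); ``z_energy_*`` are
    (n_trials, n_bins) z-scored energies.  With a distracter matrix, both
    stimuli enter each bin's regression jointly (the competitive variant)
    and the distracter kernel is returned alongside the target kernel.
    Bins with (near-)separation are refit with a small ridge penalty and
    flagged.
    """
    y = np.asarray(choices, dtype=float)
    zt = np.asarray(z_energy_target, dtype=float)
    n_bins = zt.shape[1]
    competitive = z_energy_distracter is not None
    zd = (np.asarray(z_energy_distracter, dtype=float) if competitive else None)
    beta = np.empty(n_bins)
    se = np.empty(n_bins)
    beta_d = np.empty(n_bins) if competitive else None
    se_d = np.empty(n_bins) if competitive else None
    flagged = np.zeros(n_bins, dtype=bool)
    ones = np.ones((len(y), 1))
    for b in range(n_bins):
        cols = [ones, zt[:, b:b + 1]] + ([zd[:, b:b + 1]] if competitive else [])
        X = np.hstack(cols)
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial(
                link=sm.families.links.Probit())).fit()
            params, bse = np.asarray(res.params), np.asarray(res.bse)
            if np.any(np.abs(params) > 1e2) or not np.all(np.isfinite(bse)):
                raise ValueError("separation suspected")
        except Exception:
            params, bse = _penalized_probit(X, y)
            flagged[b] = True
        beta[b], se[b] = params[1], bse[1]
        if competitive:
            beta_d[b], se_d[b] = params[2], bse[2]
    orientations = (ORIENTATIONS_DEG.copy() if n_bins == len(ORIENTATIONS_DEG)
                    else np.arange(n_bins, dtype=float))
    return DecisionKernel(
        orientations_deg=orientations, beta=beta, se=se,
        beta_distracter=beta_d, se_distracter=se_d, outcome=outcome,
        regressors="target_plus_distracter" if competitive else "target_only",
        flagged_bins=flagged)


class EnergySVD(BaseEstimator, TransformerMixin):
    """Uncentred SVD of a stimulus-by-orientation energy-profile matrix.

    scikit-learn-style transformer.  ``fit`` stores the right singular
    vectors as ``components_`` (k x n_bins, orthonormal) and the variance
    fraction carried by each; ``transform`` projects profiles onto the
    components, giving per-stimulus scores (the U*S convention).  No column
    centring is applied: the (symmetric) mean profile appears as the first
    component rather than being removed, matching a decomposition of raw
    energy rather than of deviations from the mean.
    """

    def __init__(self, variance_threshold: float = 0.95):
        self.variance_threshold = variance_threshold

    def fit(self, X: np.ndarray, y=None) -> "EnergySVD":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need at least 2 stimulus profiles")
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        total = float(np.sum(s**2))
        if total == 0 or s[0] == 0:
            raise ValueError("degenerate profile matrix (zero rank)")
        self.components_ = Vt
        self.singular_values_ = s
        self.variance_fraction_ = s**2 / total
        if np.sum(s > s[0] * 1e-12) < min(X.shape):
            import warnings
            warnings.warn("profile matrix is rank deficient")
        cum = np.cumsum(self.variance_fraction_)
        self.n_retained_ = int(np.searchsorted(cum, self.variance_threshold) + 1)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.components_.T

    def select_tilt_component(self, X: np.ndarray, thetas,
                              min_correlation: float = 0.1) -> int:
        """Identify and sign-align the tilt-informative component.

        Among the components retained at the variance threshold, picks the
        one whose scores have the largest |point-biserial correlation| with
        sign(theta), then flips its sign (component and hence scores) so
        that CW stimuli score positive on average.  Stored as
        ``tilt_component_``.
        """
        scores = self.transform(X)[:, :self.n_retained_]
        labels = np.sign(np.asarray(thetas, dtype=float))
        corrs = np.array([
            np.corrcoef(scores[:, i], labels)[0, 1]
            if np.std(scores[:, i]) > 0 else 0.0
            for i in range(self.n_retained_)])
        best = int(np.argmax(np.abs(corrs)))
        if abs(corrs[best]) <= min_correlation:
            raise ValueError(
                f"no component correlates with tilt (max |r| = "
                f"{np.max(np.abs(corrs)):.3f})")
        if corrs[best] < 0:
            self.components_[best] *= -1.0
        self.tilt_component_ = best
        self.tilt_correlation_ = abs(float(corrs[best]))
        return best


def svd_profiles(profile_matrix: np.ndarray,
                 variance_threshold: float = 0.95) -> EnergySVD:
    """Fit an :class:`EnergySVD` on a stacked profile matrix."""
    return EnergySVD(variance_threshold=variance_threshold).fit(profile_matrix)


def select_tilt_component(decomp: EnergySVD, profile_matrix: np.ndarray,
                          thetas) -> int:
    """Functional wrapper for :meth:`EnergySVD.select_tilt_component`."""
    return decomp.select_tilt_component(profile_matrix, thetas)


def component_regression(choices, scores_target, scores_distracter,
                         attention=None) -> GlmFit:
    """Consistency-bias logistic regression on tilt-component scores.

    Fits ``y = b0 + b1*U_T + b2*U_D + b3*(U_T * |U_T - U_D|)`` (plus the
    three attention interactions when ``attention`` — the A indicator or a
    cue-condition series — is given), with the per-trial component scores
    of target and distracter in place of angular offsets.
    """
    frame = pd.DataFrame({
        "theta_T": np.asarray(scores_target, dtype=float),
        "theta_D": np.asarray(scores_distracter, dtype=float),
    })
    formula = "consistency_bias"
    if attention is not None:
        a = np.asarray(attention)
        if a.dtype.kind in "OU":
            frame["cue_condition"] = a
        else:
            frame["A"] = a.astype(float)
        formula = "attention"
    return ChoiceGLM(formula=formula).fit(frame, np.asarray(choices)).to_fit()
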