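"""Simulated observers and the adaptive noise-contrast staircase.

Two observer families generate binary CW/CCW choices:

* the *parametric* observer applies the contextual-normalization transducer
  ``y = (theta_T - rho * mu) / (r + tau * sigma)`` with context mean
  ``mu = (theta_T + theta_D) / 2`` and context variability
  ``sigma = |theta_T - theta_D|``, then responds CW with probability
  ``1 / (1 + exp(-y))`` (optionally mixed with a lapse rate);
* the *energy-template* observer weights the z-scored orientation-energy
  profile of the rendered target by a fixed template, giving reverse
  correlation a recoverable ground-truth kernel.

:func:`run_staircase` implements Kesten's accelerated stochastic
approximation on noise contrast, titrating a simulated observer to a target
accuracy (0.75 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .stimgen import THETA_RANGE_DEG

__all__ = [
    "ObserverParams",
    "StaircaseTrace",
    "LogisticContrastObserver",
    "choice_probability",
    "simulate_parametric_observer",
    "simulate_energy_observer",
    "run_staircase",
]


@dataclass
class ObserverParams:
    """Parameters of a simulated observer.

    ``r`` may be a scalar or, for the attention variant, a mapping from cue
    condition (``valid`` / ``neutral`` / ``invalid``) to a condition-specific
    baseline.  ``lapse`` mixes in a uniform random choice and is an extension
    beyond the transducer itself (default 0): without it, extreme decision
    variables produce choice probabilities of exactly 0/1 and unbounded
    log-likelihood contributions in downstream fits.
    """

    r: float | dict = 3.0
    tau: float = 0.0
    rho: float = 0.0
    lapse: float = 0.0
    kind: str = "parametric"
    template: np.ndarray | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 0.5:
            raise ValueError("lapse must lie in [0, 0.5]")
        for r in self._r_values():
            if not r > 0:
                raise ValueError("r must be positive")
            if r + self.tau * 2 * THETA_RANGE_DEG <= 0:
                raise ValueError(
                    "r + tau * sigma must stay positive over sigma in [0, 20]")

    def _r_values(self):
        return list(self.r.values()) if isinstance(self.r, dict) else [self.r]

    def r_for(self, cue_condition) -> np.ndarray:
        """Per-trial baseline r, resolving condition-specific values."""
        if isinstance(self.r, dict):
            return np.asarray([self.r[c] for c in cue_condition], dtype=float)
        return np.full(len(cue_condition), float(self.r))


def choice_probability(theta_T, theta_D, params: ObserverParams,
                       cue_condition=None) -> np.ndarray:
    """Closed-form P(CW) of the parametric observer for given tilts."""
    theta_T = np.asarray(theta_T, dtype=float)
    theta_D = np.asarray(theta_D, dtype=float)
    mu = 0.5 * (theta_T + theta_D)
    sigma = np.abs(theta_T - theta_D)
    if cue_condition is None:
        r = float(params.r) if not isinstance(params.r, dict) else None
        if r is None:
            raise ValueError("condition-specific r requires cue_condition")
    else:
        r = params.r_for(cue_condition)
    denom = r + params.tau * sigma
    if np.any(denom <= 0):
        raise ValueError("transducer denominator r + tau*sigma is non-positive")
    y = (theta_T - params.rho * mu) / denom
    p = expit(y)
    return (1.0 - params.lapse) * p + params.lapse * 0.5


def simulate_parametric_observer(trials: pd.DataFrame, params: ObserverParams,
                                 rng: np.random.Generator | int | None = None,
                                 ) -> pd.DataFrame:
    """Fill ``choice`` and ``correct`` columns from the normalization observer.

    Returns a copy of the trial table; ``correct`` compares the choice with
    the sign of the target tilt.
    """
    rng = np.random.default_rng(params.rng_seed if rng is None else rng)
    out = trials.copy()
    cue = out["cue_condition"] if isinstance(params.r, dict) else None
    p = choice_probability(out["theta_T"].to_numpy(),
                           out["theta_D"].to_numpy(), params,
                           cue_condition=cue)
    choice = (rng.random(len(out)) < p).astype(int)
    out["choice"] = choice
    out["correct"] = (choice == (out["theta_T"].to_numpy() > 0)).astype(int)
    return out


def simulate_energy_observer(trials: pd.DataFrame, z_energy_target: np.ndarray,
                             template: np.ndarray,
                             rng: np.random.Generator | int | None = None,
                             z_energy_distracter: np.ndarray | None = None,
                             consistency_gain: ObserverParams | None = None,
                             ) -> pd.DataFrame:
    """Choices of a distracter-blind template observer.

    The decision variable is the inner product of the target's z-scored
    energy profile with ``template`` (one weight per orientation bin).  If
    ``consistency_gain`` is given, the decision variable is divided by
    ``r + tau * |score_T - score_D|`` computed from template scores of both
    stimuli, mirroring the normalization transducer at the energy level
    (off by default).
    """
    z_energy_target = np.asarray(z_energy_target, dtype=float)
    template = np.asarray(template, dtype=float)
    if z_energy_target.shape[1] != template.shape[0]:
        raise ValueError(
            f"template length {template.shape[0]} does not match "
            f"{z_energy_target.shape[1]} orientation bins")
    rng = np.random.default_rng(rng)
    dv = z_energy_target @ template
    if consistency_gain is not None:
        if z_energy_distracter is None:
            raise ValueError("consistency gain requires distracter energies")
        score_D = np.asarray(z_energy_distracter, dtype=float) @ template
        denom = float(consistency_gain.r) + consistency_gain.tau * np.abs(dv - score_D)
        if np.any(denom <= 0):
            raise ValueError("consistency-gain denominator is non-positive")
        dv = dv / denom
    p = expit(dv)
    out = trials.copy()
    choice = (rng.random(len(out)) < p).astype(int)
    out["choice"] = choice
    out["correct"] = (choice == (out["theta_T"].to_numpy() > 0)).astype(int)
    return out


class LogisticContrastObserver:
    """Observer whose tilt sensitivity scales with signal contrast.

    On a trial with tilt theta and noise contrast ``nu`` the observer
    responds CW with probability ``sigmoid(theta * (1 - nu) / r)``: at full
    noise it guesses, and accuracy rises monotonically as noise is removed.
    The expected accuracy over the uniform tilt distribution has a closed
    form, which :meth:`threshold_level` inverts by root finding — the
    independent oracle for staircase convergence.
    """

    def __init__(self, r: float = 1.0, theta_range: float = THETA_RANGE_DEG):
        if r <= 0:
            raise ValueError("r must be positive")
        self.r = float(r)
        self.theta_range = float(theta_range)

    def _slope(self, noise_contrast: float) -> float:
        return (1.0 - float(noise_contrast)) / self.r

    def p_correct(self, noise_contrast: float) -> float:
        """Expected accuracy at a noise contrast, averaged over tilts.

        For slope k, E[sigmoid(k|theta|)] over theta ~ U(-T, T) equals
        ``(log(1 + e^{kT}) - log 2) / (kT)``.
        """
        k = self._slope(noise_contrast)
        kt = k * self.theta_range
        if kt < 1e-12:
            return 0.5
        return float((np.logaddexp(0.0, kt) - np.log(2.0)) / kt)

    def threshold_level(self, target_p: float = 0.75) -> float:
        """Noise contrast at which expected accuracy equals ``target_p``."""
        return brentq(lambda nu: self.p_correct(nu) - target_p, 1e-6, 1 - 1e-6)

    def respond(self, noise_contrast: float, rng: np.random.Generator) -> int:
        """Simulate one trial; returns 1 if the choice was correct."""
        theta = rng.uniform(-self.theta_range, self.theta_range)
        p_cw = expit(self._slope(noise_contrast) * theta)
        choice = rng.random() < p_cw
        return int(choice == (theta > 0))


@dataclass
class StaircaseTrace:
    """Record of one adaptive-staircase run on noise contrast."""

    levels: np.ndarray
    responses: np.ndarray
    n_shifts: int
    converged_level: float
    target_p: float = 0.75


def run_staircase(observer, target_p: float = 0.75, n_max: int = 6000,
                  initial_level: float = 0.9, initial_step: float = 0.6,
                  step_floor: float = 2e-4,
                  rng: np.random.Generator | int | None = None,
                  ) -> StaircaseTrace:
    """Accelerated stochastic approximation on noise contrast.

    After each response the level moves by ``step * (resp - target_p)``
    toward the target accuracy — up (harder) on a correct response, down on
    an error — with ``step = initial_step / (2 + m)`` where ``m`` counts the
    response-direction reversals so far, so steps shrink as the run brackets
    the threshold.  The run ends after ``n_max`` trials or once the step
    falls below ``step_floor``; levels are clipped to [0, 1].

    A diagnostic sweep warns (without failing) if the observer's expected
    accuracy is not monotone decreasing in noise contrast.
    """
    rng = np.random.default_rng(rng)
    if hasattr(observer, "p_correct"):
        probe = [observer.p_correct(nu) for nu in np.linspace(0.05, 0.95, 7)]
        if np.any(np.diff(probe) > 1e-9):
            import warnings
            warnings.warn("observer accuracy is not monotone decreasing in "
                          "noise contrast; staircase may not converge")

    level = float(initial_level)
    levels, responses = [], []
    n_shifts = 0
    prev_resp = None
    for _ in range(int(n_max)):
        resp = int(observer.respond(level, rng))
        levels.append(level)
        responses.append(resp)
        if prev_resp is not None and resp != prev_resp:
            n_shifts += 1
        prev_resp = resp
        step = initial_step / (2.0 + n_shifts)
        # correct -> raise noise (harder); error -> lower it, 3x as far at p=.75
        level = float(np.clip(level + step * (resp - target_p), 0.0, 1.0))
        if step < step_floor:
            break
    return StaircaseTrace(levels=np.asarray(levels),
                          responses=np.asarray(responses),
                          n_shifts=n_shifts, converged_level=level,
                          target_p=target_p)
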