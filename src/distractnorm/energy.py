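"""Orientation-energy profiles via an oriented Gabor filter bank.

Each stimulus is regressed on a bank of Gabor filters spanning orientations
-45 to +45 deg in 0.5-deg steps (181 bins) at 5 carrier phases
({0.2, 0.6, 1.0, 1.4, 1.8} * pi).  Across the 5 phases the filter response
at a fixed orientation follows a cosine in phase,

    R(phi_n) = E * cos(phi_n - phi_max),

whose amplitude E is the stimulus *energy* at that orientation and phi_max
the best-matching phase.  Because the phases are uniformly spaced modulo
2*pi, the cosine fit has the closed form of a single discrete Fourier
coefficient: a = (2/5) sum R_n cos(phi_n), b = (2/5) sum R_n sin(phi_n),
E = hypot(a, b), phi_max = atan2(b, a).  Energies are z-scored within each
orientation bin across a stimulus ensemble before entering choice
regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimgen import StimulusSpec, StimulusImage, make_gabor

__all__ = [
    "ORIENTATIONS_DEG",
    "PHASES_RAD",
    "FilterBank",
    "EnergyProfile",
    "build_filter_bank",
    "filter_response",
    "energy_profile",
    "energy_profiles",
    "zscore_energies",
]

#: orientation grid of the filter bank (181 bins)
ORIENTATIONS_DEG = np.arange(-45.0, 45.0 + 0.25, 0.5)

#: the five filter phases, uniformly spaced modulo 2*pi
PHASES_RAD = np.array([0.2, 0.6, 1.0, 1.4, 1.8]) * np.pi

N_ORI = len(ORIENTATIONS_DEG)
N_PHASE = len(PHASES_RAD)


@dataclass
class FilterBank:
    """Mean-centred Gabor filters on the stimulus grid.

    ``filters`` is (n_ori * n_phase, n_pixels**2), row-major over
    (orientation, phase); ``filter_var`` holds each filter's pixel variance
    (the regression denominator).
    """

    orientations_deg: np.ndarray
    phases_rad: np.ndarray
    filters: np.ndarray
    filter_var: np.ndarray
    spec: StimulusSpec

    @property
    def n_pixels(self) -> int:
        return self.spec.n_pixels


@dataclass
class EnergyProfile:
    """Per-orientation energy amplitude and best phase of one stimulus."""

    energy: np.ndarray
    phi_max: np.ndarray
    orientations_deg: np.ndarray
    z_energy: np.ndarray | None = None
    stimulus_id: int | None = None
    role: str = "target"


def build_filter_bank(spec: StimulusSpec) -> FilterBank:
    """Render the 181 x 5 Gabor filter bank on the grid of ``spec``.

    Filter spatial frequency and envelope match the signal gratings, so the
    profile reads out energy at the spatial scale of the target.  Filters
    are mean-removed, making the energy invariant to the stimulus mean.
    """
    n_pix = spec.n_pixels
    filters = np.empty((N_ORI * N_PHASE, n_pix * n_pix))
    for i, ori in enumerate(ORIENTATIONS_DEG):
        for j, ph in enumerate(PHASES_RAD):
            f = make_gabor(ori, ph, spec).pixels.ravel()
            filters[i * N_PHASE + j] = f - f.mean()
    var = filters.var(axis=1)
    if np.any(var <= 0):
        raise ValueError("degenerate (zero-variance) filter in bank")
    return FilterBank(ORIENTATIONS_DEG.copy(), PHASES_RAD.copy(),
                      filters, var, spec)


def filter_response(stimulus: StimulusImage | np.ndarray,
                    filt: np.ndarray) -> float:
    """Regression slope of stimulus pixels on filter pixels.

    Implements the "variance in the filter explained by the covariance of
    filter and stimulus" readout as cov(S, F) / var(F) with mean-removed
    images; any fixed positive rescaling of this convention cancels in the
    downstream per-bin z-scoring.
    """
    s = (stimulus.pixels if isinstance(stimulus, StimulusImage) else stimulus)
    s = np.asarray(s, dtype=float).ravel()
    f = np.asarray(filt, dtype=float).ravel()
    if s.shape != f.shape:
        raise ValueError("stimulus and filter grids differ")
    f = f - f.mean()
    var = f @ f
    if var <= 0:
        raise ValueError("degenerate (zero-variance) filter")
    s = s - s.mean()
    return float((s @ f) / var)


def _phase_fit(responses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form cosine fit over the 5 phases.

    ``responses`` has shape (..., n_phase); returns (E, phi_max) of the
    least-squares fit R_n = E cos(phi_n - phi_max), exact because the
    phases are uniform modulo 2*pi.
    """
    a = (2.0 / N_PHASE) * (responses * np.cos(PHASES_RAD)).sum(axis=-1)
    b = (2.0 / N_PHASE) * (responses * np.sin(PHASES_RAD)).sum(axis=-1)
    energy = np.hypot(a, b)
    phi_max = np.mod(np.arctan2(b, a), 2.0 * np.pi)
    phi_max = np.where(energy == 0.0, 0.0, phi_max)  # undefined phase -> 0
    return energy, phi_max


def energy_profiles(stimuli: np.ndarray, bank: FilterBank,
                    batch: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Energy profiles of a stimulus batch.

    ``stimuli`` is (n, h, w) or (n, h*w); returns ``(E, phi_max)`` each of
    shape (n, 181).
    """
    stims = np.asarray(stimuli, dtype=float).reshape(len(stimuli), -1)
    if stims.shape[1] != bank.filters.shape[1]:
        raise ValueError("stimulus grid does not match filter-bank grid")
    stims = stims - stims.mean(axis=1, keepdims=True)
    energy = np.empty((len(stims), N_ORI))
    phi = np.empty((len(stims), N_ORI))
    for lo in range(0, len(stims), batch):
        chunk = stims[lo:lo + batch]
        resp = (chunk @ bank.filters.T) / bank.filter_var  # (b, 905)
        resp = resp.reshape(len(chunk), N_ORI, N_PHASE)
        energy[lo:lo + batch], phi[lo:lo + batch] = _phase_fit(resp)
    return energy, phi


def energy_profile(stimulus: StimulusImage | np.ndarray,
                   bank: FilterBank, **kw) -> EnergyProfile:
    """Energy profile of a single stimulus."""
    pixels = (stimulus.pixels if isinstance(stimulus, StimulusImage)
              else np.asarray(stimulus, dtype=float))
    e, p = energy_profiles(pixels[None], bank)
    return EnergyProfile(e[0], p[0], bank.orientations_deg.copy(), **kw)


def zscore_energies(energy: np.ndarray) -> np.ndarray:
    """Standardise energies within each orientation bin across an ensemble.

    ``energy`` is (n_stimuli, n_bins) with n_stimuli >= 2; target and
    distracter ensembles should be standardised separately.
    """
    energy = np.asarray(energy, dtype=float)
    if energy.ndim != 2 or energy.shape[0] < 2:
        raise ValueError("need an ensemble of at least 2 stimuli")
    sd = energy.std(axis=0, ddof=0)
    if np.any(sd <= 0):
        bad = np.flatnonzero(sd <= 0)
        raise ValueError(f"zero variance in orientation bin(s) {bad[:5]}")
    return (energy - energy.mean(axis=0)) / sd
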