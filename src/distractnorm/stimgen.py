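"""Noisy-Gabor stimulus rendering and trial-design generation.

Stimuli are Gabor patches (cosine carrier under a Gaussian envelope) mixed
with smoothed Gaussian noise; the signal and noise contrasts sum to 1, so a
single contrast parameter controls the signal-to-noise ratio.  Trial tables
describe three two-stimulus orientation-discrimination designs:

* ``exp1`` — both stimuli judged against a shared vertical boundary;
* ``exp2`` — orthogonal boundaries (left ring vertical, right ring
  horizontal), dissociating decision-level from sensory-level tilt;
* ``exp3_cued`` / ``exp3_neutral`` — vertical boundaries with a spatial
  pre-cue of 70% validity (or an uninformative neutral cue).

Orientation convention: degrees, 0 = vertical, positive = clockwise (CW).
Boundary-relative tilt theta is drawn uniformly on [-10, +10] degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "StimulusSpec",
    "StimulusImage",
    "DESIGNS",
    "TRIAL_COLUMNS",
    "make_gabor",
    "make_noise",
    "compose_stimulus",
    "render_trial_stimuli",
    "generate_trials",
]

#: recognised experiment-design labels
DESIGNS = ("exp1", "exp2", "exp3_cued", "exp3_neutral")

#: canonical TrialTable column order
TRIAL_COLUMNS = [
    "trial_id",
    "theta_T",
    "theta_D",
    "boundary_T",
    "boundary_D",
    "probe_side",
    "cue_condition",
    "A",
    "raw_orientation_T",
    "raw_orientation_D",
    "stim_seed_T",
    "stim_seed_D",
    "choice",
    "correct",
]

#: half-range of the uniform tilt distribution (degrees)
THETA_RANGE_DEG = 10.0

#: cue validity in cued blocks of the attention experiment
CUE_VALIDITY = 0.70


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry and contrast parameters of one rendered stimulus.

    Defaults follow the experimental display: a 4 deg square patch, Gaussian
    envelope SD 1 deg, noise-smoothing SD 0.083 deg.  The carrier spatial
    frequency was not part of the public design description; 2 cycles/deg is
    a typical choice for foveal/parafoveal gratings of this size and is kept
    configurable (the analysis filter bank must reuse the same value).
    """

    size_deg: float = 4.0
    envelope_sd_deg: float = 1.0
    spatial_freq_cpd: float = 2.0
    pixels_per_deg: int = 32
    noise_smooth_sd_deg: float = 0.083
    signal_contrast: float = 0.35
    orientation_deg: float = 0.0
    phase_rad: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("size_deg", "envelope_sd_deg", "spatial_freq_cpd",
                     "pixels_per_deg", "noise_smooth_sd_deg"):
            if not getattr(self, name) > 0:
                raise ValueError(f"StimulusSpec.{name} must be positive")
        if not 0.0 <= self.signal_contrast <= 1.0:
            raise ValueError("signal_contrast must lie in [0, 1]")

    @property
    def noise_contrast(self) -> float:
        return 1.0 - self.signal_contrast

    @property
    def n_pixels(self) -> int:
        """Side length of the square pixel grid."""
        return int(round(self.size_deg * self.pixels_per_deg))

    def grid_deg(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinates in degrees, centred on the patch.

        Returns ``(x, y)`` meshgrids with x increasing rightwards and y
        increasing upwards.
        """
        n = self.n_pixels
        coords = (np.arange(n) - (n - 1) / 2.0) / self.pixels_per_deg
        x, y = np.meshgrid(coords, -coords)  # row 0 = top of patch
        return x, y

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "StimulusSpec":
        return replace(self, **kw)


@dataclass
class StimulusImage:
    """A rendered stimulus: raw pixel grid plus generation metadata."""

    pixels: np.ndarray
    spec: StimulusSpec
    role: str = "target"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("pixels must be a square 2-D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")


def make_gabor(orientation_deg: float, phase_rad: float,
               spec: StimulusSpec) -> StimulusImage:
    """Render a unit-amplitude Gabor: cosine carrier x Gaussian envelope.

    At ``orientation_deg = 0`` the grating is vertical (luminance varies
    along x); positive orientations rotate it clockwise.
    """
    x, y = spec.grid_deg()
    th = np.deg2rad(orientation_deg)
    # wave vector of a vertical grating is +x; clockwise rotation by th
    # (with y pointing up) maps it to (cos th, -sin th)
    u = x * np.cos(th) - y * np.sin(th)
    carrier = np.cos(2.0 * np.pi * spec.spatial_freq_cpd * u + phase_rad)
    envelope = np.exp(-(x**2 + y**2) / (2.0 * spec.envelope_sd_deg**2))
    spec_out = spec.replace(orientation_deg=float(orientation_deg),
                            phase_rad=float(phase_rad))
    return StimulusImage(carrier * envelope, spec_out)


def make_noise(spec: StimulusSpec, rng: np.random.Generator) -> StimulusImage:
    """Smoothed Gaussian pixel noise, rescaled to zero mean and unit SD.

    An i.i.d. standard-normal field is low-pass filtered with a Gaussian
    kernel of SD ``noise_smooth_sd_deg`` and then standardised, so that the
    mixing weight in :func:`compose_stimulus` alone sets the stimulus
    signal-to-noise ratio.
    """
    n = spec.n_pixels
    field = rng.standard_normal((n, n))
    sigma_px = spec.noise_smooth_sd_deg * spec.pixels_per_deg
    smoothed = gaussian_filter(field, sigma=sigma_px, mode="wrap")
    smoothed -= smoothed.mean()
    sd = smoothed.std()
    if sd > 0:
        smoothed /= sd
    return StimulusImage(smoothed, spec, role="noise")


def compose_stimulus(gabor: StimulusImage, noise: StimulusImage,
                     signal_contrast: float) -> StimulusImage:
    """Contrast-weighted mixture: ``c * gabor + (1 - c) * noise``."""
    if gabor.pixels.shape != noise.pixels.shape:
        raise ValueError(
            f"grid mismatch: gabor {gabor.pixels.shape} vs noise {noise.pixels.shape}")
    if not 0.0 <= signal_contrast <= 1.0:
        raise ValueError("signal_contrast must lie in [0, 1]")
    pixels = signal_contrast * gabor.pixels + (1.0 - signal_contrast) * noise.pixels
    spec = gabor.spec.replace(signal_contrast=float(signal_contrast))
    return StimulusImage(pixels, spec, role=gabor.role)


def render_trial_stimuli(raw_orientation_deg: float, stim_seed: int,
                         spec: StimulusSpec) -> StimulusImage:
    """Reproducibly render the composite stimulus of one trial.

    The per-trial seed drives both the carrier phase (uniform on [0, 2pi))
    and the noise field, so a recorded ``(spec, seed)`` pair regenerates the
    stimulus bit-for-bit.
    """
    rng = np.random.default_rng(int(stim_seed))
    phase = rng.uniform(0.0, 2.0 * np.pi)
    gabor = make_gabor(raw_orientation_deg, phase, spec)
    noise = make_noise(spec, rng)
    return compose_stimulus(gabor, noise, spec.signal_contrast)


def wrap_orientation(deg):
    """Wrap an orientation difference to (-90, 90] (gratings have period 180)."""
    return -((-np.asarray(deg) + 90.0) % 180.0 - 90.0)


def generate_trials(design: str, n_trials: int,
                    rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Generate a trial table for one experimental design.

    Target and distracter tilts are sampled independently and uniformly on
    [-10, +10] deg about their decision boundaries; the probed side is fair.
    In ``exp3_cued`` blocks the cue matches the probe with probability 0.70
    and the attention indicator ``A`` is +1 (valid), -1 (invalid); in
    ``exp3_neutral`` blocks ``A = 0``.  Per-trial stimulus seeds are drawn
    and recorded so image rendering is reproducible from the table alone.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    if not n_trials > 0:
        raise ValueError("n_trials must be positive")
    rng = np.random.default_rng(rng)

    n = int(n_trials)
    theta_T = rng.uniform(-THETA_RANGE_DEG, THETA_RANGE_DEG, n)
    theta_D = rng.uniform(-THETA_RANGE_DEG, THETA_RANGE_DEG, n)
    probe_right = rng.random(n) < 0.5

    if design == "exp2":
        # fixed ring->boundary map: left ring vertical (0), right horizontal (90)
        boundary_T = np.where(probe_right, 90.0, 0.0)
        boundary_D = np.where(probe_right, 0.0, 90.0)
    else:
        boundary_T = np.zeros(n)
        boundary_D = np.zeros(n)

    if design == "exp3_cued":
        cue_right = rng.random(n) < 0.5
        valid = rng.random(n) < CUE_VALIDITY
        probe_right = np.where(valid, cue_right, ~cue_right)
        cue_condition = np.where(valid, "valid", "invalid")
        A = np.where(valid, 1, -1)
    elif design == "exp3_neutral":
        cue_condition = np.full(n, "neutral")
        A = np.zeros(n, dtype=int)
    else:
        cue_condition = np.full(n, "none")
        A = np.zeros(n, dtype=int)

    table = pd.DataFrame({
        "trial_id": np.arange(n),
        "theta_T": theta_T,
        "theta_D": theta_D,
        "boundary_T": boundary_T,
        "boundary_D": boundary_D,
        "probe_side": np.where(probe_right, "right", "left"),
        "cue_condition": cue_condition,
        "A": A,
        "raw_orientation_T": boundary_T + theta_T,
        "raw_orientation_D": boundary_D + theta_D,
        "stim_seed_T": rng.integers(0, 2**31, n),
        "stim_seed_D": rng.integers(0, 2**31, n),
        "choice": np.full(n, np.nan),
        "correct": np.full(n, np.nan),
    })
    return table[TRIAL_COLUMNS]
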