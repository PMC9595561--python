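"""Shared fixtures: small-raster stimulus spec, filter bank, and a rendered
stimulus ensemble with a template observer's choices.

The rendered ensemble is session-scoped because rendering dominates test
run time; every consumer treats it as read-only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import distractnorm as dn


@pytest.fixture(scope="session")
def small_spec() -> dn.StimulusSpec:
    """Reduced-raster spec (16 px/deg) used throughout the suite."""
    return dn.StimulusSpec(pixels_per_deg=16)


@pytest.fixture(scope="session")
def bank(small_spec) -> dn.FilterBank:
    return dn.build_filter_bank(small_spec)


def render_ensemble(spec: dn.StimulusSpec, trials: pd.DataFrame) -> dict:
    """Render target and distracter stimuli for every trial."""
    n, npix = len(trials), spec.n_pixels
    out = {}
    for role, ori_col, seed_col in (
            ("target", "raw_orientation_T", "stim_seed_T"),
            ("distracter", "raw_orientation_D", "stim_seed_D")):
        imgs = np.empty((n, npix, npix))
        for i, (ori, sd) in enumerate(zip(trials[ori_col], trials[seed_col])):
            imgs[i] = dn.render_trial_stimuli(ori, sd, spec).pixels
        out[role] = imgs
    return out


def antisymmetric_template(orientations_deg: np.ndarray,
                           z_target: np.ndarray) -> np.ndarray:
    """Odd template peaked at +/-5 deg, scaled to decision-variable SD 1.5."""
    t = (np.exp(-(orientations_deg - 5.0) ** 2 / 18.0)
         - np.exp(-(orientations_deg + 5.0) ** 2 / 18.0))
    return t * 1.5 / np.std(z_target @ t)


@pytest.fixture(scope="session")
def rendered(small_spec, bank) -> dict:
    """4,000 trials rendered + energy profiles + template-observer choices.

    Keys: trials, z_target, z_distracter, e_target, e_distracter, template,
    sim (trial table with choices of the distracter-blind template observer).
    """
    trials = dn.generate_trials("exp1", 4000, rng=101)
    imgs = render_ensemble(small_spec, trials)
    e_t, _ = dn.energy_profiles(imgs["target"], bank)
    e_d, _ = dn.energy_profiles(imgs["distracter"], bank)
    z_t = dn.zscore_energies(e_t)
    z_d = dn.zscore_energies(e_d)
    template = antisymmetric_template(bank.orientations_deg, z_t)
    sim = dn.simulate_energy_observer(trials, z_t, template, rng=102)
    return {"trials": trials, "e_target": e_t, "e_distracter": e_d,
            "z_target": z_t, "z_distracter": z_d, "template": template,
            "sim": sim}
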