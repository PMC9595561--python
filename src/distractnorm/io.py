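"""Table, fit and energy-store round-tripping (CSV / JSON / HDF5)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .stimgen import TRIAL_COLUMNS

__all__ = [
    "write_trials", "read_trials",
    "write_energies", "read_energies",
    "write_fit_json", "read_fit_json",
]

#: columns that must be present for a table to qualify as a TrialTable
REQUIRED_TRIAL_COLUMNS = [c for c in TRIAL_COLUMNS if c not in ("choice", "correct")]


def write_trials(trials: pd.DataFrame, path) -> Path:
    path = Path(path)
    trials.to_csv(path, index=False)
    return path


def read_trials(path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table at {path} is missing column(s) {missing}")
    return trials


def write_energies(path, orientations_deg: np.ndarray, *,
                   spec: dict | None = None, **role_matrices) -> Path:
    """Store per-role energy matrices (n_stimuli x n_bins) in HDF5.

    The orientation grid is stored as a root attribute; the stimulus spec
    (if given) as JSON in an attribute, keeping the store self-describing.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["orientations_deg"] = np.asarray(orientations_deg, dtype=float)
        if spec is not None:
            f.attrs["spec_json"] = json.dumps(spec)
        for role, mat in role_matrices.items():
            f.create_dataset(role, data=np.asarray(mat, dtype=float))
    return path


def read_energies(path) -> tuple[dict, np.ndarray, dict | None]:
    """Returns (role -> matrix, orientation grid, spec dict or None)."""
    with h5py.File(path, "r") as f:
        orientations = np.asarray(f.attrs["orientations_deg"])
        spec = (json.loads(f.attrs["spec_json"])
                if "spec_json" in f.attrs else None)
        mats = {name: np.asarray(f[name]) for name in f}
    return mats, orientations, spec


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_fit_json(fit_like, path) -> Path:
    """Serialise a GlmFit / NormModelFit-style dataclass (or dict) to JSON."""
    path = Path(path)
    if hasattr(fit_like, "__dataclass_fields__"):
        payload = {name: _jsonable(getattr(fit_like, name))
                   for name in fit_like.__dataclass_fields__}
    else:
        payload = _jsonable(fit_like)
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_fit_json(path) -> dict:
    return json.loads(Path(path).read_text())
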