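"""Reading and writing the canonical trial CSV.

The interchange format is a flat CSV with columns ``observer_id,
experiment, condition, v_surf, v_prop, amplitude, response``; extra columns
(e.g. the two interval speeds of the discrimination task) round-trip
untouched.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synth import CANONICAL_COLUMNS

__all__ = ["read_trials", "write_trials"]


def _validate(trials: pd.DataFrame, origin: str) -> pd.DataFrame:
    missing = [c for c in CANONICAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"{origin}: missing required columns {missing}")
    for col in ("v_surf", "v_prop", "amplitude"):
        values = pd.to_numeric(trials[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(values.to_numpy(dtype=float)))
        if len(bad):
            raise ValueError(f"{origin}: non-finite {col} at row {bad[0]}")
        trials[col] = values.astype(float)
    resp = pd.to_numeric(trials["response"], errors="coerce")
    bad = np.flatnonzero(~resp.isin([0, 1]).to_numpy())
    if len(bad):
        raise ValueError(f"{origin}: response must be 0 or 1, offending row {bad[0]}")
    trials["response"] = resp.astype(int)
    return trials


def read_trials(path: str | Path) -> pd.DataFrame:
    """Load and validate a trial table; errors name the offending row."""
    trials = pd.read_csv(path)
    return _validate(trials, str(path))


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Validate and write a trial table (canonical columns first)."""
    trials = _validate(trials.copy(), "write_trials")
    extra = [c for c in trials.columns if c not in CANONICAL_COLUMNS]
    trials[CANONICAL_COLUMNS + extra].to_csv(path, index=False)
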