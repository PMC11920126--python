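"""Reading, validating and writing trial-level CSV tables.

The canonical schema has one row per trial and exactly these columns:
``participant_id, instruction, difficulty, session, trial, stimulus,
pre_rating, type1_response, post_rating, rt_pre, rt_answer, rt_post``.
Empty fields encode missing responses; a missing RT makes the paired
response count as missing downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TRIAL_COLUMNS = [
    "participant_id", "instruction", "difficulty", "session", "trial",
    "stimulus", "pre_rating", "type1_response", "post_rating",
    "rt_pre", "rt_answer", "rt_post",
]

_ENUMS = {
    "instruction": {"bet", "confidence"},
    "difficulty": {"easy", "hard"},
    "stimulus": {"match", "nonmatch"},
    "type1_response": {"match", "nonmatch"},  # or missing
}
_RANGES = {"pre_rating": (1, 2), "post_rating": (1, 5), "session": (1, None),
           "trial": (1, None)}


class TrialSchemaError(ValueError):
    """Raised when a trial table violates the schema."""


def validate_trials(trials: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialSchemaError(f"missing column(s): {missing}")
    for col, allowed in _ENUMS.items():
        vals = trials[col]
        mask = vals.notna() & ~vals.isin(allowed)
        if col != "type1_response":
            mask |= vals.isna()
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0])
            raise TrialSchemaError(
                f"bad value {trials[col].iloc[row]!r} in column {col!r} at row {row}"
            )
    for col, (lo, hi) in _RANGES.items():
        vals = pd.to_numeric(trials[col], errors="coerce")
        mask = trials[col].notna() & (
            vals.isna() | (vals < lo) | ((vals > hi) if hi is not None else False)
            | (vals != vals.round())
        )
        if col in ("session", "trial"):
            mask |= trials[col].isna()
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0])
            raise TrialSchemaError(
                f"out-of-range value {trials[col].iloc[row]!r} in column {col!r} "
                f"at row {row}"
            )
    for col in ("rt_pre", "rt_answer", "rt_post"):
        vals = pd.to_numeric(trials[col], errors="coerce")
        mask = trials[col].notna() & (vals.isna() | (vals < 0))
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0])
            raise TrialSchemaError(
                f"bad RT {trials[col].iloc[row]!r} in column {col!r} at row {row}"
            )


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial CSV; missing responses come back as NA."""
    trials = pd.read_csv(path, dtype={"participant_id": str})
    validate_trials(trials)
    trials = trials[TRIAL_COLUMNS].copy()
    for col in ("session", "trial", "pre_rating", "post_rating"):
        trials[col] = pd.to_numeric(trials[col]).astype("Int64")
    for col in ("rt_pre", "rt_answer", "rt_post"):
        # a record with an empty RT is retained; the exclusion rules treat the
        # paired response as missing downstream
        trials[col] = pd.to_numeric(trials[col]).astype(float)
    return trials


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write the canonical CSV form (RTs to 0.1 ms, empty = missing)."""
    out = trials[TRIAL_COLUMNS].copy()
    for col in ("rt_pre", "rt_answer", "rt_post"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.1f}")
    out.to_csv(path, index=False, na_rep="")
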