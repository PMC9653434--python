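"""Trial/stimulus tables shared by the imaging and photometry pipelines.

A trial table is a pandas DataFrame with one row per trial:

    onset_s          stimulus onset (s, strictly increasing)
    stimulus         condition label (e.g. "odorA", "light", "odorA+light",
                     "shutter" for shutter-only controls)
    block            0-based block index
    shutter_close_s  PMT shutter close time (two-photon light trials; NaN otherwise)
    shutter_open_s   PMT shutter reopen time (NaN otherwise)
    light_onset_s    optogenetic light onset (photometry trials; NaN otherwise)

Helper accessors keep the column names in one place.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

TRIAL_COLUMNS = [
    "onset_s",
    "stimulus",
    "block",
    "shutter_close_s",
    "shutter_open_s",
    "light_onset_s",
]


def validate_trial_table(
    trials: pd.DataFrame,
    min_iti_s: float | None = None,
    trials_per_block: int | None = None,
) -> pd.DataFrame:
    """Check structural invariants of a trial table and return it.

    Onsets must be strictly increasing; optionally enforce a minimum
    inter-trial gap and a fixed number of trials per block.
    """
    missing = [c for c in ("onset_s", "stimulus", "block") if c not in trials.columns]
    if missing:
        raise InvalidParameterError(f"trial table missing columns {missing}")
    onsets = trials["onset_s"].to_numpy(dtype=float)
    if onsets.size and not np.all(np.diff(onsets) > 0):
        raise InvalidParameterError("trial onsets must be strictly increasing")
    if min_iti_s is not None and onsets.size > 1 and np.min(np.diff(onsets)) < min_iti_s:
        raise InvalidParameterError(
            f"inter-trial gap {np.min(np.diff(onsets)):.3f} s below minimum {min_iti_s} s"
        )
    if trials_per_block is not None:
        counts = trials.groupby("block").size()
        bad = counts[counts != trials_per_block]
        if len(bad):
            raise InvalidParameterError(
                f"blocks {list(bad.index)} do not have {trials_per_block} trials"
            )
    return trials


def read_trial_table(path) -> pd.DataFrame:
    """Read a trial table from CSV and validate its basic structure."""
    df = pd.read_csv(path)
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return validate_trial_table(df)


def write_trial_table(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)
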