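"""Tabular input/output in a BIDS-events-like dialect.

Events tables are UTF-8 tab-separated files, one row per trial, with
missing values written as "n/a".
"""

from __future__ import annotations

import pandas as pd

EVENTS_COLUMNS = [
    "participant",
    "group",
    "session",
    "session_day",
    "block",
    "trial_index",
    "stimulus_id",
    "learnability",
    "stimulus_set",
    "response",
    "rt_ms",
    "n_presses",
    "valid",
    "correct",
    "feedback_valence",
    "fixation_ms",
    "feedback_delay_ms",
]


def write_events(events: pd.DataFrame, path) -> None:
    """Write an events table as tab-separated UTF-8 with n/a for missing."""
    events.to_csv(path, sep="\t", index=False, na_rep="n/a", encoding="utf-8")


def read_events(path) -> pd.DataFrame:
    """Read an events table written by :func:`write_events`."""
    df = pd.read_csv(
        path,
        sep="\t",
        keep_default_na=False,
        na_values=["n/a"],
        encoding="utf-8",
    )
    for col in ("valid",):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_table(table: pd.DataFrame, path, index: bool = False) -> None:
    """Generic TSV writer used for scored amplitudes, switch records, etc."""
    table.to_csv(path, sep="\t", index=index, na_rep="n/a", encoding="utf-8")
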