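"""Behavioral metrics: block accuracy and single-trial choice switching.

Accuracy is the percentage of correct responses among *valid* learnable
trials per block (misses, multiple presses, and too-fast/too-slow responses
are excluded from numerator and denominator).  Choice switching asks, for
every valid trial, whether the response on the next valid trial with the
same stimulus differed; the final occurrence of a stimulus carries a
missing switch value, and invalid trials are skipped when searching
forward (they carry no response to compare).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["block_accuracy", "choice_switching"]

GROUP_KEYS = ["participant", "session"]


def block_accuracy(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant x session x block accuracy on valid learnable trials.

    Returns columns participant, session, block, n_valid, accuracy
    (percent).  Blocks without any valid learnable trial yield NaN.
    """
    t = trials.copy()
    t["_learnable_valid"] = (t["learnability"] == "learnable") & t["valid"].astype(bool)

    def _acc(g: pd.DataFrame) -> pd.Series:
        sel = g[g["_learnable_valid"]]
        n = len(sel)
        acc = 100.0 * sel["correct"].astype(float).mean() if n else np.nan
        return pd.Series({"n_valid": n, "accuracy": acc})

    out = (
        t.groupby(GROUP_KEYS + ["block"], sort=True)
        .apply(_acc, include_groups=False)
        .reset_index()
    )
    out["n_valid"] = out["n_valid"].astype(int)
    return out


def choice_switching(trials: pd.DataFrame) -> pd.DataFrame:
    """Single-trial switch flags with their conditioning factors.

    For each valid trial, switch = 1 if the response side on the next valid
    trial with the same stimulus differs, 0 if it is the same, and missing
    (NaN) when no later valid same-stimulus trial exists.  Invalid trials
    are skipped in the forward search and produce no record.  Conditioning
    factors carried along: feedback valence, response type
    (correct/false; missing for distractor stimuli), session (feedback
    timing), and block of the *current* trial.
    """
    records = []
    for keys, g in trials.groupby(GROUP_KEYS, sort=False):
        g = g.sort_values("trial_index")
        valid = g[g["valid"].astype(bool)]
        by_stim = {s: sub for s, sub in valid.groupby("stimulus_id", sort=False)}
        for s, sub in by_stim.items():
            responses = sub["response"].to_numpy()
            switches = np.full(len(sub), np.nan)
            switches[:-1] = (responses[1:] != responses[:-1]).astype(float)
            for (idx, row), sw in zip(sub.iterrows(), switches):
                learnable = row["learnability"] == "learnable"
                if learnable:
                    response_type = "correct" if bool(row["correct"]) else "false"
                else:
                    response_type = None
                records.append(
                    {
                        "participant": keys[0],
                        "session": keys[1],
                        "trial_index": row["trial_index"],
                        "stimulus_id": s,
                        "block": row["block"],
                        "feedback_valence": row["feedback_valence"],
                        "learnability": row["learnability"],
                        "response_type": response_type,
                        "switch": sw,
                    }
                )
    out = pd.DataFrame.from_records(records)
    if len(out):
        out = out.sort_values(GROUP_KEYS + ["trial_index"]).reset_index(drop=True)
    return out
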