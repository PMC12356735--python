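"""Shared fixtures and independent oracles.

The oracle implementations here deliberately re-derive results with naive
step-by-step bookkeeping (dicts, explicit loops, scipy densities) so that
they stay independent of the package's vectorized/optimized code paths.
"""

from __future__ import annotations

import math

import pandas as pd
import pytest
from scipy import stats

from rlerp.simulate import AgentDistributions, simulate_cohort
from rlerp.task import TaskConfig


# ---------------------------------------------------------------------------
# likelihood replay oracle (independent of rlerp.rl)

def oracle_choice_prob(q_chosen: float, q_other: float, beta: float) -> float:
    num = math.exp(beta * q_chosen)
    return num / (num + math.exp(beta * q_other))


def oracle_penalized_nll(
    trials: list[tuple[str, str, str]],
    alphas: dict[tuple[str, str], float],
    beta: float,
    q_init: float = 0.5,
    gamma_shape: float = 2.0,
    gamma_scale: float = 3.0,
) -> float:
    """Brute-force replay: trials are (stimulus, choice side, feedback)."""
    q: dict[tuple[str, str], float] = {}
    log_lik = 0.0
    for stim, side, feedback in trials:
        other = "right" if side == "left" else "left"
        qc = q.get((stim, side), q_init)
        qo = q.get((stim, other), q_init)
        log_lik += math.log(oracle_choice_prob(qc, qo, beta))
        reward = 1.0 if feedback == "positive" else 0.0
        q[(stim, side)] = qc + alphas[(stim, feedback)] * (reward - qc)
    return -log_lik - stats.gamma.logpdf(beta, a=gamma_shape, scale=gamma_scale)


def oracle_trajectories(
    trials: list[tuple[str, str, str]],
    alphas: dict[tuple[str, str], float],
    q_init: float = 0.5,
) -> list[tuple[float, float]]:
    """Per-trial (delta, upe) by naive replay; upe = |delta| - 0.5."""
    q: dict[tuple[str, str], float] = {}
    out = []
    for stim, side, feedback in trials:
        reward = 1.0 if feedback == "positive" else 0.0
        qc = q.get((stim, side), q_init)
        delta = reward - qc
        out.append((delta, abs(delta) - 0.5))
        q[(stim, side)] = qc + alphas[(stim, feedback)] * delta
    return out


# ---------------------------------------------------------------------------
# choice-switching pairing oracle (independent of rlerp.behavior)

def oracle_switches(trials: list[tuple[str, str, bool]]) -> list[float]:
    """Trials are (stimulus, response, valid); returns one switch flag per
    VALID trial (1/0/nan) by exhaustive forward search."""
    flags = []
    for i, (stim, resp, valid) in enumerate(trials):
        if not valid:
            continue
        flag = float("nan")
        for stim2, resp2, valid2 in trials[i + 1 :]:
            if valid2 and stim2 == stim:
                flag = float(resp2 != resp)
                break
        flags.append(flag)
    return flags


def trials_frame(trials: list[tuple[str, str, str]]) -> pd.DataFrame:
    """Build a minimal fit-ready trial table from (stimulus, side, feedback)."""
    return pd.DataFrame(
        {
            "stimulus_id": [t[0] for t in trials],
            "response": [t[1] for t in trials],
            "feedback_valence": [t[2] for t in trials],
        }
    )


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def task_config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def small_cohort(task_config):
    """Events + true parameters for a 2+2-participant cohort (both sessions)."""
    events, truth = simulate_cohort(
        task_config, AgentDistributions(), n_patients=2, n_controls=2, seed=123
    )
    return events, truth
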