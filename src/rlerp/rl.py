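"""Rescorla-Wagner action-value model with softmax choice rule.

The learner keeps one action value ``Q`` per (stimulus, response side) and
updates the chosen action after feedback::

    delta_t = R_t - Q_{a,t}
    Q_{a,t+1} = Q_{a,t} + alpha * delta_t

with reward coded R = 1 (positive feedback) / 0 (negative feedback) and a
separate learning rate alpha for each stimulus x feedback-valence pair.
Choices follow a softmax over the two action values with a single inverse
temperature beta.  Fitting maximises the penalized likelihood

    -sum_t log p(choice_t)  -  log GammaPDF(beta; shape=2, scale=3)

(i.e. MAP estimation with a gamma prior that discourages extreme beta) via
bounded multi-start local optimization, alpha in [0, 1], beta in (0, 50].

Single-trial regressors: the signed prediction error delta and the centered
unsigned prediction error uPE = |delta| - 0.5 in [-0.5, 0.5] (increasing
with surprise; a configuration switch flips to 0.5 - |delta|).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "AgentParams",
    "FitConfig",
    "FitResult",
    "rw_update",
    "softmax_prob",
    "penalized_nll",
    "fit_participant",
    "compute_trial_pes",
]

SIDES = ("left", "right")
VALENCES = ("negative", "positive")  # reward coding 0 / 1

BETA_MIN = 1e-3  # open lower edge: the gamma(2, 3) log-density diverges at 0
BETA_MAX = 50.0


@dataclass(frozen=True)
class AgentParams:
    """RW/softmax parameters for one participant-session.

    ``alpha`` maps (stimulus_id, feedback_valence) -> learning rate in
    [0, 1]; ``beta`` is the softmax inverse temperature in (0, 50];
    ``q_init`` the initial action value (0.5 = indifference, which also
    makes the first-encounter uPE exactly zero).
    """

    alpha: dict[tuple[str, str], float]
    beta: float
    q_init: float = 0.5

    def __post_init__(self) -> None:
        for key, a in self.alpha.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"alpha{key} = {a} outside [0, 1]")
        if not 0.0 <= self.beta <= BETA_MAX:
            raise ValueError(f"beta = {self.beta} outside [0, {BETA_MAX}]")

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": {f"{s}|{v}": a for (s, v), a in self.alpha.items()},
                "beta": self.beta,
                "q_init": self.q_init,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AgentParams":
        raw = json.loads(text)
        alpha = {tuple(k.split("|")): v for k, v in raw["alpha"].items()}
        return cls(alpha=alpha, beta=raw["beta"], q_init=raw["q_init"])


@dataclass(frozen=True)
class FitConfig:
    """Settings for penalized maximum-likelihood fitting."""

    gamma_shape: float = 2.0
    gamma_scale: float = 3.0
    n_starts: int = 20
    tol: float = 1e-7
    seed: int = 0
    upe_direction: str = "surprise"  # "surprise": |d|-0.5; "expectedness": 0.5-|d|

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("gamma penalty parameters must be positive")
        if self.upe_direction not in ("surprise", "expectedness"):
            raise ValueError("upe_direction must be 'surprise' or 'expectedness'")


@dataclass
class FitResult:
    """Outcome of fitting one participant-session."""

    params: AgentParams
    objective: float  # penalized negative log-likelihood
    nll: float  # unpenalized negative log-likelihood
    converged: bool
    trajectories: pd.DataFrame  # per-trial q_chosen, q_unchosen, delta, upe, p_choice
    n_trials: int = 0
    n_starts_ok: int = 0


def rw_update(q: float, reward: float, alpha: float) -> tuple[float, float]:
    """One Rescorla-Wagner step: returns (q_next, delta)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha = {alpha} outside [0, 1]")
    delta = reward - q
    return q + alpha * delta, delta


def softmax_prob(q_chosen: float, q_other: float, beta: float) -> float:
    """Softmax probability of the chosen action (numerically stable)."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    x = beta * (q_other - q_chosen)
    # p = 1 / (1 + exp(x)); guard exp overflow for large beta * gap
    if x > 0:
        return math.exp(-x) / (1.0 + math.exp(-x))
    return 1.0 / (1.0 + math.exp(x))


def _encode_trials(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Map a valid-trial table to (stimulus index, choice index, reward) arrays."""
    required = {"stimulus_id", "response", "feedback_valence"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns: {sorted(missing)}")
    if len(trials) == 0:
        raise ValueError("empty trial list")
    stimuli = list(dict.fromkeys(trials["stimulus_id"]))
    stim_idx = np.array([stimuli.index(s) for s in trials["stimulus_id"]], dtype=np.intp)
    choice = np.array([SIDES.index(r) for r in trials["response"]], dtype=np.intp)
    reward = np.array(
        [1.0 if v == "positive" else 0.0 for v in trials["feedback_valence"]]
    )
    return stim_idx, choice, reward, stimuli


def _replay_nll_py(
    stim_idx: np.ndarray,
    choice: np.ndarray,
    reward: np.ndarray,
    alpha: np.ndarray,  # (n_stim, 2): columns negative/positive feedback
    beta: float,
    q_init: float,
) -> float:
    """Negative log-likelihood of the choice sequence under RW + softmax."""
    n_stim = alpha.shape[0]
    q = np.full((n_stim, 2), q_init)
    nll = 0.0
    for t in range(stim_idx.size):
        s = stim_idx[t]
        c = choice[t]
        r = reward[t]
        x = beta * (q[s, 1 - c] - q[s, c])  # -beta * (q_chosen - q_other)
        if x > 0:
            nll += x + math.log1p(math.exp(-x))
        else:
            nll += math.log1p(math.exp(x))
        q[s, c] += alpha[s, int(r)] * (r - q[s, c])
    return nll


try:  # JIT-compile the replay loop; fitting calls it tens of thousands of times
    from numba import njit

    _replay_nll = njit(cache=False)(_replay_nll_py)
except ImportError:  # pragma: no cover
    _replay_nll = _replay_nll_py


def _alpha_matrix(params: AgentParams, stimuli: list[str]) -> np.ndarray:
    alpha = np.empty((len(stimuli), 2))
    for i, s in enumerate(stimuli):
        for j, v in enumerate(VALENCES):
            try:
                alpha[i, j] = params.alpha[(s, v)]
            except KeyError:
                raise ValueError(f"params lack alpha for stimulus {s!r}, valence {v!r}")
    return alpha


def penalized_nll(params: AgentParams, trials: pd.DataFrame, config: FitConfig) -> float:
    """Penalized objective: NLL minus the gamma log-density of beta."""
    stim_idx, choice, reward, stimuli = _encode_trials(trials)
    alpha = _alpha_matrix(params, stimuli)
    nll = _replay_nll(stim_idx, choice, reward, alpha, params.beta, params.q_init)
    penalty = stats.gamma.logpdf(params.beta, a=config.gamma_shape, scale=config.gamma_scale)
    return nll - penalty


def fit_participant(
    trials: pd.DataFrame, config: FitConfig | None = None, q_init: float = 0.5
) -> FitResult:
    """Fit RW/softmax parameters to one participant-session by multi-start
    bounded optimization of the penalized likelihood.

    One learning rate per stimulus x feedback valence plus a shared beta.
    Start points are drawn uniformly within the parameter bounds under
    ``config.seed``; the best converged start wins (ties broken by first
    occurrence).  Deterministic given (data, config).
    """
    config = config or FitConfig()
    stim_idx, choice, reward, stimuli = _encode_trials(trials)
    n_stim = len(stimuli)
    n_par = 2 * n_stim + 1

    shape, scale = config.gamma_shape, config.gamma_scale
    log_norm = shape * math.log(scale) + math.lgamma(shape)

    def objective(x: np.ndarray) -> float:
        alpha = x[: 2 * n_stim].reshape(n_stim, 2)
        beta = x[-1]
        logpdf = (shape - 1.0) * math.log(beta) - beta / scale - log_norm
        return _replay_nll(stim_idx, choice, reward, alpha, beta, q_init) - logpdf

    bounds = [(0.0, 1.0)] * (2 * n_stim) + [(BETA_MIN, BETA_MAX)]
    rng = np.random.default_rng(config.seed)
    best: optimize.OptimizeResult | None = None
    n_ok = 0
    for _ in range(config.n_starts):
        x0 = np.empty(n_par)
        x0[: 2 * n_stim] = rng.uniform(0.0, 1.0, size=2 * n_stim)
        x0[-1] = rng.uniform(BETA_MIN, BETA_MAX)
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds, tol=config.tol
        )
        if not np.isfinite(res.fun):
            continue
        if res.success:
            n_ok += 1
        # prefer converged starts; within a tier, strictly lower objective
        # wins and ties keep the first occurrence
        if (
            best is None
            or (res.success and not best.success)
            or (res.success == best.success and res.fun < best.fun - 1e-12)
        ):
            best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed with non-finite objectives")

    x = best.x
    alpha = {
        (s, v): float(np.clip(x[2 * i + j], 0.0, 1.0))
        for i, s in enumerate(stimuli)
        for j, v in enumerate(VALENCES)
    }
    params = AgentParams(alpha=alpha, beta=float(x[-1]), q_init=q_init)
    nll = _replay_nll(
        stim_idx, choice, reward, _alpha_matrix(params, stimuli), params.beta, q_init
    )
    traj = compute_trial_pes(trials, params, direction=config.upe_direction)
    return FitResult(
        params=params,
        objective=float(best.fun),
        nll=float(nll),
        converged=bool(n_ok > 0),
        trajectories=traj,
        n_trials=len(trials),
        n_starts_ok=n_ok,
    )


def compute_trial_pes(
    trials: pd.DataFrame, params: AgentParams, direction: str = "surprise"
) -> pd.DataFrame:
    """Replay a trial sequence under fixed parameters.

    Returns one row per input trial with the chosen/unchosen action values
    before update, the softmax probability of the observed choice, the
    signed prediction error delta, and the centered unsigned prediction
    error uPE (``|delta| - 0.5`` for direction="surprise", ``0.5 - |delta|``
    for "expectedness").
    """
    if direction not in ("surprise", "expectedness"):
        raise ValueError("direction must be 'surprise' or 'expectedness'")
    stim_idx, choice, reward, stimuli = _encode_trials(trials)
    alpha = _alpha_matrix(params, stimuli)
    q = np.full((len(stimuli), 2), params.q_init)
    rows = []
    for t in range(stim_idx.size):
        s, c, r = stim_idx[t], choice[t], reward[t]
        p = softmax_prob(q[s, c], q[s, 1 - c], params.beta)
        q_next, delta = rw_update(q[s, c], r, alpha[s, int(r)])
        upe = abs(delta) - 0.5 if direction == "surprise" else 0.5 - abs(delta)
        rows.append(
            {
                "q_chosen": q[s, c],
                "q_unchosen": q[s, 1 - c],
                "p_choice": p,
                "delta": delta,
                "upe": upe,
            }
        )
        q[s, c] = q_next
    out = pd.DataFrame(rows, index=trials.index)
    return out


def save_fit(result: FitResult, json_path, tsv_path) -> None:
    """Serialize a fit: parameters/objective as JSON, trajectories as TSV."""
    meta = {
        "params": json.loads(result.params.to_json()),
        "objective": result.objective,
        "nll": result.nll,
        "converged": result.converged,
        "n_trials": result.n_trials,
    }
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=1)
    result.trajectories.to_csv(tsv_path, sep="\t", index=True, na_rep="n/a")
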