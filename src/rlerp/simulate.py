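"""Synthetic-study generator with known ground truth.

Produces complete synthetic data sets for every stage of the pipeline:

* cohorts of RW/softmax agents performing the probabilistic learning task
  in both feedback-timing sessions (immediate, delayed) with
  criterion-triggered stimulus-set switches, ninth-block logic, and a small
  rate of invalid trials;
* single-trial FRN/P3a/P3b amplitudes generated from a linear model over
  the simple-coded design (participant random effects + Gaussian noise),
  with planted coefficients defaulting to the effect pattern the analysis
  is meant to detect: a feedback-valence effect on the FRN, unsigned-PE
  coding of FRN/P3a present only in controls for positive feedback, a
  feedback-timing effect on the FRN in controls only, and a
  timing-by-valence unsigned-PE pattern on the P3b in controls;
* continuous two-channel EEG (FCz-role, Pz-role) in which ERP components
  are embedded such that the scoring chain recovers the planted amplitudes
  exactly in the zero-noise limit.

Patients and controls differ only through the planted ERP coefficients;
behaviorally the groups are exchangeable by default.  All randomness flows
through explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import mixedlm
from .rl import AgentParams, compute_trial_pes
from .task import TaskConfig, apply_learning_criterion, draw_feedback, generate_schedule, validate_trial

__all__ = [
    "AgentDistributions",
    "EffectSpec",
    "WaveformSpec",
    "simulate_cohort",
    "attach_true_pes",
    "simulate_erp_amplitudes",
    "simulate_continuous_eeg",
]

SESSIONS = ("immediate", "delayed")
SIDES = ("left", "right")


@dataclass(frozen=True)
class AgentDistributions:
    """Sampling distributions for true agent parameters.

    Learning rates are uniform on [0.05, 0.65] per stimulus x valence and
    inverse temperatures log-uniform on [1, 15] — the ranges typically
    recovered for human learners when rewards are coded 0/1.
    """

    alpha_low: float = 0.05
    alpha_high: float = 0.65
    beta_low: float = 1.0
    beta_high: float = 15.0

    def sample(self, stimuli: list[str], rng: np.random.Generator) -> AgentParams:
        alpha = {
            (s, v): float(rng.uniform(self.alpha_low, self.alpha_high))
            for s in stimuli
            for v in ("negative", "positive")
        }
        beta = float(np.exp(rng.uniform(np.log(self.beta_low), np.log(self.beta_high))))
        return AgentParams(alpha=alpha, beta=beta)


def _session_stimuli(session: str, stimulus_set: int, config: TaskConfig) -> list[str]:
    tag = "A" if session == "immediate" else "B"
    return [f"{tag}{stimulus_set}_s{i}" for i in range(config.n_stimuli)]


def _correct_side(stim_index: int) -> str:
    return SIDES[stim_index % 2]


def simulate_session(
    participant: str,
    group: str,
    session: str,
    session_day: int,
    params: AgentParams,
    config: TaskConfig,
    rng: np.random.Generator,
    p_miss: float = 0.01,
    p_too_fast: float = 0.01,
    p_multi_press: float = 0.01,
    p_too_slow: float = 0.005,
) -> pd.DataFrame:
    """Simulate one participant-session of the task.

    The agent chooses via softmax over RW-updated action values (updated on
    every responded trial using its valence- and stimulus-specific learning
    rate).  Per-block learnable accuracy drives the learning-criterion
    logic: a switch to a fresh stimulus set when exceeded by block 2 (the
    agent's values for the new stimuli start at q_init), and a ninth block
    when never exceeded through block 8.
    """
    schedule = generate_schedule(config, seed=int(rng.integers(2**31)))
    delay_ms = 500 if session == "immediate" else 6500
    stimulus_set = 0
    stimuli = _session_stimuli(session, 0, config)
    q: dict[str, list[float]] = {s: [params.q_init, params.q_init] for s in stimuli}
    for s in stimuli:
        _require_alphas(params, s)

    rows: list[dict] = []
    block_accs: list[float] = []
    trial_index = 0
    switched = False

    def run_block(block_num: int, order, fixations) -> None:
        nonlocal trial_index
        n_corr = n_valid = 0
        for stim_i, fix in zip(order, fixations):
            sid = stimuli[stim_i]
            learnable = stim_i < config.n_learnable
            beta = params.beta
            dq = q[sid][0] - q[sid][1]
            p_left = 1.0 / (1.0 + np.exp(-beta * dq))
            response = "left" if rng.random() < p_left else "right"
            n_presses = 1
            rt = float(rng.lognormal(6.45, 0.35))
            u = rng.random()
            if u < p_miss:
                response, rt, n_presses = "none", float("nan"), 0
            elif u < p_miss + p_too_fast:
                rt = float(rng.uniform(0.0, 99.0))
            elif u < p_miss + p_too_fast + p_multi_press:
                n_presses = 2
            elif u < p_miss + p_too_fast + p_multi_press + p_too_slow:
                rt = float(rng.uniform(3001.0, 3400.0))
            valid = validate_trial(rt, n_presses, response)

            if response == "none":
                feedback = None
            else:
                feedback = draw_feedback(
                    "learnable" if learnable else "unlearnable",
                    _correct_side(stim_i) if learnable else None,
                    response,
                    config,
                    rng,
                )
                # the agent learns from any delivered feedback
                side = SIDES.index(response)
                r = 1.0 if feedback == "positive" else 0.0
                a = params.alpha[(sid, feedback)]
                q[sid][side] += a * (r - q[sid][side])

            correct: float | None
            if learnable and valid:
                correct = float(response == _correct_side(stim_i))
                n_valid += 1
                n_corr += int(correct)
            else:
                correct = None
            rows.append(
                {
                    "participant": participant,
                    "group": group,
                    "session": session,
                    "session_day": session_day,
                    "block": block_num,
                    "trial_index": trial_index,
                    "stimulus_id": sid,
                    "learnability": "learnable" if learnable else "unlearnable",
                    "stimulus_set": stimulus_set,
                    "response": response,
                    "rt_ms": rt,
                    "n_presses": n_presses,
                    "valid": valid,
                    "correct": correct,
                    "feedback_valence": feedback,
                    "fixation_ms": fix,
                    "feedback_delay_ms": delay_ms,
                }
            )
            trial_index += 1
        block_accs.append(n_corr / n_valid if n_valid else float("nan"))

    for b in range(config.n_blocks):
        run_block(b + 1, schedule.blocks[b], schedule.fixation_ms[b])
        decision = apply_learning_criterion(block_accs, config)
        if decision == "switch_stimulus_set" and not switched and b + 1 < config.n_blocks:
            switched = True
            stimulus_set = 1
            stimuli = _session_stimuli(session, 1, config)
            for s in stimuli:
                _require_alphas(params, s)
                q[s] = [params.q_init, params.q_init]
    if not switched and apply_learning_criterion(block_accs, config) == "add_ninth_block":
        extra = generate_schedule(config, seed=int(rng.integers(2**31)))
        run_block(config.n_blocks + 1, extra.blocks[0], extra.fixation_ms[0])
    return pd.DataFrame(rows)


def _require_alphas(params: AgentParams, stimulus: str) -> None:
    for v in ("negative", "positive"):
        if (stimulus, v) not in params.alpha:
            raise ValueError(f"agent parameters lack alpha for {(stimulus, v)}")


def simulate_cohort(
    config: TaskConfig,
    distributions: AgentDistributions,
    n_patients: int,
    n_controls: int,
    seed: int,
) -> tuple[pd.DataFrame, dict[str, AgentParams]]:
    """Simulate a full cohort: every participant completes both sessions.

    Session order is counterbalanced deterministically by participant
    parity.  Returns the concatenated events table and the true agent
    parameters per participant (covering the stimulus sets of both
    sessions).  Groups differ only in their labels; planted group effects
    enter at the ERP-amplitude stage.
    """
    rng = np.random.default_rng(seed)
    all_stimuli = [
        s
        for session in SESSIONS
        for stim_set in (0, 1)
        for s in _session_stimuli(session, stim_set, config)
    ]
    frames = []
    truth: dict[str, AgentParams] = {}
    roster = [(f"sub-pat-{i + 1:02d}", "patient") for i in range(n_patients)] + [
        (f"sub-con-{i + 1:02d}", "control") for i in range(n_controls)
    ]
    for k, (pid, group) in enumerate(roster):
        params = distributions.sample(all_stimuli, rng)
        truth[pid] = params
        order = SESSIONS if k % 2 == 0 else tuple(reversed(SESSIONS))
        for day, session in enumerate(order, start=1):
            cfg = replace(
                config, feedback_delay_ms=500 if session == "immediate" else 6500
            )
            frames.append(
                simulate_session(pid, group, session, day, params, cfg, rng)
            )
    events = pd.concat(frames, ignore_index=True)
    return events, truth


def attach_true_pes(
    events: pd.DataFrame,
    truth: dict[str, AgentParams],
    direction: str = "surprise",
) -> pd.DataFrame:
    """Add delta/upe columns computed by replaying each participant-session
    under its *true* generative parameters.  Only valid, responded trials
    with feedback receive values; other rows carry NaN."""
    out = events.copy()
    out["delta"] = np.nan
    out["upe"] = np.nan
    usable = out["valid"].astype(bool) & out["feedback_valence"].notna()
    for (pid, _), idx in out[usable].groupby(["participant", "session"]).groups.items():
        sub = out.loc[idx]
        traj = compute_trial_pes(sub, truth[pid], direction=direction)
        out.loc[idx, "delta"] = traj["delta"].to_numpy()
        out.loc[idx, "upe"] = traj["upe"].to_numpy()
    return out


def _slope_pattern_to_terms(
    cell_slopes: dict[tuple[float, float], float]
) -> dict[str, float]:
    """Solve coefficients (b0, bg, bv, bgv) of
    slope(g, v) = b0 + bg*g + bv*v + bgv*g*v from four +-0.5 cell slopes."""
    g = np.array([k[0] for k in cell_slopes])
    v = np.array([k[1] for k in cell_slopes])
    y = np.array(list(cell_slopes.values()))
    X = np.column_stack([np.ones(4), g, v, g * v])
    b = np.linalg.solve(X, y)
    return {"upe": b[0], "group:upe": b[1], "valence:upe": b[2], "group:valence:upe": b[3]}


def _default_frn_terms() -> dict[str, float]:
    terms = {
        "1": 2.9,
        "valence": 0.65,
        "group": -1.61,
        "timing": -1.20,
        "group:timing": 2.06,
    }
    # unsigned-PE slope 0.98 for control/positive, 0 in the other cells
    terms.update(
        _slope_pattern_to_terms(
            {(-0.5, 0.5): 0.98, (-0.5, -0.5): 0.0, (0.5, 0.5): 0.0, (0.5, -0.5): 0.0}
        )
    )
    return terms


def _default_p3a_terms() -> dict[str, float]:
    terms = {"1": 5.2, "valence": 0.57}
    terms.update(
        _slope_pattern_to_terms(
            {(-0.5, 0.5): 1.95, (-0.5, -0.5): 0.0, (0.5, 0.5): 0.0, (0.5, -0.5): 0.0}
        )
    )
    return terms


def _default_p3b_terms() -> dict[str, float]:
    # control unsigned-PE slopes by (timing, valence): delayed/positive 2.36,
    # delayed/negative -0.97, immediate/positive 1.18, immediate/negative 0;
    # patient slopes all 0.  Solved over the 8 coefficients involving upe.
    cells = {}
    slopes_c = {(0.5, 0.5): 2.36, (0.5, -0.5): -0.97, (-0.5, 0.5): 1.18, (-0.5, -0.5): 0.0}
    for (t, v), s_c in slopes_c.items():
        cells[(-0.5, t, v)] = s_c
        cells[(0.5, t, v)] = 0.0
    g = np.array([k[0] for k in cells])
    t = np.array([k[1] for k in cells])
    v = np.array([k[2] for k in cells])
    y = np.array(list(cells.values()))
    X = np.column_stack([np.ones(8), g, t, v, g * t, g * v, t * v, g * t * v])
    b = np.linalg.solve(X, y)
    names = [
        "upe",
        "group:upe",
        "timing:upe",
        "valence:upe",
        "group:timing:upe",
        "group:valence:upe",
        "timing:valence:upe",
        "group:timing:valence:upe",
    ]
    terms = {"1": 5.0}
    terms.update({n: float(c) for n, c in zip(names, b)})
    return terms


@dataclass
class EffectSpec:
    """Planted linear-model structure for the single-trial ERP amplitudes.

    ``<outcome>_terms`` map model terms (coded-predictor products joined by
    ':', '1' for the intercept) to fixed coefficients in microvolts (per
    unit uPE for terms containing it).  ``random_sd`` gives per-participant
    random-effect SDs by term, ``resid_sd`` the residual SD.  Any term
    named in an analysis model but absent here is implicitly zero.
    """

    frn_terms: dict[str, float] = field(default_factory=_default_frn_terms)
    p3a_terms: dict[str, float] = field(default_factory=_default_p3a_terms)
    p3b_terms: dict[str, float] = field(default_factory=_default_p3b_terms)
    random_sd: dict[str, float] = field(
        default_factory=lambda: {"1": 5.0, "timing": 1.0, "valence": 0.5}
    )
    resid_sd: float = 6.0

    def __post_init__(self) -> None:
        if self.resid_sd < 0 or any(sd < 0 for sd in self.random_sd.values()):
            raise ValueError("standard deviations must be non-negative")


def _term_column(term: str, coded: pd.DataFrame) -> np.ndarray:
    if term == "1":
        return np.ones(len(coded))
    value = np.ones(len(coded))
    for var in term.split(":"):
        if var not in coded.columns:
            raise ValueError(
                f"term {term!r} names predictor {var!r} unknown to the coding scheme"
            )
        value = value * coded[var].to_numpy(dtype=float)
    return value


def simulate_erp_amplitudes(
    events_pe: pd.DataFrame,
    effects: EffectSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate single-trial FRN/P3a/P3b amplitudes for a cohort.

    Input: events table with true uPE attached (see
    :func:`attach_true_pes`).  Only valid trials with feedback receive
    amplitudes.  Each outcome is an independent linear model:
    amplitude = sum(coef * coded term) + participant random effects +
    Gaussian noise.
    """
    effects = effects or EffectSpec()
    rng = np.random.default_rng(seed)
    usable = events_pe["valid"].astype(bool) & events_pe["feedback_valence"].notna()
    table = events_pe[usable].copy()
    coded = mixedlm.code_predictors(table)

    participants = sorted(table["participant"].unique())
    out = table.copy()
    for outcome, terms in (
        ("frn", effects.frn_terms),
        ("p3a", effects.p3a_terms),
        ("p3b", effects.p3b_terms),
    ):
        mu = np.zeros(len(table))
        for term, coef in terms.items():
            mu += coef * _term_column(term, coded)
        # participant random effects, independent across outcomes
        for term, sd in effects.random_sd.items():
            offsets = dict(zip(participants, rng.normal(0.0, sd, len(participants))))
            ranef = table["participant"].map(offsets).to_numpy(dtype=float)
            mu += ranef * _term_column(term, coded)
        noise = rng.normal(0.0, effects.resid_sd, len(table)) if effects.resid_sd else 0.0
        out[outcome] = mu + noise
    return out


@dataclass(frozen=True)
class WaveformSpec:
    """Shape parameters of the synthetic feedback-locked waveform.

    The FCz-role channel carries a fixed-depth negative Gaussian FRN
    component (center inside the 200-350 ms search window), a plateau
    component whose height sets the planted single-trial FRN amplitude,
    and a P3 bump confined to 300-500 ms; the Pz-role channel carries only
    its own P3 bump.  All components vanish in the baseline window, so the
    scoring chain recovers the planted amplitudes exactly at zero noise.
    """

    sfreq: float = 1000.0
    frn_center_ms: float = 250.0
    frn_sigma_ms: float = 20.0
    frn_depth_uv: float = 2.0
    noise_sd_uv: float = 4.0

    def __post_init__(self) -> None:
        if not 220.0 <= self.frn_center_ms <= 330.0:
            raise ValueError("FRN component center must sit inside the scoring window")
        if self.frn_depth_uv <= 0:
            raise ValueError("frn_depth_uv must be positive")


def _bases(times_ms: np.ndarray, spec: WaveformSpec) -> dict[str, np.ndarray]:
    t = times_ms
    frn = -np.exp(-((t - spec.frn_center_ms) ** 2) / (2 * spec.frn_sigma_ms**2))
    plateau = np.zeros_like(t)
    up = (t >= 150) & (t < 200)
    plateau[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - 150) / 50))
    plateau[(t >= 200) & (t <= 300)] = 1.0
    down = (t > 300) & (t <= 350)
    plateau[down] = 0.5 * (1 + np.cos(np.pi * (t[down] - 300) / 50))
    p3 = np.zeros_like(t)
    inside = (t >= 300) & (t <= 500)
    p3[inside] = np.sin(np.pi * (t[inside] - 300) / 200.0) ** 2
    # 25-Hz background ripple: keeps clean epochs above the flat-activity
    # rejection threshold without touching any scored quantity.  Its period
    # (40 ms) divides the 200-ms baseline, so the discrete baseline mean is
    # exactly zero, and its support avoids the FRN search window and the
    # P3 window on the frontocentral channel ([-200, 200) and [500, 600)),
    # extending to [-200, 300) on the parietal channel which is only scored
    # over 300-500 ms.
    wave = np.sin(2 * np.pi * 25.0 * t / 1000.0)
    ripple_fcz = np.where((t < 200) | (t >= 500), wave, 0.0)
    ripple_pz = np.where((t < 300) | (t >= 500), wave, 0.0)
    return {
        "frn": frn,
        "plateau": plateau,
        "p3": p3,
        "ripple_fcz": ripple_fcz,
        "ripple_pz": ripple_pz,
    }


class ContinuousEEG(NamedTuple):
    """One participant-session of synthetic continuous EEG."""

    signal: np.ndarray  # (channels, samples), microvolts
    onsets_ms: np.ndarray  # feedback onsets relative to recording start
    channel_names: list[str]
    channel_roles: dict[str, str]
    artifact_trials: np.ndarray  # indices of trials with injected spikes


def simulate_continuous_eeg(
    erp_table: pd.DataFrame,
    waveform: WaveformSpec | None = None,
    seed: int = 0,
    artifact_rate: float = 0.0,
) -> ContinuousEEG:
    """Render one participant-session's planted amplitudes as continuous EEG.

    ``erp_table`` must hold the trials of a single participant-session with
    ``frn``/``p3a``/``p3b`` target amplitudes and a ``feedback_delay_ms``
    column; inter-trial spacing respects the feedback-timing condition
    (longer for delayed feedback).  Returns (signal (2 channels x samples),
    feedback onsets in ms, channel names, channel roles).  With
    ``artifact_rate`` > 0 the corresponding fraction of trials receives a
    200-uV spike, which the artifact rejection should flag; the injected
    trial indices are returned.
    """
    spec = waveform or WaveformSpec()
    rng = np.random.default_rng(seed)
    if erp_table[["participant", "session"]].drop_duplicates().shape[0] != 1:
        raise ValueError("erp_table must hold exactly one participant-session")
    n_trials = len(erp_table)
    delay = float(erp_table["feedback_delay_ms"].iloc[0])
    spacing_ms = 2000.0 + delay  # response-to-feedback delay dominates the ITI
    if spacing_ms < 900.0:
        raise RuntimeError("trial spacing would overlap successive epochs")
    sf = spec.sfreq
    epoch_t = (np.arange(int(round(0.8 * sf))) / sf - 0.2) * 1000.0
    bases = _bases(epoch_t, spec)

    score_sel = np.abs(epoch_t - spec.frn_center_ms) <= 20.0
    p3_sel = (epoch_t >= 300.0) & (epoch_t <= 500.0)
    f_frn = bases["frn"][score_sel].mean()
    f_p3 = bases["frn"][p3_sel].mean()
    w_p3 = bases["plateau"][p3_sel].mean()
    p_p3 = bases["p3"][p3_sel].mean()

    total = int(round((1000.0 + spacing_ms * n_trials + 1000.0) * sf / 1000.0))
    signal = np.zeros((2, total))
    onsets_ms = 1000.0 + spacing_ms * np.arange(n_trials)
    d = spec.frn_depth_uv
    artifact_trials = set(np.nonzero(rng.random(n_trials) < artifact_rate)[0])
    for i, (_, row) in enumerate(erp_table.iterrows()):
        m = row["frn"] - d * f_frn  # plateau height hits the FRN target
        b_fcz = (row["p3a"] - m * w_p3 - d * f_p3) / p_p3
        b_pz = row["p3b"] / p_p3
        start = int(round((onsets_ms[i] - 200.0) * sf / 1000.0))
        sl = slice(start, start + epoch_t.size)
        signal[0, sl] += (
            m * bases["plateau"]
            + d * bases["frn"]
            + b_fcz * bases["p3"]
            + 0.3 * bases["ripple_fcz"]
        )
        signal[1, sl] += b_pz * bases["p3"] + 0.3 * bases["ripple_pz"]
        if i in artifact_trials:
            at = start + int(round(rng.uniform(0.25, 0.75) * epoch_t.size))
            signal[:, at : at + 5] += 200.0
    if spec.noise_sd_uv:
        signal += rng.normal(0.0, spec.noise_sd_uv, signal.shape)
    return ContinuousEEG(
        signal=signal,
        onsets_ms=onsets_ms,
        channel_names=["FCz", "Pz"],
        channel_roles={"frn_p3a": "FCz", "p3b": "Pz"},
        artifact_trials=np.array(sorted(artifact_trials), dtype=int),
    )
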