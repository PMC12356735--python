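"""Probabilistic feedback-based learning task engine.

Implements the task structure used throughout the package: eight blocks of
40 trials (four stimuli, ten presentations each per block), two learnable
stimuli with response-contingent 90/10 feedback, two distractor stimuli with
response-independent 50/50 feedback, a 65 %-correct learning criterion that
triggers a stimulus-set switch when exceeded within the first two blocks and
a ninth block when never exceeded, and trial-validity rules (responses
faster than 100 ms or slower than 3000 ms, multiple presses, and misses are
invalid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import yaml

__all__ = [
    "TaskConfig",
    "TaskSchedule",
    "CriterionDecision",
    "generate_schedule",
    "draw_feedback",
    "apply_learning_criterion",
    "validate_trial",
    "load_config",
]

CriterionDecision = Literal["switch_stimulus_set", "add_ninth_block", "continue"]


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the probabilistic learning task.

    Defaults reproduce the published task: 8 blocks x 40 trials = 320 trials
    per session, four stimuli (two learnable, two distractors), 90 % positive
    feedback for correct responses to learnable stimuli, 50 % for
    distractors, a strict 65 % learning criterion evaluated through block 2,
    and feedback shown either 500 ms (immediate) or 6500 ms (delayed) after
    the response.
    """

    n_blocks: int = 8
    trials_per_block: int = 40
    n_stimuli: int = 4
    n_learnable: int = 2
    p_reward_correct: float = 0.90
    p_reward_distractor: float = 0.50
    learning_criterion: float = 0.65
    criterion_block: int = 2
    feedback_delay_ms: int = 500
    rt_min_ms: float = 100.0
    rt_max_ms: float = 3000.0
    fixation_min_ms: float = 500.0
    fixation_max_ms: float = 1500.0
    reward_pos_label: str = "+20ct"
    reward_neg_label: str = "−10ct"

    def __post_init__(self) -> None:
        for name in ("p_reward_correct", "p_reward_distractor", "learning_criterion"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.n_blocks < 1 or self.trials_per_block < 1 or self.n_stimuli < 1:
            raise ValueError("counts must be positive")
        if self.trials_per_block % self.n_stimuli != 0:
            raise ValueError(
                "trials_per_block must be divisible by n_stimuli for equal "
                "stimulus presentation"
            )
        if not 0 < self.n_learnable <= self.n_stimuli:
            raise ValueError("n_learnable must be in 1..n_stimuli")
        if not self.rt_min_ms < self.rt_max_ms:
            raise ValueError("rt_min_ms must be below rt_max_ms")
        if self.feedback_delay_ms not in (500, 6500):
            raise ValueError("feedback_delay_ms must be 500 (immediate) or 6500 (delayed)")

    @property
    def total_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def presentations_per_block(self) -> int:
        return self.trials_per_block // self.n_stimuli


@dataclass(frozen=True)
class TaskSchedule:
    """Per-block stimulus presentation order plus fixation jitter.

    ``blocks[b][i]`` is a stimulus index in ``0..n_stimuli-1``; indices below
    ``n_learnable`` denote learnable stimuli.  ``fixation_ms`` mirrors the
    block structure with uniform 500-1500 ms fixation durations (logged for
    realism, unused by the analyses).
    """

    blocks: tuple[tuple[int, ...], ...]
    fixation_ms: tuple[tuple[float, ...], ...] = field(repr=False)

    @property
    def n_trials(self) -> int:
        return sum(len(b) for b in self.blocks)


def generate_schedule(config: TaskConfig, seed: int) -> TaskSchedule:
    """Generate a pseudo-random presentation schedule.

    Each block contains every stimulus exactly ``trials_per_block /
    n_stimuli`` times in shuffled order.  Reproducible under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    blocks: list[tuple[int, ...]] = []
    fixations: list[tuple[float, ...]] = []
    base = np.repeat(np.arange(config.n_stimuli), config.presentations_per_block)
    for _ in range(config.n_blocks):
        order = rng.permutation(base)
        blocks.append(tuple(int(s) for s in order))
        fix = rng.uniform(config.fixation_min_ms, config.fixation_max_ms, size=base.size)
        fixations.append(tuple(float(f) for f in fix))
    return TaskSchedule(blocks=tuple(blocks), fixation_ms=tuple(fixations))


def draw_feedback(
    learnability: str,
    correct_side: str | None,
    response: str,
    config: TaskConfig,
    rng: np.random.Generator,
) -> str:
    """Draw feedback valence for a responded trial.

    Distractor ("unlearnable") stimuli yield positive feedback with
    probability 0.5 regardless of the response.  Learnable stimuli yield
    positive feedback with probability 0.9 when the correct side was chosen
    and 0.1 otherwise.
    """
    if response not in ("left", "right"):
        raise ValueError("draw_feedback requires a given response ('left'/'right')")
    if learnability == "unlearnable":
        p_pos = config.p_reward_distractor
    elif learnability == "learnable":
        if correct_side is None:
            raise ValueError("learnable stimuli need a correct_side")
        p_pos = (
            config.p_reward_correct
            if response == correct_side
            else 1.0 - config.p_reward_correct
        )
    else:
        raise ValueError(f"unknown learnability {learnability!r}")
    return "positive" if rng.random() < p_pos else "negative"


def apply_learning_criterion(
    block_accuracies: Sequence[float], config: TaskConfig
) -> CriterionDecision:
    """Evaluate the learning criterion on per-block learnable accuracies.

    ``block_accuracies`` holds accuracies (proportions of correct responses
    on valid learnable trials) of the blocks completed so far.  Returns
    ``"switch_stimulus_set"`` if accuracy strictly exceeded the criterion in
    any block up to ``criterion_block``, ``"add_ninth_block"`` if all
    ``n_blocks`` blocks finished without ever exceeding it, and
    ``"continue"`` otherwise.  The criterion is strict ("exceeded"), so a
    block at exactly 65 % does not trigger either rule.
    """
    accs = list(block_accuracies)
    if not accs:
        raise ValueError("block_accuracies must not be empty")
    thresh = config.learning_criterion
    for i, a in enumerate(accs[: config.criterion_block], start=1):
        if a is not None and not np.isnan(a) and a > thresh:
            return "switch_stimulus_set"
    if len(accs) >= config.n_blocks and not any(
        a is not None and not np.isnan(a) and a > thresh for a in accs
    ):
        return "add_ninth_block"
    return "continue"


def validate_trial(rt_ms: float | None, n_presses: int, response: str | None) -> bool:
    """Trial-validity rule: invalid iff too fast, too slow, multiple presses,
    or no response."""
    if response is None or response == "none" or n_presses == 0:
        return False
    if n_presses > 1:
        return False
    if rt_ms is None or np.isnan(rt_ms):
        return False
    return 100.0 <= rt_ms <= 3000.0


def load_config(path) -> TaskConfig:
    """Read a TaskConfig from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in TaskConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown task config keys: {sorted(unknown)}")
    return TaskConfig(**raw)
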