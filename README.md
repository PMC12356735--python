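# rlerp

Reinforcement-learning ERP pipeline: a tested, reusable implementation of
a single-trial EEG analysis chain for probabilistic feedback-based
learning, exercised entirely on synthetic data with known ground truth.

The scientific question this pipeline serves is how the brain codes reward
prediction errors during feedback learning — for example, whether
unsigned-prediction-error coding in feedback-locked ERP components (FRN,
P3a, P3b) is intact in a patient group, and how it depends on feedback
timing. Answering that requires a long chain: a probabilistic learning
task, a trial-level learning model supplying per-trial prediction errors,
single-trial ERP amplitude extraction, and mixed-model inference. Every
link is implemented and testable here without any patient data.

## What it does

* **Task simulation** (`rlerp.task`, `rlerp.simulate`): 8 blocks x 40
  trials, two learnable stimuli (90/10 response-contingent feedback), two
  distractors (50/50), immediate (500 ms) vs delayed (6500 ms) feedback
  sessions, a strict 65 % learning criterion with stimulus-set switching
  and ninth-block logic, and trial-validity rules (100/3000 ms, multiple
  presses, misses).
* **Learning model** (`rlerp.rl`): Rescorla–Wagner action values,
  `delta_t = R_t − Q_{a,t}`, `Q_{a,t+1} = Q_{a,t} + alpha·delta_t`, with a
  softmax choice rule `p ∝ exp(beta·Q)`. One learning rate per
  stimulus x feedback valence (`alpha ∈ [0,1]`) plus a shared inverse
  temperature (`beta ∈ (0,50]`), fitted by bounded multi-start MAP with a
  gamma(shape 2, scale 3) prior on beta. Exports per-trial signed PEs and
  centered unsigned PEs (`uPE = |delta| − 0.5 ∈ [−0.5, 0.5]`).
* **ERP scoring** (`rlerp.erp`): 800-ms feedback-locked epochs
  ([−200, 600] ms, baseline [−200, 0) ms), four-rule artifact rejection,
  condition-average FRN peak localization (most negative strict local
  minimum, 200–350 ms at the FCz-role channel), single-trial FRN as the
  ±20 ms mean around that peak, and P3a/P3b as 300–500 ms means at the
  FCz-/Pz-role channels.
* **Behavioral metrics** (`rlerp.behavior`): block accuracy on valid
  learnable trials and single-trial choice switching (response change on
  the next valid same-stimulus trial).
* **Mixed models** (`rlerp.mixedlm`): the five analysis models with simple
  coding (±0.5), standardized block, Satterthwaite inference via an
  lme4/lmerTest bridge, stepwise random-structure reduction on
  convergence failure or singularity, simple-slope probing, and Cook's
  distance screening.
* **Synthetic studies** (`rlerp.simulate`): cohorts of RW/softmax agents,
  planted single-trial ERP effect structures, and continuous two-channel
  EEG from which the scoring chain recovers planted amplitudes exactly at
  zero noise.

## Worked example

```python
from rlerp.task import TaskConfig
from rlerp.simulate import (AgentDistributions, EffectSpec, attach_true_pes,
                            simulate_cohort, simulate_erp_amplitudes)
from rlerp.rl import FitConfig, fit_participant
from rlerp.behavior import choice_switching
from rlerp import mixedlm

config = TaskConfig()
events, truth = simulate_cohort(config, AgentDistributions(),
                                n_patients=4, n_controls=4, seed=7)

sw = choice_switching(events)
by_val = sw[sw.learnability == "learnable"].groupby("feedback_valence")["switch"].mean()
print(f"switch rate after negative {by_val['negative']:.2f} "
      f"vs positive {by_val['positive']:.2f} feedback")

sub = events[(events.participant == "sub-con-01")
             & (events.session == "immediate")
             & events.valid & events.feedback_valence.notna()]
fit = fit_participant(sub, FitConfig(n_starts=10, seed=0))
print(f"fitted beta {fit.params.beta:.2f} (true {truth['sub-con-01'].beta:.2f})")

pe = attach_true_pes(events, truth)                 # uPE from true parameters
erp = simulate_erp_amplitudes(pe, EffectSpec(), seed=8)
design = mixedlm.code_predictors(erp, carry=("frn",))
spec = mixedlm.MLMSpec(response="frn", fixed="group*timing*upe*valence",
                       random_terms=("timing",))
result = mixedlm.fit_mlm(design, spec)
row = result.coefficients.loc["valence"]
print(f"FRN valence effect: beta = {row.estimate:.2f}, "
      f"t({row.df:.1f}) = {row.t:.2f}, p = {row.p:.3g}")
print(mixedlm.probe_simple_slopes(result, "upe", ["group", "valence"])
      .round(3).to_string(index=False))
```

prints

```
switch rate after negative 0.54 vs positive 0.11 feedback
fitted beta 3.14 (true 2.41)
FRN valence effect: beta = 0.60, t(4968.7) = 3.02, p = 0.00254
  group  valence  estimate    se       df      t     p
patient positive    -0.458 0.557 4483.662 -0.823 0.411
patient negative    -0.386 0.695 4540.918 -0.556 0.578
control positive     1.310 0.583 4904.837  2.244 0.025
control negative    -1.096 0.749 4964.065 -1.464 0.143
```

Reading the output: agents switch responses far more after negative than
positive feedback (0.54 vs 0.11), the fitted inverse temperature lands
near its generative value, the planted 0.65-µV FRN valence effect is
detected (estimate 0.60 µV with Satterthwaite df), and the planted
unsigned-PE coding pattern — present only for controls with positive
feedback — emerges in the simple slopes even at this small 8-participant
scale (slope 1.31, p = .025; all other cells non-significant).

A complete synthetic study directory (events table, true parameters,
trial PEs, planted ERP amplitudes) can also be generated from the shell:

```
rlerp simulate --out study/ --n-patients 21 --n-controls 25 --seed 1
```

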