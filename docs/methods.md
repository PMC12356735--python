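# Methods

`rlerp` implements a complete analysis chain for probabilistic
feedback-based learning with concurrent EEG, exercised end to end on
synthetic data with known ground truth. This note documents the models,
the defaults and why they were chosen, the numerical decisions, and what
the synthetic data can and cannot show.

## Task model

The task presents four abstract stimuli per session, 8 blocks x 40 trials
(= 320 trials), each stimulus 10 times per block in randomized order. Two
stimuli are *learnable*: choosing their correct side yields positive
feedback ("+20ct") with probability 0.9 and negative feedback ("−10ct")
with probability 0.1; the incorrect side mirrors these probabilities. Two
*distractor* stimuli return positive feedback with probability 0.5
regardless of the response (Bernoulli per trial, not balanced per block).
Two sessions differ only in feedback timing: feedback appears 500 ms
(immediate) or 6500 ms (delayed) after the response.

Learning-criterion logic: if accuracy on valid learnable trials strictly
exceeds 65 % in a block no later than the second, a fresh stimulus set is
introduced (once per session) to generate more pre-learning trials; if the
criterion is never exceeded through block 8, a ninth block is appended.
Trials are invalid when the response comes within 100 ms of stimulus onset,
later than 3000 ms, with multiple presses, or not at all; invalid trials
are excluded from accuracy, switching, and model fitting. Boundary
convention: RTs of exactly 100 or 3000 ms count as valid, and a block at
exactly 65 % does not trigger either criterion rule.

## Learning model

Per stimulus, the agent keeps one action value `Q` per response side,
initialized at `q_init = 0.5`, updated only for the chosen side:

    delta_t   = R_t − Q_{a,t}
    Q_{a,t+1} = Q_{a,t} + alpha * delta_t

Rewards are coded `R = 1` (positive) / `0` (negative). This coding keeps
`Q` in [0, 1] and `|delta|` in [0, 1], which is what makes the centered
unsigned prediction error `uPE = |delta| − 0.5` span exactly [−0.5, 0.5];
the monetary magnitudes (+20/−10 ct) are labels, not reward values.
Choices follow a softmax with a single inverse temperature `beta`:

    p(a1) = exp(beta*Q_{a1}) / (exp(beta*Q_{a1}) + exp(beta*Q_{a2}))

computed in the numerically stable log-sum form, so `beta = 50` with a unit
value gap is exact to better than 1e−6.

One learning rate is fitted per stimulus x feedback valence (8 per
session under the default four-stimulus set) plus one shared `beta`.
Fitting minimizes the penalized objective

    −sum_t log p(choice_t) − log GammaPDF(beta; shape 2, scale 3)

i.e. MAP estimation with a gamma prior on `beta` that discourages extreme
values. Bounds: `alpha` in [0, 1], `beta` in [1e−3, 50] — the lower edge is
open because the gamma(2, 3) log-density diverges at 0. Optimization is
multi-start L-BFGS-B (default 20 starts, drawn uniformly within bounds
under the fit seed); the best converged start wins and ties keep the first
occurrence, so refits are bit-reproducible. Distractor trials enter the
likelihood like any other stimulus.

The sign convention for the centered unsigned PE deserves a note: `uPE`
*increases* with surprise (`|delta| − 0.5`). The opposite centering
(`0.5 − |delta|`, increasing with expectedness) is available via
`FitConfig.upe_direction` / `compute_trial_pes(direction=...)`; the default
was chosen so that a positive uPE slope on an ERP amplitude means "larger
response to more surprising feedback".

### Parameter identifiability

The recovery study in the test suite (50 agents, one 320-trial session
each, 20 optimizer starts) shows that `beta` recovers well (rank
correlation with truth above 0.7) while per-stimulus, per-valence
learning rates recover only coarsely under truth
alpha ~ Uniform(0.05, 0.65). This is an information limit of the design,
not of the optimizer: each learnable stimulus contributes ~80 trials of
which ~10 % carry negative feedback, and once a decisive agent performs at
ceiling its choices stop informing the positive-feedback learning rate;
the same estimator converges toward truth as trials per stimulus grow.
Single-trial PE regressors are nevertheless usable because they are
dominated by the well-identified `Q` trajectory.

## ERP scoring

Epochs span 800 ms, −200 to +600 ms around feedback onset, sampled at
1000 Hz; the per-channel mean of the [−200, 0) ms window is subtracted.
Artifact rejection flags an epoch when any scored channel shows: a
sample-to-sample step above 50 uV/ms; any absolute value above 100 uV; a
max-minus-min range above 100 uV within the epoch; or a max-minus-min
range below 0.1 uV inside any sliding 100-ms window (1-sample stride,
windows fully inside the epoch). By default only the channels carrying
scoring roles (FCz-role, Pz-role) are checked; the channel list is
configurable.

FRN scoring is two-stage. For each participant and condition (feedback
timing x valence x learnability by default — the factors of the
statistical models), the retained-trial average at the FCz-role channel is
searched for the most negative *strict* local minimum with latency
strictly inside 200-350 ms (endpoints excluded; a sample must be lower
than both neighbours; ties take the earliest). Single trials are then
scored as the mean amplitude from 20 ms before to 20 ms after that latency
(41 samples at 1000 Hz). Conditions without a detectable peak propagate as
outlier-flagged missing amplitudes. P3a (FCz-role) and P3b (Pz-role) are
mean amplitudes over 300-500 ms; the FRN and P3a windows overlap on
300-350 ms by construction, and both are scored from the same epoch.

Optional continuous-signal preprocessing (0.1-30 Hz band-pass and 50 Hz
notch, applied through MNE's filtering routines) mirrors a standard ERP
pipeline; the synthetic data are generated artifact-light, so ocular
correction is out of scope.

## Behavioral metrics

Accuracy is the percentage of correct responses among valid learnable
trials per block; blocks with no such trials are missing. Choice switching
is defined per valid trial as whether the response on the *next valid*
trial with the same stimulus differs; the final occurrence of a stimulus
is missing. Invalid trials are skipped in the forward search because they
carry no response to compare. Response type (correct/false) is undefined
for distractor trials and propagates as missing.

## Statistical models

Five linear mixed models are templated (`mixedlm.MODEL_TEMPLATES`), one
per outcome: block accuracy, single-trial switch flags, and single-trial
FRN/P3a/P3b amplitudes. All categorical predictors are simple coded at
+-0.5 (patient/delayed/positive/learnable/correct = +0.5), block is
standardized over the modeled rows, and the centered unsigned PE enters as
a continuous predictor. The ERP models use the full five-way factorial
fixed part `group x timing x uPE x valence x learnability`.

Models are fitted with lme4/lmerTest through an Rscript bridge (bobyqa
optimizer), so fixed-effect tests carry genuine Satterthwaite degrees of
freedom. Each template names a maximal per-participant random-slope
structure; on a convergence failure or singular fit the structure is
reduced stepwise — random interaction terms before random main effects,
higher order first, last-listed first within an order — and the realized
structure is reported. The intercept-only structure is accepted even when
singular, since nothing is left to delete; the fixed part is never
altered. Switch flags are modeled as Gaussian responses by default (the
coefficients are then risk differences); a binomial `glmer` family is
available but off by default.

Simple slopes of a focal predictor at each crossing of +-0.5 moderator
levels are linear combinations of fixed coefficients, tested as single-df
Satterthwaite contrasts (`lmerTest::contest1D`) on a refit of the realized
model. Influence screening offers observation-level Cook's distances
(leverage formula, identical to lme4's `cooks.distance`) and exact
delete-one-participant distances via refits; both flag at 4/n by default
(n = observations or participants respectively). Note that on perfectly
homogeneous mixed-model data the observation-level 4/n rule still flags a
nontrivial fraction of points because mixed-model hat values absorb the
random effects — the flags are a screen, and removal is the caller's
decision. A participant-level mean shift is invisible to observation-level
(conditional-residual) distances and requires the participant-level mode.

## Synthetic-data generator

`simulate_cohort` runs RW/softmax agents (default 21 patients + 25
controls, matching the analyzed sample) through both sessions with
deterministic parity counterbalancing of session order. True agent
parameters are drawn per participant: `alpha ~ Uniform(0.05, 0.65)` per
stimulus x valence and `beta ~ LogUniform(1, 15)`, the ranges typically
recovered for human learners under 0/1 reward coding. Invalid trials are
injected at realistic rates (1 % misses, 1 % too-fast, 1 % multi-press,
0.5 % too-slow). Groups are behaviorally exchangeable by default,
mirroring the absence of a group accuracy effect; group differences are
planted only in the ERP amplitudes.

Single-trial amplitudes are linear in the coded design:
`amplitude = sum(coef x term) + participant random effects + noise`, with
per-outcome defaults planting the effect pattern the analysis is built to
detect: an FRN valence effect (0.65 uV), an FRN group effect (−1.61 uV), a
feedback-timing effect present in controls only (timing −1.20 with
group x timing 2.06, giving a control simple slope of −2.23), uPE coding
of FRN (slope 0.98) and P3a (1.95) present only for controls with positive
feedback, and a P3b uPE-by-timing-by-valence pattern confined to controls
(2.36 / −0.97 / 1.18 / 0 across the four timing x valence cells). The
uPE-term coefficients are solved exactly from these cell-slope patterns.
Random-effect SDs default to 5 uV (intercept), 1 uV (timing slope), 0.5 uV
(valence slope) with 6 uV residual, so the total single-trial SD (~7.8 uV)
matches typical frontocentral single-trial variability.

Continuous EEG embeds, per trial, a fixed-depth negative Gaussian FRN
component (center 250 ms, sigma 20 ms, depth 2 uV), a plateau component
over 150-350 ms whose height is solved so the windowed FRN score equals
the planted amplitude, and a half-cosine-squared P3 bump confined to
300-500 ms solved for the planted P3 mean; the parietal channel carries
only its P3 bump. A 0.3 uV 25-Hz background ripple keeps clean epochs
above the flat-activity rejection threshold; its 40-ms period divides the
200-ms baseline, so the discrete baseline mean is exactly zero, and its
support avoids every scoring window. Consequently, at zero noise the full
chain — continuous signal, segmentation, baseline, peak detection,
windowed means — returns the planted amplitudes to float precision, which
is the round-trip property the tests assert. Inter-trial spacing is
2000 ms plus the feedback delay, so delayed sessions produce longer
recordings. Optional artifacts are 200 uV spikes injected into a chosen
fraction of trials.

### What the synthetic data do not show

The generator's ERP model is the analysis model: passing recovery tests
demonstrates that the pipeline estimates what was planted, not that real
EEG satisfies the linearity, Gaussianity, or independence assumptions. The
waveforms lack 1/f noise, ocular artifacts, component-latency jitter, and
volume conduction; the behavioral agents lack lapses, fatigue, and
side biases. Group labels carry no behavioral consequence by default.

## Problem sizes and verification

The test suite verifies: exhaustive likelihood equivalence with a
brute-force replay oracle over all 4,680 sequences of length <= 4 of a
two-stimulus toy; parameter recovery over 50 agents x 320 trials;
an exact zero-noise ERP round trip over 120 trials with 10 % planted
artifacts; type-I calibration of the accuracy-model group coefficient over
500 null replicates of a 46-participant study (rate within 0.05 +- 0.02);
and majority-vote recovery of the planted FRN simple-slope pattern over
three replicate 46-participant cohorts. The slope-pattern check is
replicated because each null cell retains the nominal 5 % false-positive
rate, so a single-cohort "all null cells silent" assertion would fail
roughly one run in seven even when the method is correct.
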