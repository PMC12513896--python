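# Methods

## The paradigm being modelled

The package simulates and analyses a gamified, web-based mouse-tracking
task for spoken-word recognition.  On every trial two objects fall from
the top of the screen, each wiggling horizontally inside its own corridor
on one side of the screen, while a spoken sentence plays that names one of
them.  The participant steers a spaceship (slaved to the cursor's
horizontal position) under the target object and may end the trial early
with a mouse click ("tractor beam"); otherwise the trial ends when the
objects reach the point just above the spaceship.  A catch counts as
correct when the final ship–target distance is under 5% of the screen
width.  The primary dependent measure is the *decision time*: the start of
the last continuous cursor movement that ends inside the target's
corridor, extracted from the cursor trace.

The package's purpose is measurement validation at the desk: because the
simulator knows each synthetic participant's latent commitment time, the
full preprocessing/extraction/modelling pipeline can be tested for
parameter recovery, exclusion behaviour, and type-I calibration without
collecting data.

## Coordinates and geometry

x ∈ [−0.5, +0.5] in screen widths (0 = centre, where cursor and spaceship
start), y ∈ [0, 1] bottom→top.  Corridors are closed intervals,
mirror-symmetric about 0; the defaults [−0.40, −0.08] / [+0.08, +0.40] are
free parameters of this implementation (the paradigm fixes only that each
object stays on its own side), as is the ship height.  A cursor sample
exactly on a corridor boundary counts as inside.

## Trial dynamics

* Fall duration: `max(base_fall_s, target_onset_s + min_post_onset_s)`
  with defaults 3 s and 2 s.  Target onsets span 0.73–3.26 s into the
  audio, so fall durations span 3–5.26 s.  The per-frame descent is
  `(top_y − bottom_y) / (fall_s · fps)`.  The frame count is the *ceiling*
  of `fall_s · fps`, so the emitted log never ends before the nominal fall
  end and the ≥ 2 s post-onset guarantee holds on the data as logged.
* Horizontal wiggle: per frame and per object, a uniform draw below
  1/40 flips the heading; a step that would leave the corridor flips
  instead (boundary precedence; at most one flip per frame, and the draw
  is consumed either way).  Horizontal speed defaults to 0.25 screen
  widths/s — an object crosses its 0.32-wide corridor in about 1.3 s.
* Termination: click after audio offset → end at click + 200 ms; click
  during audio → end 200 ms after audio offset; no click → end when the
  objects reach `bottom_y`.  All animations freeze at the click; frames
  emitted during the tail repeat the frozen state (a click during the tail
  is ignored).
* Host heterogeneity: logs can be emitted at 30/60/75/144 fps with ±1 ms
  timestamp jitter to exercise the regridder.  The original experiment's
  frame-rate-estimation trial is emulated by this knob, not reimplemented.

Internally a trial is simulated in a target-oriented frame (target
positive) and mapped to screen coordinates by a final sign flip, and the
guessed side and cursor noise are drawn in that oriented frame.  A trial
and its mirrored twin (same seed, target side swapped) are therefore
*exact* negations of each other — the basis of the end-to-end
mirror-invariance test.  Each trial's randomness comes from its own
`default_rng(seed)` in a fixed draw order, so logs are bit-identical
functions of (config, seed) regardless of batch composition.

## Synthetic participants

An agent holds the cursor at the centre until its commitment time
(relative to target onset), then relaxes exponentially toward the chosen
object's current position:

    c_i = α · c_{i−1} + (1 − α) · o_i,   α = exp(−1 / (fps · track_lag_s))

Commitment = participant baseline + condition shifts + item shift +
N(0, commit_noise_sd).  White positional noise (`jitter_sd`) is added to
the *emitted* sample only.  Clickers click `click_delay_s` after
committing, at the first frame within the catch tolerance of the chosen
object; non-clickers never click and so contribute no reaction times.
With probability `guess_prob` the agent instead commits to a random side
before onset — correct guesses produce always-on-target trials (decision
time undefined), and guess-driven clicks before onset exercise the
early-click screen.

Defaults (population): baseline 550 ± 80 ms, commitment noise 150 ms,
reduction cost +50 ms and similar-competitor cost +130 ms (each varying
±20 ms across participants), item intercepts ±50 ms and item-level
reduction-effect deviations ±20 ms, tracking lag 150 ms, click delay
350 ms, jitter SD 0.005 screen widths, 80% clickers, 5% guessers.  These
were chosen once to land in the paradigm's observed regime (decision
times ≈ 450–600 ms, reaction times ≈ 1 s, most participants clicking)
and to make both random intercepts and random slopes real rather than
degenerate.

The relaxation-tracking policy was chosen over minimum-jerk trajectories
for its single interpretable lag parameter; nothing in the paradigm
constrains the movement model.  What the generator does **not** emulate:
real motor kinematics (velocity profiles, overshoot), attention lapses,
learning/fatigue over a session, device differences beyond a grouping
column, or audio-driven incremental evidence (commitment is a single
latent time, not a drift process).  Passing recovery tests therefore
demonstrate that the *pipeline* is faithful, not that real data will be
this clean.

## Session design

96 experimental trials — 71 critical (34 /h/-initial, 37 vowel-initial
i.e. glottal-stop-initial, each item once per session) + 25 semantic
fillers — preceded by 5 practice trials, with performance-overview pauses
at trials 30/60/90.  32 pre-compiled orders; the within-item factors
(segment present/deleted; similar/unrelated competitor) alternate across
orders from a seeded per-item parity, so each item occurs in each
condition in exactly half the orders (how the original orders balanced
assignment is unstated; this Latin-square-like alternation is our
choice).  Target sides are an exactly balanced seeded permutation per
order.  Filler count 25 is forced by 96 − 71.

## Preprocessing

Nearest-in-time regridding (no interpolation) onto −0.5…+2.0 s at 60 Hz
(151 points; the count is derived in exact rational arithmetic so it
cannot be off by one).  Ties between equidistant samples resolve to the
earlier one; grid points past the last observation take the last observed
position (padding, `pad_from` recorded); points before the first take the
first (participants start clicked-in at the centre).  Orientation
multiplies x by −1 on left-target trials so positive always means closer
to the target.

## Decision-time extraction

Each oriented sample is 't' if inside the positive-side corridor, else
'l'/'r'/'s' by the sign of the step against a stability threshold
eps = 10⁻³ screen widths (far below any intentional per-frame movement at
60 Hz; sample 0 outside the corridor is 's').  The decision time is the
grid time of the first 'l' of the maximal contiguous 'l' run ending at the
*latest* 'lt' bigram; when the latest 'st' bigram lies later (or no 'lt'
exists), the time of that pair's 't' sample — the moment of single-frame
corridor entry — is used instead.  Conventions fixed here:

* 'l' means *toward the target on the oriented axis*, not literal screen
  left.
* The backtrack run is contiguous 'l' only; an interposed 's' (a pause)
  ends it, so a stalled-and-resumed approach dates from the resumption.
* For the 'st' fallback the reported sample is the 't' (corridor entry).
* All-'t' strings → NA "always_on_target"; strings without any 't' — and
  the rare strings with 't' but neither an 'lt' nor an 'st' bigram (trial
  started on target and left for good) — → NA "never_reached_target".
* Negative decision times are legal (the grid starts 0.5 s before onset)
  and arise from pre-onset guesses.

Movement-direction changes are counted as sign alternations of the
eps-thresholded step sequence.

## Screening

In order: (1) participants with strictly less than 70% correct catches are
excluded; (2) trials with a click before target onset, or a routine longer
than (strictly) 5.2 s measured from animation start, are dropped;
(3) always-on-target losses are counted at extraction.  Reaction time is
defined as click time − target onset.  RT trimming fits an intercept-only
model with crossed participant and item random effects (statsmodels
variance components, REML), computes conditional residuals from
closed-form BLUPs, and removes rows with |residual|/σ̂ > 3; if the crossed
fit fails or is degenerate it falls back to grand-mean standardization and
reports that.  The 5.2 s cutoff is taken relative to routine start (the
alternative — audio start — is not distinguishable from the paradigm
description).

## Statistical models

Predictors are contrast-coded ±0.5 with the "more" level positive:
segment present +0.5, /h/ +0.5, target-predictable (unrelated second
object) +0.5.  Facilitation therefore appears as negative weights.

Decision-time models are linear mixed models with crossed participant and
item random effects, fitted by REML through lme4/lmerTest (Rscript), with
the standard simplification ladder executed inside one R process: full
correlated random structure first; on non-convergence or singularity drop
the correlations, then random slopes one at a time — interaction slopes
first, then the slope with the smallest estimated variance — down to
crossed intercepts.  If nothing on the ladder is both converged and
non-singular, the last converged (singular) fit is accepted and flagged.
For the reduction design the maximal by-item structure carries the cue
slope only: segment is between-item, and the by-item interaction slope is
collinear with the by-item cue slope.  Degrees of freedom and p-values are
Satterthwaite approximations (lmerTest), named in every `ModelFit`.  A
statsmodels variance-components backend (crossed intercepts, Wald z) is
provided as an independent cross-check and is compared against the lme4
route in the test suite.

Within-participant error bars: cell values are centered per participant
(subtract participant mean, add grand mean), the cell SE of centered
values is multiplied by Morey's correction √(J/(J−1)) and the t quantile.
Participants with incomplete cells are dropped from the CI and counted.

The time-course analysis is a percentile cluster bootstrap (B = 2000,
resampling participants) of the per-participant condition-difference
curves, reporting maximal runs of grid points whose band excludes zero.
It deliberately stands in for a GAMM binary-smooth analysis; its windows
estimate the same contrast but are not expected to coincide with GAMM
windows, and no multiplicity correction across grid points is applied
beyond the cluster resampling.

## Numerical and degenerate-input choices

* Relaxation paths are computed with a first-order IIR filter
  (`scipy.signal.lfilter`); the zero-lag limit copies the object path.
* `track_lag_s = 0`, empty effect maps, all-equal RT tables (σ̂ ≈ 0 → no
  trimming), single-frame logs (fully padded trajectories), and
  boundary-sitting cursor samples are all defined and tested.
* Catch adjudication and both screening thresholds are strict
  inequalities, as worded in the task description.

## Problem sizes in the test suite

Property suites run at 10⁴ random state strings, 10⁴ simulated trials for
corridor/timing contracts, 200 trials for mirror invariance, and 20
replicates of 40 participants × 96 trials for recovery and null
calibration — sizes at which the binomial/SE arithmetic in each test is
meaningful while the whole suite stays desk-scale.

## Known limitations

* The lme4 backend requires `Rscript` with lme4/lmerTest on the PATH; the
  pure-Python backend fits crossed intercepts only.
* The simplification ladder cannot fit correlated random effects in the
  statsmodels backend, so "drop correlations" is only exercised via R.
* Decision-time monotonicity in the latent commitment holds for
  uninterrupted approaches; a wiggling object can stall a noiseless
  approach below eps, legitimately re-dating the movement start.
* The adapter for the original experiment's CSV dialect is a stub: the
  reader validates this package's documented schema only.
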