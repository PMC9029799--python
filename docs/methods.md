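# Methods

This note documents the models, algorithms and design choices behind the
package, in the order the pipeline runs them.

## Scientific setting

Vagally-mediated heart-rate variability (HRV), indexed by the RMSSD of
interbeat intervals, falls both under metabolic load and under psychosocial
stress. The *additional HRV reduction* (AddHRVr) idea separates the two: a
per-person regression of minute-level RMSSD on activity energy expenditure
(AEE) predicts the metabolically *expected* RMSSD, and only drops of the
observed RMSSD meaningfully below that expectation count as candidate
stress responses. A simple online rule turns these minute-level flags into
sparse binary triggers that a smartphone could use to prompt the wearer.
The package simulates such algorithms over recorded or generated
participant-days and evaluates, by cluster-bootstrapped multilevel
modelling, whether a given algorithm setting predicts objectively coded
increases of stress.

## Data model

A participant-day is a contiguous 0-based minute grid (any length; a full
day is 1440 minutes). Each minute carries RMSSD (ms), AEE (kcal expended
in that minute, i.e. kcal/min), a validity flag from artifact screening,
and optionally an ordinal objective stress level: 0 = routine work at the
station, 1 = routine operation, 2 = emergency operation. Gaps are explicit
`valid=False` minutes so window arithmetic never shifts. Minutes with
non-positive RMSSD or negative AEE are invalidated on read; invalid
minutes are treated as missing everywhere downstream.

## Step 0 — calibration

For each participant, ordinary least squares of RMSSD on AEE over all
valid minutes of the recording (an explicit calibration sub-range is
supported for prospective use, where calibrating on the future is
impossible). Before the final fit, gross outliers are screened
iteratively: the single worst minute whose externally studentized residual
exceeds 4.0 in absolute value is invalidated and the model refitted, up to
5 removals. The threshold is set so that artifact-free days yield almost
no removals (a handful per cohort of 38), matching how sparse visual
screening of calibration scatter plots is in practice.

Two predictor conventions exist:

* **linear** — `rmssd ~ aee`; the intercept is HRV at rest, the slope
  (negative in this population) the metabolic HRV cost of movement.
* **inverse** — `rmssd ~ 1/(aee + eps)`; the intercept is HRV at very
  high movement. `eps` defaults to the 5th percentile of the positive AEE
  values, which keeps the reciprocal bounded at zero movement without
  distorting the bulk of the fit.

The fitted model also records the calibration-period RMSSD standard
deviation `sd_cal` (the unit of the decrease threshold), the mean AEE
(the reference level of the dynamic variant's activity buffer), and the
plain Pearson correlation between RMSSD and AEE, reported identically for
both predictor kinds so cohorts are comparable.

**Units.** Slopes are stored in ms per (kcal/min). Cohort summaries
report them per 1000 kcal/24 h — the convention of ambulatory HRV
reports — via the identity 1 kcal/min = 1.44 × (1000 kcal/24 h). The
summary's AEE row is the per-day total in kcal.

## Step 1 — trigger simulation

A minute is a **meaningful decrease** when

    rmssd(t) < expected_rmssd(t) − 0.5 · sd_cal

(the multiplier is a setting, default 0.5). A **trigger** fires at minute
`t` when at least `k` of the trailing `n` minutes (`t−n+1 … t`,
inclusive) are meaningful decreases and strictly more than `silent`
minutes have passed since the previous trigger (default 20). The
(`n`, `k`) grid runs over window lengths 2–30 with thresholds
1–(length−1): 435 adjustments, 870 across the static and dynamic
variants.

Expected RMSSD depends on the variant:

* **static** — the fixed calibration line `a + b·aee`.
* **dynamic** — `m(t) + b·aee`, where `m(t)` is the mean of a 60-minute
  HRV ring buffer. The buffer absorbs the observed RMSSD of a minute only
  while the trailing 40-minute mean AEE (a second ring buffer) is below
  the calibration mean; otherwise it receives the static intercept,
  because movement-loaded HRV would contaminate the resting level the
  buffer is meant to track. Both buffers start at their neutral values
  (intercept, calibration-mean AEE).
* **inverse** — the static logic on the inverse-predictor calibration.

Numerical conventions, chosen for strict causality and determinism under
signal dropouts:

* Buffers are lag-1: the intercept used at minute `t` is read before
  minute `t` is pushed, so a minute never dilutes its own threshold. A
  step change in the HRV level under low activity therefore produces an
  exactly linear 60-minute ramp of the dynamic intercept, which the tests
  assert in closed form.
* The dynamic prediction keeps the slope term, so the dynamic variant
  degenerates exactly to the static one when the buffer mean equals the
  static intercept. (The buffer mean alone would ignore concurrent
  metabolic load; keeping the slope preserves the metabolic adjustment
  that defines the method.)
* Invalid minutes are never decreases but stay inside windows (windows
  are not compacted), and they push the neutral values into the buffers.
* No trigger can fire before the first full window; the silent rule is a
  strict inequality (`t − last > silent`), so with everything flagged a
  1-of-2 rule at silent 20 fires at minutes 1, 22, 43, …
* Flags keep being computed during silence — the silent period suppresses
  prompts, not detection.

## Stress labeling

Objective stress codes are run-length encoded; a boundary is a
**transition** only when both flanking episodes last at least 20 minutes
(a parameter). Requiring the minimum on *both* sides is deliberately
conservative: it keeps the follow windows of consecutive transitions from
nesting, so a trigger is attributable to at most one transition.
Transitions are coded 1 for increases and 0 for decreases of objective
stress. A transition counts as *triggered* when at least one trigger lies
in the half-open follow window `(t, t+20]` (40 minutes as a variant); a
trigger at the transition minute itself belongs to the preceding
situation.

## Step 2 — bootstrap evaluation

Pooled transitions form a binary regression problem: outcome = direction,
predictor = trigger presence, grouping = participant. The model is a
random-intercept logistic regression with Gaussian intercepts. The
marginal likelihood is integrated per cluster by 25-node Gauss–Hermite
quadrature and maximised with L-BFGS-B over (intercept, trigger
coefficient, log intercept-SD); the log-SD is bounded in [−6, 3].
Standard errors come from the numerical Hessian at the optimum; the
p-value is the Wald z-test on the trigger coefficient (a likelihood-ratio
option exists). On a reference clustered dataset the fitter agrees with
lme4's `glmer` (nAGQ = 25) to ~1e-4 in all parameters, which one test
verifies by calling R directly; with the intercept variance constrained
to zero it collapses to plain logistic regression and reproduces the 2×2
cross-product odds ratio exactly.

Each algorithm setting is evaluated by a participant-level bootstrap
(default 500 iterations): per iteration, cohort-size participants are
drawn with replacement, their precomputed events pooled — duplicates
entering as distinct grouping units, the standard cluster-bootstrap
convention — and the model refitted. An iteration is *invalid* on
non-convergence, a constant outcome or predictor, or a zero cell in the
pooled 2×2 table (complete separation, where the odds ratio is 0 or
infinite); a setting with more than half its iterations invalid is
flagged unreliable. Reported per setting: power (share of valid
iterations with p < 0.05), mean percentage change in odds
((OR − 1) × 100, arithmetic mean over valid iterations), its 2.5/97.5
percentiles, the total triggers delivered on the original cohort, and the
mean triggered increase/decrease counts. Power-versus-sample-size curves
resample `n` participants with replacement (so `n` may exceed the cohort)
and report the smallest `n` crossing 0.70/0.80/0.90.

Every stochastic stage is a pure function of its inputs and a seed; grid
sweeps give each setting its own deterministic child seed, so restricting
or resuming a sweep never changes an individual result.

## Synthetic cohorts

The generator emulates the structure of a 24-h on-call occupational
recording with known ground truth:

* **Stress schedule** — a semi-Markov chain over levels 0/1/2 with
  shifted-geometric episode lengths floored at 20 minutes. Operation
  episodes' mean durations are derived from the target occupancy shares
  (defaults 81.4 / 11.2 / 7.4 %) given a mean routine-episode length of
  270 minutes, which yields ≈ 5 operations and ≈ 9 qualifying transitions
  per participant-day.
* **AEE** — resting baseline 0.42 kcal/min, +0.8 during routine
  operations, +1.28 during emergencies, four 20-minute exercise bouts of
  +2.5 kcal/min during routine work, Gaussian noise (SD 0.45), clipped
  positive. Daily totals average ≈ 1025 kcal.
* **RMSSD** — `intercept + slope·aee` plus stationary AR(1) noise
  (lag-1 correlation 0.6, SD 13 ms), clipped at 1 ms. Person-level
  intercepts are N(51.05, 24.04²) ms (floored at 15); slopes are
  N(−5.96, 4.46²) per 1000 kcal/24 h, mapped to ms/(kcal/min) by the 1.44
  unit constant and truncated negative. This noise split reproduces the
  reference cohort's within-person RMSSD~AEE correlation of ≈ −0.36
  alongside its RMSSD and AEE levels.
* **Planted effect** — after every *increase* of objective stress, RMSSD
  is suppressed by `effect_drop` ms (default 10) for `effect_duration`
  minutes (default 15). With `effect_drop = 0` the noise is independent
  of the schedule and the static pipeline sees an exact null.
* About 1 % of minutes are artifact-flagged.

What the generator does **not** emulate: circadian and sleep structure,
respiration-driven RMSSD dynamics, heteroscedastic or non-Gaussian HRV
noise, device-specific artifact patterns, and stress responses that vary
in size, latency or probability across occasions. Passing tests therefore
show that the pipeline is correct and sensitive under a clean, known
signal — not that any particular setting would achieve the same power on
real recordings, where the stress signature is weaker and less reliable
(a deterministic 10 ms drop after every increase is far easier to detect
than real stress responses).

## Calibration of the type-I check, and a caution on bootstrap power

The type-I calibration check runs the *static* variant: its expected-RMSSD
correction is exactly the generating model, so with `effect_drop = 0`
trigger timing is independent of transition direction. The dynamic
variant's absorption rule is itself activity-sensitive — around a stress
transition the AEE buffer lags the activity change, so the threshold
moves relative to the static one in a direction-dependent way — and its
triggers need not be direction-neutral even without a planted HRV effect.

Two further properties are worth knowing when reading bootstrap power
numbers. First, in-sample calibration (fitting the regression on the same
day that is evaluated) leaks a small amount of schedule-correlated
estimation error into the flags, which inflates between-participant
heterogeneity of the trigger–direction association. Second, the cluster
bootstrap resamples a *single* cohort, so its "power" concentrates around
that cohort's realized association rather than averaging over cohort
draws; under a null it is a noisy, right-skewed quantity, not a sharp
estimate of the 5 % level. The model-level type-I rate of the fitter
itself is checked separately on independent simulated datasets.

## Problem sizes used by the test suite and acceptance script

Cohorts of 38 participants × 1440 minutes; 500 bootstrap iterations for
single-setting evaluations and 200 for the effect-size ladder
(2 / 6 / 20 ms) and the power-versus-n curve (n = 10–80); the
engine-versus-rescan equivalence check uses 1000 random series of up to
300 minutes. Full 435-setting sweeps at 500 iterations are supported
through the library and CLI but the bundled checks evaluate reduced grids
and single settings, which already exercise every code path.

## Known limitations

* The random-intercept model assumes a homogeneous trigger effect across
  participants; heterogeneous effects widen the Wald test beyond nominal.
* The inverse variant shares the static trigger logic; a dynamic-inverse
  hybrid is not defined (the inverse intercept means HRV at *high*
  movement, so a resting-level buffer cannot replace it).
* Episode durations are shifted-geometric; real operation durations are
  heavier-tailed (the reference cohort's maximum inter-transition time is
  ~15 h).
* Bootstrap evaluation reuses cached trigger trains, which is exact
  because the engine is deterministic given the data — but it means the
  bootstrap captures sampling-of-participants uncertainty only, not
  physiological day-to-day variation.
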