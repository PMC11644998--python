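# Methods

This note documents the models implemented in `tibload`, the choices made
where the underlying methods literature leaves the design open, and what
the synthetic cohort does and does not emulate.

## Tibia force model

The tibia compression force is estimated from the insole's total plantar
force F(t) and longitudinal center of pressure CoP(t) by a quasi-static
sagittal-plane moment balance about the ankle joint center:

    F_Tibia(t) = F(t) + (CoP(t) − x) · F(t) / r

The plantar force acting at lever arm (CoP − x) about the ankle must be
balanced by Achilles tendon tension at moment arm r; that tension adds to
the axial compression carried by the bone. Parameters:

* `ankle_offset_x` (m) — horizontal distance from the back of the insole to
  the ankle joint center, measured per participant (synthetic cohort:
  uniform on 0.10–0.14 m).
* `achilles_moment_arm_r` (m) — treated as a constant 0.05 m, the standard
  simplification for this model class.

When the CoP falls behind the effective ankle pivot the formula goes
negative; the implementation clamps at zero because this mechanism cannot
load the bone in tension. The model ignores joint moments out of the
sagittal plane and any muscle besides the Achilles-equivalent term.

**Normalization.** The loading-stimulus integral is dimensionally silent,
and raw newtons raised to the fourth power produce astronomically scaled
values. `tibload` normalizes F_Tibia to bodyweights (BW) before
exponentiation, so LS is in BW⁴·s and DLS in BW^(1/2)·s^(1/8); participants
of different mass become directly comparable. `RunConfig.normalize_bw =
False` restores raw-newton mode.

## Loading stimulus and daily load stimulus

* LS_j = ∫ F_Tibia(t)^m dt over minute j, with damage exponent m = 4 (the
  value supported by animal/cadaver bone-damage work; configurable).
* DLS = (Σ_j LS_j)^(1/(2m)), treating every minute as one discrete loading
  task with one "cycle".

Numerical choices:

* Integration is trapezoidal on the native 25 Hz grid. For a half-sine
  force pulse this is near-spectrally accurate (the integrand's odd
  derivatives vanish at the pulse boundaries), and the test suite pins the
  25 Hz error below 0.5% against the analytic integral.
* Minutes are half-open intervals [t, t+60); the integral for a minute
  includes the sample at t+60 when present so adjacent minutes tile the day
  without losing boundary segments.
* A minute's LS is computed only if ≥ 90% of its expected samples are
  present (≥ 1350 of 1500 at 25 Hz); minutes below the threshold count as
  not insole-covered. DLS refuses series with missing minutes — gap-fill
  first.
* During unloaded periods a pressure insole's CoP is meaningless; the
  reader carries the last loaded CoP forward (noise floor 1 N, config).

## Tracker minute features

Consumer trackers export per-minute metrics, not raw signals. The feature
definitions used here (and applied to the synthetic wrist stream) are:

* deviation signal: |‖a‖ − 1 g| — zero for a stationary wrist regardless of
  orientation;
* activity time: seconds per minute with deviation strictly above 50 mG;
* activity level: trapezoidal area of the deviation over the minute (g·s),
  a proportional-integration measure of motion vigor;
* scaled steps / scaled activity: step count and activity time multiplied
  by the same minute's activity level.

The exact formula inside commercial firmware is unpublished; this
definition is the closest simple reading that is exactly zero at rest. Step
counting is *not* implemented as a gait algorithm — devices export a step
counter, and the synthetic cohort provides one (generator truth plus a
configurable miss rate).

## Estimation models

Both stages are L1-regularized linear regressions (LASSO):

* **Generic:** five tracker features → insole LS, trained on the pooled
  minutes of all other participants, evaluated leave-one-participant-out.
  Pooling is unweighted across participants.
* **Calibration:** {generic LS estimate} ∪ five features → insole LS,
  trained only on insole-covered minutes inside the wear window. Windows
  with fewer than 10 nonzero-LS training minutes are flagged as
  low-information (the fit still proceeds).

Fitting details (all reproducible given data + seed):

* Features are standardized to zero mean/unit variance on the training
  rows; constant features keep scale 1 and receive coefficient 0. The
  intercept is unpenalized.
* The penalty grid is data-driven: α_max·logspace(0, −4, 9) where α_max is
  the smallest penalty that zeroes every coefficient, plus λ = 0 (plain
  least squares, solved by minimum-norm lstsq). λ is selected by seeded
  5-fold cross-validation minimizing pooled out-of-fold MSE; exact ties go
  to the larger (sparser) penalty. Including λ = 0 lets noiseless
  benchmark problems reach the exact-interpolation limit; on noisy cohort
  data CV essentially never selects it.
* Predictions are clamped at zero (LS is nonnegative by construction).
* LS is modeled on its natural BW⁴·s scale; a log1p option exists behind
  `RunConfig.log1p_target` but is off by default.
* Calibration quarters/windows are contiguous in time, matching the
  wear-time framing (a user wears insoles for one block of the day, not
  random scattered minutes).

Quarter evaluation: the day's insole-covered minutes are split into four
contiguous quarters; each quarter trains a calibration that predicts the
other three; all held-out pairs are pooled into one R². Reported
cross-participant spreads are sample standard deviations (n−1).

## Wear-time simulation

Window lengths grow from 30 min in 5-min increments to the full day; each
length slides across the day with a stride chosen automatically as the
largest value giving at least 300 simulated days (the configured target
range is 300–400), with `stride_min` as an override. For each window:
calibrate inside, gap-fill outside (clamped calibrated predictions, or
generic predictions in the comparison variant), DLS over the combined
series, absolute percent error against the all-insole reference. Windows
whose calibration cannot be fitted (< 2 usable minutes) fall back to
generic gap-filling and are flagged rather than dropped, so the error rise
at very small coverage remains observable. Days with a near-zero reference
DLS (< 1e-9) are excluded from summaries with a warning.

Summaries bin days by insole coverage into left-open right-closed 5% bins
(exactly 25% falls in (20, 25]); per-participant bin means are computed
first and then averaged across participants, so participants with more
simulated days do not dominate.

The simulation day span equals the recorded span (9–10 h), not a 16-h
waking day, and the simulation requires full insole coverage of the day —
it is an experiment about *simulated* wear windows on a complete reference
recording.

### Binned-curve experiment design

The cross-seed curve experiments in the test suite use a 600-min (10 h)
day with window lengths in 30-min steps and a 60-min stride (~105 windows
per day). With these sizes every 5% bin is sampled exactly at its right
edge and the 95–100% bin contains only the complete day, which makes the
full-coverage bin an exact-zero anchor; ten generator seeds are averaged.
The R²-contrast experiments use the default cohort (8 participants, random
9–10 h days) over ten seeds.

## Synthetic cohort

The generator emulates the statistical structure the models rely on:

* **Schedule:** 9–10 h days tiled by sedentary / standing / walking /
  vigorous bouts (durations and probabilities configurable) plus two
  ~20-min exercise sessions (morning and afternoon) modeled as alternating
  moderate/vigorous minutes — a generic stand-in for a mixed
  rehabilitation battery.
* **Plantar loading:** half-sine vertical force pulses at the participant's
  cadence (stance ≈ 0.6 s, truncated below one step period), peak
  `peak_vgrf` BW (× `run_multiplier` when vigorous), CoP ramping
  heel-to-toe within each stance, multiplicative per-step amplitude noise.
  Only the right-foot-equivalent stream is generated. Ground-truth
  per-minute LS is computed analytically from the pulse parameters on a
  fine quadrature grid, split exactly at minute boundaries; the pipeline
  reproduces it within discretization error (< 1%, tested).
* **Wrist stream:** locomotor bouts produce an arm-swing oscillation whose
  amplitude scales with a participant-specific `wrist_gain` (lognormal
  across the cohort, σ = 0.5): small arm-swingers record low activity
  levels at identical tibia load. Sedentary bouts produce hand-gesture
  bursts (rate uniform on 0.5–6 events/min across participants, amplitude
  above the 50 mG gate) that inflate activity metrics while the tibia is
  unloaded. Background noise stays below the gate.
* **Confound structure:** between-participant variation in per-step load
  (peak_vgrf⁴ spans roughly a factor of three) and in wrist behavior is
  exactly what makes a pooled generic model misscale on a held-out
  participant — producing the negative R² regime — while a within-person
  calibration absorbs it.

A `CohortConfig.noise_free_linear()` preset produces a deterministic
cohort (alternating 20-min sedentary / 10-min walking, cadence 100
steps/min so the step period divides the minute, all noise off) whose LS
is *exactly* linear in the tracker step count. It is the parameter-recovery
benchmark: calibration must reach R² = 1 and zero wear-time error in this
limit.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: biofidelic gait waveforms, stairs/slopes,
clinical (post-fracture) gait, insole measurement noise and drift, device
clock desynchronization, day-to-day behavioral variability, and the
proprietary internals of commercial activity metrics. Results on the
synthetic cohort demonstrate pipeline correctness and the *mechanism* of
generic-model failure and calibration recovery, not field accuracy.

## Known limitations

* At very low insole coverage (≲ 20% of the day) calibration models built
  from a few minutes of data can gap-fill *worse* than the uncalibrated
  generic model; the binned calibrated-error curve lies above the generic
  curve there and only dominates it from moderate coverage upward. This is
  inherent to data-poor calibration and is left observable by design.
* The wear-time simulation uses a single contiguous window; real wear
  patterns may be multi-interval.
* Multi-day repeatability is out of scope; each synthetic participant
  contributes one day.
* Clock synchronization between insole and tracker is assumed perfect.
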