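# Methods

This note documents the models, numerical choices and known limitations of
`tvorsim`.

## Stimulus and geometry

The sled stimulus is an ideal trapezoidal velocity profile: constant
acceleration `a_accel` (g-units, converted with g = 9.80665 m/s²) to
`v_peak`, a constant-speed plateau of `t_const`, and constant deceleration
`a_decel` to rest. Defaults (0.26 g, 40 cm/s, 0.320 s, 0.20 g) give
156.8 ms of acceleration, 203.9 ms of deceleration and 20.016 cm of travel.
Velocity and acceleration are evaluated piecewise-analytically on the
sample grid (chair period 2 ms by default); position is the trapezoidal
integral of the sampled velocity, so that integrating the stored velocity
reproduces the stored position identically. Signs follow the right-hand
rule (leftward positive). Internal units are cm, s and deg.

Ideal eye velocity for a target at perpendicular distance *d* is the time
derivative of the gaze angle atan(x_h/d):
ω(t) = d·ẋ_h / (d² + x_h²), reported in deg/s. The source material presents
this relationship only graphically; the formula here is the unique one
consistent with the stated geometry and is verified in the tests against a
finite difference of the gaze angle.

## The dynamic model

Linear head acceleration drives, in series: the otolith block
`k(1 + T_lead·s)/(1 + T_lag·s)`; two parallel pathways — a direct gain
`G_acc` (units s) and the tVOR integrator pathway `G_i·I(s)` with
`I(s) = 1/s` or, optionally, `1/(s + 1/T)`; a transmission delay τ bounded
to [0, 75] ms; the geometry gain `(180/π)/D`; the neural integrator
`1/(s + 1/T_ni)` with `T_ni = 20 s`; and the ocular plant, a unity-DC
low-pass of first (0.25 s) or third order (0.224, 0.013, 0.004 s —
configuration, not hard-coded, since their printed source is the earlier
plant literature). The otolith block defaults to the identity
(`T_lead = T_lag`): the exact afferent constants belong to cited prior
models and all quantitative claims in the tests hold in the identity
configuration. Eye velocity is reported as the numerical time derivative of
simulated eye position.

Default free parameters are `G_i = 0.5`, `G_acc = 0.15 s`, `τ = 31 ms` at
`D = 70 cm`. Rationale: a sustained compensation of ~50% of ideal
(undercompensation in darkness, as observed in this paradigm), and an
acceleration-pathway command at peak acceleration (`0.15 × 255 ≈ 38 cm/s`)
about twice the sustained velocity command (20 cm/s), which produces the
prominent early transient of recorded step responses and places the model
in the regime where peak velocity is governed mainly by the acceleration
gain while final position is governed mainly by the integrator gain.

### Numerics

All blocks are LTI; the chain is composed symbolically as one rational
function and discretized at a 1 ms fixed step under a zero-order hold. The
discretized system is *evaluated as a parallel sum of first-order modes*
(continuous-time partial fractions, each mode given its exact ZOH
recursion): because the hold commutes with a parallel sum this equals the
ZOH solution of the composed chain, but every recursion is a
well-conditioned scalar one. A single high-order direct-form filter loses
several digits at low frequency once its discrete poles cluster near 1
(the pure integrator at 1.0 sits 5·10⁻⁵ away from the 20 s NI pole), and
discrete-domain partial fractioning cannot separate those poles either;
the continuous-domain decomposition separates them cleanly (observed
accuracy ~10⁻⁵ against analytic frequency responses). Coincident poles,
which can arise from user-configured equal time constants, are split by a
relative 10⁻⁶ perturbation — far below every tolerance used here.

The delay is applied as a fractional-sample linear-interpolation shift of
the simulated output (exactly equivalent for an at-rest LTI chain). This
keeps objective functions smooth in τ for the optimizer. The geometry stage
is the small-angle division by D; an exact time-varying
`d/(d² + x²)` option exists for comparison (for 20 cm at 70 cm it differs
from the small-angle chain by a few percent).

"Final eye position (at 500 ms)" in the leaky-integrator comparison is
measured 500 ms after motion onset. The sensitivity module's
final-position metric is instead read at the end of the simulated trace,
after the motion has stopped: measured there, final position is governed
almost entirely by the integrator pathway (the direct pathway's
contribution is proportional to head velocity, which has returned to
zero), which is the regime in which the model's characteristic sensitivity
structure — peak velocity ↦ g_a, final position ↦ g_v — holds for any
positive gain ratio. Mid-motion readings mix the two pathways and do not
separate them cleanly.

### Frequency responses

`frequency_response` drives the model with a sinusoidal head velocity
(starting at zero so the pure integrator acquires no offset), discards a
settle window of seven slowest-pole decay times, and fits
`a·sin + b·cos + c` at the known frequency to the simulated eye velocity;
gain and phase are reported relative to head velocity or head
acceleration, optionally normalized to unit gain at 1 Hz. The remaining
systematic error against the analytic transfer function is the half-sample
hold delay (0.72° of phase at 4 Hz) and <10⁻⁴ in gain over 0.01–4 Hz.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
coil-system physics: slow-phase velocity from the forward model, plus
additive Gaussian velocity noise low-passed at 50 Hz (sd 2 deg/s), plus
quick phases injected as raised-cosine velocity pulses (20–40 ms,
80–250 deg/s peak, random sign, Poisson-distributed onsets at 1/s). Pulse
amplitudes guarantee peak accelerations and jerks far above the detection
thresholds — detectability by the pipeline's own criteria, not
physiological fidelity, is the design goal. Eye position is the cumulative
integral of the velocity trace. Every trial carries its generating
parameters and quick-phase windows as ground truth; all randomness flows
from a session seed through spawned per-trial streams.

What passing tests show about real data is therefore limited: the
generator has no vergence, no target-on (pursuit-assisted) condition, no
anti-compensatory deceleration nonlinearity, no slow drift or coil
artifacts, and its noise is stationary and Gaussian. Recovery results
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness to physiology the model omits.

A post-lesion regime is modeled by scaling the two pathway gains
(defaults 0.38 for G_i, 0.87 for G_acc), reproducing the qualitative
signature of cerebellar nodulus/uvula lesions: strongly reduced sustained
velocity with a relatively preserved early transient.

## Preprocessing

Quick phases/saccades are flagged where |acceleration| > 1400 deg/s² or
|jerk| > 50,000 deg/s³ (strict inequalities, with a 10⁻⁹ relative guard so
a derivative exactly at threshold is not flagged by float round-off).
Derivatives come from Savitzky–Golay local polynomial differentiation;
window and order are configuration. The defaults (35 ms, quadratic) were
chosen so that the jerk estimator's noise floor under the generator's
default 50 Hz band-limited noise stays below threshold (~9% false
positives, 100% quick-phase detection); a 15 ms window at this noise
bandwidth flags most of the trace. Flagged runs are dilated by 10 ms per
side to remove pre/post-saccadic shoulders. Trials synchronize on the first
sample with chair speed ≥ 1 cm/s; profiles use per-sample median and
25th/75th percentiles (linear interpolation between order statistics) over
unmasked samples.

## Fitting

The linear model pools unmasked samples across all trials of one condition
and, for each latency on the 10–80 ms grid (2 ms steps, the chair sampling
period), regresses eye velocity on the delayed chair velocity and
acceleration with iteratively reweighted least squares under a Huber loss
(tuning constant 1.345, the conventional 95%-efficiency choice; backed by
statsmodels RLM with an exact-fit guard). The latency with the smallest
summed squared residual wins; ties go to the smallest latency.

The dynamic-model fit minimizes the concatenated per-sample difference
between measured and simulated eye velocity over all unmasked samples with
scipy's trust-region-reflective least-squares solver (a damped
least-squares method with bound support; classic Levenberg–Marquardt is
unbounded), bounds 0 ≤ gains, 0 ≤ τ ≤ 75 ms. Initialization is not
critical — the objective is linear in the two gains — but a seeded
multi-start (default 5, log-uniform over plausible gain ranges) guards
against delay-axis local minima; the best residual is returned, and
non-convergence is flagged rather than raised. Epoch contrasts report
per-condition percent changes with t-based 95% confidence intervals.

## Prior architectures

Three published single-integration architectures are implemented for the
comparative simulations, with their internal constants declared in
`prior_models.PRIOR_MODEL_DEFAULTS` (the authoritative values live in the
original publications; comparative test properties are robust to ±20%
variation of these defaults):

* **Telford/Paige** — leaky tVOR integrator (0.25 s) in series with a
  high-pass stage (0.05 s), then the common NI; no plant. Block order
  within the series chain is immaterial (LTI blocks commute).
* **Green & Galiana** — a single central leaky integrator with the same
  0.25 s dynamics driving a first-order plant (0.27 s), whose low-pass
  characteristic partially substitutes for the missing second integration.
* **Angelaki** — the Green/Galiana chain behind a first-order
  otolith-afferent lead-lag; the published model's canal input is omitted
  because only pure translation is simulated.

For step comparisons all outputs are scaled to a common peak eye velocity
and share the proposed model's 31 ms delay. The comparison table reports
velocity both at the end of the constant-speed plateau and at motion end:
the motion-end reading is dominated by the anti-compensatory deceleration
transient in every single-integration architecture, so the plateau-end
value is the meaningful measure of sustained-response maintenance. With
the printed constants, the Telford and Green/Galiana velocity traces agree
to ~28% RMS of peak — clearly more similar to each other than either is to
the double-integration model (>55% RMS), though not near-identical: their
high-pass corners (20 vs ~3.7 rad/s) genuinely differ on step stimuli.

## File formats

Trials are stored as tab-separated text (columns `t, chair_x, chair_v,
chair_a, eye_pos, eye_vel, mask`, floats at 17 significant digits for
bit-exact round-trips; chair signals interpolated onto the 1 kHz eye grid)
with a JSON sidecar holding schema version, condition metadata (validated
against closed vocabularies) and ground truth; sessions add a JSON
manifest with the seed. Parameters and pipeline configuration are YAML.

## Problem sizes

The test suite and the acceptance script use desk-scale problem sizes
chosen as the smallest that make each statistical check meaningful: trial
series of 2–20 trials per condition for recovery checks, 50 Monte-Carlo
replicates for bias estimation, 200 trials for the law-of-large-numbers
check, 100 trials for detector sensitivity/specificity, 21×21 grids for
the error surface, and nine frequencies spanning 0.01–4 Hz for the
frequency-response comparison.

## Known limitations

* The anti-compensatory deceleration asymmetry seen in recordings is not
  modeled; simulated responses reverse fully during deceleration.
* The target-on (visually assisted) condition has no pursuit pathway in
  the generator, so only dark-condition analyses are meaningful.
* Otolith afferent constants and prior-model internals are declared
  defaults standing in for values printed in the original modeling papers.
* The saccadic pulse-step direct pathway and semicircular-canal inputs are
  deliberately out of scope.
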