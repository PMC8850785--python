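# Methods

`painlimits` turns repeated pain-threshold load tests into biomechanical
safety limits for power-and-force-limited collaborative robots.  A human
body location can tolerate a mechanical load up to the onset of pain;
the package models that threshold statistically per body location and
test condition and inverts the model into force and pressure limits for
a workforce with a chosen gender composition.  This note documents the
model, the processing conventions, the synthetic-data generator, and
the numerical choices, in the order the pipeline runs.

## Experimental model

Two loading protocols are modelled:

* **Quasi-static pinching (algometer).**  A contact body is pressed
  onto the body location at a constant deformation rate of 1 mm/s; the
  subject presses a switch at the onset of pain.  The force at the
  switch press is an *exact* observation of the threshold.  Signals are
  single-axis, sampled at 100 Hz.
* **Stepped impact (pendulum staircase).**  A pendulum of mass 16.5 kg
  (then 6.5 kg) strikes the location at velocities increasing in fixed
  steps of 0.05 m/s (0.01 m/s on head locations) up to 1.25 m/s, until
  the subject first reports pain.  The threshold is only *bracketed*
  between the peak loads of the last two trials: interval-censored,
  left-censored if the first impact hurts (L = 0), right-censored if
  the protocol tops out (R → ∞).  Signals are tri-axial at 10 kHz.

Two contact geometries set the limit's units: a compliant blunt
circular face (limits are maximum contact forces, N) and a semi-sharp
14 mm × 14 mm face instrumented with a pressure film (limits are peak
pressures, N/cm²).

## Signal conditioning

* **CFC filtering.**  Channel-class low-pass filtering follows the
  automotive convention: −3 dB cutoff at 1.65× the class value (CFC1 →
  1.65 Hz for algometer ramps, CFC100 → 165 Hz for impacts), realized
  as a 2nd-order Butterworth applied forward and backward (`filtfilt`
  with reflect padding), i.e. zero phase and net 4th order.
* **Offset elimination and onset detection.**  The mean of a
  pre-contact baseline window is subtracted per axis.  Contact onset is
  the last sample at the noise floor before the force norm exceeds
  `max(5 × baseline sd, 0.5 N)` for 5 consecutive samples; the
  backtracking step removes the rise-time lag of the threshold
  crossing (detected onsets are within ±0.05 s of truth at the default
  noise level).
* **Inertia compensation.**  The load cell sits between the pendulum
  body (m_B) and the contact body (m_I); the contact-tip force is the
  reading times V_f = 1 + m_I/m_B.  A processed flag guards against
  double application.
* **Measurands.**  Impact: max over time of the Euclidean force norm.
  Algometer: max restricted to samples up to the switch event.

## Pressure-film conditioning

The film bends over the 2 mm edge radius of the semi-sharp face, so its
pixels belong to five views (overhead + four lateral).  Processing runs
blur → blind-spot interpolation → force calibration, in that order:

* **Per-view blur**: 3×3 Gaussian kernel with variance 2/π.  Values are
  first scaled by the projection factor of their view (cosine between
  the local surface normal and the view normal; 1 on the flat face,
  cos 45° on the default bent border).  The kernel weights are
  renormalized over same-view sensels (normalized convolution), which
  preserves constants within a view and keeps stress from bleeding
  across views or into blind spots.  This choice is not exactly
  mass-conserving at view edges — the reason calibration runs last.
* **Blind-spot interpolation**: the four corner sensels fall outside
  the film.  Values on each nested outer contour of the face are mapped
  over their arc-length position and gaps are closed with a *periodic
  cubic* spline (each contour is a closed ring; an antecedent of this
  technique used linear interpolation).  A contour needs at least 4
  covered sensels.
* **Calibration**: one scale factor per frame so that the sensel sum
  times sensel area equals the simultaneously measured contact force,
  exactly (1e-9 relative).  Peak pressure is the space–time maximum
  over the calibrated stack.

Dequantization maps 8-bit film levels to the centers of their
quantization bins (range 1.2 kN/cm², 2.07 kHz frame rate).

## Censoring and descriptive pipeline

Staircase series become interval observations (L from the last
pain-free trial, R from the pain trial); algometer observations are
exact.  Midpoint imputation collapses an observation to R/2
(left-censored), L (right-censored), or (L+R)/2.  Repeats — including
both pendulum masses — are averaged per subject, and subjects pool into
one sample per (body location, load type, contact type) according to
the group plan.  Subjects whose every repeat is right-censored remain
in the sample at their mean lower bound and are flagged.  The neck
muscle is never tested (medical exclusion) and the pectoral muscle has
no female subjects.

## Threshold model

The threshold law is an accelerated-failure-time regression with a
logistic kernel on the log scale:

    F(y, x_G) = [1 + exp(−(log y − β0 − x_G β1)/α)]⁻¹

with intercept β0, gender effect β1 ≥ 0 (x_G = male fraction of the
target group; fractional values mix the genders), and shape α > 0.
Weibull and log-normal kernels are available for family selection,
which picks the family minimizing the Anderson–Darling statistic of the
probability-integral-transformed subject means (ties break toward
log-logistic; no critical-value table is needed because only the
ordering matters).

**Estimation.**  The censored-data likelihood (density terms for exact
observations, probability mass for intervals, tail probabilities for
one-sided censorings) is maximized over (β0, β1, log α) with L-BFGS-B
from moment-based starts plus four perturbed restarts (internal fixed
seed, so fits are deterministic given data).  The default mode fits the
imputed per-subject means as exact observations, matching the
descriptive pipeline; an interval mode on the raw repeat brackets is
available (`mode="interval"`), cross-checked in the test suite against
an independent interval-censored AFT implementation.  The covariance is
the inverse observed information (central finite-difference Hessian at
the optimum).

**Gender significance.**  The Wald test for β1 uses a small-sample
convention: the standard error is inflated by √(n/(n−p)) and the
statistic is referred to t(n−p).  With plain normal-reference Wald
tests, the type-I error at the study's cell sizes (N ≈ 11–40) measures
around 10% at nominal 5%; the corrected version measures 7.2% over 500
null replicates at N = 40 and coincides with the normal version as N
grows.  Gender is *relevant* at a body location iff p < σ (default
0.05, strict inequality) for at least two of its experimental
conditions; otherwise the cell is refitted with β1 = 0.

**Confidence intervals.**  Quantile limits carry delta-method intervals
on the linear predictor η = β0 + x_G β1 + α·logit(q), exponentiated.
For parameter-recovery checks the package provides profile-likelihood
intervals (`profile_ci`), which are far better calibrated than
natural-scale Wald intervals at N = 11 (93.5% vs 83% measured coverage
for α).

**Fit quality.**  R² is defined — as a convention of this package, the
computation being otherwise unspecified — as the squared Pearson
correlation of the quantile–quantile pairing *on the log scale*:
gender-adjusted sorted log subject means against log model quantiles at
plotting positions (i − 0.5)/N.  The log scale is where the fitted
location-scale model is linear; on the original scale the heavy
log-logistic tail makes the statistic erratic for moderate N.

## Limits and comparison

The limit for a cell is the quantile y_q = exp(β0 + x_G β1 + α z_q)
with z_q = logit(q); defaults q = 0.75 and x_G = 0.7 (a 70%-male
worker population), with x_G applied only at gender-relevant locations.
For standard-style tables, limits are rounded to the nearest 10 (halves
away from zero) and the neck-muscle row is estimated as 1.2× the
temple's rounded limits, rounded to tens again — the two locations have
similarly distributed thresholds, with the neck mean 1.2× higher.

Comparison statistics: the impact/pinching quantile ratio w_q per
location with its arithmetic mean over the 24 measured locations; the
relative deviation ε = 1 − reference/own against the bundled printed
90th-percentile columns of two earlier algometry studies; and the
Pearson correlation between maximum force and peak pressure.

## Synthetic-data generator

The generator emulates the study conditions with the published fitted
parameters as ground truth and the published group sizes and gender
compositions as rosters (41/20/20/40/20/11 subjects across groups).
Thresholds are drawn by inverting the expanded CDF at uniform variates.
The tissue is a linear spring (stiffness c_H) with additive Gaussian
force noise (sd 0.5 N) and a per-trial baseline offset (sd 1 N); under
that model an impact's peak force is √(m_P c_H)·v_P and its contact
pulse is a half-sine of duration π√(m_P/c_H).  Per-location c_H values
are chosen so the mixed-population median blunt-impact threshold is
reached at half the maximum velocity with the lighter mass — simulator
configuration, not claims about tissue.  The staircase starts one
velocity step above zero (the start value is protocol configuration);
the reaction delay defaults to 0 s (switch press treated as coincident
with pain onset).  Semi-sharp thresholds are drawn in pressure units
and mapped to forces through a pressure-concentration factor of the
film face (default 0.8 cm⁻², with 10% lognormal per-trial variation).

Two detail levels exist: `"signal"` synthesizes raw waveforms and runs
the full conditioning chain; the default `"peaks"` draws the processed
peak values from the same measurement model directly.  The two are
statistically equivalent for the downstream fit and the peaks level is
orders of magnitude cheaper, so simulation studies over many cells use
it; the waveform path is exercised end-to-end in the tests.

What the generator does *not* emulate: viscoelastic or hyper-elastic
tissue response, inter-session variability within subjects, subject
dropout, misalignment errors, or spatially structured film artifacts.
Passing tests therefore demonstrate that the statistical machinery is
correct and calibrated under the stated generating law — not that the
published parameter values are correct for real tissue.

## Problem sizes and determinism

Simulation studies in the tests and acceptance checks use: 200
replicates per cell for parameter-recovery coverage, 500 replicates for
type-I-error calibration, 100 replicates (500 draws each) for family
selection, and two full-pipeline runs over all 24 locations for
end-to-end recovery — sizes at which the binomial noise of the measured
rates is a small fraction of the asserted margins.  All randomness
flows from explicit seeds through per-cell spawned streams; a pipeline
rerun with the same configuration is byte-identical.

## Known limitations

* The exact-on-imputed default ignores the within-subject censoring
  structure once means are formed; the interval mode is provided but
  the two can differ for heavily censored cells.
* Wald quantile CIs undercover slightly below N ≈ 20; use `profile_ci`
  for parameters when the sample is small.
* The relevance rule is a hard two-condition count; locations with one
  strongly significant condition are treated as gender-neutral.
* Published parameters are printed to two decimals, so reproduced
  limits can deviate from the published tables by up to ~1% before
  rounding.
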