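# Methods

This note documents the models implemented in `motionfis`, the parameters
that matter, the numerical choices, and what the synthetic-data generator
does and does not emulate.

## Signal model and windowing

Each sensor reports time-stamped 3-axis acceleration (g, range ±10) and
angular velocity (°/s, range ±1000) on local axes 1/2/3.  Readings scatter
around their true value with an approximately Gaussian histogram, so the
analysis unit is the arithmetic mean over non-overlapping windows
(default 1 s; trailing partial windows are dropped).  The sampling rate is
configurable (default 20 Hz); all downstream features operate on window
summaries, so the rate mainly affects the precision of within-window
standard deviations.

A session opens with the static *stand* posture.  The means of the first
`n_init` windows (default 3) define the calibration baseline g₀ (≈1 g,
along the local 1-axis, which is vertical at calibration) and the gyro
bias ω₀.  All "x"-subscripted features use the local 1-axis component.

## Movement features

Per window, relative to the baseline: tilt angles θ_A, θ_B (and θ_AB
between sensors) from the clamped normalized inner product, in [0°, 180°];
relative vectors g−g₀ and ω−ω₀; per-axis population standard deviations
(divisor n) of the raw within-window samples; difference rates
|V−V₀|²/|V₀|²; and gradients of consecutive window means with Δt = the
window width.  Gradients are undefined on a session's first window and
marked NaN; projections that need them skip that window with a logged
notice.

Dynamic features enter the fuzzy systems as absolute values: every
published membership support starts at 0, so the systems are defined on
magnitudes.  Whether the original features were signed is not documented;
magnitudes are the only reading consistent with the published domains.

## Mamdani classifier

Two five-feature sets drive the same five activities:
SET-1 = {θ_A, θ_B, ω_BRx, g_BRx, σ_gBx}, SET-2 = {θ_A, θ_B, γ_ωAx, γ_gBx,
σ_gAx}.  Input membership functions are piecewise linear on the published
boundary cuts.  Two transcription choices were needed:

- the ω_BRx row publishes only the plateaus (low = 1 on (0, 25), high = 1
  on (60, 300)); both are ramped linearly across the (25, 60) gap for
  continuity, consistent with the 25 °/s walk/run cue;
- a typo "0.0.3" in the γ_gBx low row is read as 0.03 (the next domain
  starts at 0.03).

Inference is classical Mamdani: min conjunction (don't-care antecedents
skipped), min implication, max aggregation, centroid defuzzification.
Inputs are saturated to each variable's overall domain before
fuzzification — a gradient beyond the top plateau still counts as fully
"high", a tilt a shade over 90° as fully tilted — matching the behavior of
the fuzzy toolbox this family of systems is conventionally built in;
without saturation, vigorous running would fall off the high plateaus and
become unrecognized.

The five output membership functions are symmetric triangles with peaks
{0.5, 1, 1.5, 2, 2.5} for {stand, sit, lie, walk, run} and half-width 0.5.
(The generic formula accompanying the published description would place
the triangles on (n−1, n) with centroids {0.5, 1.5, 2.5, 3.5, 4.5}; the
published centroid list and the worked example — output exactly 1 for
*sit* — contradict it, and the implementation follows them.)  A lone rule
firing at full strength therefore defuzzifies exactly to its activity's
peak.  Classification is by nearest peak (ties toward the lower peak),
because the per-class index ranges overlap; if no rule fires, the window
is *unrecognized*.

The centroid is computed analytically: the aggregate of clipped triangles
is piecewise linear, so its area and first moment are integrated exactly
over subintervals delimited by all trapezoid vertices and pairwise segment
intersections.  Each subinterval is sampled at two interior points (the
aggregate is linear there; endpoints can be degenerate collapsed vertices
when a clip level underflows), making the integration exact up to
round-off.  A dense-grid discretization oracle in the test suite agrees to
1e-5.

## Walk/run ANFIS

Inputs are the thigh's per-axis acceleration deviations (σ_gBx, σ_gBy,
σ_gBz), canonically on [0, 2] g.  Grid-partition initialization: per input,
three Gaussians f(x; σ, μ) = exp(−(x−μ)²/2σ²) with σ = 0.3397 and μ at
{0, 1, 2} (scaled for other ranges: centers at the endpoints and midpoint,
widths proportional to the half-range).  The 27 rules enumerate every MF
combination; consequents initialize to 13 equal steps of 1/13 ≈ 0.0769
inside the walk band [1, 2] and the run band [3, 4], plus a 27th constant
at 2.5 — the middle of the uncertain gap — for combinations matching
neither motion.  Rule order is lexicographic with the first input most
significant (r = 9(i−1) + 3(j−1) + k); the convention travels with the
model as a `rule_order` tag.

Training targets are drawn uniformly within each label's band (walk
[1, 2], run [3, 4]), seeded.  Hybrid learning, per epoch: (a) batch least
squares for the 27 consequents given the normalized firing strengths, then
(b) one normalized full-batch gradient-descent step on all σ and μ
(analytic gradients; σ floored at 1e-4 to prevent collapse).  The step
size (initial 0.01) decreases ×0.9 when the RMSE rose and increases ×1.1
after two consecutive falls.  RMSE is recorded after the least-squares
step, so a 1-epoch run with zero step size is exactly the least-squares
solution.

When the consequent design matrix is rank deficient **or** numerically
singular (condition number above 1e8), the solve switches to ridge
(λ = 1e-6 · tr(WᵀW)/27) with a logged notice.  Rules in corners of the
grid fired by almost no training record otherwise receive arbitrarily
large constants — the published trained consequents show exactly this
pathology (values like −242.3 and 187.5 against a [1, 4] output range) —
which wrecks held-out recognition when a test record lands near such a
corner.

Crisp outputs classify as walk [1, 2], run [3, 4], uncertain (2, 3),
otherwise out of range.  Evaluation reports per-class correct/total
counts, uncertain tallies, rates both including uncertain outputs (as
misses) and excluding them from the denominator, and RMSE excluding
uncertain outputs.

The published *trained* parameter listing cannot be reproduced without
knowing its consequent-to-rule convention; `motionfis diag-table4`
evaluates the listing under all six input-significance orderings on the
two published probe inputs and reports the outputs.  No ordering
reproduces both published outputs, so the listing is treated as ambiguous
documentation, not as a reference model.

## Synthetic data

The generator emulates exactly the statistics the features consume:

- **orientation**: gravity tilted in the local 1–3 plane per activity —
  stand (θ_A = θ_B = 0°), sit (5°, 85°), lie (88°, 75°), walk/run (2°, 10°).
  For lie, the thigh is roughly horizontal just as in sit (75° vs 85°): the
  lie rule requires a high thigh tilt, and only a small θ_B difference
  separates the two postures;
- **noise**: per-sample Gaussian noise; static σ = 0.005 g, walk
  σ_gA ≈ 0.15 g, run σ_gA ≈ 0.4 g (static/dynamic cue at 0.1 g), thigh
  0.15/0.5 g;
- **gait**: thigh angular velocity = mean (80/150 °/s) + sinusoidal sway
  with RMS 15 °/s (walk) and 45 °/s (run), straddling the 25 °/s cue; a
  0.5-Hz stride modulation on chest angular velocity and thigh forward
  acceleration makes consecutive window means differ so the gradient
  features respond; forward-acceleration offsets 0.18/0.75 g place g_BRx
  inside its low/high plateaus;
- **transitions**: between-activity gaps interpolate orientation linearly;
  windows overlapping a gap, and the first window after one (whose
  gradient still sees the change), are flagged `transition` and excluded
  from scoring, mirroring the measurement protocol's exclusion of
  change-of-action intervals;
- **flexion**: gravity steps through dwell plateaus (5 s each) after an
  opening 0° calibration dwell, with optional per-step angle error;
- **training sets**: σ_gB triples per class — walk mean (0.35, 0.30, 0.25),
  run mean (1.10, 0.95, 0.85), sd ≈ 0.1 — separated by several pooled sd;
  default 187 records, matching the reference training-set size.

All generators are bit-reproducible for a fixed seed.

What the generator does **not** model: biomechanically realistic gait
waveforms, soft-tissue artifacts, sensor misalignment or drift, or the
irregular personal movement habits that degraded the original blind-test
rates.  Passing tests therefore demonstrate that the inference machinery
and the published parameterization behave as specified under the stated
signal model — not field accuracy on real patients.

## Therapy scoring

The recognized angle of a flexion step is the median per-window tilt over
the dwell, rounded to integer degrees (median for robustness; integers
match how such results are reported).  Threshold bands are inclusive at
both ends — required for the published tallies, where 45° passes 40–45 but
39° fails it.  The staircase exercise is matched per step (i-th angle vs
i-th band), since the exercise is a monotone staircase; a permissive
any-interval mode exists but is not the default.  The repetition exercise
applies its single band to every repetition.  Motion packets are
pipe-delimited ("n|time|motion_1|motion_2", −1 = absent; the typographic
minus is accepted on parse).

## Problem sizes and determinism

Default experiment sizes are desk scale by design: 187 training + ~78 test
records for the ANFIS, 40 epochs, ~60-s simulated sessions at 20 Hz.
Training is vectorized and completes in well under a second; the full test
suite runs in a few seconds.  Every stochastic path (simulation, target
drawing, training-set synthesis) is driven by explicit seeds.

## Known limitations

- The Mamdani rule base is fixed; no rule learning is provided.
- The Sugeno system is zero-order (constant consequents) with exactly
  3 inputs × 3 MFs; other arities would need a generalization of the rule
  indexing.
- Uncertain-band outputs are reported, not adjudicated; a clinical
  deployment would need a policy for them.
- The g_BRx low/high membership functions overlap on (0.28, 0.4) as
  published; both rules can partially fire there, which the max
  aggregation handles but which slightly blurs the walk/run boundary.
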