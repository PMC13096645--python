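# Methods

## Model

The circuit is a rate-based, column-discretised abstraction of the insect
central complex with three stages.

**Compass.** Heading θ is represented as a single-peaked activity bump over
`n_columns = 8` angular columns with preferred directions 0°, 45°, …, 315°.
The default kernel is a half-wave-rectified cosine,
`v_j = max(0, cos(θ_app − φ_j))`, peak-normalised to 1; a von-Mises-shaped
kernel (`exp(κ_b(cos − 1))`) is available as a config option, since any
single-peaked symmetric kernel yields the same qualitative dynamics. The
rectified cosine has the convenient property that its odd Fourier harmonics
above the fundamental vanish, so the population-vector decode is exact on the
8-column grid (the von Mises kernel aliases harmonics 7 and 9 onto the
fundamental and decodes only to ~0.01°). A celestial-cue rotation is applied
as a whole-column shift of the bump: `cells = round(deg / 45°)`, so 135° is
exactly 3 columns. Heading is imposed on the compass each step — the bump is
not self-sustained by attractor recurrence; ring-attractor dynamics are out
of scope.

**Goal field.** Two per-hemisphere banks of 8 non-negative column activities
decay by `(1 − λ)` per step (default λ = 0.2) and are charged by the
lateralised familiarity signals through copies of the compass bump shifted one
column (±45°): the left signal writes one column counter-clockwise of the
current bump, the right one clockwise. Because the left familiarity fires when
the body points clockwise of the goal, its counter-clockwise write lands on
the goal direction, and symmetrically — this is what converts egocentric
"which side is the route" information into a stable allocentric goal. With
constant input c the bank amplitude converges geometrically to `c/λ`.

**Steering.** Both drives are inner products of the *summed* goal field with
compass copies shifted ±1 column, and the turn command is
`gain · turn_scale · (d_R − d_L)/(d_R + d_L + ε) + Normal(0, σ_motor)`,
clipped at ±`turn_cap`. Normalising by the total drive makes the dynamics
invariant to goal-field amplitude; `ε = 1e−9` makes the zero-goal case exactly
noise-only. Note that swapping the two banks cannot change the turn (the
comparison reads their sum); the true antisymmetry is that mirror-reflecting
the goal field about the heading negates the noise-free command.

**Familiarity input.** Left/right familiarity are exponential-cosine tuning
curves of body orientation with concentration κ = 5 (half-maximum width
≈ ±30°), amplitude 1, centred at `route ± bias` and independently jittered
each step by `Normal(0, σ_dir)`; values below a floor (default 0.05) are
zeroed. With these defaults each signal is silent on ~63% of uniformly drawn
headings and both are silent on ~38% — the input is sporadic, not a continuous
error signal. Setting amplitude 0 disables familiarity entirely (used by the
no-input kinematics tests). The image-processing side of recognition
(panoramas, view memories, learning) is deliberately not modelled.

**Closed loop.** Per step: encode the compass at the current heading (shifted
if a rotation is active), sample familiarity at the *true* heading, update the
goal, steer, turn, then advance one step length along the new heading
(turn-then-step; the ordering is a convention). The agent starts with an empty
goal field and, by default, 90° off-route — it must acquire the goal from
familiarity alone. All randomness flows from a single per-trial seed; cohorts
spawn per-agent seeds from a base seed, so every result is bitwise
reproducible.

## Default parameters

| parameter | default | units | note |
|---|---|---|---|
| n_columns | 8 | – | 45°/column; makes 135° = 3 columns |
| decay λ | 0.2 | /step | goal-field leak |
| gain | 1 | – | steering gain |
| motor noise | 10 | °/step | SD of turn-command noise |
| turn_scale | 30 | ° | drive difference → degrees; calibrated once so the closed loop re-attracts within ~1 column per 50 steps and the rotation response shows the veer/recover dynamics |
| turn_cap | 90 | °/step | hard motor limit |
| directional bias b | +45 | ° | left-signal peak offset from goal |
| directional noise σ | 10 | ° | per-step tuning-curve jitter |
| tuning κ | 5 | – | ±30° half-maximum width |
| threshold | 0.05 | – | familiarity floor (sporadicity) |
| n_steps | 200 | steps | trial length for the sweep |

## Experiments

**Bias × noise sweep.** For each (b, σ) cell, seeded 200-step trials are
scored by the absolute angle between the start-to-end chord and the route.
Three regimes appear along σ = 10°: stable following (b > 0, mean error a few
degrees), stable reversal (b < 0, error near 180°), and a labile zone at b = 0
with mediocre mean directionality and large seed-to-seed spread. The stable
cell is insensitive to doubling motor noise, halving/raising λ (0.1–0.5),
removing the threshold, or changing κ (3–8).

**Celestial-rotation cohort.** 20 agents run 300 steps starting on-route; at
step 120 the compass bump is shifted +3 columns (the 135° rotation). Paths are
subsampled every 3 steps; per-segment bearings (relative to the route) and
junction turn angles are averaged across the cohort, aligned so index 0 is the
onset. The pre-onset window (40 segments) and post-onset window (60 segments)
are package defaults chosen to show settled behaviour on both sides. The phase
report quantifies: the pre-onset baseline; the onset veer (signed per-step
cohort-mean turn over the first 3 post-onset steps — negative, i.e. leftward,
for a +135° shift, because the stored goal suddenly appears 135°
counter-clockwise of the apparent heading); the corrective-turn latency (first
cohort-mean turn of opposite sign); and the meander window. Meander is
detected on cohort-mean *segment* turn angles — the per-step series is
dominated by the 10°/step motor noise — as post-onset segments above
baseline + 2 SD within a 20-segment horizon, counted only if the elevation
starts within 3 segments of onset so an unperturbed cohort reports no window.
The window shrinks as λ grows because the conflicting old goal trace fades as
`(1 − λ)^t`.

A useful internal consistency property: a whole-column rotation applied from
step 0, before any goal exists, merely relabels the internal frame and leaves
the behaviour unchanged; only a mid-trial rotation, after a goal has been
stored in the old frame, perturbs the path.

## Behavioural metrics

Turn ratio integrates |ω| trapezoidally over the positive and negative parts
of the recorded grid; preferred-side proportion weights samples by their local
durations, with ties (or a silent trace) at 0.5. Path discretisation places
vertices by linear interpolation at exact arc-length multiples of L and drops
the trailing remainder (< L); bearings are atan2 directions and junction turn
angles absolute wrapped differences, in [0°, 180°]. Directional error is the
absolute wrapped angle between the start-to-end chord and the goal. Circular
mean ± SE uses the resultant-vector mean and circular SD/√n; with grouping
ids, angles are first averaged within each id (mean ± SE across individuals).
The signed-rank test drops zeros, assigns average ranks to ties, and builds
the exact null of the positive-rank sum over all 2^n sign assignments via the
rank generating polynomial (n ≤ 25); two-sided p is twice the smaller
one-sided p, capped at 1. Six values all of one sign give p = 1/64 = 0.015625.

## Synthetic data

The trackball generator emulates open-loop recordings of individuals fixed in
8 compass orientations: the deterministic part of each trace is
`sign · mean_turn_speed` with the sign pointing toward the route (positive =
right turn when the route is clockwise of the body axis) and a fixed
per-individual side bias at the aligned/anti-aligned orientations; AR(1) noise
(lag-1 coefficient 0.8 at 10 Hz, stationary SD configurable) makes the traces
smooth rather than white. Defaults: 12 s at 10 Hz, mean speed 20°/s, noise SD
10°/s (SNR 2). The unfamiliar-surroundings variant randomises the sign per
trace. Ground-truth labels accompany every cohort, so sign recovery by the
metrics pipeline is scored automatically. The path generator simply exports
closed-loop trials in the metrics' path format.

What the generators do *not* emulate: real optic-flow/trackball measurement
error spectra, speed modulation, scanning head/body movements, or any visual
scene content. Passing recovery tests therefore shows the metrics pipeline is
correct and adequately powered at the stated SNR — not that real recordings
have these statistics.

## Numerical choices and edge cases

- Angles are degrees wrapped to (−180°, 180°]; positive = clockwise (right
  turn); −180° maps to +180°.
- All-zero or perfectly symmetric activity raises an undefined-angle error
  (uniform bumps have no direction); zero-displacement chords likewise.
- The expected familiarity curve is computed by dense trapezoidal quadrature
  of the thresholded tuning curve against the normal density over ±6σ —
  thresholding makes the integrand non-smooth, where adaptive quadrature
  misbehaves.
- File round trips write floats with 17 significant digits and parse with
  Python's correctly-rounded parser, so values survive a write/read cycle
  bitwise.
- Trace/path problem sizes in the tests and the acceptance script (50 seeds
  per sweep cell, 20-agent cohorts, 100 recovery seeds with 4 individuals)
  are desk-scale choices; all scale linearly if increased.

## Known limitations

- The compass is imposed, not attractor-maintained; phenomena that depend on
  bump dynamics (jumps, drift, multistability) are outside the model.
- One canonical circuit is implemented; hemisphere-specific wiring variants
  (path-integration-style vs travel-direction-style goal layers) are a
  possible extension, not included.
- The labile b = 0 regime's statistics are intentionally high-variance;
  quantities measured there are reported with their SD and should not be
  over-interpreted.
- The exact signed-rank test is restricted to n ≤ 25; larger samples should
  use a normal approximation (not provided — the target experiments have
  n ≤ 12).
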