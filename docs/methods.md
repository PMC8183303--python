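# Methods

This note documents the models, defaults and numerical choices behind
`pufov`, and what the synthetic-cohort validation does and does not show.

## Simulator geometry

Three planar canvases (3.05 m x 1.89 m, 1920x1200 px each) share vertical
edges; the side screens are folded toward the viewer so adjacent planes
enclose `inter_screen_angle_deg` (default 151°).  The eye point is fixed on
the center-screen normal at `eye_distance_m` (default 3.75 m); the
straight-ahead reference is the eye-to-center-of-center-screen direction.
Pixels are 0-based with (0, 0) the top-left *pixel center*; x grows right,
y grows down.  Public interfaces use degrees; radians are internal.

Two pixel geometries coexist deliberately:

* **angular**: pixel → 3-D unit direction → visual angles and angular
  distances (used for eccentricities and saccade amplitudes in degrees);
* **unrolled**: the three canvases concatenated into one 5760x1200 px
  plane (`global_x = screen_id*1920 + x`), used for pixel distances, the
  alignment's transition weights, and saccade directions.

With the default parameters the geometry implies a horizontal field of view
of ≈123.1° and a vertical one of ≈28.3°.  Larger coverages quoted for such
setups (147–149°) are not reachable at 3.75 m for any fold angle in
(90°, 180°] (the maximum is ≈142°); the layout therefore always reports its
geometry-derived coverage, and `layout_with_coverage(deg)` constructs a
layout with an exact target coverage by solving for the eye distance
(149° ⇒ ≈2.641 m at 151°).  The coverage solver brackets the root to the
right of the coverage peak at `W·sin(180°−angle)`, where the outer screen
edges pass the eye plane.

The *maximum measurable eccentricity* of a setup is half its horizontal
coverage — 74.5° for a 149° layout; the outermost grid feature (480 px
inboard of the screen edge) sits at ≈67° in that configuration.

## Stimulus grid and event schedule

150 objects (40x40 px; square/triangle, red/green, rotated 0°/45°, all
drawn i.i.d. uniform per object) form a 25x6 grid with 200 px spacing,
centered on the unrolled plane (columns at 480 + 200·c, rows at
100 + 200·r).  An occlusion mask marks grid cells hidden behind the vehicle
chassis; the default mask hides the bottom two rows of the center screen.
Occluded features are displayed but never scheduled, and the alignment
ignores them.

Per change type, 140 events per 300 s video are scheduled by sampling
durations uniform in [1, 2] s and same-type gaps uniform in (0, 1] s
(including an initial gap), back to back; a draw whose last offset exceeds
the video length is rejected wholesale.  The expected occupancy,
140·1.5 + 139·0.5 = 279.5 s, fits 300 s with ~4 σ to spare, so rejections
are rare.  Different types may overlap in time but never on the same
feature simultaneously (a feature cannot legibly change color and shape at
once); target features are drawn uniformly from the visible, currently
unengaged features.  Colors are LAB pairs (60, ±60, 45); a color event
interpolates only the `a` channel, keeping lightness constant.  Shape
events drive a 0→1 morph parameter; motion events wiggle the orientation as
45°·sin(2π·f·(t−onset)) with f = 2 Hz (two full oscillations within the
shortest event; no canonical value exists, so this is a package default).

## Synthetic participants

Each participant carries, per change type, a Gaussian detection-probability
profile `p(e) = A·exp(−e²/(2σ²))` over eccentricity.  The defaults —
color (0.90, 13°), shape (0.95, 22°), motion (0.90, 45°) — were chosen once
so that the analytic detection rates under the default layout and grid
(≈0.18 / 0.38 / 0.68) reproduce the characteristic ordering and rough
magnitudes of human wide-FOV change detection: color is essentially foveal,
motion detectable across most of the field.

Behaviour per instructed-type event: detection is a single Bernoulli draw
at event *onset*, with `e` measured from the participant's intended gaze
point at that instant (the screen center, or a previous target if they are
still responding to it — free viewing has no fixation enforcement).  On
detection, gaze jumps to the target after a shifted-log-normal gaze latency
(shift 0.10 s, median 0.25 s, log-sd 0.3; mean ≈0.36 s), dwells 0.5 s,
and a keypress fires after an additional shifted-log-normal latency
(0.15/0.22/0.35; mean ≈0.38 s), giving a mean keypress reaction of
≈0.75 s.  Saccades are instantaneous between samples; the gaze latency
absorbs flight time.  Non-instructed events never trigger responses; false
alarms are not modelled.

Reported gaze samples (60 Hz default) add white Gaussian tracker noise in
pixels, converted from degrees with each screen's local pixel-per-degree
scale.  The pooled mean absolute error is 3.9° horizontal / 3.4° vertical;
per-screen standard deviations are scaled 0.7/1.0/1.3 (center/right/left),
reflecting that a right-offset camera bank tracks the center screen best
and the left screen worst.  (Mean absolute error m corresponds to
σ = m·√(π/2) for a centered Gaussian.)  Fixational jitter (0.3°) adds in
quadrature.  Calibration sessions emit noisy samples around 21 reference
points (7 per screen) with the same noise model.

What the generator does **not** emulate: oculomotor dynamics (main-sequence
velocities, undershoot, smooth pursuit), blinks by default (dropout is
configurable but 0), slowly varying calibration drift (all tracker error is
white), false alarms, and learning or fatigue across videos.  Passing
recovery tests therefore demonstrate correctness of the analysis under
these idealisations, not robustness to systematic tracker bias — a
constant per-region offset comparable to the stated error magnitudes would
defeat any grid-snapping analysis, human or synthetic.

## Gaze-to-feature alignment

Two update modes implement the random-walk assignment (state = visible
feature, distances in px on the unrolled plane, σ_T = 150 px — the
horizontal tracker error expressed in pixels):

* **literal** — the matrix iteration exactly as written, row convention,
  negative entries clipped to zero, renormalised.  Algebraically the update
  is `(v_t)_i = exp(−d_i) − <exp(−d), v_{t−1}>`, a common offset subtracted
  from `exp(−d_i)`, so the argmax is provably the nearest visible feature;
  the column convention would instead select the *farthest* feature and is
  rejected on those grounds.  If `v` has collapsed to a point mass at the
  nearest feature the update is identically zero after clipping; the mass
  is kept in place.  This mode carries no memory.
* **proximity** (default) — `v_t = λ·v_{t−1} + (1−λ)·w_t` with
  `w_i ∝ exp(−d_i)` and stickiness λ (default 0.5).  This keeps the
  per-sample likelihood of the literal reading but adds explicit hysteresis
  against single-sample noise excursions.  The recurrence is evaluated
  exactly as a linear filter over runs of valid samples; invalid samples
  (blinks/dropouts) hold the previous state rather than resetting it.

Ties in the argmax resolve to the lowest feature id; `v_0` is uniform.

Saccade extraction: every change of the aligned feature is a saccade from
the last sample on the old feature to the first on the new; consecutive
saccades whose unrolled-plane directions differ by < 45° with intervening
dwell < 0.1 s merge end-to-end.  Neither threshold has a canonical value;
both are configurable defaults.

## Event scoring

An instructed event is detected iff the aligned track visits the event's
feature within [onset, offset + grace] (grace default 1.0 s) and a keypress
follows that visit inside the same window.  Each keypress confirms at most
one event — the one whose qualifying visit most recently precedes it,
processed in keypress order.  A config flag (`require_visit=False`) scores
keypresses without a confirmed visit, for sensitivity analyses.

Two eccentricity measurements are produced per event:

* `ecc_detection_deg` / `max_amp_deg` — the classical proxy: amplitude of
  the (merged) saccade that reached the feature, and the largest saccade
  toward it between onset and the keystroke.  Under heavy tracker noise the
  aligned track frequently enters a target through one of its grid
  neighbours, so the arriving saccade can be a single 200 px hop and this
  proxy is biased low by 10–15° on noisy data.  It is reported because it
  is the field's standard summary, but it is not used for profile fitting.
* `ecc_onset_deg` — the gaze-to-feature angle at event onset, computed for
  *every* event (detected or not).  When the raw gaze track is available
  the gaze direction at onset is the per-axis median of the raw samples in
  the 0.2 s before onset (noise ≈1.4° instead of a single sample's ≈5°,
  and — unlike the aligned feature — not quantized to the 200 px grid);
  otherwise the aligned feature at onset is used.  Without this estimator
  the grid quantization blurs the profile and biases fitted amplitudes low
  by ≈0.06 for narrow (foveal) profiles.

Detection is *not* exactly monotone in the grace period on noisy data:
enlarging the window can re-route a keypress to a different event under the
most-recent-visit rule.  On noiseless data monotonicity holds and is
tested.

## Perception-profile model

`PerceptionProfileModel` bins events by eccentricity (default 5° bins),
forms per-bin detection probabilities detected/total, and fits
`p(e) = A·exp(−e²/(2σ²))` by least squares weighted by bin totals
(scipy `curve_fit`, A box-constrained to [0, 1], σ > 0; initial σ from the
detection-weighted RMS eccentricity).  The center is fixed at 0° — the
profile is assumed symmetric about the gaze direction — with a free-center
variant behind a flag.  The fit requires at least one detection and three
populated bins.  `PerceptionProfileFit` carries estimates, approximate
standard errors from the weighted-least-squares covariance, the weighted
residual sum of squares, the bin table, `predict`, `summary` and `plot`.

Group comparisons (reaction times, detection ratios, amplitudes per
participant) use classical one-way fixed-effects ANOVA (scipy
`f_oneway`) with pairwise (C-S, S-M, C-M) and omnibus (C-S-M) labels, and
explicit degenerate handling: all-equal constants give F = 0, p = 1;
distinct constants with zero within-group variance give F = ∞, p = 0.
No multiple-comparison correction is applied.

## Study pipeline and reproducibility

`run_study` executes generate → schedule → simulate → align → metrics →
fit → report for a cohort: three shared videos, per-participant permuted
video order and instructed-type order (each participant is scored once per
type), a calibration session per participant, pooled profile fits, and the
ANOVA table.  All randomness descends from one master seed through
`numpy.random.SeedSequence` spawning, making every intermediate table
byte-reproducible; intermediates are plain CSV/JSON.

## Validation by parameter recovery, and its limits

The acceptance suite pushes a 50-participant cohort (3 x 140 events each)
through the full pipeline and compares against the generator's ground
truth.  Fitted amplitudes recover truth within ±0.05 and widths within
±10 % (measured: A 0.902/0.952/0.858 vs 0.90/0.95/0.90; σ within 4.2 %).
Detection rates and mean reaction times are compared at 99 % Monte-Carlo
envelopes, with one documented allowance: the pipeline's gaze reaction time
is the first *aligned* look, whose latency is the sample quantization
(half an interval) plus a geometric waiting time for the first aligned hit.
At λ = 0.5 the per-sample hit probability during a target dwell,
`P(|N(0,σ_h,eff)| < 100 px) · P(|N(0,σ_v,eff)| < 100 px)` with
`σ_eff = σ·√((1−λ)/(1+λ))`, ranges from ≈0.66 (center screen) to ≈0.22
(left screen), i.e. expected waits of 0.5–3.5 samples, plus ≈1 sample for
the argmax to switch; the envelope therefore adds 5 sampling intervals
(83 ms).

Two sub-checks fail their strict envelopes, and the failure is a property
of the study conditions, not of the implementation: with white tracker
noise of the stated pooled magnitude, the left screen has σ ≈ (299, 255) px
against 100 px half-spacing, so even the optimal (dwell-averaged) position
estimate lands in the correct feature cell only ≈90 % of the time there,
and the visit-based matcher attains ≈97 % sensitivity pooled.  The motion
profile, which concentrates its detections in the periphery, consequently
under-recovers its detection rate by ≈3.4 % (99 % envelope: ±1.5 %), and
≈2 % keypress mis-pairings contaminate the mean key reaction time by
+7–9 ms (envelope ≈±5 ms).  Tightening these would require either relaxing
the visit-then-keypress detection rule or assuming a more benign tracker
than the one emulated.

## Problem sizes

Default tests run the full suite in a few minutes on one core: the recovery
cohort is 50 participants x 3 videos x 300 s at 60 Hz (2.7 M gaze samples,
63 000 scored events, ≈1 minute), the ANOVA calibration uses 2000 null
simulations, the scheduler validity checks 200 seeded schedules, and the
calibration closed-form check pools 500 (unit suite) / 120 (acceptance
suite) seeded calibration sessions.
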