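# Methods

This note documents the models behind `cprkinemat`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic-data
generator does and does not emulate.

## The kneeling-rescuer chain

The simulated rescuer is a nine-segment biokinematic chain — hands,
forearms, upper arms, trunk, and upper legs, with the lower legs included as
ground contacts — kneeling on the +y side of a manikin whose sternum
compression point is the origin (x = manikin longitudinal axis, y lateral,
z vertical). Shanks lie flat on the floor pointing away from the manikin;
hip height follows from upper-leg length and knee flexion; the trunk runs
from the pelvis to C7‑Th1 at the configured inclination; the right palm
rests on the sternum with the left hand stacked 30 mm above it.

Joint angles use the 0° = fully-extended flexion convention. Full
joint-coordinate-system angles would require segment orientation triads; the
quantities of interest here are uniaxial flexion values, so angles are
computed as planar angles between adjacent segment axes built from sensor
positions (the stream carries MVN-style joint centres bounding each
segment). The reading-aid mapping to a chest-plane convention is
α_chest = 90° + α_dev.

**Posing.** Knee flexion angles and trunk inclination fix the lower body and
trunk shape; the elbow flexion angles fix the two shoulder-to-palm distances
through the law of cosines (the hand is modeled collinear with the forearm).
The body's horizontal placement is then solved in closed form as the unique
position where both shoulders sit at their required distances from the
stacked palms; the elbows are placed by two-link inverse kinematics, flaring
laterally. If an arm span is shorter than the vertical shoulder-to-palm
drop, or the two spans admit no common placement, the chain cannot reach
floor and chest simultaneously and posing fails with a geometry error.

A consequence of the reference posture (trunk only 23.4° above the
horizontal, hips at ~436 mm, near-straight elbows): the solved chain places
the shoulders well to the side of the sternum, so the palm→C7‑Th1 line
deviates ~47° from vertical. The chain is internally consistent and every
configured angle is exactly recoverable; the force-decomposition operation
is independent of this geometry.

**Reference postures.** `correct` is the posture associated with adequate
compression depth: knees 109° (left) / 97° (right), elbows 14.1° / 3.7°,
trunk 23.4°. `shallow` reduces both knee flexions by 8°, the direction
consistent with the positive LKFA regression coefficient and with keeping
knee flexion above 90°. `PosturePose.hip_height` is descriptive metadata
implied by the leg geometry, not an independent degree of freedom.

## Trial simulation

Motion is superimposed on the statically posed chain (re-posed per minute
when pose drift is configured):

- **Compression.** The palm marker moves down by a raised-cosine cycle
  (50% duty) at the configured rate; peak excursion equals the configured
  depth. Each compression's amplitude is additionally scaled by
  1 + ε_k, ε_k ~ N(0, `cycle_jitter_frac`²) per cycle (default 5%):
  humans are not metronomes, and a strictly periodic signal would make the
  clock-offset estimate ambiguous up to the cycle period.
- **Sway.** C7‑Th1 traces a horizontal ellipse at the compression frequency
  (trunk rocking), default semi-major amplitude 10 mm with a 0.6 axis ratio.
  This yields path lengths of ~2.8 m per 30-s window, the scale observed in
  real trials.
- **Drift.** Linear per-minute additive changes to depth and/or pose angles
  (fatigue); default zero.
- **Noise.** i.i.d. Gaussian position noise per sensor coordinate (default
  SD 2 mm, a typical inertial-capture position error).
- **Manikin stream.** Depth equals the palm's downward excursion clipped at
  zero, timestamped on a clock shifted by the configured offset. The
  manikin's compression resistance (9.0 N/cm²) is carried as metadata.

Carrying the compression with the palm marker and the sway with the C7‑Th1
marker keeps the remaining chain at the configured pose, so noiseless
round trips recover every configured angle to well under 0.5°. The price is
a rigid-body approximation: elbows and trunk do not dynamically flex within
a compression cycle. Defaults: 60 Hz sampling (typical for inertial
motion-capture exports; configurable, minimum 20), 110 cpm, 50 mm depth.

What the generator does **not** emulate: orientation (quaternion) channels,
soft-tissue artefact, sensor drift/bias of real IMUs, the irregular wander
of real postural sway (the regular sway ellipse yields EA ≈ 600 mm², below
the several-thousand-mm² medians of real trials), inter-subject
anthropometric variation, and within-cycle joint flexion. Passing round-trip
tests therefore demonstrates correctness of the extraction pipeline, not
realism of human variability.

## Sway metrics

PL is the summed Euclidean length of the projected trajectory (horizontal
plane is the headline; the projection plane is an argument). No filtering is
applied by default — sensor noise inflates PL, and an optional centred
moving-average smoother (odd window) is available in the pipeline for noisy
data. "95% of positions" is implemented as the χ²-based bivariate-normal
prediction ellipse, the standard posturography definition; an
empirical-quantile variant (`method="quantile"`, scaling by the 95th
percentile of squared Mahalanobis distances) is available where exact sample
coverage is wanted. Ellipse areas are reported in mm² (an area cannot be in
mm, whatever conventions appear elsewhere). Fewer than three points or a
rank-deficient covariance raises a degenerate-trajectory error.

## Synchronization, cycles, windowing

The manikin clock offset is the lag maximizing the normalized
cross-correlation between the manikin depth and the negated vertical palm
excursion, searched on the kinematic sample grid over ±5 s; a peak
correlation below 0.5 means the streams do not co-vary and is an error.
Resolution is one sample period.

Compression peaks need ≥10 mm prominence and ≥0.25 s separation; per-peak
depth is the local maximum; window rate is 60·(k−1)/(t_last−t_first) over
the k peaks in the window and is flagged NaN when k < 2.

Feature rows are per minute: sway and angle features over the first 30 s of
each minute (the kinematic recording window), depth and rate over the full
60 s (the depth-averaging convention) — both windows are overridable.
Windows are half-open [start, end); incomplete trailing minutes are dropped,
never padded. Grouping: `deep` iff depth ≥ threshold (boundary inclusive),
default 40 mm with an override (50 mm is the other convention in
circulation for this threshold).

## Feature-level generator and statistics

Standardized predictors (rate, PL, LKFA, LEFA) are 4-variate normal with
equicorrelation ρ; standardized depth is βᵀx + ε, ε ~ N(0, 1 − R²). Given
target R², ρ solves Σβᵢ² + 2ρΣ_{i<j}βᵢβⱼ = R² (with the default β this
gives ρ = −0.1661); ρ outside (−1/3, 1) — the positive-definiteness bound
for four predictors — is reported together with the attainable R² range.
Physical units are conventions chosen so the implied raw coefficients are of
realistic magnitude: rate (110, 10) cpm, PL (2600, 700) mm, LKFA (103, 7)°,
LEFA (9, 6)°, depth mean 42 mm with SD 4 mm. The raw intercept follows from
these means rather than being imposed.

Note an intrinsic property of the calibration: the PL coefficient is
negative (and the implied marginal PL–depth correlation ≈ −0.36), so in
generated tables the deep group has the *shorter* median path length. A
group ordering with longer PL in the deep group cannot be produced by any
generator faithful to these coefficients; published trials reporting both a
negative partial coefficient and a higher deep-group PL median are
internally inconsistent at the generator level.

OLS is solved from the normal equations with standard errors from
σ²(XᵀX)⁻¹; standardized β = b·s_x/s_y with matching SEs; two-sided
p-values; adjusted R², overall F and residual SE as conventionally defined.
Collinearity is judged on the z-scored design (scale-invariant) and
offending columns are named via pivoted QR. Mann–Whitney U uses midranks;
the two-sided p is by exact enumeration of all pooled-rank splits when both
groups have ≤ 8 observations (U is symmetric about n₁n₂/2, so the
two-sided tail is well-defined under ties), otherwise a normal approximation
with tie and continuity corrections. Group comparisons route through a
Shapiro–Wilk gate (α = 0.05 per group, delegated to scipy; overridable) to
Student's t (equal variances) or Mann–Whitney. p-values are two-sided
throughout. Degrees of freedom are always computed from the data.

## Problem sizes

The test suite and the acceptance script simulate at the study's scale where
that is cheap (10-minute trials at 60 Hz, 50 × 10⁴-row generator
replicates — all a few seconds on one core) and use 30 s trials for the
synchronization lag grid, where the estimate is already at one-sample
resolution.

## Known limitations

- Positions only; no orientation estimation from raw inertial signals.
- The reduced chain omits head, feet and per-vertebra spine segments; only
  the angles the analysis consumes are modeled.
- The compression waveform is a raised cosine; real depth traces have
  asymmetric release and incomplete recoil, which the cycle detector
  tolerates but the generator does not produce.
- Repeated-measures structure (minutes nested in subjects) is not modeled;
  the regression treats rows as exchangeable, as the feature-level
  calibration defines them.
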