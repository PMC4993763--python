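# Methods

`dyadsync` quantifies non-verbal coordination between two seated people
from a fixed camera: how much they move together (synchrony), who
follows whom and by how much (entrainment), how leadership alternates
(dominance bouts), and how much high-frequency "jitter" each person's
motion carries. This note records the model, the conventions and
defaults, what the synthetic generator does and does not emulate, and
the numerical choices.

## Motion kinetic energy

Frames are converted to grayscale (Rec. 601 luma) and dense optical flow
is estimated between consecutive frames. The kinetic energy of a frame
region is the sum of squared pixel velocities, `Σ (u² + v²)` in
px²/frame². A vertical boundary column — by default the frame midline,
configurable per recording — splits every frame into a subject region
and an actor region; flow is estimated once over the whole frame and
summed per region, so the two regional energies add up to the
whole-frame energy exactly.

Flow estimation is pluggable behind `FlowParams`:

* `ilk` (default): dense iterative Lucas–Kanade, `radius=7`, computed in
  float64. Accurate to a few percent for the ≤ 2 px/frame displacements
  of seated people, and fast enough for frame-rate video.
* `tvl1`: dense TV-L1, a robust variational estimator; slower, kept for
  cross-checking and noisy footage.
* `diff`: the absolute intensity difference treated as speed. Not a
  flow estimator (no translation-recovery property) — a cheap monotone
  proxy used in tests.

The downstream mathematics depends only on the contract that a global
translation of a textured pattern is recovered by the spatial mean of
the field (verified to within 10 %); the estimator identity is
interchangeable.

Energy series are *not* smoothed or per-person normalized: scale
invariance comes from the normalized cross-correlation, and smoothing
would bias the jitter band.

## Cross-correlation, synchrony, entrainment

For energy series `E_S(n)`, `E_A(n)` of length `N`:

    c(τ) = Σ_n (E_S(n+τ) − Ē_S)(E_A(n) − Ē_A) / ((N − |τ|) · std(E_S) · std(E_A))

Positive lag means the subject's activity matches the actor's earlier
activity (subject follows actor). Under this convention `c(0)` is the
Pearson correlation of the two series and is the synchrony feature `x`.
A "raw" normalization — plain lagged product sum divided only by the two
standard deviations, no centring, no length correction — is retained as
an option; it is not a correlation coefficient and is never used
downstream.

Entrainment `y` is the centre of mass of `c(τ)` over lags `[−T, T]`,
reported in seconds. Defaults: `T = 15 s` whole-recording, `5 s` inside
moving windows. A centre of mass needs non-negative weights, and raw
correlation values are noisy; three weighting modes exist:

* `significant` (default): estimate the sampling-noise level σ̂ as the
  RMS of the negative correlation values (for non-negatively coupled
  dyads those are pure noise), subtract `z·σ̂` with `z = 3`, clip at
  zero. If nothing survives, fall back to plain clipping. Rationale:
  with autocorrelated energy series the clipped noise floor across
  ~750 lags carries mass comparable to the true peak and drags the
  centre of mass toward zero; thresholding removes that bias (lag
  recovery at 1/2/4 s improves from roughly half the runs in-band to
  59/60).
* `clip`: clip negatives at zero (no floor subtraction).
* `raw`: signed weights; unstable when the denominator is near zero,
  provided for completeness.

Time-resolved entrainment uses a 20 s moving window with a 1 s hop;
windows are fully contained in the recording, and a window in which
either person's energy is constant yields NaN rather than an error.
Dominance bouts are maximal runs of windows with a constant centre-of-
mass sign (positive → actor leads); NaN or exactly-zero windows break
runs. Bout duration is run length × hop, and the dominance ratio is
mean subject-led duration / mean actor-led duration — near 1 for
balanced turn-taking, undefined (an error) if one side never leads.

## Jitter band power

The one-sided periodogram of an energy series uses the convention
`P[k] = |X[k]|²/N²`, doubled at interior bins, so the non-DC total
equals the series variance exactly (Parseval); a linear detrend is
applied by default so drift does not leak into low bins. No taper and
no Welch averaging by default — the band-power integral over a 3.5 Hz
band at several-minute durations is already well averaged; Welch
averaging is available as a cross-check.

Jitter is the total power in 1.5–5 Hz. The upper edge is configurable up
to Nyquist; 5 Hz is the operational upper edge of the followership
band, and at 25 fps leaves a guard zone below the 12.5 Hz Nyquist.
Group comparisons use absolute band power; a normalized fraction
(band / total non-DC) is available for scale-free checks.

## Cohort statistics and classifier

Group differences per metric use the Mann–Whitney U test with the
rank-biserial effect size `r = 2U/(n_a n_b) − 1`, where U counts pairs
with the group-B value larger (ties half). For `n_a·n_b ≤ 64` the
p-value is exact by full enumeration of group assignments, two-sided as
twice the smaller tail (the convention of scipy and R; with ties the
permutation distribution of U is asymmetric, so "distance from the null
mean" would disagree). Larger groups use the normal approximation with
midrank tie correction and continuity correction.

The scenario classifier is a two-feature logistic model

    P(engaged | x, y) = 1 / (1 + a·e^(bx + cy))

fit by unpenalized maximum likelihood (`a = e^(−β₀), b = −β₁, c = −β₂`
relative to the standard sigmoid parameterization). Uncertainty and
accuracy come from bootstrapping dyads with replacement (default 1000
replicates, seeded): each replicate is refit and its accuracy evaluated
out-of-bag — on the dyads the replicate did not draw — which avoids the
optimism of in-sample evaluation (an in-sample flag exists, as the
evaluation protocol behind a reported accuracy is ambiguous in general).
Replicates that draw a single class, or leave no out-of-bag dyads, are
redrawn so the replicate count is exact. A replicate whose resample is
linearly separable has an unbounded MLE; separability is detected
exactly (the fitted hyperplane classifies its training data perfectly)
and such replicates are excluded from parameter summaries while their
accuracy still counts. The decision threshold is P = 0.5, i.e. the
boundary line `bx + cy = −ln a`.

## Synthetic dyads

The generator exists so that every stage can be tested against known
ground truth. Each person's latent velocity is a slow drive (low-pass
filtered Gaussian noise, cutoff 0.4 Hz — posture shifts and gestures)
plus a broadband component (`fast_frac = 0.35` — fast small movements).
Three mechanisms couple the dyad:

* **shared zero-lag drive** (`sync_strength`): a common component both
  velocities carry, producing simultaneous co-movement. Because energy
  is squared velocity, `c(0)` is approximately the squared velocity
  correlation; strengths of 0.5–0.9 span `c(0)` ≈ 0.1–0.35.
* **lagged followership** (`coupling_sa`, `coupling_as` with lags):
  mixes the other person's delayed drive into one's own velocity. The
  broadband component is copied along with the slow one, which is what
  makes the cross-correlation peak sharp at the true lag.
* **jitter** (`jitter_amp`): 1.5–5 Hz band-limited noise added to a
  follower's velocity, scaled by that person's followership strength.

Energy is the squared velocity plus rectified measurement noise
(`noise_sd·|η|`), guaranteeing non-negativity.

Scenario presets: the disengaged preset A is one-way (subject follows
actor, coupling 0.55 vs 0.05, 2 s lag, weak shared drive 0.5, little
jitter 0.25); the engaged preset B is mutual (0.6 both ways, 1.5 s
lags, shared drive 0.85, jitter 0.8). Cohorts draw per-dyad log-normal
perturbations (15–30 %) around the preset and encounter durations from
a normal (210 ± 49 s) clipped to 123–379 s, at 25 fps. The preset
constants were chosen once so that group-mean `c(0)` lands near the
0.1–0.35 range the analysis is designed for; they are calibration
conveniences, not claims about real encounters.

What the generator does **not** emulate: real optical-flow noise and
occlusion, non-stationary coupling within an encounter (except by
explicit construction), asymmetric energy scales between people,
camera shake, and realistically *overlapping* group distributions —
the preset contrasts (e.g. jitter effect sizes near 1) are sharper
than real cohorts. Passing tests therefore demonstrate that the
pipeline measures what it claims on data with known structure, not
that real encounters will separate this cleanly.

The video-level generator renders one rigidly moving textured square
blob per half-frame, with blob centres rounded to integer pixels so the
ground-truth energy is exactly area × displacement². Textures are
band-limited (Gaussian-smoothed noise, correlation length 1.5 px):
aliased white-noise texture defeats gradient-based flow at odd 1-px
shifts. Background and blob carry the same contrast, so the estimator
has well-conditioned gradients everywhere and does not smear blob
motion into a flat surround; with these choices measured energy agrees
with the analytic value to ~10 % (tolerance used in tests: 25 %).

## Problem sizes

The test suite and the acceptance script run at the scale the analysis
targets: 200–210 s dyads at 25 fps (≈ 5000 energy samples), cohorts of
21 + 22 dyads, 200–1000 bootstrap replicates, and 100-frame rendered
clips at 80 × 128 px for the video stage. The full suite runs in about
a minute on one core.

## Known limitations

* Video containers requiring system codecs are not readable in a plain
  installation; image-sequence directories (and any format imageio can
  decode) are the supported video inputs, and precomputed energy CSVs
  bypass the video stage entirely.
* The analysis start/end trim is configuration — there is no automatic
  detection of when the interaction proper begins.
* Energy mixes both people's motion within each region; anything
  crossing the boundary column (hands over the desk) is attributed by
  pixel position.
* No surrogate/permutation baseline for synchrony significance is
  built in; `c(0)` of autocorrelated series has a sampling scale much
  larger than `1/√N`, so per-dyad values should be compared between
  conditions, not tested against zero informally.
* At small cohort sizes the fitted `a = e^(−β₀)` is heavy-tailed across
  bootstrap resamples; prefer the central fit and the accuracy
  distribution when summarizing.
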