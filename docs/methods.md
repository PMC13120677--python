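# Methods

This note documents the models implemented in `flukeprints`, the
assumptions behind them, the synthetic-data generator that stands in for
field footage, and the numerical choices made where the design was open.

## Measurement model

A gimbal-stabilised dual sensor (RGB + thermal) points straight down at
the sea surface, so a single scalar — the ground sample distance,
GSD = altitude / focal length in pixels — maps pixel distances to
metres. Radial lens distortion is removed with a Brown–Conrady
polynomial evaluated on the pixel radius about the principal point;
intrinsics are accepted as configuration rather than estimated, since
camera calibration is the job of external photogrammetry tooling.
Oblique frames are rejected for measurement (no uniform ground scale)
rather than corrected. Coordinates follow the standard conventions:
image origin top-left with y down; the world frame is local east/north
metres; compass bearings are atan2(Δeast, Δnorth) in [0°, 360°) with
0° = north.

Altitude enters linearly, so a ±0.5 m barometric error at 90 m
contributes ±0.6 % scale error; annotation noise of ~1 px contributes
the GSD per click. Accuracy is validated by measuring an object of known
length (the package reports mean absolute and relative error of repeated
measurements).

## Morphometrics and age classes

Flukeprint width — the print axis parallel to the fluke, perpendicular
to travel — is summarised per individual over quality-passing prints
only: annotated at most 5 s after fluke emergence and not flagged as
degraded. Degraded prints are excluded from size estimation but retained
for movement analysis, since deformation affects the print boundary more
than the centroid.

Scaling of body length and fluke span on width is fitted by OLS in four
scopes: pooled, within-adult, within-calf, and an interaction model
`response ~ width + class + width:class` whose interaction term is
tested with a partial F-test against the additive model. Model skill is
measured by k-fold cross-validation (default 10 folds, simple random
with fixed seed; folds are reduced to n with a warning when a scope is
small). Held-out R² is defined as 1 − SSE/SST over the pooled held-out
predictions, which is seed-stable and can go negative for a
signal-free response. A response with literally zero variance is
reported as R² = 0 rather than the indeterminate value OLS software
produces.

Age discrimination uses a logistic model of class on mean width. The
ROC is computed directly over width thresholds — for a single monotone
predictor this is equivalent to scanning probability thresholds — and
AUC equals the Mann–Whitney probability that a random adult's width
exceeds a random calf's. The operating threshold maximises Youden's
J = sensitivity + specificity − 1; ties are broken towards the smallest
threshold, and the reported threshold is placed at the midpoint of the
gap between the adjacent observed widths, the standard reproducible
convention. Complete separation (disjoint class widths) is flagged, the
iteration-capped logistic deviance reported as computed (≈ 0), and no
error raised: separable data are the expected regime here.

## Speed and method agreement

Each surfacing event yields two speed estimates: the mean of
frame-to-frame rostrum displacements divided by elapsed time (RGB), and
the mean of inter-centroid print spacings divided by their time
intervals (TIR), with mean spacing retained as the predictor for the
speed model. Spacing increments are formed only between consecutive
print identifiers; increments spanning a gap are dropped.

Paired event speeds are compared with differences oriented RGB − TIR
(RGB is the observational reference). The battery comprises: bias with
a t-based 95 % CI; limits of agreement bias ± 1.96 SD; RMSE, MAE and
nRMSE (RMSE / mean RGB speed); MAPE and median MAPE relative to RGB
(zero-RGB pairs excluded with a warning); ICC(A,1) from the
McGraw–Wong two-way random-effects absolute-agreement formulation with
its F-based confidence interval (identical ratings are defined as
ICC = 1); a paired t-test; proportional bias as the OLS slope of
differences on pair means; and the shares of differences within 0.5 and
1.0 m/s. Deming regression (closed-form errors-in-variables slope,
jackknife standard errors, Wald tests of slope = 1 and intercept = 0)
assesses calibration; the error-variance ratio defaults to λ = 1
because both channels are image-derived speeds of comparable precision.

## The spacing-to-speed mixed model

    log(speed_ij) = β₀ + β₁ log(spacing_ij) + u_i + ε_ij

with a whale-level random intercept u_i ~ N(0, σ_u²) absorbing repeated
events and residual ε_ij ~ N(0, σ_e²). Natural logarithms are used
throughout so the log-normal back-transform takes the familiar forms:
median exp(η) and bias-corrected mean exp(η + (σ_u² + σ_e²)/2) for a new
whale. Estimation is REML by default; ML is used when comparing
fixed-effect structures (log body length can be added behind a flag but
is excluded from the default model). Explanatory power follows
Nakagawa–Schielzeth: marginal R² = σ_f²/(σ_f²+σ_u²+σ_e²) and conditional
R² = (σ_f²+σ_u²)/(σ_f²+σ_u²+σ_e²), with σ_f² the variance of the fixed
linear predictor.

Still-image prediction propagates all three uncertainty sources: on the
log scale, η = β₀ + β₁ log s with predictive variance
v = xᵀVx + σ_u² + σ_e² (V the fixed-effect covariance), and the 95 %
prediction interval is exp(η ± z₀.₉₇₅ √v) with the plain normal
quantile — no small-sample degrees-of-freedom correction. The
bias-corrected mean deliberately excludes the fixed-effect term xᵀVx:
it is the plug-in mean of the response distribution for a new whale,
not a posterior-predictive mean; both-variance (σ_u² + σ_e²) correction
is the new-whale convention and is documented here because the
alternative (σ_e² alone) is equally defensible for a known whale.

Validation is leave-one-whale-out: all events of one whale are
withheld, the model refitted, and the withheld events predicted at the
population level (u = 0) — the left-out whale's intercept is by
construction unknown. RMSE and MAPE are computed on the back-transformed
(m/s) scale and interval coverage as the share of observed speeds inside
the prediction intervals.

Numerical choices: the optimiser retries lbfgs/bfgs/cg/powell in turn
and reports non-convergence; when the estimated σ_u² falls below 10⁻⁸
of the total variance the fit is treated as sitting on the zero
boundary and the fixed effects are replaced by their exact OLS values,
which the mixed model approaches continuously in that limit. A
single-whale dataset degenerates to OLS with a flag, since σ_u² is then
unidentifiable.

## Orientation

A flukeprint's posterior edge diffuses before its anterior edge, so the
posterior→anterior axis points along the direction of travel. Its
compass bearing is paired — by whale, event and sequential print
identifier — with the tail→rostrum bearing from the RGB frame nearest
in time. Differences are wrapped to (−180°, 180°] (exact opposition
maps to +180° by convention) and summarised with circular statistics:
mean direction and resultant length R̄ of the unit-vector sum, circular
SD √(−2 ln R̄) (reported in both degrees and radians), the Rayleigh
statistic Z = nR̄² with the small-sample p-value refinement
exp(√(1+4n+4(n²−R_v²)) − (1+2n)) alongside the asymptotic e^(−Z), and
the Fisher–Lee circular correlation with its asymptotic normal test.
Agreement categories use inclusive upper bounds (≤ 5°, ≤ 15°, ≤ 20°;
above that, Discrepant). Summaries are emitted both pooled and per
whale. World-frame bearings assume annotations in local east/north
coordinates; when only pixel coordinates exist the frame's north
alignment (drone yaw) must be supplied, otherwise bearings are
image-relative.

## The synthetic-data generator

The generator emulates the survey's sampling frame so that every
downstream stage has a known truth. Defaults, with the reasoning:

| parameter | default | why |
|---|---|---|
| adults / calves | 80 / 12 | surveyed class sizes |
| adult body length | N(12.0, 1.0) m | typical adult humpback |
| calf length | adult × U(0.30, 0.50) | calves at most half the adult's length |
| fluke span | 0.30 × body length | humpback span-to-length ratio |
| print width | 0.9 × span + class noise (adult SD 0.15 m, calf SD 0.35 m) | two separable clusters; calves' compliant flukes decouple width from morphology |
| event speed | U(0.8, 1.6) m/s | breeding-ground swimming speeds |
| stroke period | 1 / U(0.20, 0.33 Hz) | typical slow tailbeat rates |
| sampling | 30 Hz, dual sensor, 90 m altitude, ±0.5 m SD | survey protocol |
| pixel noise | 1 px per annotation | manual click accuracy |
| heading noise | TIR 6.3°, RGB 1.0° | combines to a paired-difference SD near 6.4° |
| observation model | β₀ = −0.30, β₁ = 0.33, σ_u = 0.075, σ_e = 0.143, spacing ~ logN(1.723, 0.40²) | reproduces marginal/conditional explanatory power near 0.40/0.53 and a slope SE near 0.05 at ~60–70 events |

Tracks are linear with constant speed per event (analyses are restricted
to continuous linear swimming); one print is deposited per stroke
period, so consecutive centroids are exactly speed × period apart. For
the observation model, spacing is drawn first and speed derived through
the stated equation — not the reverse — so mixed-model recovery has an
exactly known truth.

Noise channels are independent: per-click pixel jitter, per-sensor
heading jitter, and altitude jitter (Gaussian truncated at ±3 SD). Two
channels are temporally correlated rather than white: the manual
body-tracking error on rostrum/tail (a dragged marker drifts smoothly;
white 1 px error at 30 Hz would dominate frame-to-frame displacements
and inflate mean speed severalfold, which real data do not show) and the
barometric altitude within a frame-rate-sampled series (a barometer
drifts, it does not jump between consecutive 33 ms frames). Both use a
1 s moving-average window, rescaled to preserve the configured marginal
SD. Single-click print annotations keep independent noise. Emitted
world coordinates are produced by imaging the true position at the
frame's actual altitude, adding pixel noise, and back-projecting with
the nominal altitude — so both error sources propagate exactly as they
would through real photogrammetry.

What the generator does **not** emulate: wake hydrodynamics and print
decay physics (the optional thermal raster demo uses Gaussian blobs with
a free decay constant that claims no realism), curved or accelerating
tracks, overlapping prints from interacting groups, and environmental
drivers of print persistence. Passing tests therefore demonstrate the
correctness of the estimators under the stated observation model, not
the field accuracy of the method.

## Validation problem sizes

The test battery uses these scales, chosen to exercise the estimators at
the sampling structure they target: slope recovery with 36 whales of 2
events each across 100 seeded replicates (estimate within 2 SEs of truth
in ≥ 90 of them); prediction-interval calibration with 50 whales × 4
events (nominal 95 % coverage, accepted within 92–97 % to allow binomial
Monte-Carlo variation at n = 200); and oracle equivalences (circular
statistics versus direct resultant vectors, Deming versus an
orthogonal-distance grid search, ICC(A,1) versus a hand-computed two-way
ANOVA, the mixed model versus OLS at the σ_u = 0 boundary) at
tolerances of 10⁻³ or tighter. Noiseless end-to-end identities are
required to hold to 10⁻⁹ relative error.

## Known limitations

* The spacing-to-speed elasticity fitted on the generator's kinematic
  tracks differs from the observation-model value (spacing there is
  speed × period with independently drawn periods), so the two synthetic
  routes deliberately answer different questions: parameter recovery
  versus pipeline integration.
* ICC confidence intervals use the McGraw–Wong F approximation, which is
  crude below ~10 pairs.
* The Deming jackknife understates uncertainty for n < ~10.
* REML variance components on few whales often sit at the σ_u² = 0
  boundary; the reported conditional R² then equals the marginal R².
* Heading extraction pairs each print with the nearest RGB frame in
  time; at 30 Hz this is negligible, but sparse RGB annotation would
  bias the pairing.
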