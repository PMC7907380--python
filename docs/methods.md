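# Methods

This note documents the models behind `herdwatch`, the parameters that
matter, what the synthetic world does and does not emulate, and the design
choices made where the problem was genuinely open. Everything empirical
referred to here is computed by the test suite, the examples, or
`scripts/acceptance.py`.

## The synthetic study system

The generator stands in for a fenced, predator-free savanna reserve with
collared sentinel herbivores and staged human intrusions. It exists so
that every downstream stage has ground truth: true 1-s positions, true
behavior labels, true intruder routes.

**Landscape.** Tree cover and elevation are independent spatially
autocorrelated Gaussian random fields (Gaussian-filtered white noise,
correlation length 300 m default); tree cover is logistic-squashed to
[0, 1]. Habitat suitability per species and time-of-day bin is a Gaussian
niche on tree cover (species-specific preferred cover, e.g. wildebeest
0.20, eland 0.45) discounted on steep slopes and min–max rescaled — a
deliberately simple used-vs-available stand-in for a fitted habitat
selection model, sufficient to make "normal behavior varies with habitat"
true in the synthetic world.

**Herds.** Movement is a correlated random walk with three-zone social
forces restricted to herd mates: repulsion inside 5 m, heading alignment
to 60 m, attraction to 400 m, blended with directional persistence and
wrapped-Gaussian turning noise (sd 0.35 rad/s). Each herd carries a
rest/graze/walk Markov state (mean dwell 15/10/5 min, speed factors
0.01/0.25/2.0 of the species mean: zebra 0.45 m/s, wildebeest 0.40, eland
0.35, impala 0.30, lognormal per-second variation with AR(1)
autocorrelation). The states are what make the adaptive GPS schedule and
the accelerometer-informed interpolation meaningful: animals genuinely
stand still for long stretches. Speed scales with local suitability
(factor 0.3 at suitability 0), so baseline behavior differs across
habitat and time of day — the property contextual standardization
exploits.

**Responses.** An animal entering the intruder's detection radius
(default 500 m; the radius at which real animals detect humans is not
established, so it is fully configurable) switches to *flight*: heading
rotated away from the intruder with small noise (sd 0.1 rad), speed ×3,
ODBA gain 2.5, for a duration drawn from a Gamma with the species'
reported mean and SD in minutes (zebra 47 ± 28, wildebeest 39 ± 33, eland
46 ± 18, impala 43 ± 14; a Gamma keeps the support positive while
matching both moments exactly). After flight the animal *regroups* toward
its herd centroid until within 40 m. Episode intensity (low/medium/high)
is assigned from the closest intruder approach during the episode, in
thirds of the detection radius. Outside response episodes the original
displacements are replayed from the displaced location.

**Sensors.** ODBA is a linear function of speed (0.05 + 0.5·v) plus
noise, summarized on a continuous 15-s grid (mean/max/variance). GPS
fixes follow the duty cycle: 15-min cadence at rest, the sensor's fast
setting (10- or 2-min, alternated across collars) when windowed mean ODBA
exceeds the activity threshold (0.08, set between resting and grazing
ODBA so herds run the fast mode roughly half the time). A 5-m geofence
suppresses fixes near the previous retained fix. Fixes get isotropic
Gaussian noise (default sd 10 m) and, at a configurable rate, spike
offsets of 500–1500 m in a uniform direction — built to satisfy all three
spike criteria so the corrector is genuinely exercised.

*Not emulated:* weather, predators, physiological energetics, inter-herd
interactions, collar dropout patterns, terrain-dependent GPS error. A
green test suite therefore shows the pipeline recovers what the generator
plants; it does not show field-data performance.

## Trajectory reconstruction

Five steps, each independently testable:

1. *Gross errors*: fixes outside the study box inflated by 500 m, or
   implying speed over a hard cap (30 m/s), are dropped.
2. *Spikes*: a fix is corrected when both legs exceed 500 m, its
   neighbors are within 100 m of each other, and the turning angle
   exceeds 150° (thresholds configurable). The spikiness score
   (min leg / gap) / (1 − turn/π), capped, maps through a saturating
   function to a shift of 50–100% of the way to the neighbor midpoint —
   spikier patterns shift farther. Criteria use original coordinates;
   endpoints are never flagged.
3. *Kalman smoothing*: per-coordinate local linear trend (position +
   velocity state) with exact irregular-interval transition matrices;
   process and observation variances shared between x and y and estimated
   per track by Nelder–Mead maximum likelihood (jitted filter;
   degenerate estimates fall back to a floor). Smoothing is two-sided
   (RTS), not filtering.
4. *ODBA-informed densification*: inter-fix gaps are filled at 10-s
   resolution; the displacement is split equally over the slots whose
   15-s ODBA mean exceeds the stationarity threshold (plus the terminal
   leg), while stationary slots repeat the previous position. Gaps
   without ODBA coverage fall back to plain linear interpolation,
   flagged.
5. *Spline resampling*: a weighted cubic smoothing spline per coordinate
   (observed fixes weight 1.0, interpolated points 0.3, target RMS
   misfit 2 m at unit weight) evaluated on the strict 60-s grid; per-step
   ODBA statistics are averaged from the windows inside each step. The
   spline stands in for an X-spline (an R-graphics primitive); with
   near-interpolating smoothing the curves are practically equivalent,
   and the weighting achieves the intended "trust measurements more than
   interpolations".

Intruder routes are high-rate and accurate, so they are only decimated to
the 1-min grid.

## Features and context

Base features per animal-minute fall into four classes (individual
geometry, accelerometer, collective, space use); windowed statistics use
a 10-min trailing window, MSD uses lags 1–5 min (log–log slope and
intercept: ~1 diffusive, ~2 ballistic), first-passage times use radii
{50, 100, 250} m. Collective features use conspecific neighbors within
200 m; alignment is the mean resultant length of neighbor headings. Space
use couples position to the landscape: suitability and tree cover at the
animal, elevation change, the Tobler hiking speed implied by the step's
slope (6·exp(−3.5·|S + 0.05|) km/h), a cost proxy (realized/Tobler speed)
and the suitability gradient along the heading. No feature depends on
absolute coordinates or timestamps; a translation of the whole world in
space and time leaves the matrix unchanged (tested).

Standardization subtracts the reference-set mean and divides by its
standard deviation (a literal divide-by-variance mode exists as a flag).
Reference sets: per species (all features), and per 30-m area, per
time-of-day bin × 5-week period, per area × time-of-day, per individual ×
time-of-day (a configurable subset). Degenerate or unseen groups fall
back to species statistics; missing values standardize to 0. Window
variants (5-min centered, 10- and 20-min lagging, centered-minus-lagging
differences) are computed on standardized columns. Finally all columns
are winsorized at the 0.001/0.999 quantiles and discretized to ordinal
deciles per species; the discretizer stores its edges so held-out folds
are transformed without re-fitting. The registry reports its own column
count; coverage of every named feature family was preferred over
replicating any particular column total.

## Selection and reduction

Importance uses proximity labels — animal-minutes within 1 km of a
concurrent intruder versus an equal-sized seeded draw of control
minutes — and four metrics: univariate Mahalanobis distance
(|μ₁−μ₀|/pooled sd), marginality ((μ₁−μ₀)/σ₀), specialization (σ₁/σ₀),
and random-forest Mean Decrease Accuracy. MDA is computed as permutation
importance on rows held out from the forest fit (the out-of-bag analog;
in-sample permutation rewards overfitting — a pure-noise feature scores
~0.5 there). Rankings order by Mahalanobis, |marginality|,
|log specialization| and MDA; the union of the four top-k lists is kept
(k = 125 by default; 25 in the desk-scale pipeline where only ~200
columns exist). A per-class PCA retains components to 95% variance within
each feature class, and a second PCA over the pooled scores
orthogonalizes across classes; classifiers consume the leading stage-2
components. K-means with 25 clusters per species over the reduced space
provides the unsupervised behavioral vocabulary.

## Classification, detection, localization

**Per-animal.** Undisturbed-vs-response: RBF SVM, γ = 10⁻³·²,
C = 10⁻²·², 8 components, equal class weights, per-species models with a
pooled fallback; flight-vs-regroup uses γ = 10⁻²·⁰, C = 10⁻¹·⁵, 12
components. Training follows the field protocol: undisturbed rows > 1 km
from the intruder thinned to 10%, response rows of medium/high intensity
only, intrusion-present periods only. Probabilities come from Platt
scaling inside the SVM; a seeded stratified cap (1500 rows per model)
bounds the kernel cost. The per-minute series is smoothed by a centered
running maximum over ±15 min. Evaluation is leave-one-intrusion-out
(the paired control travels with its intrusion), scored by the average
precision of the response class, pooled and per fold.

**System-level.** Per 15-min block: mean/max/sd/q90 of smoothed
probabilities, Moran's I of probabilities over animal positions with
inverse-distance weights, the Clark–Evans nearest-neighbor index of
predicted-undisturbed animals within their convex hull, and the mean
cluster-association log-odds. Cluster odds are computed leaving each
segment's pair out; computing them on all segments lets a segment vote
for its own clusters and measurably inflates null accuracy — the
calibration tests caught exactly this. Blocks aggregate to segments via
eight statistics (mean, sd, min, max and the same four of first
differences). Features are ordered by iterative residualized two-sample
t-tests (largest |t| added; its original values regressed out of the
rest; residuals standardized; repeat — the ordering is affine-invariant
and matches a brute-force reimplementation). The detector is an
unpenalized logistic regression on the top 7 ordered features (2-way
interactions optional), ridge fallback under separation, validated by
25× stratified twofold CV with per-fold re-ordering.

**Localization.** The odds-ratio surface follows the two-state mixture
reading: the numerator is p·(response joint density) + (1−p)·(null joint
density), the denominator the null joint density, with the null
wrapped-normal sd ρ₀ in both undisturbed directional terms. This is the
only reading that makes O_ij a well-formed likelihood ratio; the plain
product of the two weighted terms is retained behind a flag for
comparison. An undisturbed animal (p = 0) is exactly uninformative
(O ≡ 1), as is any animal whose response geometry equals the null
geometry — constant factors are absorbed by the normalization α.
Response geometry (log-mean distance μ₁, log σ₁, log ρ₁) is fitted per
5-min t_s bin (lognormal moments of log distance; wrapped-normal sd from
the mean resultant length) and interpolated by weighted 3rd-order
polynomials; t_s is clamped to [0, 45] min. The t_s clock starts where
the *raw* probability series crosses the max-F1 boundary — the smoothed
running-max series would lead the true onset by up to the smoothing
half-window and was observed to inflate the fitted onset distance.
Null constants come from control animals paired with uniformly random
hypothetical intruder positions, baking the study-area geometry into the
null. Surfaces use a 50-m grid, one per minute by default (5-min cadence
in the demo configs); per intrusion the 10 most condensed surfaces
(smallest top-5%-mass area) are scored by peak-to-truth distance.

## Problem sizes and calibration

The desk-scale study configuration is 40 animals (10 per species, herds
of 10), 10 staged intrusions of 2 h (alternating morning/afternoon and
foot/vehicle) with 10 paired same-clock controls on adjacent days, a
3 × 3 km landscape, and a 30-min warmup before each segment. Intruder
routes are steered through one herd's vicinity — the scaled-down analog
of the encounter rate a dense sensor network achieves. The calibration
tests run this configuration twice: with the response model off, the
behavior classifier (trained on proximity pseudo-labels, which carry no
behavioral signal) must collapse to prevalence and the detector to
chance within binomial sampling error; with responses on, both must
clear those bands. Acceptance thresholds were fixed from sampling-error
arithmetic (2·0.5/√20 for accuracy on 20 segments) before the runs.

## Known limitations

* End-to-end localization error at the desk scale is of the order of the
  response-distance scale (roughly 1–1.5 km on a 3-km world): with few
  sentinels, most responders are "stale" (large t_s), and their broad
  lognormal rings dominate the surface sum. Fresh responders and denser
  networks tighten the peak — the controlled-geometry tests show error
  shrinking with the number of responding sentinels — but a field-scale
  network is needed for sub-500-m localization.
* The null-condition behavior classifier needs *some* training target;
  proximity pseudo-labels are used and flagged. This changes the label
  source, not the feature pipeline, and is exactly what makes the null
  calibration interpretable.
* Flight-vs-regroup classification is exposed with its selected
  hyperparameters but is not wired into the detection chain, which
  consumes the binary response probability only.
* The Kalman smoother assumes isotropic GPS error and a shared variance
  pair per track; collars with activity-dependent error would need a
  regime-dependent observation variance.
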