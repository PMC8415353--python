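# Methods

This note documents the models, conventions and numerical choices behind
`instaphen`, and what the synthetic-data tests do and do not establish.

## Study design being modeled

Two groups — cases with a schizophrenia spectrum disorder (SSD) and healthy
volunteers (HV), 34 per group, ages 15–35 — each contribute their full
platform archive: posted images with timestamps, connection lists and
demographics.  Participants qualify with **≥ 5 posts spanning ≥ 90 days**
("three months" is operationalized as 90 days because calendar-month
arithmetic is ambiguous).  The unit of analysis is the participant: every
per-image feature is averaged within participant before any group test.

## Archive model

One canonical JSON dialect (documented in `archive_io`) carries media
metadata, connection lists and demographics; an adapter registry allows
real export schemas to be added without touching the data model.  Videos
and other non-image media are dropped with a logged count; multi-image
posts count one record per image file.  Unreadable rasters degrade to
`missing_image` posts that still contribute timestamps.  Timestamps are
kept in the archive's recorded local clock; a fixed UTC offset can be
applied at parse time (exports historically used UTC, and the study never
states a convention).

## Image features

* **Color spaces.** RGB channels are the stored 8-bit values.  HSV uses the
  hexcone conversion with H on **[0, 180)** (the half-degree 8-bit
  convention), S and V on [0, 255].  Hue is kept as a float rather than
  being rounded to integers.
* **Moments.** Per-image mean/SD/skew are *population* moments over all
  pixels (a pixel set is a complete population, not a sample); skew is
  m₃/m₂^1.5 and defined as 0 when the channel is constant.
* **Hue.** Hue is angular, so its per-image central tendency is the
  circular mean: each hue h maps to the angle 2h°, the resultant-vector
  angle is halved back.  A resultant shorter than 1e-9 (antipodal mass)
  yields a missing value.  No SD/skew is computed for hue.  Participant
  aggregation of hue is again circular (over per-image means); whether the
  original analysis aggregated hue circularly or arithmetically is
  unstated — circular is the defensible choice and the two agree whenever
  hues lie in a narrow arc.
* **Colorfulness** follows the opponent-color formula
  √(σ²_rg + σ²_yb) + 0.3·√(μ²_rg + μ²_yb) with population SDs; it is zero
  for any uniform gray image.
* **Aspect ratio.** aspect = width/height; a post is non-square when
  |aspect − 1| > 0.005 (absorbs one-pixel rounding at typical platform
  resolutions).  Posts before 2016-01-01 are excluded from aspect
  aggregation (non-square uploads only became generally available then);
  when no post qualifies the aspect features are missing, not zero.
* **Faces.** The original analysis used an OpenCV Haar frontal-face
  cascade.  OpenCV is not available in this environment, so the default
  real detector is scikit-image's bundled OpenCV-format **LBP frontal-face
  cascade** — the same boosted-cascade family — with pinned parameters
  (scale factor 1.1, step ratio 1, min size 24 px) and greedy IoU > 0.4
  merging of overlapping detections.  For synthetic cohorts the default is
  the **stub detector** that reads the generator's embedded ground-truth
  counts, making face features exactly recoverable and deterministic.

## Network and temporal features

Connection counts (followers, following, requested, hashtag, blocked,
close, restricted) are reported absolutely, normalized per month of use,
and as ratios (followers/following, requested/following).  Usage duration
is (last − first post)/30.44 days.  A zero `following` count makes the
ratios *missing* (never 0 or ∞); missing values are dropped pairwise with
a logged count.  The follower/following ratio is scale-invariant, hence
insensitive to account age — the reason it is preferred over raw counts.

Times of day bin into night [0, 6), morning [6, 12), afternoon [12, 18),
evening [18, 24) (half-open, lower bound inclusive, so 06:00 is morning);
weekdays are ordered Monday-first (ISO).  Both proportion vectors sum to 1
by construction.

## Group statistics

* **Gate.** Welch's t is used iff both samples pass Shapiro–Wilk at
  α = 0.05 *and* neither contains an extreme outlier, operationalized as a
  point beyond 3·IQR from the nearest quartile (the source analysis cites
  the outlier concern without a rule); otherwise Mann–Whitney U.  Constant
  samples count as non-normal.
* **Welch t** uses sample variances and Satterthwaite df.  **U** is
  reported for the case (SSD) sample with midranks; p is exact by
  enumeration for tie-free samples with n₁·n₂ ≤ 400, else the
  tie-corrected normal approximation.
* **Effect sizes.** Cohen's d uses the pooled (n−1)-weighted SD — with
  equal n this is √((s₁²+s₂²)/2), the convention that reproduces the
  published rounded values; the sign is SSD − HV.  Hedges g applies
  1 − 3/(4N − 9).  The 95% CI is the normal approximation
  d ± 1.96·√((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))); published CIs for such
  tables are not always reproducible from this (or any standard) formula,
  so printed CIs are not treated as ground truth.
* **No multiple-testing correction** in the primary table (matching the
  modeled analysis); a Benjamini–Hochberg column is available behind a
  flag.
* **Secondary regression**: OLS of a feature on
  {group, sex, age, 3 race dummies} plus intercept, with overall F(6, n−7)
  and R²; rank-deficient designs are rejected naming the collinear
  columns.
* **Robust mixed ANOVA.** For J groups × K within conditions, each group's
  condition vector is estimated by per-column 20%-trimmed means; the
  covariance of that estimate is the winsorized covariance scaled by
  (n−1)/(h(h−1)), h = n − 2⌊0.2n⌋.  Johansen-type Q statistics test the
  within main effect, between main effect and interaction; each Q is
  referred to F(q, q(q+2)/(3A)) after scaling by q + 2A − 6A/(q+2), where
  A is the usual weighted trace term.  With trim = 0 this reduces to
  Johansen's classical heteroscedastic model, and the implementation
  tracks a classical mixed ANOVA (pingouin) closely there.  Trimming ≥ 0.5
  is rejected.  The design must be balanced within subject, and each
  group needs more subjects than within conditions or the contrast
  covariance is singular.

## Cohort matching

Cases are matched 1:1 without replacement to controls on age, sex and race
via a logistic propensity model (standardized covariates, light ridge so
the fit exists under complete separation) and greedy nearest-neighbor
pairing on the logit, processing cases in descending propensity with ties
broken by input order.  This transparent greedy matcher deliberately
replaces genetic/optimal matching packages: the scientific content is the
matched design, and the simple algorithm is fully testable.  A balance
report gives each covariate's absolute standardized mean difference before
and after matching.

## Synthetic cohort generator

The generator states one explicit world, parameterized from the published
group summaries:

| layer | model | defaults |
|---|---|---|
| participant HSV target | Normal per group | S: 83.9 ± 9.88 (HV) vs 77.63 ± 13.53 (SSD); V: 138.8 ± 12.3 vs 132.1 ± 17.8; H: 31.0 ± 14.7 vs 25.3 ± 15.8 |
| per-image jitter | Normal around the target | SD 5 per channel |
| pixel spread | Normal, clipped to range | S-SD 50.1 vs 47.3, V-SD 65.3 vs 65.1, hue-SD 25 |
| faces | participant rate Normal(λ, sd) ≥ 0, per-image Poisson | λ 2.38 ± 1.01 (HV) vs 1.46 ± 0.79 (SSD) |
| followers/following | lognormal matched to mean/SD | followers 906.9/1565.5 (HV) vs 416.0/352.9 (SSD) |
| other connections | negative binomial (Poisson if var ≤ mean) | published per-type means/SDs |
| timestamps | weekday-weighted days over the span, weekend uplift ×1.5, time-of-day weights (.15, .15, .35, .35) | span 3.1–91 months |
| posting volume (full scale) | posts/month lognormal | 3.6 ± 6.4 (HV) vs 6.0 ± 13.5 (SSD), min 5 posts |

Scaled-down choices, made once for CI feasibility: rendered archives
default to 6–20 posts of 48×48 px per participant (the real cohort
averaged ~176 posts of ~1080 px).  The between-participant layer — which
is what drives every group statistic — is at full scale.  Calibration and
temporal simulations sample the participant-level and timestamp-level
layers directly at full-scale posting volumes without rendering pixels.
Faces are composited as patches of a license-free portrait photograph
(scikit-image's bundled astronaut image), cropped by the package's own
cascade so that the real detector path is exercisable; the stub detector
reads the recorded ground truth.  Generation is fully deterministic:
each participant draws from an independent child stream of the seed, and
written cohorts are byte-identical across runs.

**What a green test does not establish.**  Synthetic images are noise
fields around an HSV target, not photographs: colorfulness is emergent
(its group offset arises via the saturation/value offsets rather than
being pinned), absolute width/height are not calibrated, and cascade
recall on real photographs is not measured by the stub-based tests.
Clipping S and V at the range edges biases measured means upward by ~1–2
units; recovery tolerances account for this.

## Known limitations and honest failures

* With the published saturation offset (d ≈ −0.53) the two-sided Welch
  power at n = 34/group is ≈ 0.6, so the saturation row recovers
  significance in only ~68% of seeds; a higher bar is unattainable
  without inflating the generator's effect beyond the published one.
* The robust ANOVA's between-group term is conservative (type-I ≈ 0.03 at
  nominal 0.05) on the generator's proportion profiles, because
  heavy-tailed posting volumes with a minimum of five posts produce
  coarse, tied, compositional data whose winsorized covariance
  over-estimates the trimmed-mean variance.  On continuous Gaussian data
  the same code calibrates at the nominal level.
* Caption/comment text, likes, filter detection, selfie/expression
  analysis and deep-learning image content analysis are out of scope.
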