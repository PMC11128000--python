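# Methods

This note records the models, parameter choices and numerical conventions
behind `sevquant`, and what the synthetic-data generator does and does not
emulate.

## Imaging model

The label-free channel is modeled on ratio imaging over a plasmonic
metasurface. A raw frame divided by a target-free background frame gives an
intensity-ratio (IR) map whose particle-free pixels have mean 1 and
relative SD 0.005 under the reference imaging conditions; a sub-resolution
particle adds a PSF-shaped bump whose *peak* ratio is 1 + contrast/100.
Fluorescence channels are background-subtracted instead: particle-free
difference pixels have mean 0 and SD 10 DN. Both noise figures are
adopted as defaults of `DetectionConfig` and of the simulator; they can be
re-estimated from a target-free frame pair with
`estimate_background_stats` (3σ clipping, two passes) when data come from
a different instrument.

Detection assumes Gaussian background statistics. The significance
threshold is `mean + k·σ` with k = 3: IR > 1.015 (1.5 % contrast) for the
ratio channel, > 30 DN for fluorescence. Particles are strict
8-neighborhood local maxima of the map after Gaussian smoothing
(SD 1 px). Two deliberate conventions:

* the recorded contrast is read from the **unsmoothed** map at the maximum
  pixel, so smoothing stabilizes peak counting without biasing contrast;
* the threshold must hold on **both** the raw and the smoothed value at a
  candidate maximum. Smoothing with SD 1 px shrinks i.i.d. background
  noise by roughly 1/(2√π σ) ≈ 3.5×, so the 3σ raw threshold is ≈ 11σ on
  the smoothed map and isolated noise excursions (expected ≈ 0.13 % of
  pixels above 3σ, i.e. ~90 pixels on a 256² frame) are rejected, at the
  cost of an effective detection floor slightly above 1.5 % contrast
  (≈ 2.4 %, since a real PSF-shaped peak of SD 1.3 px is attenuated by
  1.3²/(1.3²+1²) ≈ 0.63 under the smoothing). The worked precision/recall
  bounds (≥ 0.95) are therefore stated for particles of ≥ 5 % contrast.

Maxima closer than `min_separation` (default 3 px ≈ ⌈2·PSF σ⌉, Euclidean)
are merged keeping the highest smoothed value; exact ties break by
row-major order, making the detector fully deterministic. ImageJ-style
"noise tolerance" (prominence) is exposed as an optional parameter,
default 0 (threshold-only), since no value is documented for the original
workflow.

Registration is translation-only phase cross-correlation with 1/20-px
upsampling; the shift is applied to the frame by cubic-spline resampling
and the border invalidated by the shift is excluded from statistics and
detection. A normalized-correlation confidence below 0.2 raises a
`RegistrationError` rather than silently accepting a meaningless peak
(two structureless noise frames correlate near 0). No flat-field
correction, non-rigid drift or gain modeling is attempted.

## Size calibration

Contrast converts to size through the quadratic
`size = a₂x² + a₁x + a₀` with defaults (0.1531, 7.096, 20.211); the
calibration is strictly increasing over the valid contrast range
(1.5–40 %), and its inverse is the positive root of the quadratic. The
18 % sEV-like cutoff corresponds to 197.5 nm under these coefficients —
the contrast cutoff, not the nominal "200 nm", is authoritative for
classification, and the boundary is inclusive (contrast ≤ 18 % is
sEV-like).

Because individual particles cannot be paired between the ratio-imaging
and particle-tracking instruments, `fit_calibration` matches percentiles
1–99 of the two distributions and fits the quadratic through the matched
quantiles by least squares. Per-particle lists and binned histograms are
both accepted for the reference side. A fit that is non-monotone over the
observed contrast range is refused with advice to restrict the range.
Sizes are kept at full precision internally and rounded only for
presentation (integer nm; retention to integer %, ASC/µl to one decimal).

## Colocalization

The colocalization unit is the particle. Fluorescence maxima are matched
to label-free maxima greedily in increasing distance order, capped at
2 px (≈ PSF σ scale; no radius is documented for the original overlay
procedure) with each detection claimable once. Greedy nearest-first is
equivalent to optimal assignment for well-separated spots and is
deterministic. Pixel-level coefficients (Manders/Pearson) are out of
scope. Occurrence % = matched / total label-free detections; an empty
denominator reports 0 % with a warning.

## Per-sample quantities

* Settlement curve: detector counts per pre-wash timepoint.
* Retention %: post-wash / pre-wash × 100. The standalone function takes
  whatever counts the caller supplies; `summarize_sample` uses the
  pre-wash **sEV-like** count as denominator when non-zero (else the
  total) and records which was used, since published practice mixes both.
* ASC/µl: post-wash count / assay volume, default 20 µl, per-sample
  overridable.

## Cohort statistics

A sample is called positive when its count strictly exceeds the cutoff
("above the threshold"). The ROC sweeps cutoffs 2…1682 in steps of 2 and
integrates (FPR, TPR) trapezoidally with (0,0)/(1,1) endpoints appended;
on integer-count cohorts this agrees with the rank-sum (Mann–Whitney) AUC
to well within 0.01, which the tests verify on randomized cohorts. The
one-proportion z-test reports a two-sided p-value (sidedness is not
documented for the original analysis).

The count-vs-tumor-volume relationship is the saturating power law
`Y = A·|x − x₀|^β + c` with defaults A = 101.7, x₀ = 3.48·10⁻⁷ mm³,
β = 0.12013, c = 5.42. `powerlaw_fit` estimates (A, β, c) by bounded
nonlinear least squares with jittered restarts; x₀ stays fixed at its
initial value because at measurable tumor volumes (≥ 10⁻² mm³) it is
numerically irrelevant and jointly unidentifiable with β. A fit pinned at
the β → 0 boundary (flat data) is returned flagged `degenerate`.

## Synthetic-data generator

The generator exists so the whole pipeline can be exercised against known
truth. One integer seed expands into independent substreams (placement,
sizes, arrival, wash, labels, noise), so identical configurations are
bit-identical and stages can be regenerated independently. Choices:

* **Noise**: multiplicative Gaussian. Only the ratio-image SD (0.005) is
  characterized for the reference conditions, so each of the background
  and sample frames receives relative noise 0.005/√2, making the ratio's
  SD ≈ 0.005 (to first order the ratio of two weakly noisy frames sums
  the variances). Same √2 split for the fluorescence difference SD 10.
  No Poisson/shot-noise or gain model.
* **Spots**: isotropic Gaussians of SD 1.3 px whose peak (not integral)
  encodes contrast, matching the peak-contrast convention of the
  detector; overlapping spots add in ratio space.
* **Sizes**: mixtures of truncated normals (default: single component
  mean 122 nm, SD 48 nm, the measured cell-line vesicle distribution);
  contrast is derived from size through the inverse calibration, so truth
  round-trips by construction.
* **Kinetics**: each particle's arrival time is exponential with mean
  `settle_halftime` (default 20 min), so the settled count follows
  n·(1 − e^(−t/τ)) — a Langmuir-like saturating accumulation. Only the
  monotone saturating shape is constrained by observation; the functional
  form is a modeling choice exposed in the config.
* **Wash**: Bernoulli survival per particle, 0.93 for specifically bound
  and 0.03 for non-specific binders (the measured specific retention and
  IgG-control figures); retained particles keep their positions apart
  from an optional configurable rigid shift used to exercise
  registration.
* **Fluorescence**: labeled particles get amplitude
  `slope·contrast + N(0, σ)` with slope 10 DN/% and σ = 45 DN, chosen so
  the measured intensity-vs-contrast Pearson r lands in ≈ 0.6–0.85
  (centered near the observed +0.72) for the default size distribution
  after detection noise.
* **Cohorts**: post-wash counts are normal draws with the study's group
  parameters (healthy 30 ± 19, cancer 244 ± 191 per 20 µl), censored at
  zero and rounded. Censoring (clipping) rather than resampling keeps the
  realized means close to the nominal ones (resampling a N(244, 191)
  truncated at zero would inflate its mean by ≈ 37).
* **Density guard**: configurations in which more than 10 % of particles
  are expected within 2·PSF σ of a neighbor are rejected (counting is
  ill-posed); placement additionally enforces a minimum spacing
  (default 6 px) by rejection sampling.

What the generator does **not** emulate: optical aberrations, focus
drift, non-uniform illumination, aggregated/overlapping vesicles, debris
with irregular shapes, camera artifacts, and the true (heavier-tailed)
shapes of patient count distributions — only their printed means and SDs.
Passing tests therefore demonstrate the correctness and calibration of
the computations under these idealized conditions, not instrument-level
performance on real plasma. In particular the default simulated cohort
yields lower separation (AUC ≈ 0.87 at the default parameters) than the
real cohort, whose empirical distributions are not normal.

## Problem sizes

Test and demo simulations use 256²–1024² frames with 40–1600 particles,
cohorts of 30–2000 samples, and 100 randomized cohorts for the
ROC-vs-rank-statistic agreement check; these sizes make the full suite
run in well under a minute while leaving every statistical tolerance
comfortably non-degenerate.

## Known limitations

* The effective detection floor (~2.4 % contrast) sits above the nominal
  1.5 % threshold; very small vesicles (< ~45 nm) are under-detected.
* Quantile-based calibration fitting assumes the two instruments sample
  the same underlying population; selection effects (e.g. tracking's
  insensitivity below 75 nm) bias the fitted curve at the extremes.
* Greedy matching can mis-assign labels when spot density approaches the
  matching radius scale; the density guard keeps simulations out of that
  regime but real crowded fields would need a global assignment solver.
* Retention and occurrence are ratios of counts from a single field of
  view; no spatial or across-field variance model is provided.
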