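# Methods

## The evaluation model

`atrophybench` evaluates the robustness of single-subject normative atrophy
mapping. The quantity under study is the voxel-wise z-score map

z(v) = (GM(v) − μ(v)) / σ(v),   v ∈ GM analysis mask,

where μ and σ are the voxel-wise mean and sample SD (n−1 denominator) over a
reference stratum: subjects of the same sex with age inside the closed
interval [target − w, target + w], w = 2 years by default. The impact of an
image modification is the RMSE of the z-difference between modified and
unmodified scans over the mask; its context is the test–retest benchmark
RMSE between two unmodified same-session acquisitions. Outliers are flagged
(a) above the 75th percentile of the benchmark RMSEs (strictly greater —
"higher than" the threshold), and (b) by Grubbs's maximum-normalized-residual
test applied iteratively: compute G = maxᵢ|xᵢ−x̄|/s, compare with the
two-sided critical value ((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n)
Student-t quantile with n−2 df, remove the flagged observation, repeat until
acceptance or fewer than 3 observations remain. α defaults to 0.05
(two-sided) — the standard convention; both are configurable. Ties at the
maximum deviation flag the lowest index, making iteration order-stable.

## The synthetic phantom

Real pipelines operate on VBM-style preprocessed GM density maps (segmented,
spatially normalized, modulated, smoothed). The generator emulates that
end-product directly in a common grid; there is no segmentation or
registration stage, so background voxels cannot leak into tissue
classification — perturbation impact is injected directly on the GM map, a
purely phenomenological stand-in for mechanisms like background-sensitive
tissue-class priors.

* **Geometry.** Brain support is an axis-aligned ellipsoid spanning 60% of
  each grid dimension, with a unit-peak parabolic density profile (peak GM
  density 0.8, falling to 0 at the boundary). Regions are geometric sectors:
  a central "deep" ball plus anterior/posterior × superior/inferior ×
  medial/lateral sectors named frontal, frontobasal, occipital, temporal,
  cerebellum; a face-exterior slab lies anterior-inferior, strictly outside
  1.2× the brain ellipsoid. Reproducible with no atlas download.
* **Subject model.** GM = base − a·profile·(age − 40) − s_M·profile·[male]
  + smooth subject field + smooth scan noise, clipped at 0. The age-slope
  amplitude a defaults to 0.003 density/yr (≈0.4%/yr of peak, a realistic
  adult GM decline), the sex offset to 0.02. The centering age of 40 years is
  an arbitrary constant recorded here and in the config.
* **Random fields.** White noise convolved with a Gaussian kernel (FWHM
  8 mm default, the common VBM smoothing scale) and rescaled to a target
  empirical point SD: subject field SD 0.05, scan noise SD 0.02. All
  generators are pure functions of their seed.
* **Cohort defaults.** `CohortSpec` defaults emulate a large adult normative
  cohort at reduced n: ages 18–77, truncated-normal mean 46.3 / SD 17.1,
  65% female, n = 200.
* **Patients.** Atrophy is planted with known voxel-level z-magnitude:
  inside each named region the density is reduced by effect × template SD,
  so z-scoring recovers a region mean of ≈ −effect. The anatomical base is
  the analytic cohort mean model for the patient's age/sex (so template
  estimation error is part of the end-to-end recovery), or the template mean
  itself for exact-recovery checks.
* **Repeats.** A repeat acquisition adds an independent smoothed noise field
  of point SD σ_rep. The benchmark pairs **two** independent acquisitions of
  the same anatomy, because a real test–retest pair carries independent
  noise in both scans; with spatially constant template SD s the expected
  benchmark RMSE is then √2·σ_rep/s. The default σ_rep = 0.011 places the
  benchmark design point at √2·0.011/0.054 ≈ 0.28 given the default template
  point SD s = √(0.05² + 0.02²) ≈ 0.054 — the mean test–retest impact
  reported for heterogeneous multi-scanner data.
* **Perturbations.** Applied in order: multiplicative global scale, additive
  Gaussian bias A·exp(−d²/2σ²) (center a region label or voxel coordinate,
  decay in mm), sub-voxel translation along a seeded random direction,
  multiplicative erosion inside a region, final clip at 0. A failure
  probability models crashing operators; failures are a typed outcome, not an
  exception. Because the Gaussian tail underflows to exactly 0.0 beyond
  ~39σ, a sharply localized face-exterior bias leaves every brain voxel
  bit-identical — perturbations supported outside the mask provably produce
  zero impact. The named presets are illustrative patterns (localized face
  bias, temporal erosion, global rescale + jitter), not models of any
  specific defacing tool.

## Pipeline choices

* **Strata and caching.** Each patient's template is built on demand at
  (sex, rounded age) and cached. Any stratum below `min_n` (default 10 —
  SD estimates get unstable below that) aborts with a config-level error
  before any subject is processed.
* **One pooled analysis mask.** The mask (mean > 0.2 density and SD > 1e-6)
  is derived from a template over the whole reference cohort and shared by
  all subjects, so RMSEs and deviation maps are comparable across subjects;
  stratum templates supply the μ/σ used in z-scoring. Voxels at or below the
  SD floor are excluded rather than z-scored, keeping z finite on the mask.
* **Default experiment.** 32³ grid at 4 mm (64³ for demonstration runs; the
  default sizes keep a full run in seconds on a laptop). The reference
  cohort for the default experiment is sampled uniformly over ages 50–77
  with balanced sexes (n = 500) — enriched over the patient age range
  55–74 so every sex/age ±2-year stratum comfortably exceeds `min_n` for any
  seed. Patients (n = 30) carry a planted 2.5-z temporal deficit; patient
  and benchmark anatomies use the analytic mean model (an individual smooth
  anatomy field would cancel exactly in the within-subject z-difference and
  is omitted).
* **Deviation maps** default to |mean over subjects of Δz| per voxel — the
  literal reading of an "absolute mean difference" map, preserving the sign
  structure of systematic bias before collapsing it; mean(|Δz|) is available
  behind `absolute_first=True` since the two conventions differ whenever
  deviations cancel across subjects.
* **Bookkeeping.** Failed perturbations are excluded from RMSE statistics
  and counted separately; outlier percentages use the successfully processed
  count as denominator. Percentiles use linear interpolation between order
  statistics (the rank 1+(n−1)p convention). Templates average subjects in
  canonical subject-id order, so results are exactly invariant to input
  permutation; all TSV/JSON outputs are byte-reproducible from a config
  (volumes default to uncompressed .nii because gzip embeds a timestamp).

## What the synthetic setting does and does not show

Passing tests demonstrate the *statistical machinery* — template
construction, z-scoring, RMSE, benchmark calibration, both outlier criteria,
failure bookkeeping — behaves correctly and that planted effects of known
magnitude are recovered. The phantoms are stationary, Gaussian and
geometrically idealized: they do not reproduce scanner heterogeneity,
segmentation/normalization errors, the heavy right tail of real impact
distributions, or any specific defacing tool's corruption pattern (no
quantitative model of those exists). Absolute RMSE values here therefore
characterize the synthetic noise regime, not any real defacing method.

## Known limitations

* z-maps use a single time point; longitudinal change maps are out of scope.
* The region atlas is geometric, not anatomical; region names indicate
  approximate position only.
* Grubbs's test assumes approximate normality; on strongly skewed RMSE
  distributions (typical of severe perturbations) it can both mask and
  over-flag — the benchmark-percentile criterion is the more robust of the
  two, which is exactly why both are reported.
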