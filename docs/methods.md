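# Methods

## Overview

`radtiles` implements a complete, testable version of a CT-radiomics model of
tumor-infiltrating-lymphocyte (TIL) enrichment and its downstream outcome
analyses. The chain has four stages:

1. **TILes scoring** of gridded pathology maps,
2. **radiomic feature extraction** (88 features, seven categories) from
   masked CT volumes,
3. **feature selection and the predicted-TILes LASSO model**,
4. **outcome statistics** (Kaplan-Meier, log-rank, Cox, rank/count tests)
   on predicted-TILes groups.

Because no paired clinical imaging/pathology/outcome dataset is distributed
with the package, a synthetic cohort generator provides data with a known
texture → TILes → outcome effect chain, and every stage is validated either
against hand-derived worked examples, independent brute-force oracles, or
parameter-recovery simulations on that generator.

## TILes: the TIL enrichment score

Each 1 mm² grid of a whole-slide H&E image carries an intra-tumoral TIL
density, a stromal TIL density, a cancer-epithelium area and an analyzable
tumor-microenvironment (TME) area. A grid is classified

* **inflamed** if intra-tumoral density ≥ τ_int (inclusive),
* **immune-excluded** else if stromal density ≥ τ_str,
* **desert** otherwise; a grid with zero TME area is **non-evaluable**.

When both densities exceed their thresholds the grid is inflamed: this is a
convention (intra-tumoral infiltration subsumes stromal), flagged as such.
The thresholds defining "high" density live inside the upstream AI pathology
model, which is out of scope; they are required inputs here, with synthetic
defaults τ_int = 300 and τ_str = 600 cells/mm² chosen only so the generator
and scorer agree.

TILes = (TME area of inflamed + immune-excluded grids) / (total TME area of
evaluable grids) ∈ [0, 1]. The denominator is area, not grid count, because
the definition divides by the whole analyzable TME area; a grid-count mode
exists behind `area_weighted=False`. Sample QC excludes samples with less
than 0.5 mm² total cancer epithelium or fewer than ten evaluable grids —
both strict inequalities, so the boundary values pass.

## Radiomic features

88 features in seven categories: first-order (18), shape (14), GLCM (24),
GLSZM (16), CDF (5), physical (2), fractal (9). Extraction is resampling
(trilinear for intensities, nearest-neighbour for the mask, 1 mm isotropic
default) followed by gray-level discretization and per-category computation.
A machine-readable catalogue ships in `radtiles/assets/feature_manifest.json`
so the counts are auditable.

* **Discretization.** Fixed bin count 32 by default; fixed bin width (HU)
  available. Levels are 1 + floor((x − min)/width) capped at Ng; a
  zero-range ROI discretizes to the single level 1. The realized binning is
  recorded in the extraction manifest because GLCM/GLSZM values depend on it.
* **GLSZM.** Zones are connected components of equal-level masked voxels,
  26-connectivity in 3D (8-connectivity within-slice mode for 2D fixtures).
  The two model features are
  GLV = Σ p(i,j)(i − μ)² with p = P/Nz, and
  LALGLE = (1/Nz) Σ P(i,j) j²/i².
  Construction is verified against a brute-force flood-fill oracle on ≥ 10⁴
  random small arrays and against the hand-evaluated worked example
  (GLV = 2/3, LALGLE = 49/12 on the 3×3 three-zone slice).
* **GLCM.** Symmetric co-occurrences at Chebyshev distance 1 over the 13
  unique 3D directions; features computed per direction and averaged.
* **Shape.** Mesh-based surface/volume (marching cubes at the 0.5 level on
  a lightly Gaussian-smoothed mask, σ = 0.8 voxels, which removes the
  staircase bias that otherwise inflates the surface area of a digitized
  ball by ~8%; thin ROIs that would vanish under smoothing fall back to the
  raw binary mesh), convex-hull diameters, PCA axis lengths
  (4·√eigenvalue convention).
* **CDF, physical, fractal.** These three families are reconstructions: the
  original definitions are not publicly specified, so the package implements
  documented stand-ins honoring the category names and counts — five
  descriptors of the min-max-normalized empirical intensity CDF; physical
  volume (mL) and a water-equivalent mass proxy (g = mL · mean(HU+1000)/1000);
  nine box-counting descriptors (mask and boundary box-count dimensions,
  differential box-counting dimension of the intensity field, block
  lacunarity at box sizes 2/4/8, super-level-set dimensions at the 25/50/75th
  intensity quantiles). Each carries a `reconstructed` provenance tag in the
  extraction manifest and cannot be validated against the originals.

A catalogue note: an alternative published tally of 86 features exists for
the same seven categories; the per-category counts sum to 88, which is what
the package implements and what the manifest records.

## Feature selection and the predicted-TILes model

Given a cohort matrix X (samples × 88 features) and TILes response y:

1. **Median split + Student's t filter.** Each feature splits the cohort at
   its median; samples *at* the median go to the high group. The response is
   compared between groups with a pooled-variance two-sample t test (Welch
   behind a flag); features survive at p < 0.005 strictly. The split depends
   only on ranks, so the filter is invariant to monotone transforms of the
   feature.
2. **Alias removal.** Columns linearly dependent (relative tolerance 1e-8)
   on the constant and earlier kept columns are dropped, keep-first by
   position. This stage replaces a nominal regression step whose stated
   purpose was only alias detection; the original description (logistic
   regression with a continuous response) is internally inconsistent and is
   implemented as ordinary linear algebra.
3. **VIF filter.** VIF_j = 1/(1 − R²_j); iteratively remove the worst
   feature while max VIF > 10 (strict; simultaneous-removal mode behind a
   flag).
4. **LASSO.** The Gaussian elastic-net objective
   (1/2N)Σ(y_i − β0 − x_iᵀβ)² + λ[(1−α)‖β‖²/2 + α‖β‖₁], α = 1 by default,
   solved by cyclic coordinate descent on standardized features
   (1/N-variance convention) along a warm-started 100-point geometric λ path
   from λ_max down to 10⁻³·λ_max. λ is chosen by seeded K-fold
   cross-validation (10 folds, minimum-MSE rule; 1-SE rule behind a flag) —
   the original λ-selection rule was never stated. Solutions are checked
   against the stationarity (KKT) conditions to 1e-6 and cross-checked
   against an independent solver in the tests. Coefficients are mapped back
   to the original feature scale; an all-zero fit is reported as an explicit
   empty model, not an exception.

Every input feature leaves the pipeline with exactly one terminal stage
(`t_filter`, `alias`, `vif`, `lasso_zero`, `kept`) in the filter report.

The **published two-feature model** ships as a versioned JSON asset:
GLV coefficient 1.71×10⁻³, LALGLE coefficient −2.48×10⁻⁵. Its intercept was
never published, so the model carries an unknown-intercept flag and its
scores are defined up to an additive constant; every shipped downstream use
(median grouping, rank correlation, Cox on the score) is invariant to that
constant. The printed magnitudes are treated as original-scale coefficients,
consistent with typical GLV (10²–10³) and LALGLE (10⁴–10⁵) magnitudes.
Cohorts are grouped high/low at the median of the predicted score, ties to
high, mirroring the training-cohort rule for features. The TILes log2 fold
change per selected feature is reported with both mean- and median-based
group summaries, since the original base is unstated.

## Outcome statistics

Kaplan-Meier curves use the product-limit estimator with log-log
(exponential Greenwood) confidence intervals; the median is the earliest
time with S(t) ≤ 0.5 and "not reached" when the curve never crosses it.
The two-group log-rank test is the standard 1-df chi-square. Cox
proportional-hazards regression uses Efron tie handling (the better default;
Breslow behind a flag via an in-package Newton solver, which also provides
the partial-likelihood score test — with one binary covariate and no ties
the score statistic equals the log-rank statistic exactly, a property the
tests assert to 1e-8). Multivariate models admit only covariates with some
univariate coefficient at p < 0.05 (strict). Perfect separation or
non-convergence is flagged with infinite-CI markers rather than raised.
Fisher's exact test reports both the conditional-MLE odds ratio (consistent
with the exact test) and the sample odds ratio (flagged infinite on zero
cells). All tests are two-sided at 0.05. Because the continuous TILes score
lives on the unit interval, per-unit hazard ratios are small numbers; the
per-SD rescaling is left to the caller.

## The synthetic cohort generator

One latent heterogeneity score h ~ Uniform(heterogeneity_range) per subject
drives all three modalities:

* **Imaging.** An ellipsoidal tumor (random semi-axes 28–40% of the volume
  per axis) in a 40³ voxel volume at 1 mm isotropic spacing; background
  −800 HU, base lesion 40 HU. Texture is a Gaussian random field (white
  noise smoothed with a fixed-width kernel, 2 voxels), rescaled to standard
  deviation 15 + 35·h HU. Necrosis is modeled as spherical low-attenuation
  blobs (plateau 20 HU below base) inserted until they fill a volume
  fraction of about 0.25·(1 − h), echoing the mechanism that tumors with
  poor TIL enrichment carry proportionally large necrotic areas.
* **Pathology.** Each of 20 grids is TIL-enriched with probability
  logistic(−1 + 3·h), split evenly between inflamed and immune-excluded
  density patterns drawn on the correct side of the scorer's thresholds;
  grid TME areas are Uniform(0.5, 1) mm². The subject's `true_tiles` is the
  generating probability, not the realized score.
* **Outcomes.** Exponential event times with hazard
  0.25·exp(−1.5·TILes)/month and independent exponential censoring at
  0.03/month — median event times of a few months at low TILes, matching
  the progression-free-survival scale of the setting being emulated, with a
  protective TILes effect.

Default cohort size is 220 subjects (the training-cohort size of the study
design being emulated). One global seed expands into per-subject substreams
via numpy `SeedSequence` spawn keys, so cohorts are byte-reproducible and
insertion-order invariant. No effect-size estimate for the texture→TIL
association was available to calibrate against; the defaults were chosen
once for clear testability (strong but noisy monotone links), not realism.

For selection-pipeline studies the generator also emits **synthetic feature
matrices** directly: 88 named catalogue columns of which exactly two are
causal — the GLSZM gray-level-variance column rises with h (base 400,
slope +300) and the large-area-low-gray column falls with h (base 60000,
slope −30000), at the magnitudes typical of those features — while the
remaining 86 are h-independent noise at assorted scales. The response is
expected TILes plus Gaussian noise (sd 0.04), clipped to [0, 1].

### What the generator does and does not emulate

It reproduces the *logical structure* of the data — paired volumes, grid
maps and censored outcomes with a monotone effect chain — not the physics of
CT (no beam hardening, organs, partial-volume effects, scanner protocol
variation) and not pathology images (grids only). Passing recovery tests
therefore demonstrates that the pipeline detects the intended class of
signal at realistic sample sizes, not that it would achieve any particular
performance on clinical data.

### A numerical subtlety: binning and the effect chain

Fixed-bin-count discretization rescales every ROI to its own intensity
range, which exactly normalizes away the absolute texture-variance
differences the generator creates. The effect-chain checks (Spearman
ρ(h, GLV) > 0 over seeded tumors) therefore discretize with a fixed bin
width of 25 HU (`EFFECT_CHAIN_BIN_WIDTH_HU`): Hounsfield units are a
calibrated absolute scale, so fixed-width binning is the physically
meaningful lens for an absolute-variance effect. The bin-count-32 default
for generic extraction is unchanged.

## Numerical choices and degenerate inputs

* Coordinate descent: convergence when the largest coefficient update in a
  sweep falls below 1e-10; 10 000-sweep cap with an error carrying the last
  objective value.
* Constant ROI: single gray level, GLV = 0, entropy 0, uniformity 1;
  GLCM of a single-voxel ROI is an error (no pairs).
* CDF features of a zero-range ROI: AUC 0.5, slope at the 1e6 cap, tails 0.
* Fractal features require a ≥ 4-voxel span per axis (two dyadic scales);
  smaller ROIs raise a sizing error, and full 88-feature extraction is
  correspondingly restricted to ROIs at least that large (category
  subsetting via `ExtractionConfig.categories` for smaller fixtures).
* Degenerate median splits (all-equal feature) remove the feature at the
  t-filter stage with a note.
* All-equal inputs to `median_split` label everything high (degenerate,
  documented).
* Axis lengths of a single-voxel ROI are 0 with elongation/flatness 1,
  keeping every feature finite.

## Problem sizes used in the shipped checks

Worked examples are exact; simulations use 10⁴ random arrays for the
zone-matrix oracle, 25 cohorts of n = 220 for selection recovery, 100
replicates for the t-filter null, 1000 replicates at 100/arm for log-rank
calibration, and n = 1000 (point recovery) / 50×500 (CI coverage) for the
Cox checks — sizes at which the binomial/large-sample bands asserted by the
tests are informative.

## Known limitations

* The CDF/physical/fractal families are reconstructions; their values are
  internally consistent and tested but not comparable to the originals.
* The GLCM/GLSZM values depend on discretization; cross-study comparison
  requires matching the binning recorded in the manifest.
* The Cox implementation delegates to lifelines for estimation; the
  in-package Newton solver exists for Breslow ties and score tests, not as
  a general replacement.
* Clinical cohort-specific quantities (median survivals, hazard ratios,
  the identity of the 22 t-significant features) depend on patient data
  that are not distributed and are deliberately out of scope; the package
  treats them as recovery properties on synthetic data instead.
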