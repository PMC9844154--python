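# radtiles

CT texture radiomics modeling of tumor-infiltrating-lymphocyte (TIL)
enrichment, for researchers studying imaging biomarkers of the immune tumor
microenvironment and immunotherapy outcomes in solid tumors (the motivating
setting is non-small cell lung cancer treated with immune checkpoint
inhibitors).

Immune biomarkers such as TILs normally require invasive biopsy. The idea
implemented here is to read TIL enrichment off contrast-enhanced CT instead:
tumors with rich TIL infiltration have more heterogeneous intralesional
texture, and tumors with poor infiltration carry proportionally large
necrotic low-attenuation areas. Both signals live in the gray-level
size-zone matrix (GLSZM), whose entries P(i, j) count connected zones of
gray level i and size j inside the tumor mask.

The package provides the full chain as a library plus a CLI:

* **TILes scoring** — the TIL enrichment score of a sample is the fraction
  of analyzable tumor-microenvironment area occupied by 1 mm² pathology
  grids with high intra-tumoral (inflamed) or stromal (immune-excluded)
  TIL density, with strict sample QC (≥ 0.5 mm² cancer epithelium, ≥ 10
  evaluable grids).
* **Feature extraction** — 88 radiomic features in seven categories
  (first-order 18, shape 14, GLCM 24, GLSZM 16, CDF 5, physical 2,
  fractal 9) from a masked CT volume (NIfTI/NRRD).
* **Selection + model** — median split → pooled-variance t filter
  (p < 0.005) → alias removal → VIF filter (> 10) → cross-validated LASSO

      min_{β0, β} (1/2N) Σᵢ (yᵢ − β0 − xᵢᵀβ)² + λ[(1−α)‖β‖₂²/2 + α‖β‖₁]

  exposed as a `TilesLasso` model whose `fit()` returns a results object
  with coefficients, a per-feature filter audit and `summary()`. The
  published two-feature model — GLSZM gray level variance (GLV,
  coefficient 1.71×10⁻³) and large area low gray level emphasis (LALGLE,
  coefficient −2.48×10⁻⁵) — ships as a versioned JSON asset.
* **Outcome statistics** — Kaplan-Meier with log-log CIs, log-rank, Cox
  proportional hazards (Efron ties, univariate → multivariate with the
  p < 0.05 entry rule), Spearman/Wilcoxon/Fisher.
* **Synthetic cohorts** — paired CT-like volumes, grid TIL maps and
  censored survival times driven by one latent heterogeneity score, so the
  whole pipeline is testable end to end without any data download.

## Worked example

Fit the selection pipeline on a synthetic 220-subject cohort whose two
causal columns mimic the GLSZM features:

```python
from radtiles import TilesLasso, simulate_feature_matrix

df = simulate_feature_matrix(n_subjects=220, seed=3)   # 88 features + tiles
res = TilesLasso.from_dataframe(df).fit(seed=3)
print(res.summary())
```

```
Predicted-TILes LASSO selection
===============================================
Input features: 88
  removed at t_filter: 85
  selected (non-zero): 3
lambda = 0.000165607 (alpha = 1, min rule, 10-fold CV)
KKT residual = 1.09e-11
Spearman rho (fitted vs TILes) = 0.864

feature                                       coefficient
---------------------------------------------------------
intercept                                        0.507516
shape_MeshVolume                              0.000515518
glszm_GrayLevelVariance                       0.000743985
glszm_LargeAreaLowGrayLevelEmphasis          -7.89749e-06
```

The t filter removes 85 of 88 features; the LASSO keeps the two causal
texture features with the correct signs (+ for the variance-type, − for the
large-area-low-gray-type) plus one borderline noise column, and the fitted
scores rank-correlate with the true TILes at ρ = 0.86. The KKT residual
confirms the coordinate-descent solution satisfies the optimality conditions.

Scoring a new tumor with the published model:

```python
import pandas as pd
from radtiles import published_model

X = pd.DataFrame({"glszm_GrayLevelVariance": [850.0],
                  "glszm_LargeAreaLowGrayLevelEmphasis": [21000.0]})
print(published_model().predict(X))
```

```
0    0.9327
Name: predicted_tiles, dtype: float64
```

i.e. 1.71×10⁻³·850 − 2.48×10⁻⁵·21000 = 0.9327 — a score up to an additive
constant (the published intercept is unknown), used downstream only through
median grouping and rank statistics, which are invariant to that constant.

The CLI mirrors the library:

```bash
radtiles simulate --seed 7 --n 20 --out cohort/
radtiles extract  --image cohort/images/s0000_image.nii.gz \
                  --mask cohort/images/s0000_mask.nii.gz --out features.csv
radtiles full-run --seed 7 --n 60 --out run/        # end-to-end report
```

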