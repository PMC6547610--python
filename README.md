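# petpica

Constrained parallel independent component analysis (pICA) for paired PET
modalities, aimed at studies that relate the spatial deposition patterns of
two tracers — typically tau (AV1451) and amyloid-β (AV45) — across a
two-group cohort such as mild cognitive impairment (MCI) versus normal
controls (NC).

Each modality's subject × voxel matrix is modelled as a linear mixture

    X_m = A_m S_m + E_m,        m ∈ {tau, abeta}

where the rows of `S_m` are spatially independent component maps, the
columns of `A_m` are per-subject *loading parameters* (the contribution of
each component to the between-subject variance), and `E_m` is noise.
Plain spatial ICA estimates each `(A_m, S_m)` by natural-gradient infomax:

    ΔW = η (I + (1 − 2g(u)) uᵀ) W,   u = W z,  g = logistic,

on PCA-whitened data `z`. Parallel ICA adds a cross-modal objective term:
once any pair of loading columns `(a_tau_i, a_abeta_j)` exceeds an
activation threshold in Pearson correlation, a gradient-ascent step on
`r²(a_tau_i, a_abeta_j)` is interleaved with the infomax updates and
propagated to the unmixing weights through the dewhitening relation
`A = K_dw W⁻¹`. This couples the two decompositions and sharpens genuinely
correlated component pairs while leaving the rest independent.

Around that core the package provides the full study workflow:

- **`petpica.simulate`** — synthetic paired-modality cohorts with known
  sparse spatial sources, a coupled cross-modal loading pair, and
  group-discriminative components (the ground truth for every recovery
  claim made here).
- **`petpica.preprocess`** — Gaussian smoothing (FWHM in mm), SUVR-style
  intensity normalization, masking, NIfTI cohort loading.
- **`petpica.model_order`** — AIC/MDL model-order selection from the PCA
  eigenvalue spectrum (the classical signals-in-noise detector).
- **`petpica.pica`** — whitening, infomax, the constrained parallel fit,
  and evaluation utilities (Hungarian matching, Amari index).
- **`petpica.stats`** — component z-maps thresholded at |z| > 2.5, Welch
  group tests on loadings and voxels, all-pairs cross-modal correlations
  with Benjamini–Hochberg FDR (q < 0.05), covariate checks, and the
  demographic cohort table.
- **`petpica.atlas`** — cluster/peak tables (region, network, peak |z|,
  MNI-style mm coordinates) from a user-supplied label atlas.
- **`petpica.classify`** — ROI features from significant components and
  stratified 5-fold cross-validated classification (ACC/AUC/SEN/SPE, in
  percent) for the Non / Tau / Abeta / All feature conditions.
- **`petpica.pipeline`** + the `petpica` CLI — one-config orchestration of
  all stages with a reproducibility manifest.

## Worked example

`examples/simulate_and_decompose.py` simulates the default cohort
(65 MCI + 75 NC subjects, 8 components per modality on a 20×24×20 grid at
4 mm, one cross-modal pair coupled at r = 0.6, noise sd 0.1) and fits the
constrained decomposition:

```
strongest cross-modal loading pair: tau comp 6 / abeta comp 5, |r| = 0.6282 (simulated ground truth 0.6)
tau: mean matched |map correlation| = 0.9984, Amari index = 0.0076
abeta: mean matched |map correlation| = 0.9999, Amari index = 0.0037
```

The decomposition found exactly one strongly coupled cross-modal pair and
its loading correlation (0.63) brackets the simulated truth (0.6); the
spatial maps are recovered almost perfectly (matched map correlations near
1, Amari index near 0). The other example scripts demonstrate the cohort
table (`cohort_statistics.py`), order selection (`model_order_selection.py`),
the peak report (`peak_report.py`) and the classification experiment
(`classification_fusion.py`), which prints e.g.

```
condition   ACC    AUC    SEN    SPE   (mean of 5 stratified folds, %)
Tau        74.29  84.51  70.77  77.33
Abeta      83.57  91.18  78.46  88.00
All        87.86  95.38  84.62  90.67
```

— fusing both modalities outperforms either alone.

An end-to-end run with all outputs (loadings TSVs, component NIfTIs,
statistics tables, peak table, classification report, manifest):

```sh
petpica run-all --out myrun --seed 1
```

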