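# Methods

## Model and estimation

Each modality's data matrix `X` (subjects × in-mask voxels) is decomposed
in spatial-ICA orientation: voxels are the i.i.d. samples, subjects are the
sensors. After row-centering, PCA-whitening retains the top `k` principal
axes (`z = K X_c`, identity sample covariance; `K_dw K` is the identity on
the retained subspace). Natural-gradient infomax with a logistic
nonlinearity then estimates a square unmixing matrix `W` on the whitened
space:

    ΔW = η (I + (1 − 2 g(u)) uᵀ / V) W,   u = W z.

The logistic score assumes super-Gaussian sources in the separated
dimension; spatial component maps of PET/fMRI data are sparse, so the
simulator (below) generates sparse blob maps to match. Loadings follow
from the dewhitening relation `A = K_dw W⁻¹`, so `A S` reconstructs the
centered data up to the PCA truncation plus noise.

The parallel (two-modality) fit alternates one infomax step per modality
per epoch. After a burn-in (default 20 epochs), all cross-modal Pearson
correlations between loading columns are computed each epoch; for the
strongest pair whose |r| exceeds the activation threshold (default 0.3,
at most one pair by default, lexicographic tie-break), a gradient-ascent
step on r² is applied to the two loading columns,

    Δa = λ · 2r · (b̂ − r â) · ‖a‖,   â = centered a / ‖·‖,

expressed in correlation units so that one step moves r by roughly
λ·2r(1−r²). The updated columns are pushed back to the unmixing matrices
via `W = (K A)⁻¹`. λ (default 0.05) is halved whenever the constrained |r|
jumps by more than 0.05 within one epoch, which prevents the constraint
from overshooting the data-supported correlation.

Indeterminacies are fixed at the end: each source row is zero-mean,
unit-variance over the mask with nonnegative skewness; loading columns
absorb scale and sign, leaving `A S` invariant.

### Convergence behaviour

Unconstrained runs terminate when the Frobenius norm of the weight change
drops below the tolerance (default 1e-7). Constrained runs generally do
*not* meet this test: at equilibrium the constraint step and the infomax
step cancel on average but each remains of order λ, so the per-step weight
change plateaus. Such runs return `converged=False` with a warning while
the sources, loadings and the constrained correlation are stable and
accurate; this is expected behaviour, not a failure.

### Defaults that matter

| parameter | default | why |
| --- | --- | --- |
| learning rate η | 0.01 | converges within ~1000 full-batch epochs at desk scale; annealed ×0.9 on divergence |
| max iterations | 1024 | past this the weight change and constrained r have plateaued in all test configurations |
| activation threshold | 0.3 | clearly above the null spread of loading correlations at n = 140 (sd ≈ 0.085), so spurious pairs are not constrained |
| constraint strength λ | 0.05 | one step moves r by ≲ 0.03; the halving rule caps epoch-to-epoch jumps at 0.05 |
| burn-in | 20 epochs | loading estimates are meaningless before the unmixing has left its near-identity initialization |
| components | 8 per modality | the pipeline's fixed default; AIC estimation is available as an override (`n_components: auto`) |

`W` is initialized as a small random orthogonal perturbation of the
identity; the seed controls it and every other random draw, making runs
bit-reproducible.

## Model-order selection

The number of components is estimated with the classical
information-theoretic detector on sample eigenvalues: for candidate order
k, the log-likelihood of "k signals + isotropic noise" reduces to
`N (p−k) log(geometric/arithmetic mean)` of the trailing eigenvalues, with
penalty `2k(2p−k)` (AIC) or `½ k (2p−k) log N` (MDL). The chosen order is
the AIC minimizer; MDL is reported alongside and is empirically at least
as conservative. Eigenvalues are floored at 1e-12 of the largest before
taking logs so exactly low-rank (noise-free) data yields finite criteria.
In spatial orientation the sample count N is the voxel count; spatial
smoothness violates the i.i.d. assumption, making both criteria
optimistic — every estimate carries this caveat, and no subsampling
correction is applied. On pure-noise input AIC selects order 0 in the
majority of replicates but not all: at desk scale the finite-sample
(Marchenko–Pastur) eigenvalue spread is comparable to the k=0→1 penalty
margin.

## Synthetic cohorts

The generator emulates a two-tracer PET study with known ground truth:

- **Geometry**: 20×24×20 voxels at 4 mm, analysis mask = inscribed
  ellipsoid (~5000 voxels) — small enough for seconds-scale fits, large
  enough for 8 separable sources.
- **Sources**: per component, 2–4 Gaussian blobs (FWHM 8 mm) at random
  in-mask centers kept ≥ 2σ apart across components, normalized to
  zero-mean unit-variance; sources are redrawn until all pairwise spatial
  |correlations| are ≤ 0.3. Sparse blobs are strongly super-Gaussian,
  matching the infomax score.
- **Loadings**: standard normal per column. The configured cross-modal
  pair is drawn from a bivariate Gaussian (target r = 0.6 by default) and
  the realized sample correlation is recorded; all other cross-modal pairs
  are independent. Three components per modality receive a between-group
  mean shift of d = 0.8 within-group standard deviations (a conventional
  "large effect" default; no empirical effect sizes exist to copy).
- **Cohort**: 65 MCI + 75 NC subjects; noise is i.i.d. Gaussian with
  sd 0.1 (low relative to the unit-variance signal, per the reference
  study conditions this design mirrors); demographics (age, MMSE, CDR,
  APOE4 rates) are drawn to resemble a typical MCI/NC PET cohort table.

What the generator does **not** emulate: scanner physics, partial-volume
effects, spatially correlated noise, realistic SUVR kinetics, registration
error. Two consequences for interpreting green tests: (1) recovery numbers
(map correlations ≥ 0.95, Amari ≤ 0.1) certify the estimator on data that
satisfy its assumptions, not performance on real PET; (2) the "Non"
classification baseline (whole-mask means + top-5 PCA scores of the raw
data) is *not* near chance here (~87% accuracy), because the simulated
group effect lives in high-variance loading directions that unsupervised
PCA captures — in real PET the discriminative signal is a tiny fraction of
raw-image variance and this baseline hovers near chance. The fusion
ordering (All > each single modality) is the meaningful qualitative claim
and is what the tests assert.

## Inference choices

- Component significance is tested primarily on loadings (Welch t per
  component, α = 0.05), with the voxel-wise Welch t-map as a secondary
  output; Welch is used throughout because group sizes and variances
  differ.
- Component maps are z-scored with sample sd (ddof = 1) and thresholded
  strictly at |z| > 2.5 for reporting; the threshold/z-score pipeline is
  invariant to affine rescaling of the map.
- Cross-modal inference uses all n₁×n₂ loading-column Pearson correlations
  with two-sided p-values and Benjamini–Hochberg FDR across the pairs
  (pass at q < 0.05). BH, not BY: the field default under positive
  dependence of loading correlations.
- Cohort table: Welch t for continuous scores (raw or mean/sd/n summary
  form), Pearson chi-square without continuity correction for 2×2 counts
  (cells are large), tie-corrected asymptotic Mann-Whitney for CDR.
- Voxel-level multiple-comparison correction across the brain is out of
  scope; FDR applies to the correlation pairs only.

## Classification protocol

Features are mean intensities over each significant component's
thresholded map (with a most-discriminative-component fallback so a
feature set always exists); "All" concatenates both modalities. The
classifier is L2-regularized logistic regression (C = 1.0) on features
standardized with training-fold statistics only; folds are stratified
5-fold splits, deterministic given the seed. ACC/AUC/SEN/SPE are computed
per fold (SEN = MCI recall, SPE = NC recall; AUC by the rank formulation
with half-credit ties) and averaged over the five folds, on a percent
scale; a pooled-scores AUC is available as an option. Two protocols exist:
the default "fixed" mode extracts features from one decomposition of the
full data (fast; the unsupervised decomposition sees test subjects, the
supervised steps do not), and a "refit" mode re-runs the decomposition and
component selection inside every training split; reports carry the
protocol tag.

## Numerical and degenerate-case conventions

- Zero-variance voxels are dropped from the mask before whitening (they
  make the covariance singular); the dropped count is logged.
- Whitening refuses k above the measured rank; infomax signals divergence
  when any |W| entry exceeds 1e9, upon which the learning rate anneals
  ×0.9 and the step restarts.
- Gaussian smoothing uses σ = FWHM/(2√(2 ln 2))/voxel-size per axis, a
  unit-sum kernel truncated at 4σ, and nearest-edge replication, so
  constant volumes are preserved exactly.
- Cluster peaks use 26-connectivity by default (6/18 configurable); ties
  at the peak break toward the lowest linear voxel index.
- BH q-values are the standard step-up minima, capped at 1, so q ≥ p
  always; rejection uses strict q < α.
- The Amari index is normalized to [0, 1] by 2k(k−1); 0 means the gain
  matrix is a scaled permutation, 1 a flat matrix.

## Problem sizes used in tests and the acceptance script

Recovery and constraint-benefit claims are measured on the default
140-subject, ~5000-voxel, 8-component cohorts (seconds per fit), with
20-seed sweeps for fraction-type claims and 10 seeds for the coupled-pair
band; calibration claims use 500 null replicates (FDR, m = 64) and 1000
null components (type-I rate); the classification experiment uses 20
replicate cohorts. These sizes give binomial/sampling error comfortably
inside the asserted bands while keeping a full run in the minutes range
on one CPU.

## Known limitations

- The constraint currently couples at most `max_constrained_pairs` pairs
  (default 1, matching the single-pair finding the design mirrors);
  multi-pair constraint scheduling is untested beyond the default.
- Only two modalities are supported; no three-way extension.
- No ICASSO-style stability resampling; run-to-run agreement is achieved
  by seeding rather than aggregation.
- Real-data preprocessing (coregistration, nonlinear normalization to a
  template, dynamic-frame averaging) is out of scope: inputs must already
  share a grid and affine.
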