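"""Model-order selection from PCA eigenvalue structure.

Implements the classical information-theoretic detector of the number of
signals in noise: for each candidate order k the log-likelihood of the
"k signals + isotropic noise" covariance model reduces to the ratio of the
geometric to the arithmetic mean of the trailing p - k sample eigenvalues,
penalized by the number of free parameters (AIC) or by the MDL code length.

The decomposition runs in spatial-ICA orientation: subjects are the sensors
(observed dimension p) and in-mask voxels are the samples (N). Spatial
smoothness violates the i.i.d.-sample assumption and no subsampling
correction is applied; a caveat is recorded on every estimate. The pipeline
default is a fixed order of 8 components, with estimation as an override.
"""

from __future__ import annotations

import numpy as np

from petpica.errors import ConfigError, NumericalError
from petpica.types import OrderEstimate, VoxelMatrix

#: Relative floor applied to eigenvalues before taking logs, so that exactly
#: low-rank (noise-free) data does not produce -inf criteria.
EIGENVALUE_FLOOR = 1e-12

SMOOTHNESS_CAVEAT = (
    "effective sample size taken as the raw voxel count; spatial smoothness "
    "makes voxel samples dependent, so both criteria are optimistic"
)


def information_criteria(
    eigenvalues: np.ndarray, n_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """AIC and MDL curves over candidate orders 0..p-1.

    For candidate k with trailing eigenvalues l_{k+1..p}:

        L(k)   = N (p - k) log( geometric mean / arithmetic mean )
        AIC(k) = -2 L(k) + 2 k (2p - k)
        MDL(k) = -L(k) + (1/2) k (2p - k) log N

    At k = p - 1 a single trailing eigenvalue remains and the ratio is 1,
    so the log term vanishes.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    p = lam.size
    if p < 2:
        raise ConfigError("need at least 2 eigenvalues")
    tol = -1e-10 * max(lam[0], 1.0)
    if np.any(lam < tol):
        raise NumericalError(f"negative eigenvalue beyond tolerance: {lam.min()}")
    lam = np.maximum(lam, EIGENVALUE_FLOOR * max(lam[0], np.finfo(float).tiny))
    n = float(n_samples)
    ks = np.arange(p)
    aic = np.empty(p)
    mdl = np.empty(p)
    log_lam = np.log(lam)
    for k in ks:
        trailing = lam[k:]
        m = p - k
        log_geo = log_lam[k:].mean()
        log_arith = np.log(trailing.mean())
        loglik = n * m * (log_geo - log_arith)  # <= 0
        aic[k] = -2.0 * loglik + 2.0 * k * (2 * p - k)
        mdl[k] = -loglik + 0.5 * k * (2 * p - k) * np.log(n)
    return aic, mdl


def estimate_order(
    matrix: VoxelMatrix | np.ndarray, max_order: int | None = None
) -> OrderEstimate:
    """Estimate the number of latent components of one modality.

    The chosen order is the AIC minimizer (MDL is reported alongside; it is
    known to be the more conservative of the two).
    """
    x = matrix.values if isinstance(matrix, VoxelMatrix) else np.asarray(matrix, float)
    p, n = x.shape
    if p < 3:
        raise ConfigError(f"need at least 3 observations, got {p}")
    if max_order is None:
        max_order = p - 1
    if not 0 < max_order < min(p, n):
        raise ConfigError(
            f"max_order must lie in (0, min(subjects, voxels)) = (0, {min(p, n)})"
        )
    xc = x - x.mean(axis=1, keepdims=True)
    cov = xc @ xc.T / n
    lam = np.linalg.eigvalsh(cov)[::-1]
    aic, mdl = information_criteria(lam, n)
    aic = aic[: max_order + 1]
    mdl = mdl[: max_order + 1]
    chosen = int(np.argmin(aic))
    return OrderEstimate(
        aic_curve=aic, mdl_curve=mdl, chosen_order=chosen,
        eigenvalues=lam, caveats=[SMOOTHNESS_CAVEAT],
    )
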