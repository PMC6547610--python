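"""Constrained parallel infomax ICA — the computational core.

Each modality is decomposed in spatial-ICA orientation (sources are spatial
maps over voxels, loadings are per-subject mixing weights) by natural-
gradient infomax with a logistic nonlinearity:

    dW = eta * (I + (1 - 2 g(u)) u^T / V) W,   u = W z,  g = logistic.

The parallel part adds an adaptive cross-modal term: after a burn-in, the
loading matrices of the two modalities are compared; for the loading-column
pair whose Pearson correlation magnitude exceeds an activation threshold, a
gradient-ascent step on r^2 is taken with respect to the two loading
columns, propagated back to the unmixing weights through the dewhitening
relation A = K_dw W^{-1}  (so W = (K A)^{-1}). The constraint strength is
halved whenever the constrained |r| jumps by more than 0.05 in one epoch,
guarding against overshoot.

Scale and sign indeterminacies are resolved at the end: each source row is
zero-mean unit-variance over the mask with nonnegative skewness, and the
loading columns carry the magnitudes, so A @ S reconstructs the centered
data up to the retained-PCA truncation plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import expit
from scipy.stats import skew

from petpica.errors import ConfigError, NumericalError, PairingError
from petpica.types import PicaResult, VoxelMatrix

DIVERGENCE_LIMIT = 1e9


@dataclass
class PicaConfig:
    """Hyperparameters of the constrained parallel ICA fit.

    None of these are dictated by the underlying statistical model; they are
    engineering defaults, surfaced as configuration and recorded in results.
    """

    n_components: int = 8
    learning_rate: float = 0.01
    anneal_factor: float = 0.9          # learning-rate multiplier on divergence
    max_iterations: int = 1024
    convergence_tolerance: float = 1e-7  # Frobenius norm of the weight change
    constraint_activation_threshold: float = 0.3
    constraint_strength: float = 0.05    # lambda; halved on |r| jumps > 0.05
    max_constrained_pairs: int = 1
    burn_in_iterations: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.n_components <= 0:
            raise ConfigError("n_components must be positive")
        if not 0 < self.constraint_activation_threshold < 1:
            raise ConfigError("constraint_activation_threshold must be in (0, 1)")
        if self.constraint_strength < 0:
            raise ConfigError("constraint_strength must be nonnegative")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.max_constrained_pairs <= 0:
            raise ConfigError("max_constrained_pairs must be positive")


def whiten(matrix: VoxelMatrix | np.ndarray, k: int
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA-whiten to the top-k principal axes.

    Returns ``(Z, K, K_dw)`` with ``Z = K @ Xc`` having identity sample
    covariance over voxels, and ``K_dw @ K`` the identity on the retained
    subspace (``Xc`` is the row-centered data).
    """
    x = matrix.values if isinstance(matrix, VoxelMatrix) else np.asarray(matrix, float)
    p, v = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    cov = xc @ xc.T / v
    lam, vecs = np.linalg.eigh(cov)
    lam, vecs = lam[::-1], vecs[:, ::-1]
    rank = int(np.sum(lam > max(lam[0], 0) * 1e-10))
    if k > rank:
        raise NumericalError(f"requested k={k} exceeds measured rank {rank}")
    lam_k = lam[:k]
    e_k = vecs[:, :k]
    k_map = (e_k / np.sqrt(lam_k)).T          # (k, p)
    k_dw = e_k * np.sqrt(lam_k)               # (p, k)
    return k_map @ xc, k_map, k_dw


def infomax_objective(w: np.ndarray, z: np.ndarray) -> float:
    """Per-sample infomax log-likelihood (oracle for gradient checks)."""
    u = w @ z
    g = expit(u)
    return float(np.linalg.slogdet(w)[1] + np.mean(np.sum(np.log(g * (1 - g) + 1e-300), axis=0)))


def infomax_step(w: np.ndarray, batch: np.ndarray, learning_rate: float
                 ) -> tuple[np.ndarray, float]:
    """One full-batch natural-gradient infomax update.

    Returns the updated W and the Frobenius norm of the change. Raises
    :class:`NumericalError` on divergence (any entry beyond 1e9); the engine
    catches this, anneals the learning rate and restarts the step.
    """
    if not np.all(np.isfinite(w)):
        raise NumericalError("non-finite unmixing matrix")
    u = w @ batch
    g = expit(u)
    n = batch.shape[1] if batch.size else 1
    grad = np.eye(w.shape[0]) + (1.0 - 2.0 * g) @ u.T / n
    dw = learning_rate * grad @ w
    w_new = w + dw
    if np.any(np.abs(w_new) > DIVERGENCE_LIMIT) or not np.all(np.isfinite(w_new)):
        raise NumericalError(
            "infomax update diverged; anneal the learning rate and restart"
        )
    return w_new, float(np.linalg.norm(dw))


def _init_unmixing(k: int, rng: np.random.Generator) -> np.ndarray:
    """Small random orthogonal perturbation of the identity."""
    q, r = np.linalg.qr(np.eye(k) + 0.05 * rng.standard_normal((k, k)))
    return q * np.sign(np.diag(r))


def _corr_gradient_step(a1: np.ndarray, a2: np.ndarray, i: int, j: int,
                        lam: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Gradient-ascent step on r^2 for loading columns a1[:, i], a2[:, j]."""
    x = a1[:, i] - a1[:, i].mean()
    y = a2[:, j] - a2[:, j].mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return a1, a2, 0.0
    u, v = x / nx, y / ny
    r = float(u @ v)
    # d(r^2)/d(unit direction) = 2 r (other - r * self); rescaled by the
    # column norm so the step size is expressed in correlation units
    a1 = a1.copy()
    a2 = a2.copy()
    a1[:, i] = a1[:, i] + lam * 2.0 * r * (v - r * u) * nx
    a2[:, j] = a2[:, j] + lam * 2.0 * r * (u - r * v) * ny
    return a1, a2, r


def loading_correlations(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    """Pearson correlation between every column pair of two loading matrices."""
    if a1.shape[0] != a2.shape[0]:
        raise PairingError("loading matrices have different subject counts")
    x = a1 - a1.mean(axis=0)
    y = a2 - a2.mean(axis=0)
    x /= np.linalg.norm(x, axis=0)
    y /= np.linalg.norm(y, axis=0)
    return np.clip(x.T @ y, -1.0, 1.0)


def _finalize_modality(w: np.ndarray, z: np.ndarray, k_dw: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Resolve scale and sign: unit-variance, nonnegative-skew source rows."""
    s = w @ z
    a = k_dw @ np.linalg.inv(w)
    sd = s.std(axis=1)
    s = s / sd[:, None]
    a = a * sd[None, :]
    flip = np.where(skew(s, axis=1) < 0, -1.0, 1.0)
    return s * flip[:, None], a * flip[None, :]


def parallel_ica(
    data1: VoxelMatrix,
    data2: VoxelMatrix,
    config: PicaConfig | None = None,
) -> PicaResult:
    """Fit constrained parallel ICA to two paired modalities.

    The two matrices must share subjects in identical order. Runs
    alternating per-modality infomax epochs; once past burn-in, the
    strongest cross-modal loading correlation above the activation
    threshold receives the correlation-enhancing update each epoch.
    """
    config = config or PicaConfig()
    config.validate()
    if data1.subject_ids != data2.subject_ids:
        raise PairingError("modalities have different subjects or ordering")
    k = config.n_components
    rng = np.random.default_rng(config.seed)

    mods = (data1.modality or "mod1", data2.modality or "mod2")
    z, k_map, k_dw, w = {}, {}, {}, {}
    for tag, data in zip(mods, (data1, data2)):
        z[tag], k_map[tag], k_dw[tag] = whiten(data, k)
        w[tag] = _init_unmixing(k, rng)

    lr = config.learning_rate
    lam = config.constraint_strength
    log: list[dict] = []
    activated: dict[tuple[int, int], float] = {}
    prev_abs_r: dict[tuple[int, int], float] = {}
    converged = False

    for it in range(config.max_iterations):
        max_dw = 0.0
        for tag in mods:
            while True:
                try:
                    w[tag], dw_norm = infomax_step(w[tag], z[tag], lr)
                    break
                except NumericalError:
                    lr *= config.anneal_factor
                    log.append({"iteration": it, "event": "anneal", "lr": lr})
                    if lr < 1e-12:
                        raise
            max_dw = max(max_dw, dw_norm)

        active: list[tuple[int, int, float]] = []
        if it >= config.burn_in_iterations and lam > 0:
            a = {tag: k_dw[tag] @ np.linalg.inv(w[tag]) for tag in mods}
            r_mat = loading_correlations(a[mods[0]], a[mods[1]])
            pairs = _select_pairs(r_mat, config.constraint_activation_threshold,
                                  config.max_constrained_pairs)
            for (i, j) in pairs:
                a1_new, a2_new, r = _corr_gradient_step(
                    a[mods[0]], a[mods[1]], i, j, lam)
                try:
                    w1_new = np.linalg.inv(k_map[mods[0]] @ a1_new)
                    w2_new = np.linalg.inv(k_map[mods[1]] @ a2_new)
                except np.linalg.LinAlgError:  # pragma: no cover - degenerate
                    continue
                a[mods[0]], a[mods[1]] = a1_new, a2_new
                w[mods[0]], w[mods[1]] = w1_new, w2_new
                abs_r = abs(r)
                if (i, j) in prev_abs_r and abs_r - prev_abs_r[(i, j)] > 0.05:
                    lam *= 0.5
                    log.append({"iteration": it, "event": "halve_lambda",
                                "lambda": lam})
                prev_abs_r[(i, j)] = abs_r
                activated[(i, j)] = abs_r
                active.append((i, j, r))

        log.append({"iteration": it, "dW": max_dw, "lr": lr,
                    "active": [(i, j, round(r, 4)) for i, j, r in active]})
        if max_dw < config.convergence_tolerance:
            converged = True
            break

    sources, loadings = {}, {}
    for tag in mods:
        sources[tag], loadings[tag] = _finalize_modality(w[tag], z[tag], k_dw[tag])
    r_final = loading_correlations(loadings[mods[0]], loadings[mods[1]])
    constrained = [(i, j, float(r_final[i, j])) for (i, j) in sorted(activated)]
    return PicaResult(
        unmixing={tag: w[tag] for tag in mods},
        sources=sources,
        loadings=loadings,
        whitening=k_map,
        dewhitening=k_dw,
        loading_correlation=r_final,
        constrained_pairs=constrained,
        convergence_log=log,
        converged=converged,
        modalities=mods,
        seed=config.seed,
    )


def _select_pairs(r_mat: np.ndarray, threshold: float, max_pairs: int
                  ) -> list[tuple[int, int]]:
    """Strongest |r| pairs above threshold; ties broken lexicographically."""
    flat = []
    for i in range(r_mat.shape[0]):
        for j in range(r_mat.shape[1]):
            if abs(r_mat[i, j]) > threshold:
                flat.append((-abs(r_mat[i, j]), i, j))
    flat.sort()
    return [(i, j) for _, i, j in flat[:max_pairs]]


def infomax_ica(data: VoxelMatrix, config: PicaConfig | None = None) -> PicaResult:
    """Plain single-modality infomax ICA (the unconstrained engine)."""
    config = config or PicaConfig()
    config.validate()
    k = config.n_components
    rng = np.random.default_rng(config.seed)
    tag = data.modality or "mod1"
    z, k_map, k_dw = whiten(data, k)
    w = _init_unmixing(k, rng)
    lr = config.learning_rate
    log: list[dict] = []
    converged = False
    for it in range(config.max_iterations):
        while True:
            try:
                w, dw_norm = infomax_step(w, z, lr)
                break
            except NumericalError:
                lr *= config.anneal_factor
                log.append({"iteration": it, "event": "anneal", "lr": lr})
                if lr < 1e-12:
                    raise
        log.append({"iteration": it, "dW": dw_norm, "lr": lr, "active": []})
        if dw_norm < config.convergence_tolerance:
            converged = True
            break
    s, a = _finalize_modality(w, z, k_dw)
    return PicaResult(
        unmixing={tag: w}, sources={tag: s}, loadings={tag: a},
        whitening={tag: k_map}, dewhitening={tag: k_dw},
        loading_correlation=np.zeros((k, 0)),
        constrained_pairs=[], convergence_log=log, converged=converged,
        modalities=(tag,), seed=config.seed,
    )


def amari_index(g: np.ndarray) -> float:
    """Normalized Amari separation index in [0, 1] (0 = scaled permutation)."""
    g = np.abs(np.asarray(g, dtype=float))
    k = g.shape[0]
    if g.shape != (k, k):
        raise ConfigError("Amari index requires a square gain matrix")
    if k == 1:
        return 0.0
    rows = (g / g.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (g / g.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * k * (k - 1)))


def match_and_align(
    estimated: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Match estimated source maps to a reference set.

    Hungarian assignment maximizing total absolute map correlation. Returns
    ``(permutation, signs, amari, matched_abs_corr)`` where
    ``estimated[i]`` corresponds to ``reference[permutation[i]]`` with the
    given sign, and ``amari`` is the Amari index of the least-squares gain
    matrix mapping reference sources to estimated sources.
    """
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape[0] != ref.shape[0]:
        raise ConfigError("component counts differ")
    est_c = est - est.mean(axis=1, keepdims=True)
    ref_c = ref - ref.mean(axis=1, keepdims=True)
    en = est_c / np.linalg.norm(est_c, axis=1, keepdims=True)
    rn = ref_c / np.linalg.norm(ref_c, axis=1, keepdims=True)
    corr = en @ rn.T
    rows, cols = linear_sum_assignment(-np.abs(corr))
    perm = np.empty_like(cols)
    perm[rows] = cols
    matched = corr[rows, cols]
    signs = np.where(matched < 0, -1.0, 1.0)
    gain, *_ = np.linalg.lstsq(ref_c.T, est_c.T, rcond=None)
    return perm, signs, amari_index(gain.T), np.abs(matched)
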