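"""Synthetic paired-modality PET cohort generator.

Emulates a two-group (MCI / normal-control) cohort scanned with two PET
tracers sharing a voxel grid. Each modality follows the linear mixing model

    X = A @ S + E,

where ``S`` holds sparse spatial source maps (sums of 3-D Gaussian blobs,
zero-mean unit-variance over the brain-like mask), ``A`` holds per-subject
loadings (unit-variance Gaussian), and ``E`` is i.i.d. Gaussian noise.
One cross-modal loading pair is drawn jointly with a configurable
correlation (a bivariate Gaussian copula), standing in for the single
strongly coupled tau/amyloid component pair seen in real cohorts; a subset
of components carries a group mean shift expressed as Cohen's d.

Sparse blob maps are deliberately super-Gaussian in the spatial dimension:
infomax ICA with a logistic nonlinearity separates super-Gaussian sources,
which mirrors the spatial-ICA convention that maps are sparse while
loadings are unconstrained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from petpica.errors import ConfigError, IdentifiabilityError, NumericalError
from petpica.types import SourceMaps, SyntheticTruth, VoxelMatrix

MODALITIES = ("tau", "abeta")

#: Demographics used for the simulated subject table (two-group PET cohort
#: conventions: MCI slightly younger here, lower MMSE, CDR 0.5 vs 0).
_DEMOGRAPHICS = {
    "MCI": {"age": (73.27, 5.75), "mmse": (25.7, 2.3), "cdr": 0.5,
            "apoe4_rate": 32 / 65},
    "NC": {"age": (76.27, 6.22), "mmse": (27.9, 1.7), "cdr": 0.0,
           "apoe4_rate": 33 / 75},
}


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort.

    Defaults follow the study conditions this generator emulates: 65 MCI +
    75 NC subjects, 8 latent components per modality, one cross-modal pair
    with loading correlation 0.6, three group-discriminative components per
    modality at d = 0.8, additive Gaussian noise with sd 0.1.
    """

    grid_dims: tuple[int, int, int] = (20, 24, 20)
    n_subjects_per_group: tuple[int, int] = (65, 75)  # (MCI, NC)
    n_components: int = 8
    coupled_pair: tuple[int, int] = (2, 5)  # (tau comp, abeta comp)
    coupled_r: float = 0.6
    group_effect_components: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {"tau": (0, 1, 3), "abeta": (2, 4, 6)}
    )
    group_effect_size: float = 0.8
    noise_sd: float = 0.1
    blob_count_range: tuple[int, int] = (2, 4)
    blob_fwhm_mm: float = 8.0
    voxel_size_mm: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_dims) != 3 or any(d <= 0 for d in self.grid_dims):
            raise ConfigError(f"grid_dims must be 3 positive ints, got {self.grid_dims}")
        if any(n <= 0 for n in self.n_subjects_per_group):
            raise ConfigError("n_subjects_per_group must be positive")
        if self.n_components <= 0:
            raise ConfigError("n_components must be positive")
        if not all(0 <= c < self.n_components for c in self.coupled_pair):
            raise ConfigError(
                f"coupled_pair {self.coupled_pair} out of range for "
                f"{self.n_components} components"
            )
        if abs(self.coupled_r) >= 1.0:
            raise ConfigError(f"coupled_r must lie in (-1, 1), got {self.coupled_r}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if self.blob_fwhm_mm <= 0 or self.voxel_size_mm <= 0:
            raise ConfigError("blob_fwhm_mm and voxel_size_mm must be positive")
        for mod, comps in self.group_effect_components.items():
            if mod not in MODALITIES:
                raise ConfigError(f"unknown modality {mod!r}")
            if any(not 0 <= c < self.n_components for c in comps):
                raise ConfigError(f"group_effect_components[{mod}] out of range")
        # identifiability head-room: enough voxels per source
        if int(np.prod(self.grid_dims)) < self.n_components * 50:
            raise IdentifiabilityError(
                f"grid volume {int(np.prod(self.grid_dims))} < "
                f"{self.n_components} components x 50 voxels head-room"
            )

    @property
    def n_subjects(self) -> int:
        return sum(self.n_subjects_per_group)

    @property
    def affine(self) -> np.ndarray:
        """RAS+ affine centering the grid on the mm origin."""
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -self.voxel_size_mm * (np.asarray(self.grid_dims) - 1) / 2.0
        return aff


def ellipsoid_mask(grid_dims: tuple[int, int, int]) -> np.ndarray:
    """Boolean mask of the ellipsoid inscribed in the grid (brain-like support)."""
    idx = np.indices(grid_dims).astype(float)
    center = (np.asarray(grid_dims, dtype=float) - 1) / 2.0
    semi = np.asarray(grid_dims, dtype=float) / 2.0
    r2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return r2 <= 1.0


def _place_blob(vol: np.ndarray, center: np.ndarray, sigma_vox: float,
                amplitude: float) -> None:
    grid = np.indices(vol.shape).astype(float)
    d2 = sum((grid[a] - center[a]) ** 2 for a in range(3))
    vol += amplitude * np.exp(-d2 / (2.0 * sigma_vox**2))


def generate_source_maps(
    config: SimConfig,
    modality: str = "tau",
    rng: np.random.Generator | None = None,
    mask: np.ndarray | None = None,
) -> SourceMaps:
    """Generate sparse blob source maps for one modality.

    Each source is a sum of Gaussian blobs at distinct random in-mask
    centers, normalized to zero mean and unit variance over the mask.
    Sources are redrawn until every pairwise absolute spatial correlation
    is at most 0.3, so that the latent maps are identifiable.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if mask is None:
        mask = ellipsoid_mask(config.grid_dims)
    n_mask = int(mask.sum())
    if n_mask < config.n_components * 50:
        raise IdentifiabilityError(
            f"mask has {n_mask} voxels < {config.n_components} x 50 "
            "identifiability head-room"
        )
    sigma_vox = config.blob_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / config.voxel_size_mm
    min_sep_vox = 2.0 * sigma_vox  # between blob centers of different sources
    mask_coords = np.argwhere(mask)

    def draw_source(occupied: list[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray]]:
        n_blobs = int(rng.integers(config.blob_count_range[0],
                                   config.blob_count_range[1] + 1))
        vol = np.zeros(config.grid_dims, dtype=float)
        centers: list[np.ndarray] = []
        for _ in range(n_blobs):
            for _attempt in range(200):
                c = mask_coords[rng.integers(len(mask_coords))].astype(float)
                if all(np.linalg.norm(c - o) >= min_sep_vox for o in occupied + centers):
                    break
            else:
                raise IdentifiabilityError(
                    "cannot place blob centers at separation "
                    f">= {min_sep_vox:.2f} voxels: grid too small for "
                    f"{config.n_components} separable sources"
                )
            centers.append(c)
            _place_blob(vol, c, sigma_vox, float(rng.uniform(0.7, 1.3)))
        flat = vol[mask]
        flat = (flat - flat.mean()) / flat.std()
        return flat, centers

    maps = np.empty((config.n_components, n_mask))
    occupied: list[np.ndarray] = []
    per_source_centers: list[list[np.ndarray]] = []
    for i in range(config.n_components):
        maps[i], centers = draw_source(occupied)
        occupied.extend(centers)
        per_source_centers.append(centers)

    # enforce the pairwise spatial-correlation bound by redrawing offenders
    for _round in range(50):
        corr = np.corrcoef(maps)
        np.fill_diagonal(corr, 0.0)
        bad = np.argwhere(np.abs(corr) > 0.3)
        if bad.size == 0:
            break
        i = int(bad[0, 0])
        occupied = [c for j, cs in enumerate(per_source_centers) if j != i for c in cs]
        maps[i], centers = draw_source(occupied)
        per_source_centers[i] = centers
    else:
        raise IdentifiabilityError(
            "pairwise |spatial correlation| <= 0.3 unattainable on this grid"
        )
    return SourceMaps(maps=maps, mask=mask, affine=config.affine,
                      modality=modality)


def group_labels(config: SimConfig) -> np.ndarray:
    n_mci, n_nc = config.n_subjects_per_group
    return np.array(["MCI"] * n_mci + ["NC"] * n_nc)


def generate_loadings(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Draw per-subject loading matrices for both modalities.

    All columns are standard normal. The configured cross-modal pair is
    drawn jointly (Gaussian copula) with population correlation
    ``coupled_r``; every other cross-modal column pair is independent.
    Flagged components then receive a between-group mean shift of
    ``group_effect_size`` within-group standard deviations.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    k = config.n_components
    labels = group_labels(config)
    is_mci = labels == "MCI"

    a_tau = rng.standard_normal((n, k))
    a_abeta = rng.standard_normal((n, k))
    i, j = config.coupled_pair
    r = config.coupled_r
    a_abeta[:, j] = r * a_tau[:, i] + np.sqrt(1.0 - r**2) * rng.standard_normal(n)

    effect_table: dict[str, dict[int, float]] = {m: {} for m in MODALITIES}
    for mod, a in (("tau", a_tau), ("abeta", a_abeta)):
        for comp in config.group_effect_components.get(mod, ()):
            d = config.group_effect_size
            a[is_mci, comp] += d / 2.0
            a[~is_mci, comp] -= d / 2.0
            effect_table[mod][comp] = d

    realized = float(np.corrcoef(a_tau[:, i], a_abeta[:, j])[0, 1])
    truth = SyntheticTruth(
        sources={},
        loadings={"tau": a_tau, "abeta": a_abeta},
        coupled_pair=(i, j),
        coupled_r_target=r,
        coupled_r_realized=realized,
        group_labels=labels,
        effect_table=effect_table,
    )
    for a in (a_tau, a_abeta):
        if np.linalg.matrix_rank(a) < k:  # pragma: no cover - measure-zero
            raise NumericalError(f"loading matrix rank-deficient: shape {a.shape}")
    return a_tau, a_abeta, truth


def make_subject_table(config: SimConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate the cohort's demographic / clinical table."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    labels = group_labels(config)
    rows = []
    for s, grp in enumerate(labels):
        demo = _DEMOGRAPHICS[grp]
        rows.append({
            "subject_id": f"sub-{s:04d}",
            "group": grp,
            "age": round(float(rng.normal(*demo["age"])), 1),
            "sex": "M" if rng.random() < 0.5 else "F",
            "apoe4": int(rng.random() < demo["apoe4_rate"]),
            "mmse": int(np.clip(round(rng.normal(*demo["mmse"])), 0, 30)),
            "cdr": demo["cdr"],
        })
    return pd.DataFrame(rows)


def synthesize_dataset(
    config: SimConfig,
) -> tuple[VoxelMatrix, VoxelMatrix, SyntheticTruth]:
    """Generate a full paired-modality dataset: X = A @ S + noise per modality."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    mask = ellipsoid_mask(config.grid_dims)
    src = {m: generate_source_maps(config, m, rng, mask) for m in MODALITIES}
    a_tau, a_abeta, truth = generate_loadings(config, rng)
    truth.sources = {m: src[m].maps for m in MODALITIES}

    matrices = {}
    for mod, a in (("tau", a_tau), ("abeta", a_abeta)):
        data = a @ src[mod].maps
        if config.noise_sd > 0:
            data = data + config.noise_sd * rng.standard_normal(data.shape)
        matrices[mod] = VoxelMatrix(
            values=data, mask=mask, affine=config.affine,
            subject_ids=[f"sub-{s:04d}" for s in range(config.n_subjects)],
            modality=mod,
        )
    return matrices["tau"], matrices["abeta"], truth


def write_dataset(
    outdir: str | Path,
    tau: VoxelMatrix,
    abeta: VoxelMatrix,
    truth: SyntheticTruth,
    subject_table: pd.DataFrame,
) -> None:
    """Export per-subject NIfTI volumes, the subject table (TSV) and truth (JSON)."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for vm in (tau, abeta):
        for s, sid in enumerate(vm.subject_ids):
            vol = vm.unflatten(vm.values[s])
            img = nib.Nifti1Image(vol.astype(np.float32), vm.affine)
            nib.save(img, outdir / f"{vm.modality}_{sid}.nii.gz")
    subject_table.to_csv(outdir / "subjects.tsv", sep="\t", index=False)
    payload = {
        "coupled_pair": list(truth.coupled_pair),
        "coupled_r_target": truth.coupled_r_target,
        "coupled_r_realized": truth.coupled_r_realized,
        "group_labels": truth.group_labels.tolist(),
        "effect_table": {m: {str(k): v for k, v in t.items()}
                         for m, t in truth.effect_table.items()},
        "loadings": {m: a.tolist() for m, a in truth.loadings.items()},
    }
    (outdir / "truth.json").write_text(json.dumps(payload))
    mask_img = nib.Nifti1Image(tau.mask.astype(np.uint8), tau.affine)
    nib.save(mask_img, outdir / "mask.nii.gz")


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
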