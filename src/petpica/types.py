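"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VoxelMatrix:
    """Subjects x in-mask-voxels data matrix for one modality.

    Attributes
    ----------
    values
        ``(n_subjects, n_voxels)`` float array; column j corresponds to the
        j-th True voxel of ``mask`` in C (row-major) flattening order.
    mask
        3-D boolean analysis mask.
    affine
        4x4 voxel-index -> mm (RAS+) transform, NIfTI convention, 0-based
        voxel indices.
    subject_ids
        Ordered subject identifiers, one per row.
    modality
        Free-text tag, e.g. ``"tau"`` or ``"abeta"``.
    """

    values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    subject_ids: list[str]
    modality: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        n_mask = int(self.mask.sum())
        if self.values.ndim != 2 or self.values.shape[1] != n_mask:
            raise ValueError(
                f"values has shape {self.values.shape} but mask selects "
                f"{n_mask} voxels"
            )
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length does not match rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def unflatten(self, row: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place an in-mask vector back onto the 3-D grid."""
        row = np.asarray(row, dtype=float)
        if row.shape != (self.n_voxels,):
            raise ValueError("row length does not match mask voxel count")
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = row
        return vol


@dataclass
class SourceMaps:
    """Components x voxels spatial source maps over a shared mask."""

    maps: np.ndarray          # (n_components, n_voxels)
    mask: np.ndarray          # 3-D boolean
    affine: np.ndarray
    modality: str = ""

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated paired-modality dataset."""

    sources: dict[str, np.ndarray]        # modality -> (k, n_voxels)
    loadings: dict[str, np.ndarray]       # modality -> (n_subjects, k)
    coupled_pair: tuple[int, int]
    coupled_r_target: float
    coupled_r_realized: float
    group_labels: np.ndarray              # array of "MCI"/"NC"
    effect_table: dict[str, dict[int, float]]  # modality -> comp -> d


@dataclass
class PicaResult:
    """Output of a (parallel) ICA fit on one or two modalities.

    ``sources[m]`` rows are zero-mean unit-variance over the mask;
    ``loadings[m]`` columns carry the component magnitudes, so
    ``loadings[m] @ sources[m]`` reconstructs the centered data up to the
    retained-PCA truncation plus noise.
    """

    unmixing: dict[str, np.ndarray]       # modality -> (k, k) W on whitened dims
    sources: dict[str, np.ndarray]        # modality -> (k, n_voxels)
    loadings: dict[str, np.ndarray]       # modality -> (n_subjects, k)
    whitening: dict[str, np.ndarray]      # modality -> (k, n_subjects)
    dewhitening: dict[str, np.ndarray]    # modality -> (n_subjects, k)
    loading_correlation: np.ndarray       # (k1, k2) cross-modal Pearson r
    constrained_pairs: list[tuple[int, int, float]]
    convergence_log: list[dict]
    converged: bool
    modalities: tuple[str, str] | tuple[str]
    seed: int | None = None


@dataclass
class OrderEstimate:
    """Model-order estimate from PCA eigenvalue structure."""

    aic_curve: np.ndarray
    mdl_curve: np.ndarray
    chosen_order: int
    eigenvalues: np.ndarray
    caveats: list[str] = field(default_factory=list)
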