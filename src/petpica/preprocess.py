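"""Volume-to-matrix preprocessing: smoothing, SUVR-style intensity
normalization, masking and flattening into :class:`~petpica.types.VoxelMatrix`.

Coregistration and nonlinear spatial normalization are out of scope: inputs
are assumed to live on a common template grid already.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from petpica.errors import ConfigError, PairingError
from petpica.types import VoxelMatrix

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def gaussian_smooth(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float | tuple[float, float, float],
) -> np.ndarray:
    """Separable Gaussian smoothing with a unit-sum kernel.

    ``sigma`` per axis is ``fwhm_mm / (2 sqrt(2 ln 2)) / voxel_size`` in
    voxel units; boundaries use nearest-edge replication, which preserves
    constant volumes exactly.
    """
    if fwhm_mm <= 0:
        raise ConfigError(f"fwhm_mm must be positive, got {fwhm_mm}")
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    if np.any(vs <= 0):
        raise ConfigError(f"voxel sizes must be positive, got {voxel_size_mm}")
    sigma_vox = fwhm_mm / FWHM_TO_SIGMA / vs
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float),
                                   sigma=sigma_vox, mode="nearest")


def intensity_normalize(matrix: VoxelMatrix,
                        reference_mask: np.ndarray | None = None) -> VoxelMatrix:
    """Divide each subject's row by its mean over the reference region.

    The default reference is the whole analysis mask; PET pipelines differ
    on the reference region (cerebellum, pons, whole brain), so it is an
    explicit argument rather than a baked-in choice.
    """
    if reference_mask is None:
        ref_cols = np.ones(matrix.n_voxels, dtype=bool)
    else:
        reference_mask = np.asarray(reference_mask, dtype=bool)
        if reference_mask.shape != matrix.mask.shape:
            raise ConfigError("reference_mask grid does not match analysis mask")
        if np.any(reference_mask & ~matrix.mask):
            raise ConfigError("reference_mask extends outside the analysis mask")
        ref_cols = reference_mask[matrix.mask]
        if not ref_cols.any():
            raise ConfigError("reference_mask selects no in-mask voxels")
    ref_means = matrix.values[:, ref_cols].mean(axis=1)
    bad = np.flatnonzero(ref_means <= 0)
    if bad.size:
        raise ConfigError(
            "nonpositive reference mean for subject(s): "
            + ", ".join(matrix.subject_ids[int(b)] for b in bad)
        )
    return VoxelMatrix(
        values=matrix.values / ref_means[:, None],
        mask=matrix.mask,
        affine=matrix.affine,
        subject_ids=list(matrix.subject_ids),
        modality=matrix.modality,
    )


def drop_zero_variance(matrix: VoxelMatrix) -> tuple[VoxelMatrix, int]:
    """Remove in-mask voxels with zero variance across subjects.

    Zero-variance columns break whitening; the number removed is logged and
    returned.
    """
    var = matrix.values.var(axis=0)
    keep = var > 0
    n_dropped = int((~keep).sum())
    if n_dropped == 0:
        return matrix, 0
    new_mask = matrix.mask.copy()
    idx = np.flatnonzero(matrix.mask.ravel())
    new_mask.ravel()[idx[~keep]] = False
    logger.info("dropped %d zero-variance voxels from mask (%s)",
                n_dropped, matrix.modality or "unnamed")
    return VoxelMatrix(
        values=matrix.values[:, keep],
        mask=new_mask,
        affine=matrix.affine,
        subject_ids=list(matrix.subject_ids),
        modality=matrix.modality,
    ), n_dropped


def _load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine)


def load_cohort(
    volume_paths: dict[str, dict[str, str | Path]],
    mask: np.ndarray | str | Path,
    subject_table: pd.DataFrame | str | Path,
    affine_tol: float = 1e-4,
) -> tuple[dict[str, VoxelMatrix], pd.DataFrame]:
    """Load per-subject volumes of both modalities into paired matrices.

    Parameters
    ----------
    volume_paths
        ``{modality: {subject_id: path}}`` for exactly two modalities.
    mask
        Boolean 3-D array or path to a NIfTI mask volume.
    subject_table
        DataFrame or TSV path with at least a ``subject_id`` column; its
        row order fixes the subject order of both matrices.
    """
    if isinstance(subject_table, (str, Path)):
        subject_table = pd.read_csv(subject_table, sep="\t")
    if "subject_id" not in subject_table.columns:
        raise ConfigError("subject table lacks a subject_id column")
    subject_ids = subject_table["subject_id"].astype(str).tolist()

    if isinstance(mask, (str, Path)):
        mask_arr, mask_affine = _load_volume(mask)
        mask_arr = mask_arr > 0
    else:
        mask_arr = np.asarray(mask, dtype=bool)
        mask_affine = None

    for mod, paths in volume_paths.items():
        missing = [s for s in subject_ids if s not in paths]
        if missing:
            raise PairingError(
                f"subject(s) missing from modality {mod!r}: {', '.join(missing)}"
            )

    matrices: dict[str, VoxelMatrix] = {}
    ref_affine = mask_affine
    for mod, paths in volume_paths.items():
        rows = []
        for sid in subject_ids:
            vol, aff = _load_volume(paths[sid])
            if vol.shape != mask_arr.shape:
                raise PairingError(
                    f"{paths[sid]}: grid {vol.shape} does not match mask "
                    f"grid {mask_arr.shape}"
                )
            if ref_affine is None:
                ref_affine = aff
            elif not np.allclose(aff, ref_affine, atol=affine_tol):
                raise PairingError(f"{paths[sid]}: affine mismatch beyond tolerance")
            rows.append(vol[mask_arr])
        matrices[mod] = VoxelMatrix(
            values=np.asarray(rows), mask=mask_arr, affine=ref_affine,
            subject_ids=subject_ids, modality=mod,
        )

    # shared variance filter: a voxel must vary in every modality
    keep_mask = mask_arr.copy()
    for mod in matrices:
        matrices[mod], _ = drop_zero_variance(matrices[mod])
        keep_mask &= matrices[mod].mask
    for mod, vm in matrices.items():
        if vm.mask.sum() != keep_mask.sum():
            cols = keep_mask[vm.mask]
            matrices[mod] = VoxelMatrix(
                values=vm.values[:, cols], mask=keep_mask, affine=vm.affine,
                subject_ids=vm.subject_ids, modality=mod,
            )
    return matrices, subject_table


def save_voxel_matrix(matrix: VoxelMatrix, outdir: str | Path) -> None:
    """Persist a VoxelMatrix as NIfTI mask + binary matrix + JSON metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(matrix.mask.astype(np.uint8), matrix.affine),
             outdir / "mask.nii.gz")
    np.save(outdir / "values.npy", matrix.values)
    meta = {"subject_ids": matrix.subject_ids, "modality": matrix.modality,
            "affine": matrix.affine.tolist()}
    (outdir / "meta.json").write_text(json.dumps(meta))


def load_voxel_matrix(indir: str | Path) -> VoxelMatrix:
    indir = Path(indir)
    mask_img = nib.load(str(indir / "mask.nii.gz"))
    meta = json.loads((indir / "meta.json").read_text())
    return VoxelMatrix(
        values=np.load(indir / "values.npy"),
        mask=np.asarray(mask_img.get_fdata()) > 0,
        affine=np.asarray(meta["affine"]),
        subject_ids=list(meta["subject_ids"]),
        modality=meta["modality"],
    )
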