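"""Peak tables from thresholded component maps.

Turns a z-scored spatial map into a table of supra-threshold clusters with
their peak |z|, peak mm coordinates, atlas region label and network
assignment — the standard shape of a component report in PET/fMRI ICA
studies. The atlas (integer label volume + region/network tables) is user
data; a small synthetic atlas builder is provided for testing and for
simulated pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from petpica.errors import ConfigError

NETWORKS = ("DMN", "visual", "cognitive", "subcortical", "unassigned")

_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class PeakRecord:
    region: str
    network: str
    peak_abs_z: float
    component_p: float
    coords_mm: tuple[float, float, float]
    component: int = -1
    modality: str = ""
    peak_voxel: tuple[int, int, int] = (0, 0, 0)
    cluster_size: int = 0


@dataclass
class AtlasBundle:
    """Integer label volume plus label -> region and region -> network maps."""

    label_volume: np.ndarray
    label_table: dict[int, str]
    network_map: dict[str, str]

    def validate(self) -> None:
        present = set(np.unique(self.label_volume).tolist()) - {0}
        unknown = present - set(self.label_table)
        if unknown:
            raise ConfigError(f"label volume values missing from table: {unknown}")


def find_peaks(zmap: np.ndarray, threshold: float = 2.5,
               connectivity: int = 26) -> list[dict]:
    """Connected supra-threshold clusters of a 3-D |z| map.

    Returns one record per cluster with the peak voxel (maximum |z|, ties
    broken by lowest linear index — the order `argmax` visits), the peak
    value and the cluster size.
    """
    if threshold <= 0:
        raise ConfigError("threshold must be positive")
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ConfigError(f"connectivity must be one of {set(_CONNECTIVITY_STRUCTS)}")
    zabs = np.abs(np.asarray(zmap, dtype=float))
    supra = zabs > threshold
    labeled, n = ndimage.label(supra, structure=_CONNECTIVITY_STRUCTS[connectivity])
    clusters = []
    for lab in range(1, n + 1):
        inside = labeled == lab
        masked = np.where(inside, zabs, -np.inf)
        peak_flat = int(np.argmax(masked))
        peak_voxel = np.unravel_index(peak_flat, zabs.shape)
        clusters.append({
            "cluster_id": lab,
            "peak_voxel": tuple(int(v) for v in peak_voxel),
            "peak_abs_z": float(zabs[peak_voxel]),
            "size": int(inside.sum()),
        })
    return clusters


def voxel_to_mm(voxel: tuple[int, int, int] | np.ndarray,
                affine: np.ndarray) -> np.ndarray:
    """Map a 0-based voxel index triple to mm through the NIfTI affine."""
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ConfigError("affine is singular")
    hom = np.append(np.asarray(voxel, dtype=float), 1.0)
    return (affine @ hom)[:3]


def label_peaks(
    clusters: list[dict],
    atlas: AtlasBundle,
    affine: np.ndarray,
    component: int = -1,
    modality: str = "",
    component_p: float = float("nan"),
) -> list[PeakRecord]:
    """Attach region/network labels and mm coordinates to cluster peaks."""
    atlas.validate()
    records = []
    for cl in clusters:
        voxel = cl["peak_voxel"]
        if any(v >= s for v, s in zip(voxel, atlas.label_volume.shape)):
            raise ConfigError("atlas grid does not match the z-map grid")
        lab = int(atlas.label_volume[voxel])
        region = atlas.label_table.get(lab, "unassigned") if lab else "unassigned"
        network = atlas.network_map.get(region, "unassigned")
        records.append(PeakRecord(
            region=region, network=network,
            peak_abs_z=cl["peak_abs_z"], component_p=component_p,
            coords_mm=tuple(float(v) for v in voxel_to_mm(voxel, affine)),
            component=component, modality=modality,
            peak_voxel=voxel, cluster_size=cl["size"],
        ))
    return records


def peak_table(records: list[PeakRecord]) -> pd.DataFrame:
    """Report table with the conventional columns: region, |z|, network,
    component p, X/Y/Z mm."""
    rows = []
    for r in records:
        rows.append({
            "modality": r.modality, "component": r.component,
            "brain_region": r.region, "abs_z": round(r.peak_abs_z, 3),
            "network": r.network, "component_p": r.component_p,
            "X": r.coords_mm[0], "Y": r.coords_mm[1], "Z": r.coords_mm[2],
            "cluster_size": r.cluster_size,
        })
    return pd.DataFrame(rows)


def load_atlas(label_nifti: str | Path, label_tsv: str | Path,
               network_tsv: str | Path) -> AtlasBundle:
    """Read an atlas from NIfTI labels + TSV (label_id, region_name) +
    TSV (region_name, network)."""
    img = nib.load(str(label_nifti))
    labels = pd.read_csv(label_tsv, sep="\t")
    networks = pd.read_csv(network_tsv, sep="\t")
    bundle = AtlasBundle(
        label_volume=np.asarray(img.get_fdata()).astype(int),
        label_table=dict(zip(labels["label_id"].astype(int),
                             labels["region_name"].astype(str))),
        network_map=dict(zip(networks["region_name"].astype(str),
                             networks["network"].astype(str))),
    )
    bundle.validate()
    return bundle


def make_synthetic_atlas(grid_dims: tuple[int, int, int],
                         n_regions: int = 6,
                         seed: int = 0) -> AtlasBundle:
    """Synthetic atlas: labeled ellipsoids tiling the grid, round-robin
    network assignments. For tests and simulated pipelines only."""
    rng = np.random.default_rng(seed)
    vol = np.zeros(grid_dims, dtype=int)
    idx = np.indices(grid_dims).astype(float)
    centers = np.column_stack([
        rng.uniform(0.2 * d, 0.8 * d, size=n_regions) for d in grid_dims
    ])
    # nearest-center tessellation restricted to an inscribed ellipsoid
    center = (np.asarray(grid_dims, dtype=float) - 1) / 2.0
    semi = np.asarray(grid_dims, dtype=float) / 2.0
    inside = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3)) <= 1.0
    d2 = np.stack([sum((idx[a] - c[a]) ** 2 for a in range(3)) for c in centers])
    vol[inside] = (np.argmin(d2, axis=0) + 1)[inside]
    label_table = {i + 1: f"region_{i + 1:02d}" for i in range(n_regions)}
    nets = [n for n in NETWORKS if n != "unassigned"]
    network_map = {name: nets[i % len(nets)]
                   for i, name in enumerate(label_table.values())}
    return AtlasBundle(label_volume=vol, label_table=label_table,
                       network_map=network_map)


def write_atlas(atlas: AtlasBundle, affine: np.ndarray, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(atlas.label_volume.astype(np.int16), affine),
             outdir / "atlas_labels.nii.gz")
    pd.DataFrame([{"label_id": k, "region_name": v}
                  for k, v in atlas.label_table.items()]
                 ).to_csv(outdir / "atlas_labels.tsv", sep="\t", index=False)
    pd.DataFrame([{"region_name": k, "network": v}
                  for k, v in atlas.network_map.items()]
                 ).to_csv(outdir / "atlas_networks.tsv", sep="\t", index=False)
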