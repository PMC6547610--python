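"""End-to-end orchestration: simulate/load -> preprocess -> model order ->
pICA -> statistics -> atlas report -> classification, with a run manifest.

A run is configured by a single YAML-serializable mapping holding exactly
one of a ``simulate`` block or an ``inputs`` block, plus optional blocks
for each stage. All headline constants (8 components, |z| > 2.5, FDR alpha
0.05, k = 5 folds, 8 mm FWHM) are defaults in the config, never hard-coded
in stage code.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from petpica import __version__
from petpica.atlas import (find_peaks, label_peaks, load_atlas,
                           make_synthetic_atlas, peak_table, write_atlas)
from petpica.classify import CONDITIONS, build_condition_features, cross_validate
from petpica.errors import ConfigError
from petpica.model_order import estimate_order
from petpica.pica import PicaConfig, parallel_ica
from petpica.preprocess import (drop_zero_variance, gaussian_smooth,
                                intensity_normalize, load_cohort)
from petpica.simulate import (MODALITIES, SimConfig, make_subject_table,
                              synthesize_dataset)
from petpica.stats import (cohort_table, component_tests_to_frame,
                           crossmodal_correlations, crossmodal_to_frame,
                           loading_group_test, zscore_map)
from petpica.types import VoxelMatrix

logger = logging.getLogger("petpica.pipeline")

STAGES = ("data", "preprocess", "model_order", "pica", "stats",
          "atlas_report", "classification")

DEFAULT_CONFIG: dict[str, Any] = {
    "simulate": {},                 # SimConfig fields; exclusive with "inputs"
    "inputs": None,                 # {tau: {...paths}, abeta: {...}, mask, subjects}
    "preprocess": {"fwhm_mm": None, "normalize": True},
    "n_components": 8,              # int or "auto"
    "pica": {},                     # PicaConfig fields
    "stats": {"alpha": 0.05, "z_cutoff": 2.5},
    "atlas": None,                  # {labels, label_table, network_table} paths
    "classification": {"k": 5, "seed": 0, "conditions": list(CONDITIONS)},
    "output_dir": "petpica_run",
    "export_volumes": False,        # write per-subject NIfTIs when simulating
    "seed": 0,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def validate_config(config: dict) -> dict:
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    cfg = _merge(DEFAULT_CONFIG, config)
    has_inputs = cfg["inputs"] is not None
    has_simulate = "simulate" in config and config["simulate"] is not None
    if has_inputs and has_simulate:
        raise ConfigError("config must provide either inputs or a simulate "
                          "block, not both")
    if has_inputs:
        cfg["simulate"] = None
    n = cfg["n_components"]
    if not (n == "auto" or (isinstance(n, int) and n > 0)):
        raise ConfigError('n_components must be a positive int or "auto"')
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, stop_after: str | None = None) -> dict:
    """Execute all stages and return the run manifest.

    The manifest records the config hash, package version, per-stage wall
    time and every file written; reruns with identical config and seeds
    reproduce all outputs. ``stop_after`` names a stage after which the run
    ends early (used by the per-stage CLI subcommands).
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ConfigError(f"stop_after must be one of {STAGES}")
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = validate_config(config)
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": cfg, "config_hash": _config_hash(cfg),
        "version": __version__, "stages": [], "outputs": [], "seeds": {},
    }
    t_all = time.time()

    def stage(name):
        logger.info("[%s] starting", name)
        return time.time()

    def done(name, t0):
        manifest["stages"].append({"stage": name,
                                   "wall_time_s": round(time.time() - t0, 3)})
        return stop_after == name

    def finalize():
        manifest["wall_time_s"] = round(time.time() - t_all, 3)
        (outdir / "manifest.json").write_text(json.dumps(manifest, default=str))
        return manifest

    def emit(path: Path):
        manifest["outputs"].append(str(path))

    # ---- stage 1: data ---------------------------------------------------
    t0 = stage("data")
    if cfg["simulate"] is not None:
        sim_kwargs = dict(cfg["simulate"])
        sim_kwargs.setdefault("seed", cfg["seed"])
        for key in ("grid_dims", "n_subjects_per_group", "coupled_pair",
                    "blob_count_range"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        if "group_effect_components" in sim_kwargs:
            sim_kwargs["group_effect_components"] = {
                m: tuple(v) for m, v in sim_kwargs["group_effect_components"].items()}
        sim = SimConfig(**sim_kwargs)
        manifest["seeds"]["simulate"] = sim.seed
        tau, abeta, truth = synthesize_dataset(sim)
        subjects = make_subject_table(sim)
        truth_summary = {
            "coupled_pair": list(truth.coupled_pair),
            "coupled_r_target": truth.coupled_r_target,
            "coupled_r_realized": truth.coupled_r_realized,
        }
        (outdir / "truth_summary.json").write_text(json.dumps(truth_summary))
        emit(outdir / "truth_summary.json")
        if cfg["export_volumes"]:
            from petpica.simulate import write_dataset
            write_dataset(outdir / "volumes", tau, abeta, truth, subjects)
            for sid in tau.subject_ids:
                emit(outdir / "volumes" / f"tau_{sid}.nii.gz")
                emit(outdir / "volumes" / f"abeta_{sid}.nii.gz")
            for name in ("subjects.tsv", "truth.json", "mask.nii.gz"):
                emit(outdir / "volumes" / name)
    else:
        inputs = cfg["inputs"]
        matrices, subjects = load_cohort(
            {m: inputs[m] for m in MODALITIES},
            inputs["mask"], inputs["subjects"])
        tau, abeta = matrices["tau"], matrices["abeta"]
        truth = None
    labels = subjects["group"].to_numpy()
    subjects.to_csv(outdir / "subjects.tsv", sep="\t", index=False)
    emit(outdir / "subjects.tsv")
    if done("data", t0):
        return finalize()

    # ---- stage 2: preprocess --------------------------------------------
    t0 = stage("preprocess")
    pp = cfg["preprocess"]
    processed = {}
    for vm in (tau, abeta):
        if pp.get("fwhm_mm"):
            voxel_sizes = np.abs(np.diag(vm.affine)[:3])
            rows = []
            for s in range(vm.n_subjects):
                vol = vm.unflatten(vm.values[s])
                rows.append(gaussian_smooth(vol, pp["fwhm_mm"], voxel_sizes)[vm.mask])
            vm = VoxelMatrix(values=np.asarray(rows), mask=vm.mask,
                             affine=vm.affine, subject_ids=vm.subject_ids,
                             modality=vm.modality)
        if pp.get("normalize", True):
            shifted = vm
            if vm.values.min() <= 0:   # SUVR scaling needs positive means
                shifted = VoxelMatrix(
                    values=vm.values - vm.values.min() + 1.0, mask=vm.mask,
                    affine=vm.affine, subject_ids=vm.subject_ids,
                    modality=vm.modality)
            vm = intensity_normalize(shifted)
        vm, n_dropped = drop_zero_variance(vm)
        processed[vm.modality] = vm
    tau, abeta = processed["tau"], processed["abeta"]
    if done("preprocess", t0):
        return finalize()

    # ---- stage 3: model order -------------------------------------------
    t0 = stage("model_order")
    if cfg["n_components"] == "auto":
        orders = {}
        for vm in (tau, abeta):
            est = estimate_order(vm, max_order=min(vm.n_subjects - 1, 40))
            orders[vm.modality] = est
        n_components = max(1, min(est.chosen_order for est in orders.values()))
        order_report = {
            m: {"chosen_order": int(e.chosen_order),
                "aic_curve": e.aic_curve.tolist(),
                "mdl_curve": e.mdl_curve.tolist(),
                "caveats": e.caveats}
            for m, e in orders.items()}
    else:
        n_components = int(cfg["n_components"])
        order_report = {"note": f"fixed order {n_components}; estimation bypassed"}
    (outdir / "model_order.json").write_text(json.dumps(order_report))
    emit(outdir / "model_order.json")
    manifest["n_components"] = n_components
    if done("model_order", t0):
        return finalize()

    # ---- stage 4: pICA ---------------------------------------------------
    t0 = stage("pica")
    pica_kwargs = dict(cfg["pica"])
    pica_kwargs.setdefault("seed", cfg["seed"])
    pica_kwargs["n_components"] = n_components
    pica_cfg = PicaConfig(**pica_kwargs)
    manifest["seeds"]["pica"] = pica_cfg.seed
    result = parallel_ica(tau, abeta, pica_cfg)
    if not result.converged:
        logger.warning("pICA did not meet the weight-change tolerance in "
                       "%d iterations; results returned as-is",
                       pica_cfg.max_iterations)
    for mod, vm in (("tau", tau), ("abeta", abeta)):
        vols = np.stack([vm.unflatten(row) for row in result.sources[mod]], axis=-1)
        nib.save(nib.Nifti1Image(vols.astype(np.float32), vm.affine),
                 outdir / f"components_{mod}.nii.gz")
        emit(outdir / f"components_{mod}.nii.gz")
        pd.DataFrame(result.loadings[mod],
                     columns=[f"comp{c}" for c in range(n_components)],
                     index=vm.subject_ids).to_csv(
            outdir / f"loadings_{mod}.tsv", sep="\t",
            index_label="subject_id")
        emit(outdir / f"loadings_{mod}.tsv")
    pica_json = {
        "converged": result.converged,
        "constrained_pairs": [[i, j, r] for i, j, r in result.constrained_pairs],
        "loading_correlation": result.loading_correlation.tolist(),
        "n_iterations": sum(1 for e in result.convergence_log if "dW" in e),
    }
    (outdir / "pica.json").write_text(json.dumps(pica_json))
    emit(outdir / "pica.json")
    if done("pica", t0):
        return finalize()

    # ---- stage 5: statistics --------------------------------------------
    t0 = stage("stats")
    st = cfg["stats"]
    tests = {}
    for mod in MODALITIES:
        tests[mod] = loading_group_test(result.loadings[mod], labels,
                                        modality=mod, alpha=st["alpha"])
    frames = pd.concat([component_tests_to_frame(tests[m]) for m in MODALITIES])
    frames.to_csv(outdir / "component_tests.tsv", sep="\t", index=False)
    emit(outdir / "component_tests.tsv")
    corr = crossmodal_correlations(result.loadings["tau"],
                                   result.loadings["abeta"], alpha=st["alpha"])
    crossmodal_to_frame(corr).to_csv(outdir / "crossmodal_correlations.tsv",
                                     sep="\t", index=False)
    emit(outdir / "crossmodal_correlations.tsv")
    cohort_table(subjects).to_csv(outdir / "cohort_table.tsv", sep="\t",
                                  index=False)
    emit(outdir / "cohort_table.tsv")
    if done("stats", t0):
        return finalize()

    # ---- stage 6: atlas report ------------------------------------------
    t0 = stage("atlas_report")
    if cfg["atlas"]:
        bundle = load_atlas(cfg["atlas"]["labels"], cfg["atlas"]["label_table"],
                            cfg["atlas"]["network_table"])
    else:
        bundle = make_synthetic_atlas(tau.mask.shape, seed=cfg["seed"])
        write_atlas(bundle, tau.affine, outdir / "synthetic_atlas")
        for name in ("atlas_labels.nii.gz", "atlas_labels.tsv",
                     "atlas_networks.tsv"):
            emit(outdir / "synthetic_atlas" / name)
    records = []
    for mod, vm in (("tau", tau), ("abeta", abeta)):
        for t in tests[mod]:
            if not t.significant:
                continue
            zmap = vm.unflatten(zscore_map(result.sources[mod][t.component]))
            clusters = find_peaks(zmap, threshold=st["z_cutoff"])
            records.extend(label_peaks(clusters, bundle, vm.affine,
                                       component=t.component, modality=mod,
                                       component_p=t.p))
    peak_table(records).to_csv(outdir / "peak_table.tsv", sep="\t", index=False)
    emit(outdir / "peak_table.tsv")
    if done("atlas_report", t0):
        return finalize()

    # ---- stage 7: classification ----------------------------------------
    t0 = stage("classification")
    cl = cfg["classification"]
    manifest["seeds"]["classification"] = cl["seed"]
    class_report = {}
    for cond in cl["conditions"]:
        feats = build_condition_features(tau, abeta, result, labels, cond,
                                         z_cutoff=st["z_cutoff"],
                                         alpha=st["alpha"])
        rep = cross_validate(feats, labels, k=cl["k"], seed=cl["seed"])
        class_report[cond] = {"means": {m: round(v, 2)
                                        for m, v in rep.means.items()},
                              "per_fold": rep.per_fold,
                              "protocol": rep.protocol}
    (outdir / "classification.json").write_text(json.dumps(class_report))
    emit(outdir / "classification.json")
    if done("classification", t0):
        return finalize()

    return finalize()
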