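"""ROI-feature extraction and stratified cross-validated classification.

Features are mean normalized intensities over the thresholded maps of the
group-discriminative components, computed per modality ("Tau", "Abeta"),
concatenated across modalities ("All"), or replaced by a weak raw-data
baseline ("Non": whole-mask means plus top-5 PCA scores). A regularized
linear classifier (logistic loss, L2 penalty) is scored with stratified
5-fold cross-validation; ACC/AUC/SEN/SPE are reported per fold and as the
mean of the five folds, on a percent scale.

Two protocols are available: a fast "fixed" mode that extracts features
from a single decomposition of the full dataset, and a stricter "refit"
mode that re-runs the decomposition and component selection inside each
training split so that no test subject influences feature definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from petpica.errors import ConfigError
from petpica.stats import loading_group_test, threshold_map, zscore_map
from petpica.types import PicaResult, VoxelMatrix

CONDITIONS = ("Non", "Tau", "Abeta", "All")
METRICS = ("ACC", "AUC", "SEN", "SPE")


@dataclass
class FeatureTable:
    values: np.ndarray                 # (n_subjects, n_features)
    feature_names: list[str]
    condition: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("features contain non-finite values")
        if self.values.shape[1] != len(self.feature_names):
            raise ConfigError("feature_names length mismatch")


@dataclass
class ClassificationReport:
    condition: str
    per_fold: list[dict]               # fold -> {ACC, AUC, SEN, SPE}
    means: dict                        # metric -> mean over folds (percent)
    fold_assignments: np.ndarray
    classifier: str
    seed: int
    protocol: str = "fixed"
    notes: list[str] = field(default_factory=list)


def extract_roi_features(
    matrix: VoxelMatrix,
    component_masks: list[np.ndarray],
    names: list[str] | None = None,
    condition: str = "",
) -> FeatureTable:
    """One feature per mask: mean intensity over the mask's voxels."""
    feats = []
    for idx, m in enumerate(component_masks):
        m = np.asarray(m, dtype=bool)
        if m.shape == matrix.mask.shape:      # 3-D mask -> in-mask columns
            m = m[matrix.mask]
        if m.shape != (matrix.n_voxels,):
            raise ConfigError(f"component mask {idx} does not fit the grid")
        if not m.any():
            raise ConfigError(f"component mask {idx} is empty")
        feats.append(matrix.values[:, m].mean(axis=1))
    names = names or [f"{matrix.modality}_roi{idx}" for idx in range(len(feats))]
    return FeatureTable(values=np.column_stack(feats) if feats else
                        np.empty((matrix.n_subjects, 0)),
                        feature_names=names, condition=condition)


def significant_component_masks(
    result: PicaResult, labels: np.ndarray, modality: str,
    z_cutoff: float = 2.5, alpha: float = 0.05,
) -> tuple[list[np.ndarray], list[int]]:
    """Thresholded maps of the components whose loadings separate groups.

    Falls back to the single most discriminative component if none reaches
    significance, so a feature set always exists.
    """
    tests = loading_group_test(result.loadings[modality], labels,
                               modality=modality, alpha=alpha)
    chosen = [t.component for t in tests if t.significant]
    if not chosen:
        chosen = [min(tests, key=lambda t: t.p).component]
    masks = []
    for c in chosen:
        zmask, count = threshold_map(zscore_map(result.sources[modality][c]),
                                     z_cutoff)
        if count == 0:  # pragma: no cover - sparse maps always have tails
            zmask = np.abs(result.sources[modality][c]) >= np.quantile(
                np.abs(result.sources[modality][c]), 0.99)
        masks.append(zmask)
    return masks, chosen


def build_condition_features(
    tau: VoxelMatrix, abeta: VoxelMatrix, result: PicaResult,
    labels: np.ndarray, condition: str, z_cutoff: float = 2.5,
    alpha: float = 0.05, n_baseline_pcs: int = 5,
) -> FeatureTable:
    """Assemble the feature table for one condition (Non/Tau/Abeta/All)."""
    if condition not in CONDITIONS:
        raise ConfigError(f"condition must be one of {CONDITIONS}")
    if condition == "Non":
        raw = np.hstack([tau.values, abeta.values])
        raw_c = raw - raw.mean(axis=0)
        _, _, vt = np.linalg.svd(raw_c, full_matrices=False)
        pcs = raw_c @ vt[:n_baseline_pcs].T
        vals = np.column_stack([tau.values.mean(axis=1),
                                abeta.values.mean(axis=1), pcs])
        names = (["tau_global_mean", "abeta_global_mean"]
                 + [f"raw_pc{i + 1}" for i in range(n_baseline_pcs)])
        return FeatureTable(values=vals, feature_names=names, condition="Non")

    parts = []
    for mod, vm in (("tau", tau), ("abeta", abeta)):
        if condition in (mod.capitalize(), "All"):
            masks, comps = significant_component_masks(
                result, labels, mod, z_cutoff=z_cutoff, alpha=alpha)
            names = [f"{mod}_comp{c}" for c in comps]
            parts.append(extract_roi_features(vm, masks, names, condition))
    vals = np.hstack([p.values for p in parts])
    names = [n for p in parts for n in p.feature_names]
    return FeatureTable(values=vals, feature_names=names, condition=condition)


def stratified_kfold(labels: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1 per subject)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < k):
        small = classes[counts < k]
        raise ConfigError(f"class(es) smaller than k={k}: {small.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assign = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assign[test_idx] = fold
    return assign


def roc_auc(scores: np.ndarray, labels: np.ndarray,
            positive: str = "MCI") -> float:
    """AUC by the rank (Mann-Whitney) formulation, half credit for ties."""
    labels = np.asarray(labels)
    y = labels == positive
    if y.all() or not y.any():
        raise ConfigError("both classes must be present to compute AUC")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def _default_classifier() -> LogisticRegression:
    return LogisticRegression(C=1.0, max_iter=1000)


def _fold_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                  scores: np.ndarray, positive: str, negative: str) -> dict:
    pos = y_true == positive
    acc = float(np.mean(y_pred == y_true))
    sen = float(np.mean(y_pred[pos] == positive)) if pos.any() else np.nan
    spe = float(np.mean(y_pred[~pos] == negative)) if (~pos).any() else np.nan
    auc = roc_auc(scores, y_true, positive=positive)
    return {"ACC": 100 * acc, "AUC": 100 * auc,
            "SEN": 100 * sen, "SPE": 100 * spe}


def cross_validate(
    features: FeatureTable | np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
    classifier=None,
    positive: str = "MCI",
    pooled_auc: bool = False,
) -> ClassificationReport:
    """Stratified k-fold evaluation of a feature table.

    Standardization is fitted on the training folds only. Metrics are on a
    percent scale; the headline values are the arithmetic means of the k
    per-fold values (a pooled-score AUC is appended as a note when
    requested).
    """
    x = features.values if isinstance(features, FeatureTable) else np.asarray(features, float)
    condition = features.condition if isinstance(features, FeatureTable) else ""
    labels = np.asarray(labels)
    negative = [c for c in np.unique(labels) if c != positive]
    if len(negative) != 1:
        raise ConfigError("expected exactly two classes")
    negative = negative[0]
    assign = stratified_kfold(labels, k=k, seed=seed)
    per_fold = []
    pooled_scores = np.empty(len(labels))
    for fold in range(k):
        train, test = assign != fold, assign == fold
        if len(np.unique(labels[train])) < 2:
            raise ConfigError(f"training folds for fold {fold} are single-class")
        clf = classifier() if callable(classifier) else (
            classifier or _default_classifier())
        scaler = StandardScaler().fit(x[train])
        clf.fit(scaler.transform(x[train]), labels[train])
        xt = scaler.transform(x[test])
        scores = clf.decision_function(xt)
        if clf.classes_[1] != positive:      # orient scores toward positive
            scores = -scores
        pooled_scores[test] = scores
        per_fold.append(_fold_metrics(labels[test], clf.predict(xt),
                                      scores, positive, negative))
    means = {m: float(np.mean([f[m] for f in per_fold])) for m in METRICS}
    notes = []
    if pooled_auc:
        notes.append(f"pooled AUC = {100 * roc_auc(pooled_scores, labels, positive):.2f}")
    return ClassificationReport(
        condition=condition, per_fold=per_fold, means=means,
        fold_assignments=assign, classifier="logistic (L2, C=1.0)",
        seed=seed, protocol="fixed", notes=notes,
    )


def cross_validate_pipeline(
    tau: VoxelMatrix,
    abeta: VoxelMatrix,
    labels: np.ndarray,
    pica_config,
    condition: str = "All",
    k: int = 5,
    seed: int = 0,
    z_cutoff: float = 2.5,
    alpha: float = 0.05,
    positive: str = "MCI",
) -> ClassificationReport:
    """Stricter protocol: the decomposition and the component selection are
    re-run on each training split, and the held-out subjects' features are
    computed from the training split's component masks."""
    from dataclasses import replace

    from petpica.pica import parallel_ica

    labels = np.asarray(labels)
    negative = [c for c in np.unique(labels) if c != positive][0]
    assign = stratified_kfold(labels, k=k, seed=seed)
    per_fold = []
    for fold in range(k):
        train, test = assign != fold, assign == fold

        def subset(vm: VoxelMatrix, rows: np.ndarray) -> VoxelMatrix:
            return VoxelMatrix(
                values=vm.values[rows], mask=vm.mask, affine=vm.affine,
                subject_ids=[s for s, r in zip(vm.subject_ids, rows) if r],
                modality=vm.modality)

        result = parallel_ica(subset(tau, train), subset(abeta, train),
                              replace(pica_config, seed=pica_config.seed + fold))
        mods = {"Tau": ["tau"], "Abeta": ["abeta"],
                "All": ["tau", "abeta"]}.get(condition)
        if mods is None:
            raise ConfigError(f"refit protocol supports conditions Tau/Abeta/All, "
                              f"not {condition!r}")
        masks_by_mod = {
            mod: significant_component_masks(
                result, labels[train], mod, z_cutoff=z_cutoff, alpha=alpha)[0]
            for mod in mods
        }
        vms = {"tau": tau, "abeta": abeta}
        feat_cols = {rows_tag: np.hstack([
            extract_roi_features(subset(vms[mod], rows), masks_by_mod[mod]).values
            for mod in masks_by_mod
        ]) for rows_tag, rows in (("train", train), ("test", test))}
        clf = _default_classifier()
        scaler = StandardScaler().fit(feat_cols["train"])
        clf.fit(scaler.transform(feat_cols["train"]), labels[train])
        xt = scaler.transform(feat_cols["test"])
        scores = clf.decision_function(xt)
        if clf.classes_[1] != positive:
            scores = -scores
        per_fold.append(_fold_metrics(labels[test], clf.predict(xt),
                                      scores, positive, negative))
    means = {m: float(np.mean([f[m] for f in per_fold])) for m in METRICS}
    return ClassificationReport(
        condition=condition, per_fold=per_fold, means=means,
        fold_assignments=assign, classifier="logistic (L2, C=1.0)",
        seed=seed, protocol="refit",
    )
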