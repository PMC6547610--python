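import numpy as np
import pytest

from petpica.classify import (FeatureTable, build_condition_features,
                              cross_validate, cross_validate_pipeline,
                              extract_roi_features, roc_auc,
                              stratified_kfold)
from petpica.errors import ConfigError
from petpica.types import VoxelMatrix


def toy_matrix(values):
    values = np.asarray(values, dtype=float)
    mask = np.ones((values.shape[1], 1, 1), dtype=bool)
    return VoxelMatrix(values=values, mask=mask, affine=np.eye(4),
                       subject_ids=[f"s{i}" for i in range(values.shape[0])],
                       modality="tau")


def auc_oracle(scores, labels, positive="MCI"):
    """Fraction of concordant pairs, ties at half credit."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == positive]
    neg = scores[np.asarray(labels) != positive]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestFeatures:
    def test_single_voxel_mask_returns_that_voxel(self, rng):
        vals = rng.standard_normal((5, 8))
        mask = np.zeros(8, dtype=bool)
        mask[3] = True
        ft = extract_roi_features(toy_matrix(vals), [mask])
        assert np.allclose(ft.values[:, 0], vals[:, 3])

    def test_constant_image_gives_constant_feature(self):
        vals = np.full((4, 10), 2.5)
        masks = [np.ones(10, dtype=bool), np.arange(10) < 3]
        ft = extract_roi_features(toy_matrix(vals), masks)
        assert np.allclose(ft.values, 2.5)

    def test_matches_direct_summation_oracle(self, rng):
        vals = rng.standard_normal((6, 20))
        mask = rng.random(20) > 0.5
        ft = extract_roi_features(toy_matrix(vals), [mask])
        expected = [sum(vals[s, v] for v in range(20) if mask[v]) / mask.sum()
                    for s in range(6)]
        assert np.allclose(ft.values[:, 0], expected)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ConfigError, match="0"):
            extract_roi_features(toy_matrix(np.ones((3, 5))),
                                 [np.zeros(5, dtype=bool)])


class TestStratifiedKfold:
    def test_balanced_140_subjects_fold_sizes(self):
        labels = np.array(["MCI"] * 65 + ["NC"] * 75)
        assign = stratified_kfold(labels, k=5, seed=0)
        for fold in range(5):
            idx = assign == fold
            assert idx.sum() == 28
            assert (labels[idx] == "MCI").sum() == 13
            assert (labels[idx] == "NC").sum() == 15

    def test_partition_property(self, rng):
        labels = rng.choice(["MCI", "NC"], size=47, p=[0.4, 0.6])
        assign = stratified_kfold(labels, k=5, seed=3)
        assert set(assign) == set(range(5))
        sizes = np.bincount(assign)
        assert sizes.max() - sizes.min() <= 1

    def test_deterministic_given_seed(self):
        labels = np.array(["MCI"] * 30 + ["NC"] * 30)
        assert np.array_equal(stratified_kfold(labels, seed=5),
                              stratified_kfold(labels, seed=5))

    def test_class_smaller_than_k_rejected(self):
        labels = np.array(["MCI"] * 3 + ["NC"] * 30)
        with pytest.raises(ConfigError, match="MCI"):
            stratified_kfold(labels, k=5)


class TestRocAuc:
    def test_perfect_separation(self):
        labels = np.array(["NC"] * 5 + ["MCI"] * 5)
        assert roc_auc(np.arange(10), labels) == 1.0

    def test_all_ties_give_half(self):
        labels = np.array(["NC"] * 5 + ["MCI"] * 5)
        assert roc_auc(np.zeros(10), labels) == 0.5

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 30))
            labels = np.array(["MCI"] * (n // 2) + ["NC"] * (n - n // 2))
            scores = rng.integers(0, 5, size=n).astype(float)  # force ties
            assert roc_auc(scores, labels) == pytest.approx(
                auc_oracle(scores, labels))

    def test_sign_reversal_complements(self, rng):
        labels = np.array(["MCI"] * 10 + ["NC"] * 10)
        scores = rng.standard_normal(20)
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == \
            pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        labels = np.array(["MCI"] * 10 + ["NC"] * 10)
        scores = rng.standard_normal(20)
        assert roc_auc(scores, labels) == roc_auc(np.exp(scores), labels)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigError):
            roc_auc(np.arange(4), np.array(["MCI"] * 4))


class TestCrossValidate:
    def test_linearly_separable_features_score_perfectly(self):
        labels = np.array(["MCI"] * 20 + ["NC"] * 20)
        x = np.where(labels == "MCI", 5.0, -5.0)[:, None]
        rep = cross_validate(FeatureTable(x, ["f0"], "Tau"), labels, seed=1)
        assert rep.means["ACC"] == 100.0
        assert rep.means["AUC"] == 100.0
        assert rep.means["SEN"] == 100.0
        assert rep.means["SPE"] == 100.0
        assert len(rep.per_fold) == 5

    def test_permuted_labels_near_chance_auc(self, rng):
        aucs = []
        for _ in range(50):
            x = rng.standard_normal((140, 4))
            labels = rng.permutation(np.array(["MCI"] * 65 + ["NC"] * 75))
            rep = cross_validate(FeatureTable(x, list("abcd"), "Tau"),
                                 labels, seed=0)
            aucs.append(rep.means["AUC"])
        assert 40.0 <= np.mean(aucs) <= 60.0

    def test_standardization_fitted_on_training_folds_only(self, rng):
        """Each fold's metrics must be reproducible from a scaler and
        classifier fitted with the training rows alone; an extreme artifact
        confined to the held-out rows must leave that fit untouched."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.preprocessing import StandardScaler

        labels = np.array(["MCI"] * 20 + ["NC"] * 20)
        x = rng.standard_normal((40, 3)) + np.where(
            labels == "MCI", 1.0, 0.0)[:, None]
        assign = stratified_kfold(labels, k=5, seed=7)
        x[assign == 0] *= 1000.0  # test-fold-only artifact for fold 0
        rep = cross_validate(FeatureTable(x, list("abc"), "Tau"),
                             labels, seed=7)
        train, test = assign != 0, assign == 0
        scaler = StandardScaler().fit(x[train])  # training rows only
        clf = LogisticRegression(C=1.0, max_iter=1000).fit(
            scaler.transform(x[train]), labels[train])
        pred = clf.predict(scaler.transform(x[test]))
        acc = 100 * np.mean(pred == labels[test])
        assert rep.per_fold[0]["ACC"] == pytest.approx(acc)

    def test_metrics_on_percent_scale(self, rng):
        labels = np.array(["MCI"] * 10 + ["NC"] * 10)
        rep = cross_validate(rng.standard_normal((20, 2)), labels, seed=2)
        for metrics in rep.per_fold:
            for v in metrics.values():
                assert 0.0 <= v <= 100.0


@pytest.fixture(scope="module")
def fitted():
    from petpica.pica import PicaConfig, parallel_ica
    from petpica.simulate import SimConfig, synthesize_dataset
    cfg = SimConfig(grid_dims=(14, 16, 14), n_subjects_per_group=(20, 20),
                    n_components=4, coupled_pair=(0, 2),
                    group_effect_components={"tau": (1,), "abeta": (3,)},
                    group_effect_size=1.2, seed=13)
    tau, abeta, truth = synthesize_dataset(cfg)
    res = parallel_ica(tau, abeta, PicaConfig(n_components=4, seed=13))
    return cfg, tau, abeta, truth, res


class TestConditions:

    def test_all_concatenates_both_modalities(self, fitted):
        cfg, tau, abeta, truth, res = fitted
        labels = truth.group_labels
        ft_tau = build_condition_features(tau, abeta, res, labels, "Tau")
        ft_ab = build_condition_features(tau, abeta, res, labels, "Abeta")
        ft_all = build_condition_features(tau, abeta, res, labels, "All")
        assert ft_all.values.shape[1] == (ft_tau.values.shape[1]
                                          + ft_ab.values.shape[1])
        assert all(n.startswith(("tau_", "abeta_"))
                   for n in ft_all.feature_names)

    def test_non_condition_shape(self, fitted):
        cfg, tau, abeta, truth, res = fitted
        ft = build_condition_features(tau, abeta, res, truth.group_labels,
                                      "Non")
        assert ft.values.shape[1] == 7  # 2 global means + 5 PCA scores
        assert ft.condition == "Non"

    def test_refit_protocol_runs_and_flags_itself(self, fitted):
        from petpica.pica import PicaConfig
        cfg, tau, abeta, truth, res = fitted
        pc = PicaConfig(n_components=4, seed=13, max_iterations=200)
        rep = cross_validate_pipeline(tau, abeta, truth.group_labels, pc,
                                      condition="Tau", seed=13)
        assert rep.protocol == "refit"
        assert len(rep.per_fold) == 5
        assert rep.means["ACC"] > 50.0
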