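import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petpica.errors import ConfigError, NumericalError, PairingError
from petpica.stats import (bh_fdr, chi2_2x2, cohort_table, covariate_check,
                           crossmodal_correlations, loading_group_test,
                           mann_whitney, threshold_map, ttest_from_summary,
                           voxelwise_group_test, zscore_map)
from petpica.types import VoxelMatrix


def bh_oracle(pvals, alpha):
    """Exhaustive step-up rule: largest i with p_(i) <= i*alpha/m."""
    p = np.asarray(pvals)
    order = np.argsort(p)
    m = len(p)
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            k = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestZscore:
    def test_three_point_symmetric_case(self):
        assert zscore_map([1.0, 2.0, 3.0]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_input(self, rng):
        x = rng.standard_normal(50)
        z = zscore_map(x)
        assert np.allclose(zscore_map(z), z, atol=1e-12)

    def test_output_moments(self, rng):
        z = zscore_map(rng.uniform(5, 9, size=200))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(NumericalError):
            zscore_map([2.0, 2.0, 2.0])


class TestThreshold:
    def test_enumeration(self):
        mask, count = threshold_map(np.array([3.0, 1.0, -2.6]), 2.5)
        assert mask.tolist() == [True, False, True]
        assert count == 2

    def test_boundary_is_strict(self):
        mask, count = threshold_map(np.array([2.5]), 2.5)
        assert count == 0

    def test_all_zero_map_empty(self):
        _, count = threshold_map(np.zeros(10), 2.5)
        assert count == 0

    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_affine_rescaling(self, a, b):
        rng = np.random.default_rng(99)
        s = rng.standard_normal(200)
        m1, _ = threshold_map(zscore_map(s), 2.5)
        m2, _ = threshold_map(zscore_map(a * s + b), 2.5)
        assert np.array_equal(m1, m2)


class TestLoadingGroupTest:
    def test_identical_groups_give_null_result(self):
        col = np.tile(np.arange(10.0), 2)[:, None]
        labels = np.array(["MCI"] * 10 + ["NC"] * 10)
        (res,) = loading_group_test(col, labels)
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert not res.significant

    def test_strong_separation_is_significant(self, rng):
        col = np.concatenate([rng.normal(0, 0.1, 50),
                              rng.normal(1, 0.1, 50)])[:, None]
        labels = np.array(["MCI"] * 50 + ["NC"] * 50)
        (res,) = loading_group_test(col, labels)
        assert res.p < 1e-10

    def test_null_rejection_rate_calibrated(self, rng):
        a = rng.standard_normal((100, 1000))
        labels = np.array(["MCI"] * 46 + ["NC"] * 54)
        tests = loading_group_test(a, labels)
        frac = np.mean([t.p < 0.05 for t in tests])
        assert 0.036 <= frac <= 0.064  # binomial 95% band at m = 1000


class TestVoxelwise:
    def make_matrix(self, values):
        mask = np.ones((values.shape[1], 1, 1), dtype=bool)
        return VoxelMatrix(values=values, mask=mask, affine=np.eye(4),
                           subject_ids=[f"s{i}" for i in range(len(values))])

    def test_injected_shift_detected(self, rng):
        vals = rng.standard_normal((140, 20))
        labels = np.array(["MCI"] * 65 + ["NC"] * 75)
        vals[labels == "MCI", 7] += 2.0  # d = 2 at n = 140
        _, p = voxelwise_group_test(self.make_matrix(vals), labels)
        assert p[7] < 1e-6

    def test_constant_voxel_flagged_nan(self, rng):
        vals = rng.standard_normal((20, 5))
        vals[:, 2] = 4.0
        labels = np.array(["MCI"] * 10 + ["NC"] * 10)
        t, p = voxelwise_group_test(self.make_matrix(vals), labels)
        assert np.isnan(t[2]) and np.isnan(p[2])
        assert np.all(np.isfinite(np.delete(t, 2)))

    def test_permuted_labels_consistent_with_null(self, rng):
        vals = rng.standard_normal((30, 60))
        labels = np.array(["MCI"] * 15 + ["NC"] * 15)
        perm_labels = rng.permutation(labels)
        t_obs, _ = voxelwise_group_test(self.make_matrix(vals), perm_labels)
        max_obs = np.nanmax(np.abs(t_obs))
        null_max = []
        for _ in range(200):
            t_null, _ = voxelwise_group_test(self.make_matrix(vals),
                                             rng.permutation(labels))
            null_max.append(np.nanmax(np.abs(t_null)))
        p_of_max = np.mean(np.asarray(null_max) >= max_obs)
        assert p_of_max > 0.01  # not an outlier of its own null distribution


class TestBhFdr:
    def test_uniform_identical_p(self):
        q, reject = bh_fdr(np.full(10, 0.01), alpha=0.05)
        assert np.allclose(q, 0.01)
        assert reject.all()

    def test_matches_exhaustive_step_up_oracle(self, rng):
        cases = [np.array([0.01, 0.02, 0.03, 0.5])]
        cases += [rng.uniform(size=rng.integers(3, 40)) for _ in range(50)]
        for p in cases:
            _, reject = bh_fdr(p, alpha=0.05)
            assert np.array_equal(reject, bh_oracle(p, 0.05))

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ConfigError):
            bh_fdr(np.array([0.2, 1.3]))

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_q_at_least_p_and_bonferroni_subset(self, pvals):
        p = np.asarray(pvals)
        q, reject = bh_fdr(p, alpha=0.05)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        bonferroni = p < 0.05 / len(p)
        assert np.all(reject[bonferroni] | (q[bonferroni] >= 0.05))


class TestCrossmodal:
    def test_self_correlation_is_one(self, rng):
        a = rng.standard_normal((30, 1))
        (rec,) = crossmodal_correlations(a, a.copy())
        assert rec.r == pytest.approx(1.0)

    def test_all_pairs_reported_with_q_above_p(self, rng):
        a1 = rng.standard_normal((140, 8))
        a2 = rng.standard_normal((140, 8))
        recs = crossmodal_correlations(a1, a2)
        assert len(recs) == 64
        assert all(rec.q >= rec.p - 1e-12 for rec in recs)
        assert all(abs(rec.r) <= 1 for rec in recs)

    def test_subject_mismatch_rejected(self, rng):
        with pytest.raises(PairingError):
            crossmodal_correlations(rng.standard_normal((10, 2)),
                                    rng.standard_normal((12, 2)))


class TestCovariates:
    def test_loadings_equal_to_age_give_r_one(self, rng):
        age = rng.uniform(60, 90, size=40)
        sex = np.array(["M", "F"] * 20)
        table = covariate_check(age[:, None], age, sex)
        assert table.loc[0, "age_r"] == pytest.approx(1.0)

    def test_residualized_loadings_orthogonal_to_age(self, rng):
        age = rng.uniform(60, 90, size=60)
        sex = np.array(["M", "F"] * 30)
        loadings = rng.standard_normal((60, 3)) + 0.05 * age[:, None]
        table = covariate_check(loadings, age, sex, residualize=True)
        resid = table.attrs["residualized_loadings"]
        for c in range(3):
            assert abs(np.corrcoef(resid[:, c], age)[0, 1]) < 1e-10

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ConfigError):
            covariate_check(rng.standard_normal((10, 2)),
                            np.full(10, 70.0), np.array(["M", "F"] * 5))


class TestCohort:
    def test_mmse_summary_comparison_is_highly_significant(self):
        t, p = ttest_from_summary(25.7, 2.3, 65, 27.9, 1.7, 75)
        assert p < 0.001
        assert t < 0

    def test_identical_groups_are_null_everywhere(self):
        half = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(20)],
            "group": ["MCI"] * 10 + ["NC"] * 10,
            "age": list(range(60, 70)) * 2,
            "sex": ["M", "F"] * 10,
            "apoe4": [0, 1] * 10,
            "mmse": list(range(20, 30)) * 2,
            "cdr": [0.5, 0.0] * 10,
        })
        table = cohort_table(half).set_index("variable")
        assert table.loc["age", "statistic"] == pytest.approx(0.0)
        assert table.loc["age", "p"] == pytest.approx(1.0)
        assert table.loc["sex", "statistic"] == pytest.approx(0.0)
        assert table.loc["sex", "p"] == pytest.approx(1.0)

    def test_chi_square_closed_form(self):
        a, b, c, d = 32, 33, 33, 42
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        chi2, _ = chi2_2x2(np.array([[a, b], [c, d]]))
        assert chi2 == pytest.approx(expected)

    def test_missing_column_rejected(self):
        with pytest.raises(ConfigError, match="cdr"):
            cohort_table(pd.DataFrame({"subject_id": [], "group": [],
                                       "age": [], "sex": [], "apoe4": [],
                                       "mmse": []}))

    def test_mann_whitney_detects_ordinal_shift(self, rng):
        x = rng.choice([0.5, 1.0], size=40)
        y = np.zeros(40)
        _, p = mann_whitney(x, y)
        assert p < 1e-6
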