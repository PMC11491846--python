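"""Scaling, fold arithmetic, nested CV, retest and accuracy statistics."""

import numpy as np
import pytest
from scipy import stats

from cravedecode import classify
from cravedecode.classify import (
    Contrast,
    CvScheme,
    compare_cells,
    make_folds,
    minmax_apply,
    minmax_fit,
    minmax_fit_per_voxel,
    nested_cv,
    retest,
    run_pair_contrasts,
    trend_regression,
)
from cravedecode.online_nf import ClassifierModel


class TestMinMax:
    def test_global_scaling(self):
        X = np.array([[0.0, 5.0], [10.0, 5.0]])
        sc = minmax_fit(X)
        np.testing.assert_allclose(
            minmax_apply(np.array([0.0, 5.0, 10.0]), sc), [0, 0.5, 1]
        )

    def test_out_of_range_test_values_allowed(self):
        sc = minmax_fit(np.array([[0.0, 10.0]]))
        assert minmax_apply(np.array(12.0), sc) == pytest.approx(1.2)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            minmax_fit(np.full((3, 3), 2.0))

    def test_per_voxel_variant_matches_rowwise_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((6, 2))
        lo, hi = minmax_fit_per_voxel(X)
        for j in range(2):
            assert lo[j] == X[:, j].min() and hi[j] == X[:, j].max()


class TestMakeFolds:
    def test_individual_level_counts(self):
        split = make_folds(144, 10, np.random.default_rng(0))
        assert len(split.test) == 15 and len(split.validation) == 15
        assert len(split.train) == 114

    def test_group_level_counts(self):
        split = make_folds(31, 10, np.random.default_rng(0))
        assert len(split.test) == 4 and len(split.validation) == 3
        assert len(split.train) == 24

    def test_singleton_folds(self):
        split = make_folds(10, 10, np.random.default_rng(0))
        assert len(split.test) == len(split.validation) == 1
        assert len(split.train) == 8

    @pytest.mark.parametrize("n", [31, 100, 144])
    def test_folds_partition_samples(self, n):
        split = make_folds(n, 10, np.random.default_rng(1))
        joined = np.concatenate([split.train, split.validation, split.test])
        assert sorted(joined) == list(range(n))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            make_folds(5, 10)


def _separable_toy(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 4))
    y = np.where(X[:, 0] > 0, 1, -1)
    X[:, 0] += y * 2.0  # wide margin
    return X, y


class TestNestedCv:
    def test_separable_data_perfect_every_repeat(self):
        X, y = _separable_toy()
        res = nested_cv(X, y, CvScheme(n_folds=5, n_repeats=5, seed=0))
        assert np.all(res.test_acc == 100.0)

    def test_permuted_labels_at_chance(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((60, 8))
        y = np.array([1, -1] * 30)
        res = nested_cv(X, y, CvScheme(n_folds=5, n_repeats=20, seed=1))
        # mean of 20 test folds of 12 samples; binomial-ish CI around 50%
        assert 30.0 < res.mean < 70.0

    def test_nu_grid_degenerate_imbalance(self):
        """With 2 positives in 20 samples only nu = 0.1 is feasible."""
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 3))
        y = np.array([1, 1] + [-1] * 18)
        X[y == 1] += 4.0
        res = nested_cv(X, y, CvScheme(n_folds=4, n_repeats=3, seed=0))
        assert all(nu == pytest.approx(0.1) for nu in res.chosen)

    def test_deterministic_single_repeat(self):
        X, y = _separable_toy(seed=3)
        a = nested_cv(X, y, CvScheme(5, 1, 42))
        b = nested_cv(X, y, CvScheme(5, 1, 42))
        assert np.array_equal(a.test_acc, b.test_acc)
        np.testing.assert_array_equal(a.model.weights, b.model.weights)

    def test_c_and_nu_svm_agree_on_separable_toys(self):
        """nu-C correspondence: both parameterizations find the same sign
        pattern on separable data."""
        for seed in range(3):
            X, y = _separable_toy(seed=seed)
            rn = nested_cv(X, y, CvScheme(5, 2, seed), "nu_svm")
            rc = nested_cv(X, y, CvScheme(5, 2, seed), "c_svm")
            dn = minmax_apply(X, rn.model.scaling) @ rn.model.weights + rn.model.bias
            dc = minmax_apply(X, rc.model.scaling) @ rc.model.weights + rc.model.bias
            assert np.all(np.sign(dn) == np.sign(dc))

    def test_label_symmetry(self):
        X, y = _separable_toy(seed=7)
        a = nested_cv(X, y, CvScheme(5, 3, 0))
        b = nested_cv(X, -y, CvScheme(5, 3, 0))
        np.testing.assert_allclose(a.test_acc, b.test_acc)

    def test_scaling_fitted_on_training_folds_only(self):
        """Perturbing values that only ever sit in validation/test folds of a
        fixed split must not change the training-fold scaling."""
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 1, (20, 3))
        split = make_folds(20, 5, np.random.default_rng(0))
        sc1 = minmax_fit(X[split.train])
        X2 = X.copy()
        X2[split.test] *= 100.0
        sc2 = minmax_fit(X2[split.train])
        assert sc1 == sc2


class TestRetest:
    def test_retest_on_training_data_matches_direct_accuracy(self):
        X, y = _separable_toy(seed=9)
        res = nested_cv(X, y, CvScheme(5, 2, 0))
        acc = retest(res.model, X, y)
        d = minmax_apply(X, res.model.scaling) @ res.model.weights + res.model.bias
        direct = 100.0 * float((np.where(d > 0, 1, -1) == y).mean())
        assert acc == pytest.approx(direct)

    def test_orthogonal_pattern_transfer_at_chance(self):
        """A decoder trained on one pattern is at chance on data generated
        from an orthogonal pattern."""
        rng = np.random.default_rng(10)
        p = 50
        w1 = rng.standard_normal(p)
        w2 = rng.standard_normal(p)
        w2 -= w2 @ w1 / (w1 @ w1) * w1  # orthogonalize
        y = np.array([1, -1] * 40)
        X1 = np.outer(y, w1) + 0.5 * rng.standard_normal((80, p))
        X2 = np.outer(y, w2) + 0.5 * rng.standard_normal((80, p))
        res = nested_cv(X1, y, CvScheme(5, 2, 0))
        assert retest(res.model, X1, y) > 90.0
        assert 30.0 < retest(res.model, X2, y) < 70.0

    def test_dimension_mismatch(self):
        m = ClassifierModel(weights=np.ones(3), bias=0.0, hyperparams={})
        with pytest.raises(ValueError):
            retest(m, np.ones((4, 5)), np.ones(4))


class TestContrasts:
    def test_nine_run_pair_contrasts(self):
        cs = run_pair_contrasts()
        assert len(cs) == 9
        assert len({c.name for c in cs}) == 9
        assert all(c.mask_policy == "exclude_visual" for c in cs)

    def test_run_pair_forces_visual_exclusion(self):
        c = Contrast("run_pair", (0, 1), "collapsed", "whole_brain")
        assert c.mask_policy == "exclude_visual"

    def test_condition_contrast_keeps_whole_brain(self):
        c = Contrast("condition", (0,), "collapsed", "whole_brain")
        assert c.mask_policy == "whole_brain"


class TestAccuracyStatistics:
    def test_identical_vectors_give_null_result(self):
        a = np.array([80.0, 85.0, 90.0])
        out = compare_cells(a, a.copy(), paired=True, bonferroni_n=31)
        assert out["t"] == 0.0 and out["p_corrected"] == 1.0

    def test_two_sample_t_matches_pooled_formula_oracle(self):
        a = np.array([80.0, 82.0, 84.0])
        b = np.array([70.0, 72.0, 74.0])
        # pooled: sp^2 = 4, se = 2*sqrt(2/3), t = 10/se
        t_oracle = 10.0 / (2.0 * np.sqrt(2.0 / 3.0))
        out = compare_cells(a, b, paired=False, bonferroni_n=100)
        assert out["t"] == pytest.approx(t_oracle, abs=1e-10)
        assert out["df"] == 4

    def test_trend_regression_p_shrinks_with_noise(self):
        clean = [np.full(10, 70.0), np.full(10, 80.0), np.full(10, 90.0)]
        noisy = [v + np.random.default_rng(i).normal(0, 15, 10) for i, v in enumerate(clean)]
        p_clean = trend_regression(clean)["p_raw"]
        p_noisy = trend_regression(noisy)["p_raw"]
        assert p_clean < 1e-20
        assert p_clean < p_noisy

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            compare_cells(np.ones(2), np.ones(2), paired=True, bonferroni_n=1)


class TestMotionCheck:
    def test_identical_fd_null(self):
        import pandas as pd

        fd = pd.DataFrame({"fd_crave": [0.1, 0.2, 0.3, 0.4],
                           "fd_nocrave": [0.1, 0.2, 0.3, 0.4]})
        out = classify.motion_check(fd, np.array([90, 85, 88, 92.0]))
        assert out["paired_t"]["t"] == 0.0
        assert out["paired_t"]["p_corrected"] == 1.0

    def test_null_fd_slope_p_uniform(self):
        """When FD and accuracy are independent the regression p-value is
        uniform across simulated cohorts."""
        import pandas as pd

        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            fd = pd.DataFrame({
                "fd_crave": rng.uniform(0.05, 0.3, 20),
                "fd_nocrave": rng.uniform(0.05, 0.3, 20),
            })
            acc = rng.normal(85, 5, 20)
            ps.append(classify.motion_check(fd, acc)["regression"]["p_raw"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_strong_coupling_detected(self):
        import pandas as pd

        rng = np.random.default_rng(1)
        hits = 0
        for seed in range(10):
            r2 = np.random.default_rng(seed)
            diff = r2.standard_normal(31)
            acc = 85 + 5 * (0.9 * (diff - diff.mean()) / diff.std()
                            + np.sqrt(1 - 0.81) * r2.standard_normal(31))
            fd = pd.DataFrame({"fd_crave": 0.2 + 0.05 * diff, "fd_nocrave": np.full(31, 0.2)})
            out = classify.motion_check(fd, acc, bonferroni_n=31)
            hits += out["regression"]["p_corrected"] < 0.05
        assert hits >= 9
        del rng


class TestCohortContrasts:
    def test_individual_and_group_tables(self, small_cohort):
        contrast = [Contrast("condition", (1,), "collapsed", "whole_brain")]
        t_ind = classify.run_contrasts(
            small_cohort, contrast, "individual", CvScheme(10, 2, 0), thin=3
        )
        t_grp = classify.run_contrasts(
            small_cohort, contrast, "group", CvScheme(4, 6, 0)
        )
        ind = t_ind.cell(contrast[0].name, "individual")
        grp = t_grp.cell(contrast[0].name, "group")
        assert len(ind.values) == small_cohort.n_subjects
        assert len(grp.values) == 6
        assert 0 <= grp.mean <= 100
        assert ind.mean > 60.0  # default conditions decode well
        frame = t_ind.to_frame()
        assert set(frame.phase) == {"train", "test"}

    def test_run_pair_contrast_individual(self, small_cohort):
        contrast = [Contrast("run_pair", (0, 1), "collapsed")]
        t = classify.run_contrasts(
            small_cohort, contrast, "individual", CvScheme(10, 2, 0), thin=3
        )
        cell = t.cell(contrast[0].name, "individual")
        # distinguishing two different runs of the same subject is easy when
        # patterns and amplitudes drift between runs
        assert cell.mean > 50.0
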