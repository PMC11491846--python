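"""Signal-conditioning stages against hand and closed-form oracles."""

import numpy as np
import pytest

from cravedecode import preprocess, synth
from cravedecode.synth import CRAVE, NOCRAVE


class TestTemporalSmooth:
    def test_constant_series_invariant(self):
        x = np.full(20, 3.7)
        np.testing.assert_allclose(preprocess.temporal_smooth(x), x)

    def test_interior_impulse_spreads_one_third(self):
        x = np.zeros(11)
        x[5] = 1.0
        sm = preprocess.temporal_smooth(x)
        np.testing.assert_allclose(sm[4:7], [1 / 3] * 3, atol=1e-12)
        assert sm[3] == 0 and sm[7] == 0

    def test_window_one_is_identity(self):
        x = np.random.default_rng(0).standard_normal(15)
        np.testing.assert_array_equal(preprocess.temporal_smooth(x, 1), x)

    def test_edges_renormalized(self):
        x = np.ones(6)
        sm = preprocess.temporal_smooth(x)
        np.testing.assert_allclose(sm, 1.0)  # truncated window, not attenuated

    def test_window_errors(self):
        with pytest.raises(ValueError):
            preprocess.temporal_smooth(np.ones(5), 2)
        with pytest.raises(preprocess.PreprocessError):
            preprocess.temporal_smooth(np.ones(3), 5)


class TestDetrend:
    def test_exact_ramp_removed(self):
        x = np.linspace(3.0, 9.0, 30)
        assert np.max(np.abs(preprocess.detrend(x))) < 1e-10

    def test_order_zero_is_centering(self):
        x = np.random.default_rng(1).standard_normal(12) + 5
        np.testing.assert_allclose(preprocess.detrend(x, 0), x - x.mean(), atol=1e-12)

    def test_signal_survives_detrending(self):
        """Residual correlation with the HRF regressor matches the
        closed-form partial correlation (linear trend projected out)."""
        d = synth.make_run_design("no_feedback", 2.0, 2)
        reg = synth.hrf_regressor(d, (CRAVE,))
        t = np.linspace(-1, 1, d.n_volumes)
        x = 4.0 * t + reg
        resid = preprocess.detrend(x)
        # oracle: project regressor on [1, t] and correlate residuals
        basis = np.column_stack([np.ones_like(t), t])
        proj = basis @ np.linalg.lstsq(basis, reg, rcond=None)[0]
        oracle = np.corrcoef(reg - proj, resid)[0, 1]
        assert oracle == pytest.approx(1.0, abs=1e-8)
        r = np.corrcoef(resid, reg)[0, 1]
        partial = np.corrcoef(reg - proj, reg)[0, 1]
        assert abs(r - partial) < 0.05


class TestComputePsc:
    def test_hand_example(self):
        data = np.array([[100.0, 100.0, 110.0, 110.0]])
        d = synth.ExperimentDesign(
            "no_feedback", 2.0, (synth.Block(CRAVE, 4.0, 4.0),), 8.0, 4
        )
        reg = np.array([-0.1, -0.2, 0.5, 0.6])
        psc = preprocess.compute_psc(data, d, task_regressor=reg)
        assert psc.baseline[0] == pytest.approx(100.0)
        np.testing.assert_allclose(psc.data[0], [0.0, 0.0, 10.0, 10.0], atol=1e-12)

    def test_all_rest_regressor_uses_global_mean(self):
        data = np.array([[10.0, 20.0, 30.0]])
        d = synth.ExperimentDesign(
            "no_feedback", 2.0, (synth.Block(CRAVE, 0.0, 6.0),), 6.0, 3
        )
        psc = preprocess.compute_psc(data, d, task_regressor=np.array([-1.0, -0.5, -0.1]))
        expected = 100 * (data[0] - 20.0) / 20.0
        np.testing.assert_allclose(psc.data[0], expected, atol=1e-12)

    def test_constant_series_is_zero(self):
        data = np.full((2, 5), 50.0)
        psc = preprocess.compute_psc(
            data, None, task_regressor=np.array([-1, -1, 1, 1, 1.0])
        )
        np.testing.assert_allclose(psc.data, 0.0, atol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        data = 100 + rng.standard_normal((3, 20))
        reg = np.where(np.arange(20) < 8, -0.5, 0.8)
        a = preprocess.compute_psc(data, None, task_regressor=reg)
        b = preprocess.compute_psc(7.3 * data, None, task_regressor=reg)
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)

    def test_error_paths(self):
        with pytest.raises(preprocess.PreprocessError):
            preprocess.compute_psc(
                np.ones((1, 3)), None, task_regressor=np.array([0.1, 0.2, 0.3])
            )
        psc = preprocess.compute_psc(
            np.array([[-5.0, -5.0, 1.0]]), None,
            task_regressor=np.array([-1.0, -0.5, 1.0]),
        )
        assert not psc.mask[0]  # non-positive baseline flagged out


class TestGlmBetas:
    def test_noiseless_amplitude_recovery(self, designs):
        d = designs[0]
        rng = np.random.default_rng(4)
        amps = []
        cols = []
        for b in d.blocks:
            if b.condition not in (CRAVE, NOCRAVE):
                continue
            single = synth.ExperimentDesign(
                d.run_type, d.tr, (b,), d.total_duration, d.n_volumes
            )
            cols.append(synth.hrf_regressor(single, (b.condition,)))
            amps.append(rng.uniform(0.5, 2.0))
        data = (np.array(amps) @ np.array(cols))[None, :]
        bm = preprocess.glm_betas(data, d)
        np.testing.assert_allclose(bm.block_betas[0], amps, rtol=1e-6)

    def test_single_block_matches_normal_equations(self):
        """Tiny GLM against an explicit 2x2 normal-equation solve."""
        block = synth.Block(CRAVE, 2.0, 4.0)
        d = synth.ExperimentDesign("no_feedback", 2.0, (block,), 8.0, 4)
        reg = synth.hrf_regressor(d, (CRAVE,))
        y = np.array([0.3, 1.1, 2.0, 1.4])
        bm = preprocess.glm_betas(y[None, :], d, include_nuisance=False)
        # oracle for the intercept-free single-regressor design
        beta_oracle = float(reg @ y / (reg @ reg))
        assert bm.block_betas[0, 0] == pytest.approx(beta_oracle, abs=1e-10)

    def test_rank_deficient_design_raises(self):
        b = synth.Block(CRAVE, 2.0, 4.0)
        d = synth.ExperimentDesign("no_feedback", 2.0, (b, b), 8.0, 4)
        with pytest.raises(preprocess.PreprocessError, match="collinear"):
            preprocess.glm_betas(np.ones((1, 4)), d)

    def test_null_data_t_rejection_rate(self, designs):
        """On pure noise the condition-level t follows a central t: the
        alpha=0.05 rejection rate over 1000 voxels stays in its binomial CI."""
        d = designs[0]
        rng = np.random.default_rng(11)
        data = rng.standard_normal((1000, d.n_volumes))
        bm = preprocess.glm_betas(data, d)
        from scipy import stats

        crit = stats.t.ppf(0.975, bm.dof)
        rate = float((np.abs(bm.condition_t[CRAVE]) > crit).mean())
        # binomial 95% CI around 0.05 with n=1000 (voxels independent here)
        assert 0.03 < rate < 0.07


class TestAutomask:
    def test_bright_object_recovered_exactly(self):
        grid = (6, 6, 5)
        truth = np.zeros(grid, bool)
        truth[1:5, 1:5, 1:4] = True
        data = np.where(truth.ravel()[:, None], 1000.0, 0.0) + 0.0 * np.ones((180, 8))
        mask = preprocess.automask(data, grid)
        np.testing.assert_array_equal(mask, truth.ravel())

    def test_flat_image_keeps_everything(self):
        mask = preprocess.automask(np.full((60, 4), 7.0), (5, 4, 3))
        assert mask.all()

    def test_largest_component_kept(self):
        grid = (10, 5, 5)
        vol = np.zeros(grid)
        vol[0:5, :, :2] = 1000.0  # 50 voxels
        vol[8:10, 0:2, 3:5] = 1000.0  # separate 8-voxel cluster
        big = vol >= 500
        from scipy import ndimage

        lab, n = ndimage.label(big)
        sizes = ndimage.sum_labels(big, lab, index=np.arange(1, n + 1))
        oracle = (lab == (np.argmax(sizes) + 1)).ravel()
        mask = preprocess.automask(vol.reshape(-1, 1), grid)
        np.testing.assert_array_equal(mask, oracle)


class TestExcludeRegions:
    def test_no_visual_voxels_leaves_mask(self, brain):
        mask, atlas = brain
        inner = mask & ~atlas.voxels("visual")
        np.testing.assert_array_equal(
            preprocess.exclude_regions(inner, atlas), inner
        )

    def test_all_visual_warns_empty(self, brain):
        _, atlas = brain
        only_visual = atlas.voxels("visual")
        with pytest.warns(UserWarning):
            out = preprocess.exclude_regions(only_visual, atlas)
        assert not out.any()

    def test_set_arithmetic(self, brain):
        mask, atlas = brain
        n_visual_in_mask = (mask & atlas.voxels("visual")).sum()
        out = preprocess.exclude_regions(mask, atlas)
        assert out.sum() == mask.sum() - n_visual_in_mask

    def test_unknown_label_raises(self, brain):
        mask, atlas = brain
        with pytest.raises(KeyError):
            preprocess.exclude_regions(mask, atlas, ("cerebellum",))


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        fd = preprocess.compute_fd(np.zeros((6, 10)))
        np.testing.assert_array_equal(fd.fd, 0.0)

    def test_translation_step(self):
        m = np.zeros((6, 5))
        m[0, 3:] = 1.0  # 1 mm x-translation step at frame 3
        fd = preprocess.compute_fd(m)
        np.testing.assert_allclose(fd.fd, [0, 0, 0, 1.0, 0])

    def test_rotation_step_arc_length(self):
        m = np.zeros((6, 4))
        m[4, 2:] = 0.02  # rad; x 50 mm radius -> 1 mm
        fd = preprocess.compute_fd(m)
        np.testing.assert_allclose(fd.fd, [0, 0, 1.0, 0], atol=1e-12)

    def test_offset_invariance(self):
        rng = np.random.default_rng(8)
        m = rng.standard_normal((6, 30)) * 0.1
        a = preprocess.compute_fd(m).fd
        b = preprocess.compute_fd(m + rng.standard_normal((6, 1))).fd
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_condition_means(self, designs):
        d = designs[0]
        m = np.zeros((6, d.n_volumes))
        m[0] = np.arange(d.n_volumes) * 0.01
        fd = preprocess.compute_fd(m, d)
        assert set(fd.condition_means) == {CRAVE, NOCRAVE}
        assert fd.condition_means[CRAVE] == pytest.approx(0.01, abs=1e-9)


class TestPipelineProperties:
    def test_smooth_detrend_commute_for_interior_signal(self):
        """Smoothing and detrending commute exactly when the signal vanishes
        near the run boundaries (constant offsets are preserved by the
        renormalized window and the trend fit is then identical)."""
        rng = np.random.default_rng(9)
        x = np.full(60, 5.0)
        x[10:50] += rng.standard_normal(40)
        a = preprocess.detrend(preprocess.temporal_smooth(x))
        b = preprocess.temporal_smooth(preprocess.detrend(x))
        np.testing.assert_allclose(a[2:-2], b[2:-2], atol=1e-10)

    def test_smooth_detrend_ramp_discrepancy_is_small(self):
        """With a linear ramp the truncated edge window biases the trend fit
        slightly; the order-of-operations discrepancy stays a small fitted-
        line difference, shrinking with series length."""
        t = np.linspace(-1, 1, 60)
        rng = np.random.default_rng(9)
        x = 3 * t + rng.standard_normal(60)
        a = preprocess.detrend(preprocess.temporal_smooth(x))
        b = preprocess.temporal_smooth(preprocess.detrend(x))
        assert np.max(np.abs(a[2:-2] - b[2:-2])) < 0.05
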