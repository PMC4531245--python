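"""Confound construction and the five cleanup variants."""

import numpy as np
import pytest

from rscleanbench.cleaning import (
    ConfoundMatrix,
    clean,
    expand_motion_24,
    extract_mean_timeseries,
    regress_out_full,
)
from rscleanbench.ica import ComponentDecomposition
from rscleanbench.preprocess import preprocess_subject, PreprocessConfig


def make_decomposition(timecourses, labels, grid=(4, 4, 3)):
    k = timecourses.shape[1]
    mask = np.ones(grid, dtype=bool)
    rng = np.random.default_rng(0)
    maps = rng.normal(size=(k,) + grid)
    return ComponentDecomposition(
        spatial_maps=maps,
        timecourses=timecourses,
        explained_variance=np.full(k, 1.0 / k),
        mask=mask,
        temporal_mean=np.zeros(grid),
        spatial_mean_tc=np.zeros(timecourses.shape[0]),
        labels=list(labels),
    )


class TestExpandMotion24:
    def test_zero_motion_gives_zero_matrix(self):
        out = expand_motion_24(np.zeros((10, 6)))
        assert out.values.shape == (10, 24)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_shape_and_names(self, rng):
        out = expand_motion_24(rng.normal(size=(25, 6)))
        assert out.values.shape == (25, 24)
        assert len(out.column_names) == 24
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-12)

    def test_hand_computed_columns(self):
        motion = np.zeros((3, 6))
        motion[:, 0] = [1.0, 2.0, 4.0]
        X = expand_motion_24(motion).values
        # columns are demeaned; add the means back to compare with raw values
        np.testing.assert_allclose(X[:, 0] + np.mean([1, 2, 4]), [1, 2, 4], atol=1e-12)
        np.testing.assert_allclose(X[:, 6] + np.mean([0, 1, 2]), [0, 1, 2], atol=1e-12)
        np.testing.assert_allclose(X[:, 12] + np.mean([1, 4, 16]), [1, 4, 16], atol=1e-12)
        np.testing.assert_allclose(X[:, 18] + np.mean([0, 1, 4]), [0, 1, 4], atol=1e-12)

    def test_wrong_column_count(self):
        with pytest.raises(ValueError):
            expand_motion_24(np.zeros((10, 5)))


class TestExtractMeanTimeseries:
    def test_single_voxel(self, rng):
        data = rng.normal(size=(3, 3, 2, 20))
        mask = np.zeros((3, 3, 2), dtype=bool)
        mask[1, 2, 0] = True
        np.testing.assert_array_equal(extract_mean_timeseries(data, mask), data[1, 2, 0])

    def test_opposite_series_cancel(self):
        data = np.zeros((2, 1, 1, 15))
        s = np.sin(np.arange(15.0))
        data[0, 0, 0] = s
        data[1, 0, 0] = -s
        mask = np.ones((2, 1, 1), dtype=bool)
        np.testing.assert_allclose(extract_mean_timeseries(data, mask), 0.0, atol=1e-14)

    def test_two_voxel_average(self, rng):
        data = rng.normal(size=(4, 4, 2, 12))
        mask = np.zeros((4, 4, 2), dtype=bool)
        mask[0, 1, 0] = mask[3, 2, 1] = True
        expected = (data[0, 1, 0] + data[3, 2, 1]) / 2.0
        np.testing.assert_allclose(extract_mean_timeseries(data, mask), expected, atol=1e-12)

    def test_empty_mask(self, rng):
        with pytest.raises(ValueError):
            extract_mean_timeseries(np.zeros((2, 2, 2, 5)), np.zeros((2, 2, 2), dtype=bool))


class TestRegressOutFull:
    def test_empty_design_is_identity(self, rng):
        data = rng.normal(size=(3, 3, 2, 20))
        np.testing.assert_array_equal(regress_out_full(data, np.zeros((20, 0))), data)

    def test_confound_plus_constant_leaves_constant(self, rng):
        T = 30
        x = rng.normal(size=T)
        data = np.tile(5.0 + 2.0 * x, (2, 2, 1, 1)).reshape(2, 2, 1, T)
        X = ConfoundMatrix((x - x.mean())[:, None], ["x"])
        out = regress_out_full(data, X)
        np.testing.assert_allclose(out, 5.0 + 2.0 * x.mean(), atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        T = 40
        X = rng.normal(size=(T, 3))
        y = rng.normal(size=T)
        Xd = X - X.mean(axis=0)
        yd = y - y.mean()
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ yd)
        expected = yd - Xd @ beta + y.mean()
        out = regress_out_full(y.reshape(1, 1, 1, T), Xd)
        np.testing.assert_allclose(out.ravel(), expected, atol=1e-10)

    def test_residual_orthogonal_to_design(self, rng):
        data = rng.normal(size=(4, 3, 2, 35))
        X = rng.normal(size=(35, 4))
        out = regress_out_full(data, X)
        resid = out.reshape(-1, 35)
        resid = resid - resid.mean(axis=1, keepdims=True)
        Xd = X - X.mean(axis=0)
        assert np.abs(resid @ Xd).max() < 1e-8

    def test_time_mismatch(self, rng):
        with pytest.raises(ValueError):
            regress_out_full(rng.normal(size=(2, 2, 2, 10)), rng.normal(size=(12, 2)))


class TestCleanModes:
    def _data(self, rng, T=40, grid=(4, 4, 3)):
        return rng.normal(size=grid + (T,)) + 100.0

    def test_none_is_identity(self, rng):
        data = self._data(rng)
        out = clean(data, np.zeros((40, 6)), None, None, "none")
        np.testing.assert_array_equal(out, data)

    def test_comp_modes_require_labeled_decomposition(self, rng):
        data = self._data(rng)
        with pytest.raises(ValueError):
            clean(data, rng.normal(size=(40, 6)), None, None, "compsoft")
        dec = make_decomposition(rng.normal(size=(40, 2)), ["noise", "signal"])
        dec.labels = None
        with pytest.raises(ValueError):
            clean(data, rng.normal(size=(40, 6)), None, dec, "compagg")

    def test_soft_without_noise_labels_equals_motreg(self, rng):
        data = self._data(rng)
        motion = rng.normal(size=(40, 6)) * 0.1
        dec = make_decomposition(rng.normal(size=(40, 3)), ["signal", "signal", "unlabeled"])
        soft = clean(data, motion, None, dec, "compsoft")
        motreg = clean(data, motion, None, dec, "motreg")
        np.testing.assert_allclose(soft, motreg, atol=1e-9)

    def test_aggressive_residual_orthogonality(self, rng):
        data = self._data(rng)
        motion = rng.normal(size=(40, 6)) * 0.1
        tcs = rng.normal(size=(40, 3))
        dec = make_decomposition(tcs, ["noise", "signal", "noise"])
        out = clean(data, motion, None, dec, "compagg")
        resid = out.reshape(-1, 40)
        resid = resid - resid.mean(axis=1, keepdims=True)
        M = expand_motion_24(motion).values
        noise = tcs[:, [0, 2]] - tcs[:, [0, 2]].mean(axis=0)
        assert np.abs(resid @ M).max() < 1e-7
        assert np.abs(resid @ noise).max() < 1e-7

    def test_soft_equals_aggressive_for_orthogonal_components(self, rng):
        T = 60
        data = self._data(rng, T=T)
        motion = np.zeros((T, 6))
        X = rng.normal(size=(T, 4))
        X = X - X.mean(axis=0)
        Q, _ = np.linalg.qr(X)  # orthonormal, zero-mean columns
        dec = make_decomposition(Q, ["signal", "noise", "signal", "noise"])
        soft = clean(data, motion, None, dec, "compsoft")
        agg = clean(data, motion, None, dec, "compagg")
        np.testing.assert_allclose(soft, agg, atol=1e-8)

    def test_cleanup_idempotent(self, rng, small_cohort):
        # motreg and the component modes reuse fixed regressors, so a second
        # pass is a no-op; mwcreg re-derives WM/CSF means from its own output
        # and is deliberately excluded
        cfg, cohort, truth = small_cohort
        subj = cohort.subjects[0]
        pre = preprocess_subject(subj.data, PreprocessConfig(), cfg.voxel_size_mm, cfg.tr_s)
        once = clean(pre, subj.motion6, cohort.masks, None, "motreg")
        twice = clean(once, subj.motion6, cohort.masks, None, "motreg")
        np.testing.assert_allclose(once, twice, atol=1e-8)
        tcs = rng.normal(size=(cfg.n_volumes, 3))
        dec = make_decomposition(tcs, ["noise", "signal", "noise"])
        once = clean(pre, subj.motion6, cohort.masks, dec, "compagg")
        twice = clean(once, subj.motion6, cohort.masks, dec, "compagg")
        np.testing.assert_allclose(once, twice, atol=1e-8)

    def test_nested_designs_reduce_variance(self, rng, small_cohort):
        cfg, cohort, truth = small_cohort
        subj = cohort.subjects[1]
        pre = preprocess_subject(subj.data, PreprocessConfig(), cfg.voxel_size_mm, cfg.tr_s)
        v_none = pre.var(axis=-1, ddof=1)
        v_mot = clean(pre, subj.motion6, cohort.masks, None, "motreg").var(axis=-1, ddof=1)
        v_mwc = clean(pre, subj.motion6, cohort.masks, None, "mwcreg").var(axis=-1, ddof=1)
        tol = 1e-8 * v_none.max()
        assert np.all(v_none >= v_mot - tol)
        assert np.all(v_mot >= v_mwc - tol)
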