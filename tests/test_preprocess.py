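"""Temporal preprocessing: volume dropping, FD/QC, nuisance regression,
band-pass filtering and mask-renormalized smoothing."""

import numpy as np
import pandas as pd
import pytest

from lifespan_localfc import (
    LocalFCMap,
    MotionTrace,
    bandpass,
    build_nuisance,
    drop_initial_volumes,
    exclude_by_fd,
    mean_fd,
    regress_nuisance,
    smooth,
)
from lifespan_localfc.preprocess import (
    EmptySeriesError,
    InvalidBandError,
    NuisanceSet,
    framewise_displacement,
)

from conftest import make_series


class TestDropInitialVolumes:
    def test_drops_from_both_data_and_motion(self, rng, zero_motion):
        v = make_series(rng.standard_normal((4, 4, 4, 261)))
        m = MotionTrace(rng.standard_normal((261, 6)))
        v2, m2 = drop_initial_volumes(v, m, 5)
        assert v2.n_timepoints == 256 and m2.n_timepoints == 256
        np.testing.assert_array_equal(v2.data, v.data[..., 5:])
        np.testing.assert_array_equal(m2.params, m.params[5:])

    def test_zero_drop_is_identity(self, rng):
        v = make_series(rng.standard_normal((3, 3, 3, 10)))
        m = MotionTrace(rng.standard_normal((10, 6)))
        v2, m2 = drop_initial_volumes(v, m, 0)
        np.testing.assert_array_equal(v2.data, v.data)

    def test_dropping_everything_errors(self, rng):
        v = make_series(rng.standard_normal((3, 3, 3, 10)))
        m = MotionTrace(np.zeros((10, 6)))
        with pytest.raises(EmptySeriesError):
            drop_initial_volumes(v, m, 10)


class TestMeanFD:
    def test_zero_motion_gives_zero(self, zero_motion):
        assert mean_fd(zero_motion(20)) == 0.0

    def test_translation_step(self):
        # one +0.1 mm step in x over two frames
        params = np.zeros((2, 6))
        params[1, 0] = 0.1
        assert mean_fd(MotionTrace(params)) == pytest.approx(0.1)

    def test_rotation_step_scaled_by_head_radius(self):
        # 0.002 rad on one axis at 50 mm radius -> 0.1 mm of arc
        params = np.zeros((2, 6))
        params[1, 4] = 0.002
        assert mean_fd(MotionTrace(params), head_radius=50.0) == pytest.approx(0.1)

    def test_invariant_to_constant_offset(self, rng):
        params = rng.standard_normal((30, 6)) * 0.05
        shifted = params + rng.standard_normal(6)
        assert mean_fd(MotionTrace(params)) == pytest.approx(
            mean_fd(MotionTrace(shifted))
        )

    def test_single_timepoint_errors(self):
        with pytest.raises(EmptySeriesError):
            mean_fd(MotionTrace(np.zeros((1, 6))))

    def test_framewise_values_sum_abs_changes(self):
        params = np.zeros((3, 6))
        params[1] = [0.1, -0.2, 0.0, 0.001, 0.0, 0.0]
        fd = framewise_displacement(MotionTrace(params), head_radius=50.0)
        assert fd[0] == pytest.approx(0.1 + 0.2 + 0.05)
        assert fd[1] == pytest.approx(0.1 + 0.2 + 0.05)  # moving back costs the same


class TestExcludeByFD:
    @staticmethod
    def _cohort(fds):
        return pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(len(fds))], "mean_fd": fds}
        )

    def test_outlier_excluded(self):
        out = exclude_by_fd(self._cohort([0.1] * 9 + [1.0]))
        # mean 0.19, sample SD ~0.2846 -> threshold ~0.759: only the 1.0 subject fails
        assert out["included"].tolist() == [True] * 9 + [False]

    def test_zero_variance_group_keeps_everyone(self):
        out = exclude_by_fd(self._cohort([0.2] * 5))
        assert out["included"].all()

    def test_empty_cohort(self):
        out = exclude_by_fd(self._cohort([]))
        assert len(out) == 0 and "included" in out.columns

    def test_group_stats_use_all_subjects(self):
        # with the outlier in the group stats, borderline subjects survive
        fds = [0.1, 0.12, 0.11, 0.13, 0.1, 2.0]
        out = exclude_by_fd(self._cohort(fds))
        assert out["included"].tolist() == [True] * 5 + [False]


class TestBuildNuisance:
    def _inputs(self, rng, t=40):
        v = make_series(rng.standard_normal((6, 6, 6, t)) + 100.0)
        m = MotionTrace(rng.standard_normal((t, 6)) * 0.01)
        wm = np.zeros((6, 6, 6), dtype=bool)
        wm[1, 1, 1] = True
        csf = np.zeros((6, 6, 6), dtype=bool)
        csf[4, 4, 4] = True
        return v, m, wm, csf

    def test_lfcd_recipe_has_16_columns_with_global(self, rng):
        v, m, wm, csf = self._inputs(rng)
        n = build_nuisance(v, m, wm, csf, "lfcd")
        assert n.regressors.shape[1] == 16
        assert "global_mean" in n.labels

    def test_foca_recipe_has_15_columns_no_global(self, rng):
        v, m, wm, csf = self._inputs(rng)
        n = build_nuisance(v, m, wm, csf, "foca")
        assert n.regressors.shape[1] == 15
        assert "global_mean" not in n.labels

    def test_motion_derivatives_are_backward_differences(self, rng):
        v, m, wm, csf = self._inputs(rng)
        n = build_nuisance(v, m, wm, csf, "foca")
        d = n.regressors[:, n.labels.index("trans_x_deriv")]
        assert d[0] == 0.0
        np.testing.assert_allclose(d[1:], np.diff(m.params[:, 0]))

    def test_zero_motion_columns_dropped_with_warning(self, rng, zero_motion):
        v, _, wm, csf = self._inputs(rng)
        with pytest.warns(UserWarning, match="constant-zero"):
            n = build_nuisance(v, zero_motion(v.n_timepoints), wm, csf, "foca")
        assert all(not lab.startswith(("trans", "rot")) for lab in n.labels)

    def test_unknown_recipe(self, rng):
        v, m, wm, csf = self._inputs(rng)
        with pytest.raises(ValueError, match="recipe"):
            build_nuisance(v, m, wm, csf, "reho")


class TestRegressNuisance:
    def test_regressor_timecourse_becomes_zero(self, rng):
        t = 30
        reg = rng.standard_normal((t, 2))
        data = np.zeros((2, 1, 1, t))
        data[0, 0, 0] = 3.0 * reg[:, 0] - 1.0
        data[1, 0, 0] = rng.standard_normal(t)
        v = make_series(data)
        out = regress_nuisance(v, NuisanceSet(reg, ["a", "b"]))
        np.testing.assert_allclose(out.data[0, 0, 0], 0.0, atol=1e-10)

    def test_residuals_match_normal_equations_oracle(self, rng):
        t, n_vox = 25, 10
        reg = rng.standard_normal((t, 3))
        data = rng.standard_normal((n_vox, 1, 1, t))
        v = make_series(data)
        out = regress_nuisance(v, NuisanceSet(reg, list("abc")))
        X = np.column_stack([np.ones(t), reg])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        for i in range(n_vox):
            expected = data[i, 0, 0] - H @ data[i, 0, 0]
            np.testing.assert_allclose(out.data[i, 0, 0], expected, atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self, rng):
        t = 40
        reg = rng.standard_normal((t, 4))
        v = make_series(rng.standard_normal((4, 4, 4, t)))
        out = regress_nuisance(v, NuisanceSet(reg, list("abcd")))
        Xn = reg / np.linalg.norm(reg, axis=0)
        dots = np.einsum("vt,tk->vk", out.data.reshape(-1, t), Xn)
        assert np.abs(dots).max() < 1e-8

    def test_collinear_columns_dropped_with_warning(self, rng):
        t = 20
        base = rng.standard_normal((t, 2))
        reg = np.column_stack([base, base[:, 0] * 2.0])
        v = make_series(rng.standard_normal((2, 2, 2, t)))
        with pytest.warns(UserWarning, match="rank-deficient"):
            regress_nuisance(v, NuisanceSet(reg, ["a", "b", "a2"]))

    def test_out_of_mask_zeroed(self, rng):
        t = 20
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[0, 0, 0] = True
        v = make_series(rng.standard_normal((2, 2, 2, t)), mask=mask)
        out = regress_nuisance(v, NuisanceSet(rng.standard_normal((t, 1)), ["a"]))
        assert np.all(out.data[~mask] == 0)


class TestBandpass:
    TR = 1.97

    def _sine(self, freq, t=256):
        # snap to the nearest DFT bin so the pure tone has no leakage
        k = round(freq * t * self.TR)
        time = np.arange(t) * self.TR
        data = np.sin(2 * np.pi * (k / (t * self.TR)) * time)[None, None, None, :]
        return make_series(np.tile(data, (2, 1, 1, 1)), tr=self.TR)

    def test_constant_maps_to_zero(self):
        v = make_series(np.full((2, 2, 2, 64), 7.0), tr=self.TR)
        out = bandpass(v, 0.01, 0.08)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-9)

    def test_passband_sinusoid_preserved(self):
        v = self._sine(0.04)
        out = bandpass(v, 0.01, 0.08)
        ratio = np.abs(out.data[0, 0, 0]).max() / np.abs(v.data[0, 0, 0]).max()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_stopband_sinusoid_removed(self):
        v = self._sine(0.2)
        out = bandpass(v, 0.01, 0.08)
        ratio = np.abs(out.data[0, 0, 0]).max() / np.abs(v.data[0, 0, 0]).max()
        assert ratio < 0.01

    def test_idempotent(self, rng):
        v = make_series(rng.standard_normal((3, 3, 3, 100)), tr=self.TR)
        once = bandpass(v, 0.01, 0.08)
        twice = bandpass(once, 0.01, 0.08)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-10)

    def test_band_above_nyquist_errors(self, rng):
        v = make_series(rng.standard_normal((2, 2, 2, 50)), tr=self.TR)
        with pytest.raises(InvalidBandError):
            bandpass(v, 0.01, 0.3)  # Nyquist ~0.254 Hz


class TestSmooth:
    @staticmethod
    def _map(values, mask, voxel_mm=3.0):
        affine = np.diag([voxel_mm] * 3 + [1.0])
        return LocalFCMap(values=values, statistic="lfcd", mask=mask, affine=affine)

    def test_fwhm_zero_is_identity(self, rng):
        vals = rng.standard_normal((6, 6, 6))
        m = self._map(vals, np.ones((6, 6, 6), dtype=bool))
        out = smooth(m, 0.0)
        np.testing.assert_array_equal(out.values, vals)

    def test_constant_in_mask_unchanged(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        m = self._map(np.where(mask, 5.0, 0.0), mask)
        out = smooth(m, 8.0)
        np.testing.assert_allclose(out.values[mask], 5.0, rtol=1e-10)

    def test_impulse_response_width_matches_fwhm(self):
        # measure the FWHM of the smoothed delta along one axis, in mm
        n, voxel_mm, fwhm = 31, 3.0, 8.0
        vals = np.zeros((n, n, n))
        vals[n // 2, n // 2, n // 2] = 1.0
        m = self._map(vals, np.ones((n, n, n), dtype=bool), voxel_mm)
        out = smooth(m, fwhm)
        profile = out.values[:, n // 2, n // 2]
        half = profile.max() / 2
        above = np.flatnonzero(profile >= half)
        # linear interpolation at the half-maximum crossings
        lo, hi = above[0], above[-1]
        f = lambda i, j: i + (half - profile[i]) / (profile[j] - profile[i]) * (j - i)
        width_vox = f(hi, hi + 1) - f(lo, lo - 1)
        assert width_vox * voxel_mm == pytest.approx(fwhm, abs=voxel_mm / 2)

    def test_negative_fwhm_errors(self):
        m = self._map(np.zeros((4, 4, 4)), np.ones((4, 4, 4), dtype=bool))
        with pytest.raises(ValueError):
            smooth(m, -1.0)
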