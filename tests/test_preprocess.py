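"""Tests of the temporal preprocessing operations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alffdev.datatypes import MotionTrace, Volume4D
from alffdev.preprocess import (
    NuisanceSet,
    bandpass_filter,
    detrend_linear,
    discard_initial_volumes,
    extract_tissue_means,
    framewise_displacement,
    friston24_expand,
    motion_exclusion,
    regress_nuisance,
    smooth_gaussian,
)


def _vol(data, tr=2.0):
    return Volume4D(np.asarray(data, dtype=float), (3.0, 3.0, 3.0), tr)


def _trace(t=20, tr=2.0):
    return MotionTrace(np.zeros((t, 6)), tr)


class TestDiscard:
    def test_180_minus_10_gives_170_jointly(self):
        vol = _vol(np.random.default_rng(0).normal(size=(4, 4, 4, 180)))
        vol2, mot2 = discard_initial_volumes(vol, _trace(180), 10)
        assert vol2.n_volumes == 170 and mot2.n_volumes == 170
        assert np.array_equal(vol2.data, vol.data[..., 10:])

    def test_zero_is_identity(self):
        vol = _vol(np.arange(2 * 2 * 2 * 5.0).reshape(2, 2, 2, 5))
        vol2, _ = discard_initial_volumes(vol, _trace(5), 0)
        assert np.array_equal(vol2.data, vol.data)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="discard"):
            discard_initial_volumes(_vol(np.zeros((2, 2, 2, 5))), _trace(5), 5)


class TestMotionExclusion:
    def test_zero_trace_kept(self):
        assert motion_exclusion(_trace()) is False

    def test_translation_over_3mm_excluded(self):
        p = np.zeros((10, 6))
        p[4, 1] = 3.5
        assert motion_exclusion(MotionTrace(p)) is True

    def test_rotation_threshold_is_in_degrees(self):
        p = np.zeros((10, 6))
        p[4, 4] = np.radians(3.4)  # 3.4 degrees > 3
        assert motion_exclusion(MotionTrace(p)) is True
        p[4, 4] = np.radians(2.8)
        assert motion_exclusion(MotionTrace(p)) is False


class TestFramewiseDisplacement:
    def test_zero_trace_zero_fd(self):
        fd, mean_fd = framewise_displacement(_trace())
        assert np.all(fd == 0) and mean_fd == 0

    def test_excursion_and_return_both_count(self):
        p = np.zeros((3, 6))
        p[1, 0] = 1.0  # out 1 mm then back
        fd, _ = framewise_displacement(MotionTrace(p))
        assert fd[1] == pytest.approx(1.0) and fd[2] == pytest.approx(1.0)

    def test_rotation_scaled_by_sphere_radius(self):
        p = np.zeros((2, 6))
        p[1, 3] = 0.01  # rad; 50 mm sphere -> 0.5 mm
        fd, _ = framewise_displacement(MotionTrace(p))
        assert fd[1] == pytest.approx(0.5)


class TestSmoothing:
    def test_fwhm_zero_is_identity(self):
        vol = _vol(np.random.default_rng(0).normal(size=(6, 6, 6, 3)))
        out = smooth_gaussian(vol, 0.0)
        assert np.array_equal(out.data, vol.data)

    def test_constant_image_unchanged_in_interior(self):
        vol = _vol(np.ones((16, 16, 16, 1)))
        out = smooth_gaussian(vol, 6.0)
        assert out.data[8, 8, 8, 0] == pytest.approx(1.0, abs=1e-6)

    def test_delta_spreads_to_stated_fwhm(self):
        data = np.zeros((21, 21, 21, 1))
        data[10, 10, 10, 0] = 1.0
        out = smooth_gaussian(_vol(data), 8.0)
        profile = out.data[:, 10, 10, 0]
        half = profile.max() / 2
        above = np.where(profile >= half)[0]
        # linear interpolation of the half-maximum crossings, in mm
        lo, hi = above[0], above[-1]
        f_lo = lo - (profile[lo] - half) / (profile[lo] - profile[lo - 1])
        f_hi = hi + (profile[hi] - half) / (profile[hi] - profile[hi + 1])
        fwhm_mm = (f_hi - f_lo) * 3.0
        assert fwhm_mm == pytest.approx(8.0, rel=0.05)


class TestDetrend:
    def test_exact_line_removed(self):
        t = np.arange(30.0)
        assert np.allclose(detrend_linear(3.0 + 0.5 * t), 0.0, atol=1e-10)

    def test_residual_orthogonal_to_ramp(self, rng):
        ts = rng.normal(size=(40, 7))
        out = detrend_linear(ts)
        t = np.arange(40.0)
        assert np.allclose(out.sum(axis=0), 0.0, atol=1e-9)
        assert np.allclose(t @ out, 0.0, atol=1e-8)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_linearity(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=(2, 25))
        lhs = detrend_linear(a + b)
        rhs = detrend_linear(a) + detrend_linear(b)
        assert np.allclose(lhs, rhs, atol=1e-10)


class TestFriston24:
    def test_zero_trace_gives_24_zero_columns(self):
        out = friston24_expand(_trace())
        assert out.regressors.shape == (20, 24)
        assert np.all(out.regressors == 0)

    def test_structure_of_expansion(self, rng):
        p = rng.normal(size=(15, 6))
        out = friston24_expand(MotionTrace(p))
        R = out.regressors
        assert np.array_equal(R[:, :6], p)
        assert np.array_equal(R[:, 6:12], p**2)
        assert np.all(R[0, 12:] == 0)
        assert np.array_equal(R[1:, 12:18], p[:-1])
        assert np.array_equal(R[:, 18:24], R[:, 12:18] ** 2)


class TestTissueMeans:
    def test_constant_volume_gives_constant_series(self):
        vol = _vol(np.full((4, 4, 4, 6), 3.5))
        wm = np.zeros((4, 4, 4), bool); wm[0, 0, 0] = True
        csf = np.zeros((4, 4, 4), bool); csf[1, 1, 1] = True
        wm_ts, csf_ts = extract_tissue_means(vol, wm, csf)
        assert np.allclose(wm_ts, 3.5) and np.allclose(csf_ts, 3.5)

    def test_single_voxel_mask_returns_that_series(self, rng):
        data = rng.normal(size=(3, 3, 3, 8))
        vol = _vol(data)
        m = np.zeros((3, 3, 3), bool); m[2, 1, 0] = True
        wm_ts, _ = extract_tissue_means(vol, m, m)
        assert np.allclose(wm_ts, data[2, 1, 0])

    def test_disjoint_masks_on_two_valued_image(self):
        data = np.zeros((4, 4, 4, 2))
        data[:2] = 1.0
        data[2:] = 5.0
        wm = np.zeros((4, 4, 4), bool); wm[:2] = True
        csf = ~wm
        wm_ts, csf_ts = extract_tissue_means(_vol(data), wm, csf)
        assert np.allclose(wm_ts, 1.0) and np.allclose(csf_ts, 5.0)

    def test_empty_mask_rejected(self):
        vol = _vol(np.zeros((3, 3, 3, 4)))
        with pytest.raises(ValueError, match="empty"):
            extract_tissue_means(vol, np.zeros((3, 3, 3), bool), np.ones((3, 3, 3), bool))


class TestNuisanceRegression:
    def _setup(self, rng, t=60):
        Z = rng.normal(size=(t, 4))
        nuis = NuisanceSet(Z, [f"z{i}" for i in range(4)])
        mask = np.ones((2, 2, 2), bool)
        return Z, nuis, mask

    def test_series_equal_to_regressor_removed(self, rng):
        Z, nuis, mask = self._setup(rng)
        data = np.tile(Z[:, 0], (2, 2, 2, 1))
        out = regress_nuisance(_vol(data), nuis, mask)
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_all_regressors(self, rng):
        Z, nuis, mask = self._setup(rng)
        data = rng.normal(size=(2, 2, 2, 60))
        out = regress_nuisance(_vol(data), nuis, mask)
        resid = out.data.reshape(-1, 60)
        for j in range(4):
            c = resid @ Z[:, j]
            assert np.all(np.abs(c) < 1e-8)
        assert np.all(np.abs(resid.sum(axis=1)) < 1e-8)  # intercept too

    def test_rank_deficient_design_warns_and_survives(self, rng):
        t = 60
        Z = np.zeros((t, 3))  # all-zero motion columns
        nuis = NuisanceSet(Z, ["a", "b", "c"])
        data = rng.normal(size=(2, 2, 2, t))
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            out = regress_nuisance(_vol(data), nuis, np.ones((2, 2, 2), bool))
        assert np.isfinite(out.data).all()


class TestBandpass:
    def _sine_vol(self, f_hz, t=170, tr=2.0):
        tt = np.arange(t) * tr
        return _vol(np.tile(np.sin(2 * np.pi * f_hz * tt), (1, 1, 1, 1)), tr)

    def test_in_band_sinusoid_preserved(self):
        vol = self._sine_vol(0.04)
        out = bandpass_filter(vol, 0.01, 0.08)
        ratio = out.data.std() / vol.data.std()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_out_of_band_sinusoid_removed(self):
        vol = self._sine_vol(0.2)
        out = bandpass_filter(vol, 0.01, 0.08)
        assert out.data.std() < 1e-10 * vol.data.std()

    def test_out_of_band_power_negligible(self, rng):
        vol = _vol(rng.normal(size=(2, 2, 2, 170)))
        out = bandpass_filter(vol, 0.01, 0.08)
        spec = np.fft.rfft(out.data, axis=-1)
        freqs = np.fft.rfftfreq(170, 2.0)
        outside = (freqs < 0.01) | (freqs > 0.08)
        p_out = (np.abs(spec[..., outside]) ** 2).sum()
        p_tot = (np.abs(spec) ** 2).sum()
        assert p_out < 1e-10 * p_tot

    def test_band_outside_nyquist_rejected(self):
        vol = self._sine_vol(0.04)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(vol, 0.01, 0.3)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_temporal_linearity(self, seed):
        r = np.random.default_rng(seed)
        a = _vol(r.normal(size=(2, 2, 1, 50)))
        b = _vol(r.normal(size=(2, 2, 1, 50)))
        lhs = bandpass_filter(a.with_data(a.data + b.data), 0.01, 0.08).data
        rhs = bandpass_filter(a, 0.01, 0.08).data + bandpass_filter(b, 0.01, 0.08).data
        assert np.allclose(lhs, rhs, atol=1e-10)
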