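"""Mono-exponential mapping, coupling slopes and SNR estimation."""

import numpy as np
import pytest

from drcoupling import (CompartmentParams, classify_coupling, coupling_slopes,
                        estimate_snr, evaluate_signal, fit_mono_adc,
                        fit_mono_r2, fit_parameter_maps, roi_mean_series)
from drcoupling.fitting import RAYLEIGH_SD_FACTOR

from .conftest import grid_search_monoexp

TES = np.array([53.0, 71.0, 89.0])
BVALS = np.array([0.0, 500.0, 1000.0])


class TestMonoExpFits:
    def test_exact_adc_recovery(self):
        s = 800.0 * np.exp(-0.8e-3 * BVALS)
        fit = fit_mono_adc(s, BVALS)
        assert fit.rate == pytest.approx(0.8e-3, rel=1e-9)
        assert fit.amplitude == pytest.approx(800.0, rel=1e-9)
        assert fit.converged

    def test_exact_r2_recovery(self):
        s = 1000.0 * np.exp(-20.0 * TES / 1000.0)
        fit = fit_mono_r2(s, TES)
        assert fit.rate == pytest.approx(20.0, rel=1e-9)

    def test_constant_signal_gives_zero_rate(self):
        assert fit_mono_adc(np.full(3, 500.0), BVALS).rate == 0.0
        assert fit_mono_r2(np.full(3, 500.0), TES).rate == 0.0

    def test_two_point_fit_is_exact_log_ratio(self):
        b = np.array([0.0, 1000.0])
        s = np.array([900.0, 900.0 * np.exp(-1.1e-3 * 1000.0)])
        fit = fit_mono_adc(s, b)
        assert fit.rate == pytest.approx(1.1e-3, rel=1e-12)
        assert fit.resid_norm == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_signal_rejected(self):
        with pytest.raises(ValueError):
            fit_mono_adc(np.array([100.0, 0.0, 10.0]), BVALS)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            fit_mono_adc(np.array([100.0]), np.array([0.0]))

    def test_apparent_adc_matches_grid_search_oracle(self, two_pool_params):
        s = evaluate_signal(two_pool_params, 53.0, BVALS)
        fit = fit_mono_adc(s, BVALS)
        k_oracle, _ = grid_search_monoexp(BVALS, s, 0.0, 0.01)
        assert fit.rate == pytest.approx(k_oracle, rel=1e-3)

    def test_apparent_r2_matches_grid_search_oracle(self, two_pool_params):
        s = evaluate_signal(two_pool_params, TES, 0.0)
        fit = fit_mono_r2(s, TES)
        k_oracle, _ = grid_search_monoexp(TES / 1000.0, s, 0.0, 100.0)
        assert fit.rate == pytest.approx(k_oracle, rel=1e-3)

    def test_apparent_rates_bracketed_by_compartments(self, rng):
        """The apparent mono-exponential rate of a two-pool mixture lies
        between the two pool rates."""
        for _ in range(20):
            f1 = rng.uniform(0.2, 0.8)
            adc = rng.uniform(0.3e-3, 1.5e-3, 2)
            r2 = rng.uniform(10.0, 40.0, 2)
            p = CompartmentParams(f1, 1 - f1, adc[0], adc[1], r2[0], r2[1], 1000.0)
            a = fit_mono_adc(evaluate_signal(p, 71.0, BVALS), BVALS).rate
            assert adc.min() - 1e-6 <= a <= adc.max() + 1e-6
            r = fit_mono_r2(evaluate_signal(p, TES, 500.0), TES).rate
            assert r2.min() - 1e-6 <= r <= r2.max() + 1e-6


class TestParameterMaps:
    def _uniform_volume(self, params, shape=(2, 2, 1)):
        sig = evaluate_signal(params, TES[:, None], BVALS[None, :])
        return np.broadcast_to(sig, shape + sig.shape).copy()

    def test_uniform_phantom_equals_scalar_fits(self, two_pool_params, grid):
        vol = self._uniform_volume(two_pool_params)
        maps = fit_parameter_maps(vol, grid)
        sig = evaluate_signal(two_pool_params, TES[:, None], BVALS[None, :])
        for i in range(3):
            expected = fit_mono_adc(sig[i], BVALS).rate
            assert np.allclose(maps.adc_per_te[..., i], expected, rtol=1e-12)
        for j in range(3):
            expected = fit_mono_r2(sig[:, j], TES).rate
            assert np.allclose(maps.r2_per_b[..., j], expected, rtol=1e-12)
        assert maps.valid.all()

    def test_zero_sample_flags_only_that_voxel(self, two_pool_params, grid):
        vol = self._uniform_volume(two_pool_params)
        vol[0, 0, 0, 1, 1] = 0.0
        maps = fit_parameter_maps(vol, grid)
        assert not maps.valid[0, 0, 0]
        assert np.isnan(maps.adc_per_te[0, 0, 0]).all()
        assert maps.valid[1, 1, 0]
        assert np.isfinite(maps.adc_per_te[1, 1, 0]).all()

    def test_shape_mismatch_rejected(self, grid):
        with pytest.raises(ValueError):
            fit_parameter_maps(np.ones((2, 2, 1, 3, 2)), grid)

    def test_mask_restricts_fitting(self, two_pool_params, grid):
        vol = self._uniform_volume(two_pool_params)
        mask = np.zeros((2, 2, 1), dtype=bool)
        mask[0, 0, 0] = True
        maps = fit_parameter_maps(vol, grid, mask)
        assert maps.valid[0, 0, 0]
        assert not maps.valid[1, 1, 0]
        assert np.isnan(maps.adc_per_te[1, 1, 0]).all()


class TestRoiMeans:
    def test_uniform_roi_mean_equals_voxel_value(self, two_pool_params, grid):
        vol = TestParameterMaps()._uniform_volume(two_pool_params, (3, 3, 1))
        maps = fit_parameter_maps(vol, grid)
        roi = np.ones((3, 3, 1), dtype=bool)
        mean_adc, mean_r2, n = roi_mean_series(maps, roi)
        assert n == 9
        assert np.allclose(mean_adc, maps.adc_per_te[0, 0, 0], rtol=1e-12)

    def test_mean_matches_sum_count_oracle(self, grid, rng):
        # distinct decay rates per voxel; ROI mean must equal sum/count
        shape = (2, 2, 1)
        vol = np.empty(shape + (3, 3))
        rates = rng.uniform(0.4e-3, 1.2e-3, shape)
        for idx in np.ndindex(shape):
            vol[idx] = 700.0 * np.exp(-30.0 * TES[:, None] / 1000.0
                                      - rates[idx] * BVALS[None, :])
        maps = fit_parameter_maps(vol, grid)
        roi = np.ones(shape, dtype=bool)
        mean_adc, _, n = roi_mean_series(maps, roi)
        manual = maps.adc_per_te.reshape(-1, 3).sum(axis=0) / 4
        assert np.allclose(mean_adc, manual, rtol=1e-12)
        assert n == 4

    def test_flagged_voxels_excluded(self, two_pool_params, grid):
        vol = TestParameterMaps()._uniform_volume(two_pool_params)
        vol[0, 0, 0, 0, 0] = 0.0  # invalidate one voxel
        maps = fit_parameter_maps(vol, grid)
        _, _, n = roi_mean_series(maps, np.ones((2, 2, 1), bool))
        assert n == 3

    def test_empty_roi_rejected(self, two_pool_params, grid):
        vol = TestParameterMaps()._uniform_volume(two_pool_params)
        maps = fit_parameter_maps(vol, grid)
        with pytest.raises(ValueError, match="no valid voxels"):
            roi_mean_series(maps, np.zeros((2, 2, 1), bool))


class TestCouplingSlopes:
    def test_constant_adc_gives_zero_slope(self):
        m = coupling_slopes([1e-3, 1e-3, 1e-3], TES, [20.0, 20.0, 20.0], BVALS)
        assert m.k_adc_te == pytest.approx(0.0, abs=1e-15)
        assert m.k_r2_b == pytest.approx(0.0, abs=1e-15)

    def test_exact_line_recovered(self):
        # ADC linear in TE (seconds) with slope 5e-4 mm^2/s^2
        adc = 0.7e-3 + 5e-4 * TES / 1000.0
        m = coupling_slopes(adc, TES, [20.0, 21.0, 22.0], BVALS)
        assert m.k_adc_te == pytest.approx(5e-4, rel=1e-12)
        assert m.k_r2_b == pytest.approx(0.002, rel=1e-12)

    def test_r2_b0_is_measured_b0_rate_in_per_ms(self):
        m = coupling_slopes([1e-3] * 3, TES, [18.0, 20.0, 22.0], BVALS)
        assert m.r2_b0 == pytest.approx(0.018, rel=1e-12)

    def test_sign_agrees_with_analytic_classification(self, two_pool_params):
        """Noiseless young-regime tissue: fitted slopes are positive, in
        agreement with the analytic sign rule."""
        adcs = [fit_mono_adc(evaluate_signal(two_pool_params, te, BVALS), BVALS).rate
                for te in TES]
        r2s = [fit_mono_r2(evaluate_signal(two_pool_params, TES, b), TES).rate
               for b in BVALS]
        m = coupling_slopes(adcs, TES, r2s, BVALS)
        assert classify_coupling(two_pool_params).label == "positive"
        assert m.k_adc_te > 0
        assert m.k_r2_b > 0

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            coupling_slopes([1e-3], [53.0], [20.0, 21.0], [0.0, 500.0])


class TestEstimateSnr:
    def test_noiseless_background_returns_inf_with_warning(self):
        img = np.zeros((10, 10))
        img[:5] = 100.0
        sig = np.zeros((10, 10), bool)
        sig[:5] = True
        with pytest.warns(UserWarning, match="zero variance"):
            assert estimate_snr(img, sig, ~sig) == np.inf

    def test_rayleigh_background_recovers_sigma(self, rng):
        sigma = 7.0
        n = 200_000
        background = np.hypot(rng.normal(0, sigma, n), rng.normal(0, sigma, n))
        img = np.concatenate([np.full(100, 100.0), background])
        sig_mask = np.zeros(img.size, bool)
        sig_mask[:100] = True
        snr = estimate_snr(img, sig_mask, ~sig_mask)
        assert 100.0 / snr == pytest.approx(sigma, rel=0.02)

    def test_constructed_snr_of_60(self, rng):
        a = 300.0
        sigma = a / 60.0
        n = 200_000
        background = np.hypot(rng.normal(0, sigma, n), rng.normal(0, sigma, n))
        img = np.concatenate([np.full(500, a), background])
        sig_mask = np.zeros(img.size, bool)
        sig_mask[:500] = True
        assert estimate_snr(img, sig_mask, ~sig_mask) == pytest.approx(60.0, rel=0.05)

    def test_mask_validation(self):
        img = np.ones((4, 4))
        full = np.ones((4, 4), bool)
        with pytest.raises(ValueError, match="disjoint"):
            estimate_snr(img, full, full)
        with pytest.raises(ValueError, match="non-empty"):
            estimate_snr(img, np.zeros((4, 4), bool), full)

    def test_rayleigh_factor_value(self):
        assert RAYLEIGH_SD_FACTOR == pytest.approx(np.sqrt(2 - np.pi / 2), rel=1e-12)
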