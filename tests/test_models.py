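"""Closed-form model functions vs independent quadrature oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from msmr import (GAMMA2_3DG, ModelParams, PSFGeometry, binning_diffusion,
                  binning_isomerization, g_diffusion_3dg, g_isomerization,
                  gamma_factor, msmr_model, q_model)
from msmr.errors import ConfigError
from msmr.models import (binning_diffusion_numeric,
                         binning_isomerization_numeric, gamma_factor_numeric)


class TestGammaFactor:
    def test_order_one_is_unity(self):
        assert gamma_factor(1) == 1.0

    def test_order_two_is_gaussian_closed_form(self):
        assert gamma_factor(2) == pytest.approx(1 / (2 * math.sqrt(2)), abs=1e-12)
        assert gamma_factor(2) == pytest.approx(0.3535533906, abs=1e-9)

    @pytest.mark.parametrize("geometry", [PSFGeometry(0.4, 0.4), PSFGeometry(0.4, 2.0)])
    def test_quadrature_oracle_matches(self, geometry):
        # direct 3D integration of PSF^2 / PSF over a wide domain
        assert gamma_factor_numeric(2, geometry) == pytest.approx(0.35355, abs=1e-4)
        assert gamma_factor_numeric(1, geometry) == pytest.approx(1.0, abs=1e-10)

    def test_invalid_order_rejected(self):
        with pytest.raises(ConfigError):
            gamma_factor(0)
        with pytest.raises(ConfigError):
            gamma_factor(-1)


class TestDiffusionKernel:
    def test_zero_lag_is_unity(self):
        assert g_diffusion_3dg(0.0, 1e-3, 1.0) == 1.0

    def test_value_at_tau_d(self):
        assert g_diffusion_3dg(1e-3, 1e-3, 1.0) == pytest.approx(0.3535533906, abs=1e-9)
        assert g_diffusion_3dg(1e-3, 1e-3, 10.0) == pytest.approx(1 / (2 * math.sqrt(1.01)), rel=1e-9)

    def test_negative_lag_rejected(self):
        with pytest.raises(ConfigError):
            g_diffusion_3dg(-1e-6, 1e-3, 1.0)

    @given(st.floats(1e-6, 1e2), st.floats(1.0, 20.0))
    def test_decreasing_and_bounded(self, tau_over_taud, r):
        g = g_diffusion_3dg(np.array([0.0, tau_over_taud, 2 * tau_over_taud]), 1.0, r)
        assert g[0] == 1.0
        assert g[0] >= g[1] >= g[2] > 0


class TestIsomerizationKernel:
    def test_no_dark_state(self):
        assert g_isomerization(5e-6, 0.0, 1e-5) == 1.0

    def test_zero_lag(self):
        assert g_isomerization(0.0, 0.2, 1e-5) == pytest.approx(1.25, abs=1e-12)

    def test_one_relaxation_time(self):
        assert g_isomerization(1e-5, 0.2, 1e-5) == pytest.approx(1 + 0.25 / math.e, rel=1e-9)

    def test_divergent_fraction_rejected(self):
        with pytest.raises(ConfigError):
            g_isomerization(1e-6, 1.0, 1e-5)


class TestBinningDiffusion:
    def test_short_time_limit(self):
        assert binning_diffusion(1e-9 * 1e-3, 1e-3, 1.0) == pytest.approx(1.0, abs=1e-6)

    def test_r1_closed_form_at_tau_d(self):
        expected = 8 * (0.5 - math.sqrt(2) + 1)
        assert binning_diffusion(1e-3, 1e-3, 1.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.6862915, abs=1e-7)

    @pytest.mark.parametrize("r", [1.0, 2.0, 5.0, 10.0])
    @pytest.mark.parametrize("alpha", np.logspace(-3, 3, 13).tolist())
    def test_matches_quadrature(self, r, alpha):
        closed = binning_diffusion(alpha, 1.0, r)
        oracle = binning_diffusion_numeric(alpha, 1.0, r)
        assert closed == pytest.approx(oracle, rel=1e-8)

    def test_branch_continuity_at_switch_boundary(self):
        # artanh branch just outside the |beta-1| < 1e-6 switch tolerance
        r_near = 1.0 + 5.1e-7  # beta - 1 ~ -1.02e-6
        for alpha in np.logspace(-2, 2, 9):
            near = binning_diffusion(alpha, 1.0, r_near)
            at_one = binning_diffusion(alpha, 1.0, 1.0)
            assert near == pytest.approx(at_one, rel=1e-6)

    def test_true_branch_gap_shrinks_linearly(self):
        # the residual gap between r = 1 + eps and r = 1 is genuine
        # (matches quadrature) and scales ~linearly in eps
        gaps = []
        for eps in (1e-4, 1e-5):
            g = binning_diffusion(10.0, 1.0, 1.0 + eps) - binning_diffusion(10.0, 1.0, 1.0)
            oracle = (binning_diffusion_numeric(10.0, 1.0, 1.0 + eps)
                      - binning_diffusion_numeric(10.0, 1.0, 1.0))
            assert g == pytest.approx(oracle, rel=1e-3)
            gaps.append(abs(g))
        assert gaps[0] / gaps[1] == pytest.approx(10.0, rel=0.05)

    @pytest.mark.parametrize("r", [1.0, 3.0])
    def test_monotone_decreasing_with_limits(self, r):
        T = np.logspace(-7, 2, 200)
        g = binning_diffusion(T, 1e-3, r)
        assert np.all(np.diff(g) < 0)
        assert np.all((g > 0) & (g <= 1))
        assert g[0] == pytest.approx(1.0, abs=1e-4)
        assert g[-1] < 1e-3

    def test_invalid_arguments(self):
        with pytest.raises(ConfigError):
            binning_diffusion(0.0, 1e-3, 1.0)
        with pytest.raises(ConfigError):
            binning_diffusion(1e-3, -1.0, 1.0)
        with pytest.raises(ConfigError):
            binning_diffusion(1e-3, 1e-3, 0.5)


class TestBinningIsomerization:
    def test_no_dark_state(self):
        assert binning_isomerization(1e-5, 0.0, 1e-5) == 1.0

    def test_short_time_limit(self):
        assert binning_isomerization(1e-6 * 1e-5, 0.2, 1e-5) == pytest.approx(1.25, abs=1e-5)

    @pytest.mark.parametrize("F", [0.2, 0.5])
    @pytest.mark.parametrize("x", np.logspace(-3, 3, 13).tolist())
    def test_matches_quadrature(self, F, x):
        closed = binning_isomerization(x * 1e-5, F, 1e-5)
        oracle = binning_isomerization_numeric(x * 1e-5, F, 1e-5)
        assert closed == pytest.approx(oracle, rel=1e-8)

    @pytest.mark.parametrize("x", [0.9e-4, 0.99e-4, 1.01e-4, 1.1e-4])
    def test_both_branches_accurate_at_series_threshold(self, x):
        T = x * 1e-5
        assert binning_isomerization(T, 0.3, 1e-5) == pytest.approx(
            binning_isomerization_numeric(T, 0.3, 1e-5), rel=1e-10)

    def test_monotone_with_limits(self):
        T = np.logspace(-11, 0, 200)
        g = binning_isomerization(T, 0.3, 1e-5)
        assert np.all(np.diff(g) <= 0)
        assert g[0] == pytest.approx(1 / 0.7, rel=1e-6)
        assert g[-1] == pytest.approx(1.0, rel=1e-4)

    def test_divergent_fraction_rejected(self):
        with pytest.raises(ConfigError):
            binning_isomerization(1e-5, 1.0, 1e-5)


class TestFullModel:
    def test_short_time_amplitude_no_blinking(self):
        p = ModelParams(mu0=100e3, tau_d=1e-3, r=1.0)
        assert msmr_model(1e-9, p) == pytest.approx(GAMMA2_3DG * 100e3, rel=1e-3)
        assert msmr_model(1e-9, p) == pytest.approx(35355.3, rel=1e-3)

    def test_short_time_amplitude_with_blinking(self):
        p = ModelParams(mu0=100e3, tau_d=1e-3, r=1.0, F=0.2, tau_f=1e-5)
        assert msmr_model(1e-12, p) == pytest.approx(GAMMA2_3DG * 100e3 / 0.8, rel=1e-3)
        assert msmr_model(1e-12, p) == pytest.approx(44194.2, rel=1e-3)

    def test_q_example_composition(self):
        p = ModelParams(mu0=1e5, tau_d=1e-3, r=1.0)
        assert q_model(1e-3, p) == pytest.approx(24.264, abs=1e-3)

    @given(st.floats(1e-7, 1.0), st.floats(1e3, 1e6), st.floats(1e-5, 1e-1),
           st.floats(1.0, 10.0), st.floats(0.0, 0.8))
    def test_q_is_t_times_mu(self, T, mu0, tau_d, r, F):
        p = ModelParams(mu0=mu0, tau_d=tau_d, r=r, F=F, tau_f=1e-5)
        assert q_model(T, p) == pytest.approx(T * msmr_model(T, p), rel=1e-12)

    def test_model_strictly_positive(self):
        p = ModelParams(mu0=1e5, tau_d=1e-3, r=5.0, F=0.3, tau_f=1e-5)
        T = np.logspace(-8, 0, 50)
        assert np.all(msmr_model(T, p) > 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigError):
            ModelParams(mu0=-1, tau_d=1e-3)
        with pytest.raises(ConfigError):
            ModelParams(mu0=1e5, tau_d=1e-3, F=1.0)
        with pytest.raises(ConfigError):
            ModelParams(mu0=1e5, tau_d=1e-3, r=0.5)


class TestPSFGeometry:
    def test_aspect_ratio_and_beta(self):
        g = PSFGeometry(r0=0.4, z0=2.0)
        assert g.aspect_ratio == pytest.approx(5.0)
        assert g.beta == pytest.approx(0.04)

    def test_oblate_rejected(self):
        with pytest.raises(ConfigError):
            PSFGeometry(r0=0.4, z0=0.2)
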