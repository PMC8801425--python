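"""Forward spectral models: closed-form values, limits and invariants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from incoscat.exceptions import GridError, ParameterError
from incoscat.models import (ConvolvedQensModel, GaussianEinsParams,
                             HBAR_UEV_PS, MspfParams, QensModelParams,
                             ResolutionParams, eins_gaussian_intensity,
                             eins_mspf_intensity, eisf_sphere,
                             gamma_fluctuation_pdf, jump_diffusion_hwhm,
                             lorentzian_profile, qens_model_intensity,
                             resolution_profile)


class TestElasticModels:
    @pytest.mark.parametrize("q,s0,u2,expected", [
        (0.0, 2.0, 0.5, 2.0),            # exponent vanishes at Q=0
        (3.0, 1.7, 0.0, 1.7),            # rigid limit
        (2.0, 1.0, 0.6, np.exp(-0.8)),   # direct evaluation
    ])
    def test_gaussian_values(self, q, s0, u2, expected):
        out = eins_gaussian_intensity(q, GaussianEinsParams(s0, u2))
        assert out == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("q,s0,r2,beta,expected", [
        (0.0, 3.0, 0.9, 2.0, 3.0),
        (1.0, 1.0, 1.0, 2.0, 1.5 ** -2),  # (1 + 1/2)^-2
    ])
    def test_mspf_values(self, q, s0, r2, beta, expected):
        out = eins_mspf_intensity(q, MspfParams(s0, r2, beta))
        assert out == pytest.approx(expected, rel=1e-12)

    def test_mspf_gaussian_limit_pointwise(self):
        out = eins_mspf_intensity(1.0, MspfParams(1.0, 0.5, 1e8))
        assert abs(out / np.exp(-0.5) - 1.0) < 1e-6

    def test_mspf_gaussian_limit_sup_norm(self):
        """At beta -> infinity the heterogeneity curve is the Gaussian-form decay."""
        q = np.linspace(0.0, 5.0, 501)
        for r2 in (0.2, 0.86, 1.5):
            mspf = eins_mspf_intensity(q, MspfParams(1.0, r2, 1e8))
            gauss = np.exp(-q * q * r2)
            assert np.max(np.abs(mspf - gauss)) < 1e-5

    def test_gaussian_strictly_decreasing(self, q_grid=None):
        q = np.linspace(0.0, 5.0, 100)
        out = eins_gaussian_intensity(q, GaussianEinsParams(1.0, 0.4))
        assert np.all(np.diff(out) < 0)

    @pytest.mark.parametrize("bad", [
        lambda: GaussianEinsParams(0.0, 0.5),
        lambda: GaussianEinsParams(1.0, -0.1),
        lambda: MspfParams(1.0, 0.5, 0.0),
        lambda: MspfParams(1.0, -0.5, 1.0),
    ])
    def test_parameter_domain_errors(self, bad):
        with pytest.raises(ParameterError):
            bad()


class TestGammaDistribution:
    def test_exponential_at_origin(self):
        assert gamma_fluctuation_pdf(0.0, 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("beta", [0.1, 0.5, 1.0, 3.0, 50.0, 1e3])
    def test_normalization_and_unit_mean(self, beta):
        norm, _ = quad(lambda x: gamma_fluctuation_pdf(x, beta), 0, np.inf)
        mean, _ = quad(lambda x: x * gamma_fluctuation_pdf(x, beta), 0, np.inf)
        assert norm == pytest.approx(1.0, abs=1e-8)
        assert mean == pytest.approx(1.0, abs=1e-8)

    def test_beta_domain_error(self):
        with pytest.raises(ParameterError):
            gamma_fluctuation_pdf(0.5, 0.0)


class TestLorentzian:
    def test_peak_and_hwhm(self):
        gamma = 2.5
        peak = lorentzian_profile(0.0, gamma)
        assert peak == pytest.approx(1.0 / (np.pi * gamma))
        assert lorentzian_profile(gamma, gamma) == pytest.approx(peak / 2)

    def test_unit_area_quadrature(self):
        gamma = 3.0
        area, _ = quad(lambda w: lorentzian_profile(w, gamma),
                       -200 * gamma, 200 * gamma)
        assert area == pytest.approx(1.0, abs=0.01)

    def test_domain_error(self):
        with pytest.raises(ParameterError):
            lorentzian_profile(0.0, -1.0)


class TestJumpDiffusion:
    def test_printed_parameter_width(self):
        # D = 7.6e-8 cm^2/s = 7.6e-4 A^2/ps, tau = 18 ps, Q = 1.67 1/A
        assert jump_diffusion_hwhm(1.67, 7.6e-4, 18.0) == pytest.approx(
            1.344, abs=2e-3)

    def test_high_q_asymptote(self):
        assert jump_diffusion_hwhm(1e6, 7.6e-4, 18.0) == pytest.approx(
            HBAR_UEV_PS / 18.0, rel=1e-3)

    def test_free_diffusion_limit(self):
        q = 1e-4
        ratio = jump_diffusion_hwhm(q, 5e-4, 20.0) / (HBAR_UEV_PS * 5e-4 * q * q)
        assert ratio == pytest.approx(1.0, abs=1e-6)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(d=st.floats(1e-5, 1e-2), tau=st.floats(0.5, 500.0))
    def test_monotone_and_bounded(self, d, tau):
        q = np.linspace(0.01, 10.0, 200)
        g = jump_diffusion_hwhm(q, d, tau)
        assert np.all(np.diff(g) >= -1e-12)
        assert np.all(g <= HBAR_UEV_PS / tau + 1e-9)

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            jump_diffusion_hwhm(1.0, -1e-4, 18.0)
        with pytest.raises(ParameterError):
            jump_diffusion_hwhm(1.0, 1e-4, 0.0)


class TestEisfSphere:
    def test_q_zero_limit(self):
        assert eisf_sphere(0.0, 1.3, 0.2) == pytest.approx(1.0)

    def test_fully_immobile(self):
        q = np.linspace(0, 5, 50)
        assert np.allclose(eisf_sphere(q, 1.3, 1.0), 1.0)

    def test_first_bessel_zero_gives_p0(self):
        # 3 j1(x)/x vanishes at the first zero of j1
        x0 = 4.493409457909064
        a = 1.3
        assert eisf_sphere(x0 / a, a, 0.45) == pytest.approx(0.45, abs=1e-9)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(a=st.floats(0.2, 5.0), p0=st.floats(0.0, 1.0))
    def test_bounds(self, a, p0):
        q = np.linspace(0.0, 10.0, 300)
        a0 = eisf_sphere(q, a, p0)
        assert np.all(a0 >= p0 - 1e-12)
        assert np.all(a0 <= 1.0 + 1e-12)

    def test_series_continuity_near_zero(self):
        # series branch must join the Bessel branch smoothly at x = 1e-3
        below = eisf_sphere(1e-3 * (1 - 1e-6), 1.0, 0.0)
        above = eisf_sphere(1e-3 * (1 + 1e-6), 1.0, 0.0)
        assert below == pytest.approx(above, abs=1e-9)

    def test_domain_error(self):
        with pytest.raises(ParameterError):
            eisf_sphere(1.0, 1.0, 1.2)


class TestResolutionProfile:
    def test_peak_value(self):
        p = ResolutionParams(amp=2.0, omega0=1.0, sigma=3.4, xi=2.0, bg=0.1)
        assert resolution_profile(1.0, p) == pytest.approx(2.1)

    def test_symmetric_when_xi_zero(self):
        p = ResolutionParams(amp=1.0, omega0=0.5, sigma=3.0, xi=0.0, bg=0.05)
        x = np.linspace(0.1, 25, 80)
        assert np.allclose(resolution_profile(0.5 - x, p),
                           resolution_profile(0.5 + x, p))

    def test_left_branch_broadened(self):
        p = ResolutionParams(amp=1.0, omega0=0.0, sigma=3.4, xi=2.77, bg=0.0)
        x = np.linspace(0.1, 40, 120)
        assert np.all(resolution_profile(-x, p) > resolution_profile(x, p))

    def test_single_maximum(self):
        # the adopted broadened branch must not create a secondary peak
        p = ResolutionParams(amp=1.0, omega0=0.0, sigma=3.4, xi=2.77, bg=0.0)
        w = np.linspace(-60, 60, 2001)
        y = resolution_profile(w, p)
        assert np.all(np.diff(y[w < 0]) > 0) and np.all(np.diff(y[w > 0]) < 0)

    def test_domain_error(self):
        with pytest.raises(ParameterError):
            ResolutionParams(amp=1.0, omega0=0.0, sigma=0.0, xi=1.0, bg=0.0)


class TestConvolvedModel:
    res = ResolutionParams(amp=1.0, omega0=0.0, sigma=3.4, xi=2.77, bg=0.0)
    params = QensModelParams(p0=0.45, a=1.3, tau=18.0, d=7.6e-4,
                             s=0.0, t=0.01, scale=(20.0,))

    def _evaluator(self, span=400.0, step=0.5):
        omega = np.arange(-span, span + step / 2, step)
        return omega, ConvolvedQensModel(1.67, omega, self.res)

    def test_pure_elastic_is_scaled_resolution(self):
        omega, ev = self._evaluator()
        par = dataclasses.replace(self.params, p0=1.0)
        out = ev.intensity(par)
        expected = 20.0 * ev._res_elastic + 0.01
        assert np.allclose(out, expected, rtol=0, atol=1e-12)

    def test_narrow_lorentzian_recovers_elastic(self):
        omega, ev = self._evaluator()
        out = ev.intensity(self.params, gamma=1e-4)
        elastic = ev.intensity(dataclasses.replace(self.params, p0=1.0))
        assert np.max(np.abs(out - elastic)) < 1e-4 * elastic.max()

    @pytest.mark.parametrize("gamma", [0.5, 5.0, 20.0])
    def test_area_conservation(self, gamma):
        omega, ev = self._evaluator()
        out = ev.intensity(self.params, gamma=gamma)
        bg_area = 0.01 * (omega[-1] - omega[0])
        assert np.trapezoid(out, omega) - bg_area == pytest.approx(20.0, rel=0.01)

    def test_scale_linearity(self):
        omega, ev = self._evaluator(span=100, step=1.0)
        one = ev.intensity(self.params, scale=1.0)
        five = ev.intensity(self.params, scale=5.0)
        bg = 0.01
        assert np.allclose(five, 5.0 * (one - bg) + bg, rtol=1e-12, atol=1e-12)

    def test_nonuniform_grid_rejected(self):
        omega = np.array([-10.0, -5.0, -1.0, 0.0, 5.0, 10.0])
        with pytest.raises(GridError):
            qens_model_intensity(1.0, omega, self.params, self.res)

    def test_offcenter_resolution_warns(self):
        omega = np.linspace(-40, 40, 81)
        shifted = dataclasses.replace(self.res, omega0=90.0)
        with pytest.warns(UserWarning, match="resolution center"):
            ConvolvedQensModel(1.0, omega, shifted)
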