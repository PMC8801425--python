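"""QENS analysis: resolution fits, the global fit and the chi^2 convention."""

import dataclasses

import numpy as np
import pytest

from incoscat.exceptions import ParameterError
from incoscat.models import HBAR_UEV_PS, ResolutionParams
from incoscat.qens import (QensDataset, QensSpectrum, chi_squared,
                           compare_width_models, fit_resolution, global_fit)
from incoscat.synthetic import (default_resolution, generate_qens_dataset,
                                generate_vanadium_spectrum, qens_truth_preset)


def spectrum(q, omega, intensity, error):
    return QensSpectrum(q=q, omega=omega, intensity=np.asarray(intensity, float),
                        error=np.asarray(error, float))


class TestChiSquared:
    def test_perfect_model_is_zero(self):
        w = np.linspace(-5, 5, 11)
        specs = tuple(spectrum(q, w, np.ones(11), np.full(11, 0.1))
                      for q in (0.5, 1.0))
        data = QensDataset(spectra=specs)
        assert chi_squared(data, [np.ones(11), np.ones(11)]) == 0.0

    def test_hand_sum(self):
        # 2 Q values, 3 points each, every residual equal to sigma -> 6/(2-1)
        w = np.array([-1.0, 0.0, 1.0])
        specs = tuple(spectrum(q, w, [1.0, 2.0, 1.0], [0.2, 0.3, 0.2])
                      for q in (0.5, 1.5))
        data = QensDataset(spectra=specs)
        model = [s.intensity - s.error for s in data.spectra]
        assert chi_squared(data, model) == pytest.approx(6.0)

    def test_quadratic_in_standardized_residuals(self):
        w = np.linspace(-2, 2, 5)
        rng = np.random.default_rng(1)
        base = [spectrum(q, w, rng.normal(1, 0.1, 5), np.full(5, 0.1))
                for q in (0.5, 1.0, 2.0)]
        model = [np.ones(5)] * 3
        c1 = chi_squared(QensDataset(spectra=tuple(base)), model)
        doubled = tuple(dataclasses.replace(s, error=2 * s.error) for s in base)
        c2 = chi_squared(QensDataset(spectra=doubled), model)
        assert c2 == pytest.approx(c1 / 4.0)

    def test_single_q_rejected(self):
        w = np.linspace(-2, 2, 5)
        data = QensDataset(spectra=(spectrum(1.0, w, np.ones(5), np.ones(5)),))
        with pytest.raises(ParameterError):
            chi_squared(data, [np.ones(5)])


class TestResolutionFit:
    def test_noiseless_recovery(self):
        truth = ResolutionParams(amp=1.3, omega0=0.4, sigma=3.4, xi=2.77, bg=0.02)
        vana = generate_vanadium_spectrum({1.67: truth}, noise=0.0, seed=0)
        fit = fit_resolution(vana)[1.67]
        for name in ("amp", "sigma", "xi", "bg"):
            assert getattr(fit, name) == pytest.approx(getattr(truth, name),
                                                       rel=1e-4, abs=1e-6)
        assert fit.omega0 == pytest.approx(0.4, abs=1e-4)

    def test_published_asymmetry_recovered_under_noise(self):
        truth = default_resolution(xi=2.77)
        vana = generate_vanadium_spectrum({1.67: truth}, noise=0.0075, seed=4)
        fit = fit_resolution(vana)[1.67]
        assert fit.xi == pytest.approx(2.77, abs=0.3)

    def test_symmetric_peak_yields_small_xi(self):
        truth = default_resolution(xi=0.0)
        vana = generate_vanadium_spectrum({1.0: truth}, noise=0.005, seed=2)
        fit = fit_resolution(vana)[1.0]
        assert fit.xi < 0.05

    def test_too_few_points_rejected(self):
        w = np.linspace(-10, 10, 10)
        data = QensDataset(spectra=(spectrum(1.0, w, np.ones(10), np.ones(10)),))
        with pytest.raises(ParameterError, match="15"):
            fit_resolution(data)


class TestGlobalFit:
    def test_noiseless_exact_recovery(self):
        truth = qens_truth_preset("LP60", noise=0.0)
        data = generate_qens_dataset(truth, seed=1)
        fit = global_fit(data, n_starts=1)
        assert fit.chi2 < 1e-6
        assert fit.params.p0 == pytest.approx(0.45, abs=1e-4)
        assert fit.params.a == pytest.approx(1.3, abs=1e-3)
        assert fit.params.tau == pytest.approx(18.0, abs=0.05)
        assert fit.params.d_1e8_cm2_s == pytest.approx(7.6, abs=1e-3)

    def test_scale_equivariance(self):
        truth = qens_truth_preset("LP27", noise=0.02, n_omega=81)
        data = generate_qens_dataset(truth, seed=9)
        k = 3.0
        scaled = QensDataset(
            spectra=tuple(dataclasses.replace(s, intensity=k * s.intensity,
                                              error=k * s.error)
                          for s in data.spectra),
            temperature=data.temperature, resolution=data.resolution)
        f1 = global_fit(data, n_starts=1)
        f2 = global_fit(scaled, n_starts=1)
        assert f2.params.p0 == pytest.approx(f1.params.p0, abs=1e-5)
        assert f2.params.d == pytest.approx(f1.params.d, rel=1e-4)
        assert np.allclose(np.array(f2.params.scale),
                           k * np.array(f1.params.scale), rtol=1e-4)
        assert f2.chi2 == pytest.approx(f1.chi2, rel=1e-6)

    def test_chi2_scales_like_point_count(self):
        """Correctly specified noise gives chi^2 near M*N/(N-1)."""
        truth = qens_truth_preset("LP60", noise=0.02, n_omega=81)
        chis = []
        for seed in range(5):
            data = generate_qens_dataset(truth, seed=300 + seed)
            chis.append(global_fit(data, n_starts=1).chi2)
        n, m = 10, 81
        expected = m * n / (n - 1)
        assert np.mean(chis) == pytest.approx(expected, rel=0.1)

    def test_pure_elastic_truth_flags_degeneracy(self):
        truth = qens_truth_preset("LP60", noise=0.01, n_omega=81)
        truth = dataclasses.replace(
            truth, params=dataclasses.replace(truth.params, p0=1.0))
        data = generate_qens_dataset(truth, seed=3)
        fit = global_fit(data, n_starts=1)
        assert fit.params.p0 > 0.99
        assert "width_unidentifiable" in fit.flags

    def test_requires_three_q_values(self):
        truth = qens_truth_preset("LP60", noise=0.01, q_values=(0.5, 1.67))
        data = generate_qens_dataset(truth, seed=1)
        with pytest.raises(ParameterError):
            global_fit(data)

    def test_requires_resolution(self):
        truth = qens_truth_preset("LP60", noise=0.01, n_omega=81)
        data = generate_qens_dataset(truth, seed=1)
        bare = QensDataset(spectra=data.spectra, temperature=data.temperature)
        with pytest.raises(ParameterError):
            global_fit(bare)


class TestWidthLawComparison:
    def test_jump_diffusion_truth_prefers_jump_diffusion(self):
        truth = qens_truth_preset("LP27", noise=0.02, n_omega=81)
        data = generate_qens_dataset(truth, seed=21)
        cmp = compare_width_models(data, n_starts=1)
        assert cmp.preferred == "jump_diffusion"
        assert cmp.chi2_ratio > 1.0

    def test_constant_width_truth_not_beaten_by_jump_diffusion(self):
        from incoscat.models import ConvolvedQensModel

        truth = qens_truth_preset("LP27", noise=0.02, n_omega=81)
        resmap = truth.resolution_map()
        omega = np.linspace(-80, 85, 81)
        gamma = HBAR_UEV_PS / 30.0
        rng = np.random.default_rng(8)
        specs = []
        for q in truth.q_values:
            ev = ConvolvedQensModel(q, omega, resmap[q])
            m = ev.intensity(truth.params, scale=20.0, gamma=gamma)
            s = np.maximum(0.02 * np.sqrt(np.clip(m, 0, None)), 1e-12)
            specs.append(spectrum(q, omega, m + rng.normal(size=m.size) * s, s))
        data = QensDataset(spectra=tuple(specs), resolution=resmap)
        cmp = compare_width_models(data, n_starts=1)
        assert cmp.constant_width.chi2 <= cmp.jump_diffusion.chi2 * 1.01

    def test_constant_width_fit_recovers_correlation_time(self):
        from incoscat.models import ConvolvedQensModel

        truth = qens_truth_preset("LP60", noise=0.0, n_omega=81)
        resmap = truth.resolution_map()
        omega = np.linspace(-80, 85, 81)
        tau = 30.0
        specs = []
        for q in truth.q_values:
            ev = ConvolvedQensModel(q, omega, resmap[q])
            m = ev.intensity(truth.params, scale=20.0, gamma=HBAR_UEV_PS / tau)
            specs.append(spectrum(q, omega, m, np.ones_like(m)))
        data = QensDataset(spectra=tuple(specs), resolution=resmap)
        fit = global_fit(data, width_law="constant_width", n_starts=1)
        assert fit.model_tag == "constant_width"
        assert fit.tau_corr == pytest.approx(tau, rel=1e-3)
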