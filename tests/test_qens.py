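"""QENS fitting: resolution-convolved Lorentzians, Q-law fits and Arrhenius
activation energies."""

import numpy as np
import pytest

from confokit import qens, simulate
from confokit.qens import (HBAR_UEV_PS, LorentzianFitResult, QENSSpectrum,
                           arrhenius_fit, convolve_resolution, fit_global_diffusion,
                           fit_internal_dynamics, fit_spectrum, lorentzian)

ENERGY = np.arange(-100.0, 100.2, 0.4)
RESOLUTION = simulate.gaussian_resolution(ENERGY, 3.4)


def make_spectrum(g_narrow, g_broad, a1=0.6, a2=0.4, bg=0.002, slope=0.0,
                  noise_rel=0.0, seed=0, q=1.0, t=300.0):
    clean = convolve_resolution(
        ENERGY, lambda e: a1 * lorentzian(e, g_narrow) + a2 * lorentzian(e, g_broad),
        RESOLUTION) + bg + slope * ENERGY
    rng = np.random.default_rng(seed)
    if noise_rel > 0:
        y = clean * (1 + noise_rel * rng.normal(size=clean.size))
        s = noise_rel * np.abs(clean)
    else:
        y, s = clean, np.full_like(clean, 1e-6 * clean.max())
    return QENSSpectrum(q=q, temperature=t, energy=ENERGY, intensity=y,
                        sigma=s, resolution=RESOLUTION)


class TestFitSpectrum:
    def test_noiseless_single_lorentzian(self):
        spec = make_spectrum(2.0, 20.0, a2=0.0)
        fit = fit_spectrum(spec)
        dominant = (fit.gamma_narrow if fit.amp_narrow > fit.amp_broad
                    else fit.gamma_broad)
        assert dominant == pytest.approx(2.0, rel=0.01)

    def test_two_lorentzians_with_noise(self):
        spec = make_spectrum(2.0, 20.0, noise_rel=0.01, seed=1)
        fit = fit_spectrum(spec)
        assert fit.gamma_narrow == pytest.approx(2.0, rel=0.05)
        assert fit.gamma_broad == pytest.approx(20.0, rel=0.05)
        assert not fit.collapsed

    def test_noiseless_residuals_negligible(self):
        spec = make_spectrum(1.5, 15.0)
        fit = fit_spectrum(spec)
        model_peak = spec.intensity.max()
        recon = convolve_resolution(
            ENERGY, lambda e: (fit.amp_narrow * lorentzian(e, fit.gamma_narrow)
                               + fit.amp_broad * lorentzian(e, fit.gamma_broad)),
            RESOLUTION) + fit.bg_offset + fit.bg_slope * ENERGY
        assert np.max(np.abs(recon - spec.intensity)) < 1e-6 * model_peak

    def test_invariance_to_intensity_rescaling(self):
        spec = make_spectrum(2.0, 20.0, noise_rel=0.01, seed=2)
        scaled = QENSSpectrum(q=spec.q, temperature=spec.temperature,
                              energy=spec.energy, intensity=10 * spec.intensity,
                              sigma=10 * spec.sigma, resolution=spec.resolution)
        f1, f2 = fit_spectrum(spec), fit_spectrum(scaled)
        assert f2.gamma_narrow == pytest.approx(f1.gamma_narrow, rel=1e-3)
        assert f2.gamma_broad == pytest.approx(f1.gamma_broad, rel=1e-3)

    def test_narrow_range_rejected(self):
        e = np.arange(-30.0, 30.2, 0.4)
        res = simulate.gaussian_resolution(e, 3.4)
        spec = QENSSpectrum(q=1.0, temperature=300.0, energy=e,
                            intensity=np.ones_like(e), sigma=np.ones_like(e),
                            resolution=res)
        with pytest.raises(ValueError):
            fit_spectrum(spec)


def _fake_results(gammas, q_values, t=300.0, narrow=True):
    return [LorentzianFitResult(
        q=q, temperature=t,
        gamma_narrow=g if narrow else 0.1, gamma_broad=g if not narrow else 99.0,
        amp_narrow=1, amp_broad=1, bg_offset=0, bg_slope=0,
        gamma_narrow_err=0.01 * g if narrow else 0.01,
        gamma_broad_err=0.01 * g if not narrow else 1.0,
        redchi=1.0, success=True) for q, g in zip(q_values, gammas)]


class TestQLaws:
    def test_exact_q_squared_law(self):
        q = np.array([0.7, 0.9, 1.1, 1.3, 1.5])
        fit = fit_global_diffusion(_fake_results(2.0 * q**2, q))
        assert fit.diffusivity == pytest.approx(2.0, rel=1e-12)

    def test_diffusivity_linearity(self):
        q = np.array([0.7, 1.0, 1.3])
        d1 = fit_global_diffusion(_fake_results(1.5 * q**2, q)).diffusivity
        d2 = fit_global_diffusion(_fake_results(3.0 * q**2, q)).diffusivity
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_noisy_diffusivity_recovery(self):
        rng = np.random.default_rng(3)
        q = np.array([0.7, 0.9, 1.1, 1.3, 1.5])
        g = 1.5 * q**2 * (1 + 0.03 * rng.normal(size=q.size))
        assert fit_global_diffusion(_fake_results(g, q)).diffusivity == \
            pytest.approx(1.5, rel=0.05)

    def test_negative_slope_unphysical(self):
        q = np.array([0.7, 1.0, 1.3])
        with pytest.raises(ValueError):
            fit_global_diffusion(_fake_results(-(2.0 * q**2), q))

    def test_exact_power_law(self):
        q = np.array([0.7, 0.9, 1.1, 1.3, 1.5])
        fit = fit_internal_dynamics(_fake_results(12.0 * q**1.8, q,
                                                  narrow=False))
        assert fit.rate == pytest.approx(12.0, rel=1e-9)
        assert fit.alpha == pytest.approx(1.8, abs=1e-9)

    def test_rate_to_relaxation_time(self):
        q = np.array([0.7, 1.0, 1.3])
        fit = fit_internal_dynamics(_fake_results(12.0 * q**1.8, q,
                                                  narrow=False))
        assert fit.tau0_ps == pytest.approx(HBAR_UEV_PS / 12.0, rel=1e-9)
        assert fit.tau0_ps == pytest.approx(54.85, abs=0.01)

    def test_q_independent_rate(self):
        q = np.array([0.7, 1.0, 1.3])
        fit = fit_internal_dynamics(_fake_results(np.full(3, 7.0), q,
                                                  narrow=False))
        assert fit.rate == pytest.approx(7.0, rel=1e-9)
        assert fit.alpha == pytest.approx(0.0, abs=1e-9)


class TestArrhenius:
    def test_two_point_closed_form(self):
        fit = arrhenius_fit([1.0, 2.0], [280.0, 310.0])
        expected = 8.314 * np.log(2) / (1 / 280 - 1 / 310) / 1000
        assert fit.activation_energy == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(16.7, abs=0.1)

    def test_flat_rates_zero_energy(self):
        fit = arrhenius_fit([3.0, 3.0, 3.0, 3.0], [280, 290, 300, 310])
        assert fit.activation_energy == pytest.approx(0.0, abs=1e-9)

    def test_recovery_under_noise_replicates(self):
        rng = np.random.default_rng(4)
        t = np.array([280.0, 290.0, 300.0, 310.0])
        truth = 8.2
        rates0 = 289.1 * np.exp(-truth * 1000 / (8.314 * t))
        recovered = np.array(
            [arrhenius_fit(rates0 * (1 + 0.03 * rng.normal(size=4)),
                           t).activation_energy
             for _ in range(100)])
        # unbiased, and the rms error sits inside the quoted ±1.5 band
        assert abs(recovered.mean() - truth) < 0.5
        assert np.sqrt(np.mean((recovered - truth) ** 2)) < 1.5

    def test_non_positive_values_rejected(self):
        with pytest.raises(ValueError):
            arrhenius_fit([1.0, -2.0], [280.0, 310.0])


class TestChain:
    def test_gamma_over_q_squared_constant(self):
        cfg = simulate.QENSSimConfig(temperatures=[300.0], noise_rel=0.01,
                                     seed=5)
        spectra, truth = simulate.simulate_qens(cfg)
        fits = [fit_spectrum(s) for s in spectra]
        ratios = np.array([f.gamma_narrow / f.q**2 for f in fits])
        d = truth["diffusivity"][300.0]
        assert np.all(np.abs(ratios - d) < 0.15 * d)

    def test_activation_energy_recovery_full_chain(self):
        spectra, truth = simulate.simulate_qens(simulate.QENSSimConfig(seed=6))
        res = qens.analyze_temperature_series(spectra)
        assert abs(res["arrhenius_global"].activation_energy
                   - truth["ea_global"]) < 1.0
        assert abs(res["arrhenius_internal"].activation_energy
                   - truth["ea_internal"]) < 1.5
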