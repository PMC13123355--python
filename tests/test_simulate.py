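"""Generator-level checks: each synthetic module must invert its analysis
model exactly in the noiseless limit and carry usable ground truth."""

import numpy as np
import pytest

from confokit import simulate
from confokit.simulate import (BeadModel, FretSimConfig, MeltSimConfig,
                               QENSSimConfig, debye_intensity)


class TestFretGenerator:
    def test_single_state_half_efficiency_gives_equal_channels(self):
        cfg = FretSimConfig(state_means=[0.5], rate_matrix=np.zeros((1, 1)),
                            noise_sd=0.0, bleach_rate=0.0, n_traces=2,
                            n_frames_max=50, seed=0)
        for tr in simulate.simulate_fret_traces(cfg):
            np.testing.assert_allclose(tr.donor, tr.acceptor)

    def test_zero_rates_freeze_initial_state(self):
        cfg = FretSimConfig(state_means=[0.3, 0.7],
                            rate_matrix=np.zeros((2, 2)), noise_sd=0.0,
                            bleach_rate=0.0, n_traces=10, n_frames_max=100,
                            seed=1)
        for tr in simulate.simulate_fret_traces(cfg):
            assert np.unique(tr.truth_states).size == 1
            np.testing.assert_allclose(tr.truth_efficiency,
                                       tr.truth_efficiency[0])

    def test_per_state_mean_efficiency_matches_truth(self):
        # oracle: average observed E over frames with known true state
        cfg = FretSimConfig(noise_sd=50.0, bleach_rate=0.0, n_traces=200,
                            n_frames_max=300, seed=2)
        traces = simulate.simulate_fret_traces(cfg)
        e_obs = np.concatenate(
            [tr.acceptor / (tr.donor + tr.acceptor) for tr in traces])
        states = np.concatenate([tr.truth_states for tr in traces])
        for k, mean in enumerate(cfg.state_means):
            assert abs(e_obs[states == k].mean() - mean) < 0.01

    def test_transition_counts_match_rate_matrix(self):
        # empirical jump frequency over long traces ~ rate * frame_time
        q = simulate.uniform_rate_matrix(4, leave_rate=0.5)
        cfg = FretSimConfig(rate_matrix=q, noise_sd=0.0, bleach_rate=0.0,
                            n_traces=30, n_frames_max=2000, seed=3)
        traces = simulate.simulate_fret_traces(cfg)
        states = np.concatenate([tr.truth_states for tr in traces])
        jumps = np.count_nonzero(np.diff(states) != 0)
        expected = 0.5 * cfg.frame_time * states.size
        assert abs(jumps - expected) < 4 * np.sqrt(expected)

    def test_non_stochastic_rate_matrix_rejected(self):
        with pytest.raises(ValueError):
            FretSimConfig(rate_matrix=np.array([[0.0, -1.0], [1.0, 0.0]]))

    def test_reproducible_under_seed(self):
        a = simulate.simulate_fret_traces(FretSimConfig(n_traces=3, seed=9))
        b = simulate.simulate_fret_traces(FretSimConfig(n_traces=3, seed=9))
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.donor, tb.donor)
            np.testing.assert_array_equal(ta.acceptor, tb.acceptor)

    def test_occupancy_helper_has_requested_stationary_distribution(self):
        pi = np.array([0.267, 0.349, 0.246, 0.139])
        q = simulate.rate_matrix_from_occupancies(pi)
        np.testing.assert_allclose(simulate.stationary_distribution(q),
                                   pi / pi.sum(), atol=1e-10)


class TestQENSGenerator:
    def test_unit_area_preserved_under_convolution(self):
        cfg = QENSSimConfig(noise_rel=0.0, amp_broad=0.0, bg_offset=0.0,
                            bg_slope=0.0, temperatures=[300.0],
                            q_values=[1.0], seed=0)
        spectra, _ = simulate.simulate_qens(cfg)
        area = np.trapezoid(spectra[0].intensity, spectra[0].energy)
        # ±100 μeV truncates ~(2/π)(Γ/E_max) of the Lorentzian tails
        assert abs(area - cfg.amp_narrow) < 0.02 * cfg.amp_narrow

    def test_narrow_width_follows_q_squared(self):
        cfg = QENSSimConfig(temperatures=[300.0],
                            q_values=[1.0, np.sqrt(2.0)], seed=0)
        _, truth = simulate.simulate_qens(cfg)
        g1 = truth["gamma_narrow"][(300.0, 1.0)]
        g2 = truth["gamma_narrow"][(300.0, float(np.sqrt(2.0)))]
        assert g2 / g1 == pytest.approx(2.0, rel=1e-12)

    def test_arrhenius_rates_exactly_collinear(self):
        cfg = QENSSimConfig(seed=0)
        _, truth = simulate.simulate_qens(cfg)
        t = np.array(sorted(truth["internal_rate"]))
        logr = np.log([truth["internal_rate"][tt] for tt in t])
        resid = np.polyval(np.polyfit(1.0 / t, logr, 1), 1.0 / t) - logr
        assert np.max(np.abs(resid)) < 1e-12

    def test_noiseless_spectra_symmetric_up_to_background(self):
        cfg = QENSSimConfig(noise_rel=0.0, bg_slope=0.0, temperatures=[300.0],
                            q_values=[1.0], seed=0)
        spectra, _ = simulate.simulate_qens(cfg)
        s = spectra[0]
        np.testing.assert_allclose(s.intensity, s.intensity[::-1], rtol=1e-9)

    def test_coarse_energy_grid_rejected(self):
        with pytest.raises(ValueError, match="coarse"):
            QENSSimConfig(energy_grid=np.arange(-100.0, 101.0, 1.0))


class TestDebye:
    def test_single_bead_is_flat(self):
        m = BeadModel("one", [[0.0, 0.0, 0.0]])
        np.testing.assert_allclose(debye_intensity(m, [0.0, 0.1, 0.4]), 1.0)

    def test_two_bead_closed_form(self):
        d = 10.0
        m = BeadModel("two", [[0, 0, 0], [0, 0, d]])
        q = np.array([0.0, 0.05, 0.2, 0.45])
        expected = np.where(q > 0, 2 * (1 + np.sin(q * d) / (q * d + 1e-300)),
                            4.0)
        np.testing.assert_allclose(debye_intensity(m, q), expected, rtol=1e-9)

    def test_sphere_guinier_radius(self):
        from confokit.sas import guinier_fit
        radius = 61.5
        model = simulate.bead_sphere(radius, spacing=14.0)   # ~70 beads
        assert model.coordinates.shape[0] >= 64
        curve = simulate.debye_curve(model, np.linspace(0.004, 0.2, 200))
        fit = guinier_fit(curve)
        assert fit.rg == pytest.approx(radius * np.sqrt(3 / 5), rel=0.03)

    def test_monotone_over_guinier_region(self, sphere_curve):
        curve, radius = sphere_curve
        rg = radius * np.sqrt(3 / 5)
        low = curve.q < 1.3 / rg
        assert np.all(np.diff(curve.intensity[low]) < 0)


class TestSasMixture:
    def test_single_curve_identity(self, oligomer_curves):
        c = oligomer_curves["monomer"]
        mix = simulate.simulate_sas_mixture([c], [1.0], noise_rel=0.0)
        np.testing.assert_allclose(mix.intensity, c.intensity)

    def test_equal_mix_of_identical_curves(self, oligomer_curves):
        c = oligomer_curves["dimer"]
        mix = simulate.simulate_sas_mixture([c, c], [0.5, 0.5], noise_rel=0.0)
        np.testing.assert_allclose(mix.intensity, c.intensity, rtol=1e-12)

    def test_nnls_recovers_mixture_weights(self, oligomer_curves):
        from confokit.sas import nnls_weights
        basis = list(oligomer_curves.values())
        truth = np.array([0.821, 0.037, 0.037, 0.105])
        mix = simulate.simulate_sas_mixture(basis, truth, noise_rel=0.01,
                                            seed=4)
        w, _, _ = nnls_weights(basis, mix)
        np.testing.assert_allclose(w, truth, atol=0.03)

    def test_mismatched_grids_rejected(self, oligomer_curves):
        c = oligomer_curves["monomer"]
        other = simulate.debye_curve(simulate.BeadModel("x", [[0, 0, 0]]),
                                     np.linspace(0.01, 0.3, 50))
        with pytest.raises(ValueError):
            simulate.simulate_sas_mixture([c, other], [0.5, 0.5])


class TestMeltGenerator:
    def test_midpoint_at_tm(self):
        cfg = MeltSimConfig(tm=55.0, noise_sd=0.0,
                            temp_range=np.arange(20.0, 90.5, 0.5))
        curve = simulate.simulate_melt_curve(cfg)
        idx = np.argmin(np.abs(curve.temperature - 55.0))
        assert curve.fluorescence[idx] == pytest.approx(
            0.5 * (cfg.f_min + cfg.f_max), rel=1e-9)

    def test_small_slope_approaches_step(self):
        cfg = MeltSimConfig(tm=55.0, slope=0.05, noise_sd=0.0)
        f = simulate.simulate_melt_curve(cfg).fluorescence
        t = cfg.temp_range
        assert np.all(np.abs(f[t < 54.0] - cfg.f_min) < 1e-6)
        assert np.all(np.abs(f[t > 56.0] - cfg.f_max) < 1e-6)

    def test_refit_recovers_tm(self):
        from confokit.thermal import fit_boltzmann
        curve = simulate.simulate_melt_curve(MeltSimConfig(tm=55.0, seed=11))
        assert fit_boltzmann(curve).tm == pytest.approx(55.0, abs=0.2)
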