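"""Scattering-curve analysis: Guinier, P(r), NNLS and GA ensemble selection."""

from itertools import combinations

import numpy as np
import pytest

from confokit import simulate
from confokit.sas import (ScatteringCurve, ga_select, guinier_fit,
                          nnls_weights, pr_transform)


class TestGuinier:
    def test_exact_guinier_law(self):
        rg, i0 = 40.0, 1000.0
        q = np.linspace(0.002, 0.05, 100)
        i = i0 * np.exp(-(rg * q) ** 2 / 3)
        fit = guinier_fit(ScatteringCurve(q, i, 0.01 * i))
        assert fit.rg == pytest.approx(rg, rel=1e-6)
        assert fit.i0 == pytest.approx(i0, rel=1e-6)
        assert fit.qmax_rg <= 1.3 + 1e-9

    def test_sphere_radius_relation(self, sphere_curve):
        curve, radius = sphere_curve
        fit = guinier_fit(curve)
        assert fit.rg == pytest.approx(radius * np.sqrt(3 / 5), rel=0.03)

    def test_scale_invariance(self, sphere_curve):
        curve, _ = sphere_curve
        scaled = ScatteringCurve(curve.q, 10 * curve.intensity,
                                 10 * curve.sigma)
        f1, f2 = guinier_fit(curve), guinier_fit(scaled)
        assert f2.rg == pytest.approx(f1.rg, rel=1e-9)
        assert f2.i0 == pytest.approx(10 * f1.i0, rel=1e-9)

    def test_rising_low_q_rejected(self):
        q = np.linspace(0.002, 0.05, 50)
        i = 1 + (q / 0.05) ** 2
        with pytest.raises(ValueError):
            guinier_fit(ScatteringCurve(q, i, 0.01 * i))


class TestPr:
    def test_two_bead_mode_at_separation(self):
        d = 10.0
        model = simulate.BeadModel("pair", [[0, 0, 0], [0, 0, d]])
        curve = simulate.debye_curve(model, np.linspace(0.02, 0.8, 200))
        pr = pr_transform(curve, dmax=14.0)
        mask = pr.r > d / 2          # ignore the bead self-term near r = 0
        assert pr.r[mask][np.argmax(pr.pr[mask])] == pytest.approx(d, abs=1.0)

    def test_sphere_rg_moment(self, sphere_curve):
        curve, radius = sphere_curve
        pr = pr_transform(curve, dmax=2.1 * radius)
        assert pr.rg == pytest.approx(radius * np.sqrt(3 / 5), rel=0.03)

    def test_guinier_and_pr_rg_agree(self, sphere_curve):
        curve, radius = sphere_curve
        g = guinier_fit(curve)
        p = pr_transform(curve, dmax=2.1 * radius)
        assert p.rg == pytest.approx(g.rg, rel=0.03)

    def test_chi2_monotone_in_regularization(self, sphere_curve):
        from confokit.sas import _pr_solve
        curve, radius = sphere_curve
        chis = [_pr_solve(curve, 2.1 * radius, 101, lam)[2]
                for lam in (1e-4, 1e-1, 1e2, 1e5)]
        assert all(np.diff(chis) >= -1e-9)

    def test_endpoints_pinned_to_zero(self, sphere_curve):
        curve, radius = sphere_curve
        pr = pr_transform(curve, dmax=2.1 * radius)
        assert pr.pr[0] == 0.0 and pr.pr[-1] == 0.0


class TestNnls:
    def test_self_fit(self, oligomer_curves):
        c = oligomer_curves["monomer"]
        target = simulate.simulate_sas_mixture([c], [1.0], noise_rel=0.0)
        w, scale, chi = nnls_weights([c], target)
        assert w[0] == pytest.approx(1.0, rel=1e-9)
        assert chi < 1e-6

    def test_even_mixture_recovered_exactly(self, oligomer_curves):
        basis = [oligomer_curves["monomer"], oligomer_curves["tetramer"]]
        target = simulate.simulate_sas_mixture(basis, [0.5, 0.5],
                                               noise_rel=0.0)
        w, _, _ = nnls_weights(basis, target)
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-6)

    def test_wrong_basis_has_large_misfit(self, oligomer_curves):
        target = simulate.simulate_sas_mixture(
            [oligomer_curves["tetramer"]], [1.0], noise_rel=0.01, seed=1)
        _, _, chi = nnls_weights([oligomer_curves["monomer"]], target)
        assert chi > 100

    def test_weighted_residual_orthogonal_to_active_members(self,
                                                            oligomer_curves):
        basis = list(oligomer_curves.values())
        target = simulate.simulate_sas_mixture(
            basis, [0.7, 0.1, 0.1, 0.1], noise_rel=0.01, seed=2)
        w, scale, _ = nnls_weights(basis, target)
        resid = (target.intensity
                 - scale * np.sum([wk * c.intensity
                                   for wk, c in zip(w, basis)], axis=0))
        for wk, c in zip(w, basis):
            if wk > 1e-9:
                dot = np.sum(resid * c.intensity / target.sigma**2)
                norm = np.linalg.norm(resid / target.sigma) * \
                    np.linalg.norm(c.intensity / target.sigma)
                assert abs(dot) / norm < 1e-8


class TestGa:
    def test_single_member_target(self, oligomer_curves):
        pool = list(oligomer_curves.values())
        target = simulate.simulate_sas_mixture([oligomer_curves["dimer"]],
                                               [1.0], noise_rel=0.0)
        sol = ga_select(pool, target, n_max=2, generations=20, iterations=2,
                        seed=0)
        # the true member carries all the weight; any extra slot is inert
        assert sol.class_fractions["dimer"] == pytest.approx(1.0, abs=1e-6)
        assert sol.redchi < 1e-6

    def test_pool_too_small_rejected(self, oligomer_curves):
        target = simulate.simulate_sas_mixture(
            [oligomer_curves["monomer"]], [1.0], noise_rel=0.0)
        with pytest.raises(ValueError):
            ga_select(list(oligomer_curves.values())[:2], target, n_max=3)

    def test_matches_exhaustive_enumeration(self, oligomer_curves):
        basis = list(oligomer_curves.values())
        rng = np.random.default_rng(7)
        target = simulate.simulate_sas_mixture(
            basis, [0.821, 0.037, 0.037, 0.105], noise_rel=0.01, seed=rng)
        pool = basis + [simulate.debye_curve(m, target.q)
                        for m in simulate.decoy_pool(seed=rng)][:8]
        sol = ga_select(pool, target, n_max=3, seed=11)

        from scipy.optimize import nnls as _nnls
        a = np.column_stack([c.intensity / target.sigma for c in pool])
        b = target.intensity / target.sigma
        best = np.inf
        for k in (1, 2, 3):
            for sub in combinations(range(len(pool)), k):
                _, rnorm = _nnls(a[:, list(sub)], b)
                best = min(best, rnorm**2 / (target.q.size - k))
        assert sol.redchi == pytest.approx(best, rel=1e-9)

    def test_deterministic_under_seed(self, oligomer_curves):
        basis = list(oligomer_curves.values())
        target = simulate.simulate_sas_mixture(
            basis, [0.8, 0.1, 0.05, 0.05], noise_rel=0.01, seed=3)
        s1 = ga_select(basis * 3, target, n_max=2, generations=10,
                       iterations=2, seed=5)
        s2 = ga_select(basis * 3, target, n_max=2, generations=10,
                       iterations=2, seed=5)
        assert s1.redchi == s2.redchi and s1.indices == s2.indices

    def test_class_fractions_sum_to_one(self, oligomer_curves):
        basis = list(oligomer_curves.values())
        target = simulate.simulate_sas_mixture(
            basis, [0.6, 0.2, 0.1, 0.1], noise_rel=0.01, seed=4)
        sol = ga_select(basis, target, n_max=4, generations=30, iterations=2,
                        seed=6)
        assert sum(sol.class_fractions.values()) == pytest.approx(1.0,
                                                                  abs=1e-6)
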