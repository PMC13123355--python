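#!/usr/bin/env python
"""Oligomeric composition in solution from small-angle scattering.

Builds Debye curves for monomer/dimer/trimer/tetramer bead models, mixes
them at the measured ensemble fractions (82.1/3.7/3.7/10.5 %) with 1 %
noise, then analyses the mixture three ways: iterative Guinier fit, P(r) by
regularized indirect Fourier transform, and minimal-ensemble decomposition
by genetic algorithm (N ≤ 5, 100 generations, 5 restarts) over a 24-member
candidate pool with NNLS weights.

Writes results/sas_guinier_pr.csv, results/sas_pr_curve.csv and
results/sas_ensemble.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from confokit import sas, simulate

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SEED = 2026

Q = np.linspace(0.002, 0.5, 501)
WEIGHTS = np.array([0.821, 0.037, 0.037, 0.105])


def main() -> None:
    rng = np.random.default_rng(SEED)
    models = simulate.default_oligomer_models()
    basis = [simulate.debye_curve(m, Q) for m in models.values()]
    target = simulate.simulate_sas_mixture(basis, WEIGHTS, noise_rel=0.01,
                                           seed=rng, label="mixture")

    g = sas.guinier_fit(target)
    dmax = 170.0      # tetramer diagonal (80√2 Å) plus two subunit radii
    pr = sas.pr_transform(target, dmax=dmax, n_r=151)
    print(f"Guinier: Rg = {g.rg:.1f} Å ({g.n_points} pts, "
          f"qmax·Rg = {g.qmax_rg:.2f})")
    print(f"P(r):    Rg = {pr.rg:.1f} Å (Dmax = {dmax:.0f} Å, "
          f"λ = {pr.reg_weight:.2e})")
    pd.DataFrame([{"guinier_rg_A": round(g.rg, 1),
                   "guinier_qmax_rg": round(g.qmax_rg, 2),
                   "pr_rg_A": round(pr.rg, 1), "pr_dmax_A": dmax,
                   "reg_weight": pr.reg_weight}]).to_csv(
        OUT / "sas_guinier_pr.csv", index=False)
    pd.DataFrame({"r_A": pr.r, "pr": pr.pr}).to_csv(
        OUT / "sas_pr_curve.csv", index=False)

    pool = basis + [simulate.debye_curve(m, Q)
                    for m in simulate.decoy_pool(seed=rng)]
    sol = sas.ga_select(pool, target, n_max=5, generations=100, iterations=5,
                        seed=rng)
    print(f"GA ensemble: χ²_red = {sol.redchi:.2f}, "
          f"{len(sol.members)} members")
    for name, frac in sorted(sol.class_fractions.items(),
                             key=lambda kv: -kv[1]):
        true = dict(zip(models, WEIGHTS)).get(name, float("nan"))
        print(f"  {name:9s} {100 * frac:5.1f} %  (generated at {100 * true:.1f} %)")
    with open(OUT / "sas_ensemble.json", "w") as fh:
        json.dump({"members": sol.members,
                   "weights": [float(w) for w in sol.weights],
                   "redchi": sol.redchi,
                   "class_fractions": sol.class_fractions,
                   "best_chi2_per_size": sol.size_scan}, fh, indent=2)


if __name__ == "__main__":
    main()
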