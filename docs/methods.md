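# Methods

This note documents the models behind each analysis stage, the synthetic
study conditions, the numerical choices, and what the parameter-recovery
tests do and do not demonstrate.

## smFRET

### Efficiency computation

`compute_fret` reports `E = I_A/(I_D + I_A)` per 100-ms frame after
background subtraction, up to the photobleaching point.  Bleaching is
detected as the first frame where the acceptor channel — or the summed
intensity — falls below 25 % of its trailing running median (21-frame
window) and stays low for 5 frames; a 2-frame guard before the detected
point is discarded because detection can lag the true bleach.  The trailing
(causal) median matters: a centred window is contaminated by the dark
frames it is meant to detect.

Backgrounds are estimated from genuinely dark frames only — the acceptor
after its bleach (skipping 3 guard frames), the donor after total-intensity
collapse.  Two earlier candidate recipes were rejected after measurement:
taking the modal bin of a channel's lowest intensity decile steals signal
in traces that never bleach, and selecting "dark" frames by thresholding
the summed intensity conditions the noise (E[noise | sum < c] < 0) and
shrinks every state mean by ~3 %.  For batch work, `traces_to_fret` pools
the per-trace estimates across molecules (median): the camera baseline is a
field property, and per-molecule estimates would add a correlated ±0.01–0.03
offset to each trace's efficiencies — enough to split states.  A channel
that never goes dark is assumed already baseline-subtracted.

### State identification

`stasi` implements change-point segmentation with minimum-description-length
model selection:

1. noise sd from Haar detail coefficients,
   `σ = MAD(ΔE)/0.6745/√2`, robust to the (sparse) true steps;
2. recursive binary splitting of each trace at the frame maximizing the
   two-sample *t* statistic, accepted while *t* exceeds the 99.9th
   percentile of the null *t* distribution for the segment length;
3. pooling of segments across traces and bottom-up Ward merging of their
   means (adjacent-in-mean merges, optimal in 1-D);
4. selection of the state count *m* minimizing

   `MDL(m) = Σ resid²/(2σ² ln 2) + (p/2)·log₂(n) + n_cp·log₂(m)`

   with `p = m + n_cp`, *n* the frame count and `n_cp` the number of
   boundaries between consecutive segments assigned to different states.

The `n_cp·log₂(m)` term is the code length of naming which state each dwell
visits.  It is essential: without it, splitting any state's cluster of
segment means along noise recovers ≈0.46 bits per segment while the extra
state costs only `½log₂(n)` bits, so the description length decreases
monotonically in *m* and no minimum exists in the multi-trace regime (we
verified this numerically before adding the term).

Segment statistics exclude up to two frames at each segment end.  A frame
during which the molecule switches states time-averages the two
efficiencies; left in place, these blurred frames seed spurious sub-states
±0.015 around each true mean.

### Histogram populations

`fit_fret_histogram` pools valid frames (equal per-frame weight) into 50
bins over [0, 1] and fits a sum of Gaussians with means fixed (by default)
to the state values, sds bounded in [0.01, 0.2], weights `1/√(counts+1)`.
Per-bin standard errors come from a bootstrap over molecules.

The mixture additionally contains a noise-smeared uniform **bridge**
component between each adjacent pair of state means, with free amplitude.
Transition frames land uniformly between the two state efficiencies (the
switch time is uniform within the frame), and without an explicit term this
mass drains population from edge states into mid-spectrum components
(measured ≈2 points on a 40 % state).  Each bridge's fitted mass is credited
half to each endpoint state, since the switching frame's occupancy splits
evenly on average.  Populations are the (bridge-corrected) component areas
normalized to 100 %.

### Förster relation

`R0 = 0.211·[κ² η⁻⁴ Q_D J]^(1/6)` Å with
`J = ∫F_D ε_A λ⁴ dλ / ∫F_D dλ` in M⁻¹cm⁻¹nm⁴, trapezoidal quadrature on the
common wavelength grid; `r = R0 (1/E − 1)^(1/6)`.  Displacements are
reported against the highest-FRET state (the inactive conformation, TM6
inward) by default and rounded to 0.1 Å.  With R0 = 54.8 Å, κ² = 2/3,
η = 1.4: E = 0.49 → Δr ≈ 10.8 Å; E = 0.33 → Δr ≈ 17.3 Å.

### Synthetic traces

Continuous-time Markov dynamics discretized at 100 ms frames; the per-frame
acceptor fraction is the occupancy-weighted mean of the state efficiencies,
so transition frames are genuinely blurred as in measurement.  Defaults:
state means 0.33/0.49/0.63/0.78; uniform exchange with 0.3 s⁻¹ state-exit
rate (dwells of seconds, well below the 10 s⁻¹ bound implied by the 100-ms
frame; molecules sample a few dwells per trace).  Occupancy-conditioned
runs use `rate_matrix_from_occupancies` (rates `q_ij = k·π_j`, detailed
balance for any target π) at `k = 2 s⁻¹`: at 94–154 molecules the sampling
noise of the realized occupancy dominates the population-recovery error and
scales with the number of independent dwells.  Intensities: total 1000
photons/frame; additive Gaussian channel noise sd 70 photons (≈0.05 in E at
mid-range; Poisson emission available but off by default, matching the
Gaussian histogram model downstream).  Photobleaching is single-step:
geometric acceptor bleach (0.005/frame) followed by donor-only emission and
a later donor bleach.

## QENS

Model: `S(Q,E) = R ⊗ [A₁L(Γ₁) + A₂L(Γ₂)] + a + bE`, L unit-area Lorentzian,
R the measured resolution (generator: Gaussian, 3.4 μeV FWHM).  Convolution
is discrete on the energy grid with edge padding by analytic evaluation of
the model on an extended grid, so there are no wrap-around artefacts; the
kernel is the resolution trimmed to support and normalized to unit sum.
Grids must provide ≥5 points per resolution FWHM; the generator default is
0.2 μeV channels over ±100 μeV (instrument-native binning for a 3.4 μeV
backscattering spectrometer).  At 0.4 μeV channels the recovered global
activation energy scattered with sd ≈0.45 kJ/mol, wider than the ±0.8
uncertainty the measurement itself supports; 0.2 μeV channels bring it to
≈0.3.

Components are identified by ordering Γ₁ < Γ₂ after the fit (lmfit
Levenberg–Marquardt, weights 1/σ); Γ₂/Γ₁ < 1.5 flags a collapsed fit.  No
elastic delta term is included by default (the two-component model is the
measurement model); an optional elastic term exists.  The Q² fit for D is
forced through the origin (`Γ = DQ²` has no intercept); a free-intercept
variant exists for diagnostics.  The internal-dynamics power law
`Γ = (1/τ₀)Q^α` is fit two ways: per temperature, and jointly with one
shared exponent α and per-temperature rates.  The Arrhenius line uses the
shared-α rates by default: the Q exponent reflects motion geometry and is
not expected to drift over a 30 K window, and per-temperature α estimates
correlate strongly with the rate intercept.  Activation energies come from
unweighted regression of ln X on 1/T; `Ea = −slope·R`, R = 8.314 J/(mol·K).
Unit anchor: `τ[ps] = 658.2/Γ[μeV]` (ħ = 658.2 μeV·ps); the power law is
dimensionally anchored at Q = 1 Å⁻¹.

Generator study conditions: T = {280, 290, 300, 310} K,
Q = {0.7, 0.9, 1.1, 1.3, 1.5} Å⁻¹, amplitudes 0.6/0.4, small linear
background, 3 % multiplicative Gaussian noise with σ = 0.03·I.  Arrhenius
anchors: D(310 K) = 3.5 Å²·μeV (≈5×10⁻⁷ cm²/s apparent diffusivity at high
protein concentration) with Ea = 21.1 kJ/mol; 1/τ₀(310 K) = 12 μeV
(τ₀ = 55 ps) with Ea = 8.2 kJ/mol; α = 1.8.

## Small-angle scattering

`guinier_fit` iterates window selection (weighted fit of ln I vs q²,
re-restricting to q ≤ 1.3/Rg) until Rg stabilizes within 1 %; upward low-q
curvature flags possible aggregation.  `pr_transform` solves the regularized
least-squares `min ‖(I − K·P)/σ‖² + λ‖P″‖²` with
`K_jk = 4πΔr·sinc(q_j r_k)` and hard endpoints P(0) = P(Dmax) = 0; λ defaults
to the maximum-curvature corner of the L-curve.  Rg and I(0) come from the
moments of P(r).

Ensemble decomposition: weights for any candidate subset come from exact
NNLS with one global scale (deterministic and reproducible — the subset, not
the weights, is the discrete search problem), reduced χ² uses `n_q − n_members`
degrees of freedom (a convention; stated because dof definitions vary).  The
GA evolves index subsets per ensemble size 1..5 with tournament selection
(size 3), uniform crossover with duplicate repair, 0.1 per-slot mutation,
population 64, elitism, 100 generations × 5 restarts; duplicates within an
individual are disallowed.  Subset fitness values are memoized, so the GA's
cost is dominated by the distinct subsets visited.

Bead fixtures: subunit = filled 25 Å sphere of grid beads (6 Å spacing);
dimer and tetramer place subunit surfaces 30 Å apart (detergent-mediated,
micelle-like organisation); the trimer is a compact touching triangle.  The
tetramer is a planar **square**, deliberately not a regular tetrahedron: a
cluster with a single inter-subunit distance d has
`I ∈ span{F(q), F(q)·sinc(dq)}`, exactly the span of the monomer and dimer
curves, making the species weights unidentifiable regardless of noise level
(monomer-fraction sd 2.1 % vs 0.9 % for the square).  The q grid for
ensemble work is 501 linear points over 0.002–0.5 Å⁻¹, matching the
standard theoretical-curve computation; mixtures carry 1 % multiplicative
noise with σ = 0.01·I.  Decoy candidates are conformer-scale perturbations
of each species (±10 % anisotropic scaling, 2 Å bead jitter), labeled by
parent species so class fractions aggregate correctly.  The Debye sum is
evaluated through a pair-distance histogram (0.5 Å bins, per-bin mean
distance), exact to (qΔr)²/24.

## Thermal shift

Boltzmann sigmoid fit by least squares; plateaus initialized from the
first/last decile means, Tm from the half-height crossing.  Descending
curves are auto-detected and fit with swapped plateaus; an optional upper
temperature cutoff excludes post-transition quench.  A curve whose decile
means differ by less than 3× the residual sd is rejected as transition-free.
Generator: 20–90 °C at 0.5 °C steps, slope 2 °C, plateau span 900 with
noise sd 9 (1 % of range); Tm anchors 55.0 / 59.7 / 59.5 °C per condition.

## Pipeline

`pipeline.run` executes configured stages in order with per-stage substreams
spawned from the global seed (`SeedSequence(seed, spawn_key)`), so a stage
rerun in isolation reproduces its in-pipeline output and identical
config+seed gives identical reports.  Stage failure halts downstream stages
and emits a partial report.  `pipeline.acceptance_check` compares report
values against a target table (eq/le/ge with tolerance); missing values are
unevaluable, not failed.

## What the synthetic tests show — and what they do not

The generators emulate the statistical structure the analyses assume:
Markovian state exchange with frame averaging and single-step bleaching;
spectra that are exactly two Lorentzians under a Gaussian resolution;
mixtures that are exact non-negative combinations of known curves; clean
sigmoidal melts.  Passing recovery tests therefore demonstrates that the
estimators are correct and well-conditioned under the study conditions —
not that real data satisfy those conditions.  Known departures in real
measurements that are out of scope here: dye photophysics beyond bleaching
(blinking, spectral crosstalk, γ-correction), non-Markovian or
sub-frame-rate dynamics, elastic incoherent scattering and multiple
scattering in QENS, inter-particle structure factors and smearing in SAS,
and partially cooperative or multi-step unfolding.  Problem sizes in the
tests (e.g. 94–200 molecules, 20 spectra, 24-member pools, 100 melt
replicates) are the study's own scales.
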