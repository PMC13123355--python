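"""Synthetic-data generators for every analysis stage.

Each generator inverts the model its analysis counterpart fits, with ground
truth returned alongside, so every stage of the chain can be verified by
parameter recovery:

* four-state Markov FRET dynamics at 100-ms frames with anti-correlated dye
  channels and single-step photobleaching;
* QENS spectra built from two Lorentzians (narrow: Γ = D Q² global diffusion;
  broad: Γ = (1/τ0) Q^α internal motions, both Arrhenius in T) convolved with
  a Gaussian instrument resolution over ±100 μeV;
* small-angle scattering curves from bead models via the Debye formula and
  noisy weighted mixtures of species curves;
* Boltzmann sigmoid melt curves.

Default parameter values are the measurement conditions of the wsMOR study
this toolkit models: FRET states 0.33/0.49/0.63/0.78, a 3.4 μeV FWHM
resolution with Q = 0.7–1.5 Å⁻¹ and T = 280–310 K, oligomer bead models with
~30 Å inter-subunit surface gaps, and melt curves on a 20–90 °C ramp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .qens import GAS_CONSTANT, QENSSpectrum, convolve_resolution, lorentzian
from .sas import ScatteringCurve
from .smfret import IntensityTrace
from .thermal import MeltCurve

__all__ = [
    "FretSimConfig",
    "QENSSimConfig",
    "BeadModel",
    "MeltSimConfig",
    "stationary_distribution",
    "rate_matrix_from_occupancies",
    "uniform_rate_matrix",
    "simulate_fret_traces",
    "gaussian_resolution",
    "simulate_qens",
    "debye_intensity",
    "debye_curve",
    "bead_sphere",
    "default_oligomer_models",
    "decoy_pool",
    "simulate_sas_mixture",
    "simulate_melt_curve",
]


# ---------------------------------------------------------------------------
# smFRET generator
# ---------------------------------------------------------------------------

def uniform_rate_matrix(n_states: int, leave_rate: float = 1.0) -> np.ndarray:
    """Rate matrix with equal off-diagonal rates and total exit ``leave_rate``/s."""
    q = np.full((n_states, n_states), leave_rate / (n_states - 1))
    np.fill_diagonal(q, -leave_rate)
    return q


def rate_matrix_from_occupancies(occupancies: np.ndarray,
                                 exchange_rate: float = 1.0) -> np.ndarray:
    """Rate matrix whose stationary distribution matches ``occupancies``.

    Uses q_ij = k π_j (i ≠ j), which satisfies detailed balance for any
    target distribution π; ``exchange_rate`` sets the overall time scale
    (state-exit rates are k (1 − π_i) per second).  Occupancies are
    renormalised to sum to one.
    """
    pi = np.asarray(occupancies, dtype=float)
    if np.any(pi <= 0):
        raise ValueError("occupancies must be positive")
    pi = pi / pi.sum()
    q = exchange_rate * np.tile(pi, (pi.size, 1))
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def stationary_distribution(rate_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution π with π Q = 0, Σπ = 1."""
    q = np.asarray(rate_matrix, dtype=float)
    n = q.shape[0]
    a = np.vstack([q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


@dataclass
class FretSimConfig:
    """Study conditions for the smFRET generator.

    state_means       FRET efficiency of each state, strictly increasing
    rate_matrix       transition rates (s⁻¹); rows sum to zero
    frame_time        camera exposure (s)
    total_intensity   mean donor+acceptor photons per frame
    noise_sd          per-channel additive Gaussian sd (photons); the default
                      gives an efficiency noise of ≈0.05 at mid-range E
    bleach_rate       per-frame single-step photobleach probability
    """

    state_means: np.ndarray = field(
        default_factory=lambda: np.array([0.33, 0.49, 0.63, 0.78]))
    rate_matrix: np.ndarray | None = None
    frame_time: float = 0.1
    total_intensity: float = 1000.0
    noise_sd: float = 70.0
    bleach_rate: float = 0.005
    n_traces: int = 200
    n_frames_max: int = 500
    poisson_emission: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        self.state_means = np.asarray(self.state_means, dtype=float)
        if np.any(np.diff(self.state_means) <= 0):
            raise ValueError("state_means must be strictly increasing")
        if np.any((self.state_means <= 0) | (self.state_means >= 1)):
            raise ValueError("state_means must lie in (0, 1)")
        if self.rate_matrix is None:
            # slow exchange: dwell times of several seconds, well beyond the
            # 100-ms frame, so individual molecules sample a few dwells each
            self.rate_matrix = uniform_rate_matrix(self.state_means.size,
                                                   leave_rate=0.3)
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        q = self.rate_matrix
        if q.shape != (self.state_means.size,) * 2:
            raise ValueError("rate_matrix shape must match state count")
        off = q[~np.eye(q.shape[0], dtype=bool)]
        if np.any(off < 0) or not np.allclose(q.sum(axis=1), 0.0, atol=1e-9):
            raise ValueError("rate_matrix must have non-negative off-diagonals "
                             "and zero row sums")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        if not 0 <= self.bleach_rate <= 1:
            raise ValueError("bleach_rate must lie in [0, 1]")


def _ctmc_path(q: np.ndarray, pi: np.ndarray, t_end: float,
               rng: np.random.Generator) -> list[tuple[float, float, int]]:
    """Continuous-time Markov path [(t0, t1, state), ...] over [0, t_end]."""
    state = int(rng.choice(pi.size, p=pi))
    t = 0.0
    path = []
    while t < t_end:
        leave = -q[state, state]
        dt = rng.exponential(1.0 / leave) if leave > 0 else t_end - t + 1.0
        t1 = min(t + dt, t_end)
        path.append((t, t1, state))
        if t + dt >= t_end:
            break
        rates = q[state].copy()
        rates[state] = 0.0
        state = int(rng.choice(pi.size, p=rates / rates.sum()))
        t = t1
    return path


def simulate_fret_traces(config: FretSimConfig) -> list[IntensityTrace]:
    """Simulate intensity traces with ground-truth state paths.

    Each trace is a continuous-time Markov path discretized at the frame
    time; the per-frame acceptor fraction is the occupancy-weighted mean of
    the state efficiencies.  Donor = total (1 − E) + noise and
    acceptor = total E + noise, anti-correlated by construction.  After a
    geometric bleach time the acceptor (and later the donor) drops to
    background.  Ground truth (majority state per frame, the exact per-frame
    acceptor fraction, and the acceptor bleach frame) rides along on the
    returned traces.
    """
    rng = np.random.default_rng(config.seed)
    pi = stationary_distribution(config.rate_matrix)
    dt = config.frame_time
    n_frames = config.n_frames_max
    traces = []
    for _ in range(config.n_traces):
        path = _ctmc_path(config.rate_matrix, pi, n_frames * dt, rng)
        e_frame = np.zeros(n_frames)
        occ_frame = np.zeros((n_frames, pi.size))
        for t0, t1, s in path:
            k0, k1 = int(t0 / dt), min(int(np.ceil(t1 / dt)), n_frames)
            for k in range(k0, k1):
                overlap = min(t1, (k + 1) * dt) - max(t0, k * dt)
                if overlap > 0:
                    frac = overlap / dt
                    e_frame[k] += frac * config.state_means[s]
                    occ_frame[k, s] += frac
        truth_state = np.argmax(occ_frame, axis=1)

        if config.bleach_rate > 0:
            bleach_a = int(rng.geometric(config.bleach_rate))
            bleach_d = bleach_a + int(rng.geometric(config.bleach_rate))
        else:
            bleach_a = bleach_d = n_frames + 1
        bleach_a = min(bleach_a, n_frames)
        bleach_d = min(bleach_d, n_frames)

        total = config.total_intensity
        donor_mean = total * (1.0 - e_frame)
        acceptor_mean = total * e_frame
        donor_mean[bleach_a:bleach_d] = total      # no FRET once acceptor dark
        acceptor_mean[bleach_a:] = 0.0
        donor_mean[bleach_d:] = 0.0
        if config.poisson_emission:
            donor = rng.poisson(donor_mean).astype(float)
            acceptor = rng.poisson(acceptor_mean).astype(float)
            donor += rng.normal(0.0, config.noise_sd, n_frames)
            acceptor += rng.normal(0.0, config.noise_sd, n_frames)
        else:
            donor = donor_mean + rng.normal(0.0, config.noise_sd, n_frames)
            acceptor = acceptor_mean + rng.normal(0.0, config.noise_sd, n_frames)
        traces.append(IntensityTrace(
            donor=donor, acceptor=acceptor, frame_time=dt,
            truth_states=truth_state, truth_efficiency=e_frame,
            truth_bleach_frame=bleach_a))
    return traces


# ---------------------------------------------------------------------------
# QENS generator
# ---------------------------------------------------------------------------

# Arrhenius anchors: diffusivity and internal rate at 310 K, extrapolated to
# prefactors with the unliganded activation energies.  D(310 K) = 3.5 Å²·μeV
# (≈5×10⁻⁷ cm²/s apparent diffusivity) and 1/τ0(310 K) = 658.2/55 ≈ 12 μeV
# (a 55 ps internal relaxation time at Q = 1 Å⁻¹).
_D_310 = 3.5
_RATE_310 = 658.2 / 55.0
_EA_GLOBAL = 21.1     # kJ/mol
_EA_INTERNAL = 8.2    # kJ/mol


def _arrhenius_prefactor(value_at_t: float, ea_kj: float, t_ref: float) -> float:
    return value_at_t * math.exp(ea_kj * 1000.0 / (GAS_CONSTANT * t_ref))


@dataclass
class QENSSimConfig:
    """Study conditions for the QENS generator.

    ``d0`` and ``rate0`` are Arrhenius prefactors (value = prefactor ×
    exp(−Ea/RT)); the defaults anchor D = 3.5 Å²·μeV and 1/τ0 = 12 μeV at
    310 K with the unliganded activation energies.
    """

    temperatures: np.ndarray = field(
        default_factory=lambda: np.array([280.0, 290.0, 300.0, 310.0]))
    q_values: np.ndarray = field(
        default_factory=lambda: np.array([0.7, 0.9, 1.1, 1.3, 1.5]))
    energy_grid: np.ndarray = field(
        default_factory=lambda: np.arange(-100.0, 100.0 + 0.1, 0.2))
    resolution_fwhm: float = 3.4
    d0: float = _arrhenius_prefactor(_D_310, _EA_GLOBAL, 310.0)
    ea_global: float = _EA_GLOBAL
    rate0: float = _arrhenius_prefactor(_RATE_310, _EA_INTERNAL, 310.0)
    ea_internal: float = _EA_INTERNAL
    alpha: float = 1.8
    amp_narrow: float = 0.6
    amp_broad: float = 0.4
    bg_offset: float = 0.002
    bg_slope: float = 1e-5
    noise_rel: float = 0.03
    seed: int | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.q_values = np.asarray(self.q_values, dtype=float)
        self.energy_grid = np.asarray(self.energy_grid, dtype=float)
        if np.any(self.q_values <= 0) or np.any(self.temperatures <= 0):
            raise ValueError("q values and temperatures must be positive")
        e = self.energy_grid
        if abs(e.max() + e.min()) > 0.5 * np.mean(np.diff(e)):
            raise ValueError("energy grid must be symmetric about zero")
        de = float(np.mean(np.diff(e)))
        if de > self.resolution_fwhm / 5.0:
            raise ValueError("energy grid too coarse: need >= 5 points per "
                             "resolution FWHM")

    def diffusivity(self, temperature: float) -> float:
        return self.d0 * math.exp(-self.ea_global * 1000.0
                                  / (GAS_CONSTANT * temperature))

    def internal_rate(self, temperature: float) -> float:
        return self.rate0 * math.exp(-self.ea_internal * 1000.0
                                     / (GAS_CONSTANT * temperature))


def gaussian_resolution(energy: np.ndarray, fwhm: float) -> np.ndarray:
    """Unit-area Gaussian resolution function of the given FWHM."""
    sd = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    g = np.exp(-0.5 * (energy / sd) ** 2)
    return g / np.trapezoid(g, energy)


def simulate_qens(config: QENSSimConfig) -> tuple[list[QENSSpectrum], dict]:
    """Generate spectra for every (T, Q) plus the ground-truth parameters.

    For each combination, Γ_narrow = D(T) Q² and Γ_broad = (1/τ0)(T) Q^α with
    Arrhenius temperature dependence; the spectrum is
    resolution ⊗ [A1 L(Γn) + A2 L(Γb)] + a + b E with multiplicative Gaussian
    noise of relative sd ``noise_rel``.
    """
    rng = np.random.default_rng(config.seed)
    e = config.energy_grid
    resolution = gaussian_resolution(e, config.resolution_fwhm)
    spectra = []
    truth = {"diffusivity": {}, "internal_rate": {}, "gamma_narrow": {},
             "gamma_broad": {}, "alpha": config.alpha,
             "ea_global": config.ea_global, "ea_internal": config.ea_internal}
    for t in config.temperatures:
        d = config.diffusivity(t)
        rate = config.internal_rate(t)
        truth["diffusivity"][float(t)] = d
        truth["internal_rate"][float(t)] = rate
        for q in config.q_values:
            g_n = d * q**2
            g_b = rate * q**config.alpha
            truth["gamma_narrow"][(float(t), float(q))] = g_n
            truth["gamma_broad"][(float(t), float(q))] = g_b
            clean = convolve_resolution(
                e,
                lambda x: (config.amp_narrow * lorentzian(x, g_n)
                           + config.amp_broad * lorentzian(x, g_b)),
                resolution)
            clean = clean + config.bg_offset + config.bg_slope * e
            if config.noise_rel > 0:
                noisy = clean * (1.0 + config.noise_rel * rng.normal(size=e.size))
                sigma = config.noise_rel * np.abs(clean)
            else:
                noisy = clean
                sigma = np.full_like(clean, 1e-6 * np.abs(clean).max())
            spectra.append(QENSSpectrum(
                q=float(q), temperature=float(t), energy=e.copy(),
                intensity=noisy, sigma=np.maximum(sigma, 1e-12),
                resolution=resolution.copy()))
    return spectra, truth


# ---------------------------------------------------------------------------
# bead models and the Debye formula
# ---------------------------------------------------------------------------

@dataclass
class BeadModel:
    """Coarse bead representation of one species."""

    label: str
    coordinates: np.ndarray            # (n, 3), Å
    bead_scattering_length: float = 1.0

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        if self.coordinates.shape[0] < 1 or self.coordinates.shape[1] != 3:
            raise ValueError("need >= 1 bead with 3-D coordinates")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("bead coordinates must be finite")

    @property
    def rg(self) -> float:
        c = self.coordinates - self.coordinates.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum(c**2, axis=1))))


def debye_intensity(model: BeadModel, q: np.ndarray,
                    bin_width: float = 0.5) -> np.ndarray:
    """Debye-formula intensity I(q) = Σ_ij f_i f_j sin(q r_ij)/(q r_ij).

    Evaluated through a pair-distance histogram (bin width ``bin_width`` Å,
    exact to (q Δr)²/24 relative error).  q = 0 uses the analytic limit
    I(0) = (Σ f)².
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    coords = model.coordinates
    n = coords.shape[0]
    f = model.bead_scattering_length
    if n == 1:
        return np.full(q.shape, f**2)
    d = pdist(coords)
    edges = np.arange(0.0, d.max() + 2 * bin_width, bin_width)
    hist, edges = np.histogram(d, bins=edges)
    dsum, _ = np.histogram(d, bins=edges, weights=d)
    keep = hist > 0
    hist = hist[keep]
    centers = dsum[keep] / hist          # per-bin mean distance, not center
    qr = np.outer(q, centers)
    with np.errstate(invalid="ignore", divide="ignore"):
        sinc = np.where(qr > 1e-12, np.sin(qr) / qr, 1.0)
    return f**2 * (n + 2.0 * sinc @ hist)


def debye_curve(model: BeadModel, q_values: np.ndarray,
                rel_error: float = 0.01) -> ScatteringCurve:
    """ScatteringCurve from a bead model, with σ = ``rel_error`` × I."""
    q = np.asarray(q_values, dtype=float)
    i = debye_intensity(model, q)
    return ScatteringCurve(q, i, np.maximum(rel_error * np.abs(i), 1e-30),
                           label=model.label)


def bead_sphere(radius: float, spacing: float = 6.0, label: str = "sphere",
                center: np.ndarray | None = None) -> BeadModel:
    """Filled sphere of beads on a cubic grid (Rg → R sqrt(3/5))."""
    g = np.arange(-radius, radius + spacing, spacing)
    xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    pts = pts[np.sum(pts**2, axis=1) <= radius**2]
    if center is not None:
        pts = pts + np.asarray(center, dtype=float)
    return BeadModel(label=label, coordinates=pts)


_SUBUNIT_RADIUS = 25.0       # Å, compact receptor-sized subunit
_SURFACE_GAP = 30.0          # Å, inter-subunit surface separation


def default_oligomer_models(subunit_radius: float = _SUBUNIT_RADIUS,
                            gap: float = _SURFACE_GAP,
                            spacing: float = 6.0) -> dict[str, BeadModel]:
    """Monomer/dimer/trimer/tetramer bead fixtures.

    The dimer and tetramer place subunit surfaces ~30 Å apart (detergent-
    mediated, micelle-like organisation); the trimer is a compact touching
    triangle.  The tetramer is a planar square rather than a regular
    tetrahedron: a cluster with a single shared inter-subunit distance would
    make its curve an exact linear combination of the monomer and dimer
    curves (all three live in span{F(q), F(q)·sinc(d q)}), leaving the
    species weights unidentifiable; the square's edge/diagonal pair breaks
    that degeneracy.
    """
    r = subunit_radius
    far = 2 * r + gap           # center-to-center with a 30 Å surface gap
    near = 2 * r                # touching
    def multi(centers, label):
        pts = np.vstack([bead_sphere(r, spacing, center=c).coordinates
                         for c in centers])
        return BeadModel(label=label, coordinates=pts)

    models = {
        "monomer": bead_sphere(r, spacing, label="monomer"),
        "dimer": multi([(-far / 2, 0, 0), (far / 2, 0, 0)], "dimer"),
        "trimer": multi([(0, 0, 0), (near, 0, 0),
                         (near / 2, near * np.sqrt(3) / 2, 0)], "trimer"),
        "tetramer": multi([(0, 0, 0), (far, 0, 0),
                           (far, far, 0), (0, far, 0)], "tetramer"),
    }
    return models


def decoy_pool(n_per_species: int = 5, seed: int | np.random.Generator | None = None,
               spacing: float = 6.0) -> list[BeadModel]:
    """Perturbed conformers of each species, used as GA decoys.

    Each decoy stretches the parent model anisotropically (±10 % per axis)
    and jitters bead positions by ~2 Å, mimicking conformational sampling
    around each oligomeric state.  Labels are "<species>/decoyN" so class
    fractions still aggregate by species.
    """
    rng = np.random.default_rng(seed)
    parents = default_oligomer_models(spacing=spacing)
    pool = []
    for name, parent in parents.items():
        for k in range(n_per_species):
            scale = rng.uniform(0.9, 1.1, size=3)
            coords = parent.coordinates * scale
            coords = coords + rng.normal(0.0, 2.0, size=coords.shape)
            pool.append(BeadModel(label=f"{name}/decoy{k}", coordinates=coords))
    return pool


def simulate_sas_mixture(basis: list[ScatteringCurve], weights: np.ndarray,
                         noise_rel: float = 0.01,
                         seed: int | np.random.Generator | None = None,
                         label: str = "mixture") -> ScatteringCurve:
    """Noisy weighted sum of basis curves on a shared q grid.

    I_mix = Σ w_k I_k with multiplicative Gaussian noise of relative sd
    ``noise_rel``; the σ column is noise_rel × I.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if len(basis) != w.size:
        raise ValueError("one weight per basis curve required")
    q = basis[0].q
    for c in basis[1:]:
        if c.q.shape != q.shape or not np.allclose(c.q, q):
            raise ValueError("basis curves must share one q grid")
    i = np.sum([wk * c.intensity for wk, c in zip(w, basis)], axis=0)
    rng = np.random.default_rng(seed)
    if noise_rel > 0:
        noisy = i * (1.0 + noise_rel * rng.normal(size=i.size))
        sigma = noise_rel * np.abs(i)
    else:
        noisy = i
        sigma = 1e-10 * np.abs(i)    # noise-free: keep weights proportional
    return ScatteringCurve(q, noisy, np.maximum(sigma, 1e-30), label=label)


# ---------------------------------------------------------------------------
# melt-curve generator
# ---------------------------------------------------------------------------

@dataclass
class MeltSimConfig:
    """Boltzmann sigmoid melt-curve conditions (2 °C/min ramp, 20–90 °C)."""

    tm: float = 55.0
    slope: float = 2.0
    f_min: float = 100.0
    f_max: float = 1000.0
    temp_range: np.ndarray = field(
        default_factory=lambda: np.arange(20.0, 90.0 + 0.25, 0.5))
    noise_sd: float = 9.0        # 1 % of the default plateau span
    seed: int | None = None

    def __post_init__(self) -> None:
        self.temp_range = np.asarray(self.temp_range, dtype=float)
        if self.f_max <= self.f_min:
            raise ValueError("f_max must exceed f_min")
        if self.slope <= 0:
            raise ValueError("slope must be positive")


def simulate_melt_curve(config: MeltSimConfig, label: str = "") -> MeltCurve:
    """F(T) = f_min + (f_max − f_min)/(1 + exp((tm − T)/slope)) + noise."""
    rng = np.random.default_rng(config.seed)
    t = config.temp_range
    f = config.f_min + (config.f_max - config.f_min) / (
        1.0 + np.exp((config.tm - t) / config.slope))
    if config.noise_sd > 0:
        f = f + rng.normal(0.0, config.noise_sd, size=t.size)
    return MeltCurve(temperature=t, fluorescence=f, label=label)
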