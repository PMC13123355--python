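"""Quasi-elastic neutron scattering (QENS) analysis.

Each spectrum S(Q, E) is modelled as two Lorentzian components convolved with
the instrument resolution plus a linear background,

    S(Q, E) = R ⊗ [A1 L(E; Γ1) + A2 L(E; Γ2)] + a + b E ,

with L a unit-area Lorentzian of HWHM Γ.  The narrow component tracks global
(predominantly translational) diffusion, Γ_narrow = D Q², and the broad
component tracks internal motions through a power law Γ_broad = (1/τ0) Q^α
anchored at Q = 1 Å⁻¹.  Temperature series of D and 1/τ0 give activation
energies from Arrhenius fits of ln X vs 1/T.

Energies are in μeV and Q in Å⁻¹ throughout; a HWHM Γ in μeV corresponds to a
relaxation time τ = ħ/Γ = 658.2/Γ ps.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
from scipy import stats

__all__ = [
    "HBAR_UEV_PS",
    "GAS_CONSTANT",
    "QENSSpectrum",
    "LorentzianFitResult",
    "DiffusivityFit",
    "InternalDynamicsFit",
    "ArrheniusFit",
    "lorentzian",
    "convolve_resolution",
    "fit_spectrum",
    "fit_global_diffusion",
    "fit_internal_dynamics",
    "fit_internal_dynamics_shared",
    "arrhenius_fit",
    "analyze_temperature_series",
]

HBAR_UEV_PS = 658.2        # ħ in μeV·ps
GAS_CONSTANT = 8.314       # J / (mol K)


@dataclass
class QENSSpectrum:
    """S(Q, E) on an energy-transfer grid with its resolution function."""

    q: float                    # Å⁻¹
    temperature: float          # K
    energy: np.ndarray          # μeV
    intensity: np.ndarray
    sigma: np.ndarray
    resolution: np.ndarray      # measured resolution on the same grid

    def __post_init__(self) -> None:
        self.energy = np.asarray(self.energy, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.resolution = np.asarray(self.resolution, dtype=float)
        if not (self.energy.shape == self.intensity.shape
                == self.sigma.shape == self.resolution.shape):
            raise ValueError("energy, intensity, sigma and resolution grids must match")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


@dataclass
class LorentzianFitResult:
    q: float
    temperature: float
    gamma_narrow: float
    gamma_broad: float
    amp_narrow: float
    amp_broad: float
    bg_offset: float
    bg_slope: float
    gamma_narrow_err: float
    gamma_broad_err: float
    redchi: float
    success: bool
    collapsed: bool = False     # Γ_broad/Γ_narrow < 1.5: components degenerate


@dataclass
class DiffusivityFit:
    temperature: float
    diffusivity: float          # Å²·μeV
    stderr: float

    @property
    def cm2_per_s(self) -> float:
        # 1 μeV·Å² = (1/ħ) Å²/ps = 1e-4/658.2 cm²/s per unit
        return self.diffusivity / HBAR_UEV_PS * 1e-4


@dataclass
class InternalDynamicsFit:
    temperature: float
    rate: float                 # 1/τ0, μeV at Q = 1 Å⁻¹
    alpha: float
    rate_err: float
    alpha_err: float

    @property
    def tau0_ps(self) -> float:
        return HBAR_UEV_PS / self.rate


@dataclass
class ArrheniusFit:
    activation_energy: float    # kJ/mol
    prefactor: float
    ea_stderr: float
    r_value: float


# ---------------------------------------------------------------------------
# model pieces
# ---------------------------------------------------------------------------

def lorentzian(energy: np.ndarray, hwhm: float) -> np.ndarray:
    """Unit-area Lorentzian of half-width ``hwhm``."""
    return hwhm / np.pi / (energy**2 + hwhm**2)


def _kernel_from_resolution(energy: np.ndarray, resolution: np.ndarray,
                            trim: float = 1e-8) -> tuple[np.ndarray, int]:
    """Unit-area convolution kernel centred on E = 0, trimmed to support."""
    kern = np.clip(resolution, 0.0, None)
    keep = kern > trim * kern.max()
    peak = int(np.argmax(kern))
    first, last = np.flatnonzero(keep)[[0, -1]]
    half = max(peak - first, last - peak)
    a, b = max(0, peak - half), min(kern.size, peak + half + 1)
    kern = kern[a:b]
    if kern.size % 2 == 0:     # keep an odd, centred kernel
        kern = kern[:-1]
    kern = kern / kern.sum()   # sum-1 kernel preserves the discrete area
    return kern, kern.size // 2


def convolve_resolution(energy: np.ndarray, model_fn, resolution: np.ndarray) -> np.ndarray:
    """Convolve an analytic line-shape with a measured resolution function.

    ``model_fn`` is evaluated on an edge-padded extension of the grid so the
    convolution is exact over the reported range (no wrap-around artefacts).
    """
    kern, half = _kernel_from_resolution(energy, resolution)
    de = float(np.mean(np.diff(energy)))
    left = energy[0] - de * np.arange(half, 0, -1)
    right = energy[-1] + de * np.arange(1, half + 1)
    e_ext = np.concatenate([left, energy, right])
    return np.convolve(model_fn(e_ext), kern, mode="valid")


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def fit_spectrum(spectrum: QENSSpectrum, init: dict | None = None,
                 elastic: bool = False) -> LorentzianFitResult:
    """Weighted fit of resolution ⊗ [A1 L(Γ1) + A2 L(Γ2)] + a + b E.

    Components are identified by ordering Γ1 < Γ2 after the fit.  An optional
    delta-like elastic term (a scaled copy of the resolution) can be enabled
    but is off by default.  A result with Γ2/Γ1 < 1.5 is flagged as collapsed.
    """
    e = spectrum.energy
    if e.max() < 50 or e.min() > -50:
        raise ValueError("spectrum must cover at least ±50 μeV")
    y, s = spectrum.intensity, np.maximum(spectrum.sigma, 1e-12)

    kern, half = _kernel_from_resolution(e, spectrum.resolution)
    de = float(np.mean(np.diff(e)))
    left = e[0] - de * np.arange(half, 0, -1)
    right = e[-1] + de * np.arange(1, half + 1)
    e_ext = np.concatenate([left, e, right])
    res_peak = convolve_resolution(e, lambda x: lorentzian(x, 1e-6), spectrum.resolution)

    total_area = float(np.trapezoid(y, e))
    params = lmfit.Parameters()
    defaults = {"a1": 0.6 * total_area, "g1": 1.5,
                "a2": 0.4 * total_area, "g2": 15.0,
                "bg_offset": float(np.median(y[np.abs(e) > 0.8 * e.max()])),
                "bg_slope": 0.0, "elastic": 0.0}
    if init:
        defaults.update(init)
    params.add("a1", value=max(defaults["a1"], 1e-9), min=0)
    params.add("g1", value=defaults["g1"], min=0.01, max=30.0)
    params.add("a2", value=max(defaults["a2"], 1e-9), min=0)
    params.add("g2", value=defaults["g2"], min=0.5, max=200.0)
    params.add("bg_offset", value=defaults["bg_offset"])
    params.add("bg_slope", value=defaults["bg_slope"])
    params.add("el", value=defaults["elastic"], min=0, vary=elastic)

    def model(p) -> np.ndarray:
        shape = (p["a1"].value * lorentzian(e_ext, p["g1"].value)
                 + p["a2"].value * lorentzian(e_ext, p["g2"].value))
        out = np.convolve(shape, kern, mode="valid")
        out = out + p["bg_offset"].value + p["bg_slope"].value * e
        if elastic:
            out = out + p["el"].value * res_peak
        return out

    result = lmfit.minimize(lambda p: (model(p) - y) / s, params, method="leastsq")

    vals = result.params
    pairs = sorted([(vals["g1"].value, vals["a1"].value, vals["g1"].stderr),
                    (vals["g2"].value, vals["a2"].value, vals["g2"].stderr)])
    (g_n, a_n, ge_n), (g_b, a_b, ge_b) = pairs
    collapsed = g_b / max(g_n, 1e-12) < 1.5
    return LorentzianFitResult(
        q=spectrum.q, temperature=spectrum.temperature,
        gamma_narrow=g_n, gamma_broad=g_b, amp_narrow=a_n, amp_broad=a_b,
        bg_offset=vals["bg_offset"].value, bg_slope=vals["bg_slope"].value,
        gamma_narrow_err=ge_n or np.nan, gamma_broad_err=ge_b or np.nan,
        redchi=float(result.redchi), success=bool(result.success),
        collapsed=collapsed)


def fit_global_diffusion(results: list[LorentzianFitResult],
                         through_origin: bool = True) -> DiffusivityFit:
    """Diffusivity from the Q² law of the narrow component.

    Weighted linear fit of Γ_narrow vs Q², through the origin by default
    (Γ = D Q² has no intercept).
    """
    if len(results) < 3:
        raise ValueError("need >= 3 Q points")
    temps = {r.temperature for r in results}
    if len(temps) != 1:
        raise ValueError("all results must share one temperature")
    q2 = np.array([r.q**2 for r in results])
    g = np.array([r.gamma_narrow for r in results])
    w = np.array([1.0 / r.gamma_narrow_err**2
                  if np.isfinite(r.gamma_narrow_err) and r.gamma_narrow_err > 0
                  else 1.0 for r in results])
    if through_origin:
        d = float(np.sum(w * q2 * g) / np.sum(w * q2 * q2))
        resid = g - d * q2
        dof = max(len(results) - 1, 1)
        var = np.sum(w * resid**2) / dof / np.sum(w * q2 * q2)
        err = float(np.sqrt(var))
    else:
        fit = np.polyfit(q2, g, 1, w=np.sqrt(w), cov=True)
        d, err = float(fit[0][0]), float(np.sqrt(fit[1][0, 0]))
    if d <= 0:
        raise ValueError("negative diffusivity is unphysical")
    return DiffusivityFit(temperature=temps.pop(), diffusivity=d, stderr=err)


def fit_internal_dynamics(results: list[LorentzianFitResult]) -> InternalDynamicsFit:
    """Rate and exponent of the broad component from log Γ = log(1/τ0) + α log Q."""
    if len(results) < 3:
        raise ValueError("need >= 3 Q points")
    temps = {r.temperature for r in results}
    if len(temps) != 1:
        raise ValueError("all results must share one temperature")
    g = np.array([r.gamma_broad for r in results])
    if np.any(g <= 0):
        raise ValueError("broad-component HWHM must be positive")
    logq = np.log(np.array([r.q for r in results]))
    fit = stats.linregress(logq, np.log(g))
    return InternalDynamicsFit(
        temperature=temps.pop(), rate=float(np.exp(fit.intercept)),
        alpha=float(fit.slope),
        rate_err=float(np.exp(fit.intercept) * fit.intercept_stderr),
        alpha_err=float(fit.stderr))


def fit_internal_dynamics_shared(results: list[LorentzianFitResult]
                                 ) -> list[InternalDynamicsFit]:
    """Joint power-law fit over all temperatures with one shared exponent.

    The Q exponent reflects the geometry of the internal motions and is not
    expected to change over a 30 K window, so fitting log Γ = log r_T +
    α log Q with a common α and per-temperature rates r_T removes the strong
    per-temperature correlation between α and the rate estimate.
    """
    temps = sorted({r.temperature for r in results})
    if any(sum(r.temperature == t for r in results) < 3 for t in temps):
        raise ValueError("need >= 3 Q points per temperature")
    g = np.array([r.gamma_broad for r in results])
    if np.any(g <= 0):
        raise ValueError("broad-component HWHM must be positive")
    logq = np.log(np.array([r.q for r in results]))
    t_idx = np.array([temps.index(r.temperature) for r in results])
    # design: one intercept per temperature + shared slope
    a = np.zeros((g.size, len(temps) + 1))
    a[np.arange(g.size), t_idx] = 1.0
    a[:, -1] = logq
    coef, *_ = np.linalg.lstsq(a, np.log(g), rcond=None)
    resid = np.log(g) - a @ coef
    dof = max(g.size - coef.size, 1)
    cov = np.linalg.inv(a.T @ a) * (resid @ resid / dof)
    err = np.sqrt(np.diag(cov))
    alpha, alpha_err = float(coef[-1]), float(err[-1])
    return [InternalDynamicsFit(temperature=t, rate=float(np.exp(coef[k])),
                                alpha=alpha,
                                rate_err=float(np.exp(coef[k]) * err[k]),
                                alpha_err=alpha_err)
            for k, t in enumerate(temps)]


def arrhenius_fit(values: np.ndarray, temperatures: np.ndarray) -> ArrheniusFit:
    """Activation energy from ln X = ln X0 − Ea/(R T).

    ``values`` must be positive rates or diffusivities; Ea is returned in
    kJ/mol.  Two points give an exact line (no uncertainty); three or more
    give a standard error from the regression.
    """
    x = np.asarray(values, dtype=float)
    t = np.asarray(temperatures, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 temperatures")
    if np.any(x <= 0) or np.any(t <= 0):
        raise ValueError("values and temperatures must be positive")
    fit = stats.linregress(1.0 / t, np.log(x))
    ea = -fit.slope * GAS_CONSTANT / 1000.0
    err = (fit.stderr * GAS_CONSTANT / 1000.0) if x.size > 2 else np.nan
    return ArrheniusFit(activation_energy=float(ea),
                        prefactor=float(np.exp(fit.intercept)),
                        ea_stderr=float(err), r_value=float(fit.rvalue))


def analyze_temperature_series(spectra: list[QENSSpectrum],
                               share_alpha: bool = True) -> dict:
    """Full chain: spectrum fits → Q laws per T → Arrhenius energies.

    Returns a dict with per-spectrum Lorentzian results, per-temperature
    diffusivity and internal-dynamics fits (both the per-temperature and the
    shared-exponent power laws), and the two Arrhenius fits.  With
    ``share_alpha`` (default) the Arrhenius line for the internal rate uses
    the shared-exponent rates.
    """
    fits = [fit_spectrum(s) for s in spectra]
    temps = sorted({f.temperature for f in fits})
    diff, internal_per_t = [], []
    for t in temps:
        at_t = [f for f in fits if f.temperature == t]
        diff.append(fit_global_diffusion(at_t))
        internal_per_t.append(fit_internal_dynamics(at_t))
    internal_shared = fit_internal_dynamics_shared(fits)
    internal = internal_shared if share_alpha else internal_per_t
    arr_global = arrhenius_fit(np.array([d.diffusivity for d in diff]),
                               np.array(temps))
    arr_internal = arrhenius_fit(np.array([i.rate for i in internal]),
                                 np.array(temps))
    return {"lorentzian_fits": fits, "diffusivity": diff,
            "internal": internal, "internal_per_temperature": internal_per_t,
            "arrhenius_global": arr_global, "arrhenius_internal": arr_internal,
            "temperatures": temps}
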