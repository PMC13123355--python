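"""Thermal-shift (melting) analysis.

Thermal unfolding monitored by a cysteine-reactive dye gives a sigmoidal
fluorescence-vs-temperature curve.  The midpoint of the Boltzmann sigmoid

    F(T) = f_min + (f_max − f_min) / (1 + exp((Tm − T)/slope))

is the melting temperature Tm; ligand binding shifts Tm upward when it
stabilises the folded state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["MeltCurve", "MeltFit", "fit_boltzmann", "delta_tm"]


@dataclass
class MeltCurve:
    """Fluorescence intensity vs temperature (°C) for one condition."""

    temperature: np.ndarray
    fluorescence: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperature.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence must match in length")
        if self.temperature.size < 10:
            raise ValueError("need at least 10 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class MeltFit:
    tm: float
    slope: float
    f_min: float
    f_max: float
    tm_stderr: float
    slope_stderr: float
    r_squared: float
    label: str = ""
    descending: bool = False


def _boltzmann(t, f_min, f_max, tm, slope):
    return f_min + (f_max - f_min) / (1.0 + np.exp((tm - t) / slope))


def fit_boltzmann(curve: MeltCurve, max_temperature: float | None = None) -> MeltFit:
    """Least-squares Boltzmann sigmoid fit of a melt curve.

    Plateaus are initialised from the first/last decile means and Tm from the
    half-height crossing.  Descending curves (fluorescence falls on
    unfolding) are detected automatically and fitted with swapped plateaus.
    ``max_temperature`` optionally excludes post-transition quench points.
    """
    t, f = curve.temperature, curve.fluorescence
    if max_temperature is not None:
        keep = t <= max_temperature
        t, f = t[keep], f[keep]
    n = t.size
    k = max(3, n // 10)
    lo_mean, hi_mean = float(np.mean(f[:k])), float(np.mean(f[-k:]))
    descending = hi_mean < lo_mean

    resid_sd = float(np.std(np.diff(f)) / np.sqrt(2.0))
    if abs(hi_mean - lo_mean) <= 3.0 * resid_sd:
        raise ValueError("no melting transition: curve is flat within noise")

    half = 0.5 * (lo_mean + hi_mean)
    crossing = np.flatnonzero(np.diff(np.sign(f - half)))
    tm0 = float(t[crossing[0]]) if crossing.size else float(np.median(t))
    f_min0, f_max0 = sorted((lo_mean, hi_mean))
    p0 = (f_min0, f_max0, tm0, 2.0)
    if descending:
        # swapped plateaus: the sigmoid still rises in its own frame
        p0 = (f_max0, f_min0, tm0, 2.0)

    popt, pcov = curve_fit(_boltzmann, t, f, p0=p0, maxfev=20000)
    f_min, f_max, tm, slope = popt
    if slope < 0:  # equivalent parameterisation; normalise sign
        slope = -slope
        f_min, f_max = f_max, f_min
    perr = np.sqrt(np.diag(pcov))
    pred = _boltzmann(t, *popt)
    ss_res = float(np.sum((f - pred) ** 2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    return MeltFit(tm=float(tm), slope=float(slope),
                   f_min=float(min(f_min, f_max)), f_max=float(max(f_min, f_max)),
                   tm_stderr=float(perr[2]), slope_stderr=float(perr[3]),
                   r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
                   label=curve.label, descending=bool(descending))


def delta_tm(fit_a: MeltFit, fit_b: MeltFit) -> tuple[float, float]:
    """Melting-temperature shift ΔTm = Tm_b − Tm_a with propagated error."""
    shift = fit_b.tm - fit_a.tm
    err = float(np.hypot(fit_a.tm_stderr, fit_b.tm_stderr))
    return float(shift), err
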