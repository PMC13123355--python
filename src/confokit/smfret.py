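"""Single-molecule FRET trace analysis.

Converts donor/acceptor intensity traces into FRET-efficiency trajectories,
identifies conformational states by change-point segmentation with minimum
description length (MDL) model selection (STaSI-style analysis), quantifies
state populations from pooled efficiency histograms, and converts FRET
efficiencies into inter-fluorophore distances through the Förster relation.

The physical picture: an immobilized receptor carries a donor/acceptor dye
pair across two helices; conformational motion changes the dye separation r,
which modulates the transfer efficiency E = 1/(1 + (r/R0)^6).  Plateaus in the
E(t) trace are conformational states; their means map back to distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "IntensityTrace",
    "FretTrace",
    "StateModel",
    "HistogramFit",
    "DyePair",
    "DistanceEstimate",
    "compute_fret",
    "estimate_background",
    "traces_to_fret",
    "stasi",
    "fit_fret_histogram",
    "forster_radius",
    "fret_to_distance",
    "displacement",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class IntensityTrace:
    """Per-frame donor/acceptor photon intensities for one molecule.

    Ground-truth fields are populated by the synthetic generator and ignored
    by the analysis path.
    """

    donor: np.ndarray
    acceptor: np.ndarray
    frame_time: float = 0.1
    truth_states: np.ndarray | None = None
    truth_efficiency: np.ndarray | None = None
    truth_bleach_frame: int | None = None

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape:
            raise ValueError("donor and acceptor channels must have equal length")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")

    def __len__(self) -> int:
        return self.donor.size


@dataclass
class FretTrace:
    """FRET efficiency per frame, valid up to the photobleaching point."""

    efficiency: np.ndarray
    bleach_frame: int
    frame_time: float = 0.1
    valid: bool = True

    @property
    def values(self) -> np.ndarray:
        """Efficiencies of the valid (pre-bleach) frames."""
        return self.efficiency[: self.bleach_frame]

    def __len__(self) -> int:
        return int(self.bleach_frame)


@dataclass
class StateModel:
    """Result of change-point + MDL state identification."""

    n_states: int
    means: np.ndarray                   # ascending
    noise_sd: float
    assignments: list[np.ndarray]       # per trace, state index per valid frame
    segments: list[tuple[int, int, int, float]]  # (trace, start, stop, mean)
    mdl_by_m: dict[int, float]

    def state_of(self, efficiency: float) -> int:
        """Index of the state whose mean is closest to ``efficiency``."""
        return int(np.argmin(np.abs(self.means - efficiency)))


@dataclass
class HistogramFit:
    """Gaussian-mixture description of a pooled FRET histogram."""

    bin_edges: np.ndarray
    counts: np.ndarray
    bin_se: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray        # component areas, arbitrary units
    populations: np.ndarray    # percent, sums to 100
    redchi: float


@dataclass
class DyePair:
    """Spectral description of a donor/acceptor pair.

    wavelength   nm grid shared by both spectra
    donor_emission   F_D(λ), arbitrary units (normalised internally)
    acceptor_extinction  ε_A(λ) in M⁻¹ cm⁻¹
    quantum_yield    donor quantum yield Q_D
    kappa2       dipole orientation factor (2/3 for isotropic averaging)
    refractive_index  medium refractive index
    """

    wavelength: np.ndarray
    donor_emission: np.ndarray
    acceptor_extinction: np.ndarray
    quantum_yield: float
    kappa2: float = 2.0 / 3.0
    refractive_index: float = 1.4

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.donor_emission = np.asarray(self.donor_emission, dtype=float)
        self.acceptor_extinction = np.asarray(self.acceptor_extinction, dtype=float)
        if np.any(self.donor_emission < 0) or np.any(self.acceptor_extinction < 0):
            raise ValueError("spectra must be non-negative")
        if not 0 <= self.kappa2 <= 4:
            raise ValueError("kappa2 must lie in [0, 4]")
        if self.refractive_index <= 1:
            raise ValueError("refractive index must exceed 1")


@dataclass
class DistanceEstimate:
    efficiency: float
    forster_radius: float
    distance: float
    displacement: float | None = None


# ---------------------------------------------------------------------------
# intensity -> efficiency
# ---------------------------------------------------------------------------

def _running_median(x: np.ndarray, window: int = 21) -> np.ndarray:
    """Trailing (causal) running median.

    Using only preceding frames keeps the baseline bright right up to a
    bleaching edge, so the collapse test stays sharp even near trace ends.
    """
    from scipy.ndimage import median_filter

    if x.size == 0:
        return x
    size = min(window, max(1, x.size))
    return median_filter(x, size=size, mode="nearest", origin=size // 2)


def _collapse_point(signal: np.ndarray, frac: float, window: int,
                    persist: int) -> int:
    """First frame where ``signal`` falls below ``frac`` of its trailing
    running median and stays low for ``persist`` frames; size if never."""
    n = signal.size
    med = _running_median(signal, window)
    floor = np.maximum(med, 1e-12)
    low = signal < frac * floor
    for i in np.flatnonzero(low):
        stop = min(n, i + persist)
        if np.mean(signal[i:stop]) < frac * floor[i]:
            return int(i)
    return n


def _detect_bleach(donor: np.ndarray, acceptor: np.ndarray,
                   frac: float = 0.25, window: int = 21,
                   persist: int = 5) -> int:
    """First frame where the acceptor (or total) signal collapses.

    The FRET trace is valid only before the earlier of the acceptor and
    total-intensity drops.
    """
    total = donor + acceptor
    return min(_collapse_point(acceptor, frac, window, persist),
               _collapse_point(total, frac, window, persist))


def _trace_background(donor: np.ndarray, acceptor: np.ndarray, bleach: int,
                      frac: float, guard: int = 3) -> tuple[float, float]:
    """Per-trace channel baselines from genuinely dark frames.

    The acceptor is dark after its bleach (skipping ``guard`` frames in case
    detection lagged), the donor only after total-intensity collapse.  A
    channel that never goes dark is assumed already baseline-subtracted.
    """
    n = donor.size
    bg_a = (float(np.mean(acceptor[bleach + guard:]))
            if bleach + guard < n - 2 else 0.0)
    collapse = _collapse_point(donor + acceptor, frac, 21, 5)
    bg_d = (float(np.mean(donor[collapse + guard:]))
            if collapse + guard < n - 2 else 0.0)
    return bg_d, bg_a


def estimate_background(traces: list[IntensityTrace],
                        bleach_frac: float = 0.25) -> tuple[float, float]:
    """Field-wide channel baselines pooled across molecules.

    The camera offset is common to the field of view, so pooling post-bleach
    baselines across traces (median of per-trace estimates) removes the
    per-molecule estimation noise that would otherwise shift whole traces in
    E.  Feed the result to :func:`compute_fret` via ``background=``.
    """
    est_d, est_a = [], []
    for tr in traces:
        n = tr.donor.size
        bleach = _detect_bleach(tr.donor, tr.acceptor, frac=bleach_frac)
        if bleach + 3 < n - 2:
            est_a.append(float(np.mean(tr.acceptor[bleach + 3:])))
        collapse = _collapse_point(tr.donor + tr.acceptor, bleach_frac, 21, 5)
        if collapse + 3 < n - 2:
            est_d.append(float(np.mean(tr.donor[collapse + 3:])))
    bg_a = float(np.median(est_a)) if est_a else 0.0
    bg_d = float(np.median(est_d)) if est_d else 0.0
    return bg_d, bg_a


def compute_fret(trace: IntensityTrace, bleach_frac: float = 0.25,
                 background: tuple[float, float] | None = None,
                 bleach_guard: int = 2) -> FretTrace:
    """Background-correct a trace and compute E = I_A / (I_D + I_A).

    The photobleaching point is the first frame where the acceptor or the
    summed intensity drops below ``bleach_frac`` of its running median;
    efficiencies are reported only before that frame.  Background per channel
    is the mean of the frames where that channel is genuinely dark (the
    acceptor after its bleach, the donor after total-intensity collapse); a
    channel that never goes dark is assumed already baseline-subtracted
    (zero background) unless an explicit ``background = (bg_donor,
    bg_acceptor)`` is supplied.  ``bleach_guard`` frames immediately before
    the detected bleach are discarded as well, since the detector can lag
    the true bleach by a frame or two.  Output is clipped to [0, 1].
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    donor, acceptor = trace.donor, trace.acceptor
    n = donor.size
    bleach = _detect_bleach(donor, acceptor, frac=bleach_frac)

    if background is not None:
        bg_d, bg_a = background
    else:
        bg_d, bg_a = _trace_background(donor, acceptor, bleach, bleach_frac)

    d = donor - bg_d
    a = acceptor - bg_a
    s = d + a
    if np.all(np.abs(s) < 1e-12):
        return FretTrace(np.zeros(n), 0, trace.frame_time, valid=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(np.abs(s) > 1e-12, a / s, 0.0)
    e = np.clip(e, 0.0, 1.0)
    end = bleach if bleach >= n else max(bleach - bleach_guard, 0)
    return FretTrace(e, end, trace.frame_time, valid=end > 0)


def traces_to_fret(traces: list[IntensityTrace],
                   bleach_frac: float = 0.25) -> list[FretTrace]:
    """Convert a batch of traces using one pooled field background."""
    bg = estimate_background(traces, bleach_frac)
    return [compute_fret(t, bleach_frac=bleach_frac, background=bg)
            for t in traces]


# ---------------------------------------------------------------------------
# STaSI: change-point detection + MDL state count selection
# ---------------------------------------------------------------------------

def _haar_noise_sd(values: list[np.ndarray]) -> float:
    """Robust noise sd from Haar detail coefficients.

    For a piecewise-constant signal with additive iid noise the first
    differences are (noise_i − noise_{i−1}) except at the sparse change
    points, so MAD(diff)/0.6745/sqrt(2) estimates the per-frame sd.
    """
    diffs = np.concatenate([np.diff(v) for v in values if v.size >= 2])
    if diffs.size == 0:
        return 0.0
    mad = np.median(np.abs(diffs - np.median(diffs)))
    return float(mad / 0.6745 / np.sqrt(2.0))


def _best_split(y: np.ndarray, sigma: float) -> tuple[int, float]:
    """Index and t statistic of the best two-sample split of ``y``.

    The statistic compares left/right means using the global noise sd
    (piecewise-constant model), t = |mL − mR| / (σ sqrt(1/nL + 1/nR)).
    """
    n = y.size
    if n < 4:
        return -1, 0.0
    csum = np.cumsum(y)
    k = np.arange(1, n)                      # split after index k-1
    mean_l = csum[:-1] / k
    mean_r = (csum[-1] - csum[:-1]) / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(mean_l - mean_r) / (sigma * np.sqrt(1.0 / k + 1.0 / (n - k)))
    # forbid length-1 ends: single frames are indistinguishable from outliers
    t[0] = t[-1] = 0.0
    j = int(np.argmax(t))
    return j + 1, float(t[j])


def _segment_trace(y: np.ndarray, sigma: float, p_crit: float = 0.999) -> list[tuple[int, int]]:
    """Recursive change-point segmentation of one trace.

    A split is accepted while its t statistic exceeds the ``p_crit`` quantile
    of the null t distribution for the segment length.
    """
    out: list[tuple[int, int]] = []
    stack = [(0, y.size)]
    while stack:
        a, b = stack.pop()
        n = b - a
        split, t = _best_split(y[a:b], sigma)
        thresh = stats.t.ppf(p_crit, df=max(n - 2, 1))
        if split > 0 and t > thresh:
            stack.append((a, a + split))
            stack.append((a + split, b))
        else:
            out.append((a, b))
    out.sort()
    return out


def _merge_levels(seg_n: np.ndarray, seg_sum: np.ndarray, m_max: int):
    """Bottom-up 1-D Ward merging of segment means.

    Returns {m: labels} where ``labels`` maps each segment to one of m
    clusters.  Only adjacent clusters in mean order may merge, which is
    optimal for 1-D Ward distances.
    """
    order = np.argsort(seg_sum / seg_n)
    n_c = [seg_n[i] for i in order]
    s_c = [seg_sum[i] for i in order]
    members: list[list[int]] = [[int(i)] for i in order]

    def snapshot() -> np.ndarray:
        lab = np.empty(seg_n.size, dtype=int)
        # clusters stay sorted by mean -> label 0 = lowest mean
        for ci, mem in enumerate(members):
            lab[mem] = ci
        return lab

    levels: dict[int, np.ndarray] = {}
    while True:
        m = len(members)
        if m <= m_max:
            levels[m] = snapshot()
        if m == 1:
            break
        mu = np.array(s_c) / np.array(n_c)
        nn = np.array(n_c)
        cost = (nn[:-1] * nn[1:] / (nn[:-1] + nn[1:])) * (np.diff(mu) ** 2)
        j = int(np.argmin(cost))
        n_c[j] += n_c[j + 1]
        s_c[j] += s_c[j + 1]
        members[j] = members[j] + members[j + 1]
        del n_c[j + 1], s_c[j + 1], members[j + 1]
    return levels


def stasi(traces: list[FretTrace], m_max: int = 10,
          p_crit: float = 0.999) -> StateModel:
    """Identify FRET states across traces by change points + MDL.

    Pipeline: (i) estimate the noise sd from Haar detail coefficients pooled
    over traces; (ii) split each trace recursively at the frame maximizing a
    two-sample t statistic, accepted above the ``p_crit`` null quantile;
    (iii) pool segments across traces and merge their means agglomeratively;
    (iv) for each candidate state count m, score the piecewise-constant fit by
    a two-part description length

        MDL(m) = Σ resid² / (2 σ² ln 2)
               + (p/2) log2(n) + n_cp log2(m)

    with p = m + n_cp, n the total frame count and n_cp the number of
    boundaries between consecutive segments assigned to different states.
    The n_cp·log2(m) term charges for encoding which state each dwell visits;
    without it the description length keeps falling as clusters of segment
    means are split along noise and the state count is never bounded.
    Returns the model minimizing MDL(m).
    """
    values = [t.values for t in traces if t.valid and len(t) >= 10]
    if not values:
        raise ValueError("need at least one trace with >= 10 valid frames")

    sigma = _haar_noise_sd(values)
    if sigma <= 0:
        # noiseless degenerate input: states are the unique levels
        levels = np.unique(np.concatenate(values))
        means = np.sort(levels)
        assignments = [np.searchsorted(means, v) for v in values]
        segs = []
        for ti, v in enumerate(values):
            bounds = np.flatnonzero(np.diff(v) != 0) + 1
            edges = np.concatenate(([0], bounds, [v.size]))
            segs += [(ti, int(a), int(b), float(v[a]))
                     for a, b in zip(edges[:-1], edges[1:])]
        return StateModel(means.size, means, 0.0, assignments, segs,
                          {means.size: 0.0})

    # (ii) per-trace segmentation
    seg_trace, seg_start, seg_stop = [], [], []
    for ti, v in enumerate(values):
        for a, b in _segment_trace(v, sigma, p_crit):
            seg_trace.append(ti)
            seg_start.append(a)
            seg_stop.append(b)
    seg_trace = np.array(seg_trace)
    seg_start = np.array(seg_start)
    seg_stop = np.array(seg_stop)

    # Segment statistics exclude the boundary frames of each segment (when
    # it is long enough to spare them): a frame straddling a transition
    # averages two states and would otherwise bias segment means and inflate
    # apparent substructure within states.
    def _interior(a: int, b: int) -> tuple[int, int]:
        if b - a >= 6:
            return (a + 2, b - 2)       # change-point jitter spans ±2 frames
        if b - a >= 4:
            return (a + 1, b - 1)
        return (a, b)

    interior = [_interior(a, b) for a, b in zip(seg_start, seg_stop)]
    seg_n = np.array([b - a for a, b in interior], dtype=float)
    seg_sum = np.array([values[t][a:b].sum()
                        for t, (a, b) in zip(seg_trace, interior)])
    seg_sumsq = np.array([(values[t][a:b] ** 2).sum()
                          for t, (a, b) in zip(seg_trace, interior)])

    n_total = int(seg_n.sum())
    m_cap = min(m_max, seg_n.size)
    levels = _merge_levels(seg_n, seg_sum, m_cap)

    log2n = np.log2(n_total)
    best = None
    mdl_by_m: dict[int, float] = {}
    for m, labels in sorted(levels.items()):
        cl_n = np.bincount(labels, weights=seg_n, minlength=m)
        cl_sum = np.bincount(labels, weights=seg_sum, minlength=m)
        cl_mean = cl_sum / np.maximum(cl_n, 1)
        # frame-level SSE to assigned state means
        sse = float(np.sum(seg_sumsq - 2 * cl_mean[labels] * seg_sum
                           + seg_n * cl_mean[labels] ** 2))
        # change points: boundaries between consecutive segments (same trace)
        # assigned to different states
        n_cp = 0
        for ti in range(len(values)):
            lab = labels[seg_trace == ti]
            n_cp += int(np.count_nonzero(np.diff(lab) != 0))
        p = m + n_cp
        mdl = sse / (2 * sigma**2 * np.log(2)) + 0.5 * p * log2n
        if m > 1:
            mdl += n_cp * np.log2(m)
        mdl_by_m[m] = mdl
        if best is None or mdl < best[0]:
            best = (mdl, m, labels, cl_mean)

    _, m_opt, labels, cl_mean = best
    means = cl_mean[:m_opt]

    assignments = []
    segments = []
    for ti, v in enumerate(values):
        idx = np.flatnonzero(seg_trace == ti)
        assign = np.empty(v.size, dtype=int)
        for i in idx:
            assign[seg_start[i]:seg_stop[i]] = labels[i]
            segments.append((ti, int(seg_start[i]), int(seg_stop[i]),
                             float(means[labels[i]])))
        assignments.append(assign)

    return StateModel(m_opt, np.asarray(means), sigma, assignments, segments,
                      mdl_by_m)


# ---------------------------------------------------------------------------
# histogram populations
# ---------------------------------------------------------------------------

def fit_fret_histogram(traces: list[FretTrace], state_means: np.ndarray,
                       n_bins: int = 50, fix_means: bool = True,
                       n_bootstrap: int = 100, min_sd: float = 0.01,
                       dynamics_bridges: bool = True,
                       rng: np.random.Generator | None = None) -> HistogramFit:
    """Population histogram of valid frames + sum-of-Gaussians fit.

    Frames are pooled across molecules with equal per-frame weight into
    ``n_bins`` bins over [0, 1]; a sum of Gaussian components with means
    initialised (by default fixed) at ``state_means`` is fitted by weighted
    least squares.  Populations are the component areas normalised to 100 %.
    Per-bin standard errors come from a bootstrap over molecules.

    With ``dynamics_bridges`` (default) the mixture additionally contains a
    noise-smeared uniform "bridge" between each adjacent pair of state
    means: a frame during which the molecule switches state time-averages
    the two efficiencies, with a switch time uniform over the frame, so
    transition frames populate the whole interval between the peaks.  Each
    bridge's mass is credited half to each endpoint state (the switch
    splits the frame's occupancy evenly on average), which removes the
    population bias that blurred frames otherwise introduce.
    """
    state_means = np.sort(np.asarray(state_means, dtype=float))
    m = state_means.size
    if m < 2:
        raise ValueError("need at least two states")
    values = [t.values for t in traces if t.valid and len(t) > 0]
    pooled = np.concatenate(values)
    n_params = m * (3 if not fix_means else 2)
    if pooled.size < 5 * n_params:
        raise ValueError("too few frames for a stable mixture fit "
                         f"({pooled.size} < {5 * n_params})")

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(pooled, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    rng = np.random.default_rng(rng)
    boot = np.empty((n_bootstrap, n_bins))
    for b in range(n_bootstrap):
        pick = rng.integers(0, len(values), size=len(values))
        sample = np.concatenate([values[i] for i in pick])
        # rescale to the original frame count so bins are comparable
        boot[b], _ = np.histogram(sample, bins=edges)
        boot[b] *= pooled.size / max(sample.size, 1)
    bin_se = boot.std(axis=0, ddof=1)

    import lmfit
    from scipy.special import erf

    def _bridge(x, a, b, s):
        # uniform on [a, b] convolved with Gaussian noise sd s, unit height
        return 0.5 * (erf((x - a) / (np.sqrt(2) * s))
                      - erf((x - b) / (np.sqrt(2) * s)))

    def model(params: lmfit.Parameters) -> np.ndarray:
        out = np.zeros_like(centers)
        for k in range(m):
            a = params[f"amp{k}"].value
            mu = params[f"mu{k}"].value
            s = params[f"sd{k}"].value
            out += a * np.exp(-0.5 * ((centers - mu) / s) ** 2)
        if dynamics_bridges:
            for k in range(m - 1):
                s = 0.5 * (params[f"sd{k}"].value + params[f"sd{k + 1}"].value)
                out += params[f"br{k}"].value * _bridge(
                    centers, params[f"mu{k}"].value,
                    params[f"mu{k + 1}"].value, s)
        return out

    params = lmfit.Parameters()
    sd0 = 0.05
    for k in range(m):
        amp0 = max(counts.max() / m, 1.0)
        params.add(f"amp{k}", value=amp0, min=0.0)
        params.add(f"mu{k}", value=state_means[k], vary=not fix_means,
                   min=max(0.0, state_means[k] - 0.05),
                   max=min(1.0, state_means[k] + 0.05))
        params.add(f"sd{k}", value=sd0, min=min_sd, max=0.2)
    if dynamics_bridges:
        for k in range(m - 1):
            params.add(f"br{k}", value=0.0, min=0.0)

    weights = 1.0 / np.sqrt(counts + 1.0)

    def resid(params):
        return (model(params) - counts) * weights

    res = lmfit.minimize(resid, params, method="leastsq")
    amp = np.array([res.params[f"amp{k}"].value for k in range(m)])
    mus = np.array([res.params[f"mu{k}"].value for k in range(m)])
    sds = np.array([res.params[f"sd{k}"].value for k in range(m)])
    areas = amp * sds * np.sqrt(2 * np.pi)
    totals = areas.copy()
    if dynamics_bridges:
        for k in range(m - 1):
            span = mus[k + 1] - mus[k]
            mass = res.params[f"br{k}"].value * span
            totals[k] += 0.5 * mass
            totals[k + 1] += 0.5 * mass
    pops = 100.0 * totals / totals.sum()
    return HistogramFit(edges, counts, bin_se, mus, sds, areas, pops,
                        float(res.redchi))


# ---------------------------------------------------------------------------
# Förster relation
# ---------------------------------------------------------------------------

def overlap_integral(pair: DyePair) -> float:
    """Spectral overlap J = ∫F_D ε_A λ⁴ dλ / ∫F_D dλ  (M⁻¹ cm⁻¹ nm⁴)."""
    lam = pair.wavelength
    fd = pair.donor_emission
    norm = np.trapezoid(fd, lam)
    if norm <= 0:
        raise ValueError("donor emission spectrum integrates to zero")
    j = np.trapezoid(fd * pair.acceptor_extinction * lam**4, lam) / norm
    return float(j)


def forster_radius(pair: DyePair) -> float:
    """Förster radius R0 = 0.211 [κ² η⁻⁴ Q_D J]^(1/6) in Å.

    J is the spectral overlap in M⁻¹ cm⁻¹ nm⁴ (trapezoidal quadrature on the
    pair's common wavelength grid).
    """
    j = overlap_integral(pair)
    if j == 0 and pair.quantum_yield > 0:
        raise ValueError("non-overlapping spectra: J = 0")
    arg = pair.kappa2 * pair.refractive_index**-4 * pair.quantum_yield * j
    return float(0.211 * arg ** (1.0 / 6.0))


def fret_to_distance(efficiency: float, r0: float) -> float:
    """Invert E = 1/(1 + (r/R0)^6):  r = R0 (1/E − 1)^(1/6), in Å."""
    if not 0 < efficiency < 1:
        raise ValueError("efficiency must lie strictly between 0 and 1")
    if r0 <= 0:
        raise ValueError("R0 must be positive")
    return float(r0 * (1.0 / efficiency - 1.0) ** (1.0 / 6.0))


def displacement(e_state: float, e_reference: float, r0: float) -> float:
    """Distance change Δr = r(E_state) − r(E_reference) in Å.

    The reference is conventionally the highest-FRET (inactive) state, so a
    lower-FRET state gives a positive outward displacement.
    """
    return fret_to_distance(e_state, r0) - fret_to_distance(e_reference, r0)
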