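"""Small-angle scattering (SAS) curve analysis and ensemble decomposition.

Operations on 1-D scattering profiles I(q):

* Guinier analysis — radius of gyration from the low-q law
  ln I = ln I0 − (Rg²/3) q², iterated so the fitted window satisfies
  q_max·Rg ≤ 1.3.
* P(r) — pair-distance distribution by regularized indirect Fourier
  transform with P(0) = P(Dmax) = 0.
* Ensemble decomposition — a genetic algorithm picks a minimal subset
  (≤ N_max members) of candidate species curves whose non-negative linear
  combination minimizes the reduced χ² against a target curve; member
  weights come from exact non-negative least squares for every candidate
  subset, so the GA only searches over identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import nnls as _nnls

__all__ = [
    "ScatteringCurve",
    "GuinierFit",
    "PrFunction",
    "EnsembleSolution",
    "guinier_fit",
    "pr_transform",
    "nnls_weights",
    "ga_select",
]


@dataclass
class ScatteringCurve:
    """(q, I, σ) triplet; q in Å⁻¹, strictly increasing and positive."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.q.shape == self.intensity.shape == self.sigma.shape):
            raise ValueError("q, I and sigma must have matching shapes")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing and positive")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")

    def interpolated_to(self, q: np.ndarray) -> "ScatteringCurve":
        """Monotone cubic interpolation onto another q grid (no extrapolation)."""
        q = np.asarray(q, dtype=float)
        if q.min() < self.q.min() - 1e-12 or q.max() > self.q.max() + 1e-12:
            raise ValueError("extrapolation beyond the measured q range is forbidden")
        fi = PchipInterpolator(self.q, self.intensity)
        fs = PchipInterpolator(self.q, self.sigma)
        return ScatteringCurve(q, fi(q), np.maximum(fs(q), 1e-30), self.label)


@dataclass
class GuinierFit:
    rg: float
    i0: float
    q_min: float
    q_max: float
    qmax_rg: float
    rg_stderr: float
    n_points: int
    aggregation_warning: bool = False


@dataclass
class PrFunction:
    r: np.ndarray
    pr: np.ndarray
    dmax: float
    rg: float
    i0: float
    reg_weight: float
    oscillation_warning: bool = False


@dataclass
class EnsembleSolution:
    members: list[str]
    indices: list[int]
    weights: np.ndarray          # non-negative, sum to 1
    scale: float
    redchi: float
    class_fractions: dict[str, float]
    size_scan: dict[int, float] = field(default_factory=dict)  # best χ² per N


# ---------------------------------------------------------------------------
# Guinier
# ---------------------------------------------------------------------------

def guinier_fit(curve: ScatteringCurve, qrg_limit: float = 1.3,
                max_iter: int = 30) -> GuinierFit:
    """Iterative Guinier fit restricted to q·Rg ≤ ``qrg_limit``.

    Starts from the lowest-q points, fits ln I = ln I0 − (Rg²/3) q² by
    weighted least squares, then re-selects the window so q_max ≤ limit/Rg,
    repeating until Rg changes by < 1 %.  Upward curvature at the lowest q
    (an aggregation signature) sets a warning flag.
    """
    q, i, s = curve.q, curve.intensity, curve.sigma
    pos = i > 0
    q, i, s = q[pos], i[pos], s[pos]
    if q.size < 5:
        raise ValueError("need >= 5 positive-intensity points")

    n_window = max(5, min(20, q.size))
    rg_prev = None
    sel = np.arange(n_window)
    for _ in range(max_iter):
        qq, ii, ss = q[sel], i[sel], s[sel]
        w = (ii / ss) ** 2                   # weights for ln I
        coeffs, cov = np.polyfit(qq**2, np.log(ii), 1, w=np.sqrt(w), cov=True)
        slope, icept = coeffs
        if slope >= 0:
            raise ValueError("non-decreasing low-q intensity: Guinier fit impossible")
        rg = float(np.sqrt(-3.0 * slope))
        if rg_prev is not None and abs(rg - rg_prev) < 0.01 * rg_prev:
            break
        rg_prev = rg
        sel = np.flatnonzero(q <= qrg_limit / rg)
        if sel.size < 5:
            sel = np.arange(5)
    else:
        raise RuntimeError("Guinier window did not converge")

    rg_err = float(np.sqrt(cov[0, 0]) * 3.0 / (2.0 * rg))
    resid = np.log(i[sel]) - (icept + slope * q[sel]**2)
    k = max(3, sel.size // 4)
    aggregation = bool(np.mean(resid[:k]) > 2.0 * np.std(resid) + 1e-12)
    return GuinierFit(rg=rg, i0=float(np.exp(icept)),
                      q_min=float(q[sel][0]), q_max=float(q[sel][-1]),
                      qmax_rg=float(q[sel][-1] * rg), rg_stderr=rg_err,
                      n_points=int(sel.size), aggregation_warning=aggregation)


# ---------------------------------------------------------------------------
# P(r) indirect Fourier transform
# ---------------------------------------------------------------------------

def _pr_solve(curve: ScatteringCurve, dmax: float, n_r: int,
              reg_weight: float):
    r = np.linspace(0.0, dmax, n_r)
    dr = r[1] - r[0]
    qr = np.outer(curve.q, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        sinc = np.where(qr > 1e-12, np.sin(qr) / qr, 1.0)
    K = 4.0 * np.pi * dr * sinc
    # endpoint constraints P(0) = P(Dmax) = 0: solve for interior points only
    Ki = K[:, 1:-1] / curve.sigma[:, None]
    b = curve.intensity / curve.sigma
    # second-difference curvature penalty on the full (zero-padded) grid
    m = n_r - 2
    L = np.zeros((m + 2, m))
    for j in range(m):
        L[j, j] += 1.0
        L[j + 1, j] += -2.0
        L[j + 2, j] += 1.0
    A = Ki.T @ Ki + reg_weight * (L.T @ L)
    p_int = np.linalg.solve(A, Ki.T @ b)
    p = np.zeros(n_r)
    p[1:-1] = p_int
    resid = Ki @ p_int - b
    chi2 = float(resid @ resid)
    rough = float(p_int @ (L.T @ L) @ p_int)
    return r, p, chi2, rough


def pr_transform(curve: ScatteringCurve, dmax: float, n_r: int = 101,
                 reg_weight: float | None = None) -> PrFunction:
    """Regularized indirect Fourier transform to the pair-distance function.

    Minimizes ||(I − K P)/σ||² + λ ||P''||² with K_jk = 4π Δr sinc(q_j r_k)
    and hard endpoint constraints P(0) = P(Dmax) = 0.  When ``reg_weight`` is
    None, λ is chosen by an L-curve heuristic (maximum curvature of the
    log-residual vs log-roughness trade-off).  Rg and I(0) are the moments

        Rg² = ∫ r² P dr / (2 ∫ P dr),      I0 = 4π ∫ P dr .
    """
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    if curve.q.min() > np.pi / dmax * 1.5:
        import warnings
        warnings.warn("q_min is large relative to pi/dmax; P(r) is poorly "
                      "constrained at large r", stacklevel=2)

    if reg_weight is None:
        lams = np.logspace(-6, 4, 25)
        pts = [(_pr_solve(curve, dmax, n_r, lam)[2:4]) for lam in lams]
        rho = np.log(np.array([max(c, 1e-300) for c, _ in pts]))
        eta = np.log(np.array([max(g, 1e-300) for _, g in pts]))
        # discrete curvature of the L-curve; corner = max curvature
        d1r, d1e = np.gradient(rho), np.gradient(eta)
        d2r, d2e = np.gradient(d1r), np.gradient(d1e)
        with np.errstate(divide="ignore", invalid="ignore"):
            curv = (d1r * d2e - d2r * d1e) / (d1r**2 + d1e**2) ** 1.5
        curv[~np.isfinite(curv)] = -np.inf
        reg_weight = float(lams[int(np.argmax(curv))])

    r, p, chi2, _ = _pr_solve(curve, dmax, n_r, reg_weight)
    total = np.trapezoid(p, r)
    if total <= 0:
        raise ValueError("P(r) integrates to a non-positive total")
    neg = np.trapezoid(np.clip(-p, 0, None), r)
    oscillatory = bool(neg > 0.2 * total)
    rg = float(np.sqrt(np.trapezoid(r**2 * p, r) / (2.0 * total)))
    i0 = float(4.0 * np.pi * total)
    return PrFunction(r=r, pr=p, dmax=dmax, rg=rg, i0=i0,
                      reg_weight=reg_weight, oscillation_warning=oscillatory)


# ---------------------------------------------------------------------------
# ensemble decomposition
# ---------------------------------------------------------------------------

def nnls_weights(basis: list[ScatteringCurve], target: ScatteringCurve
                 ) -> tuple[np.ndarray, float, float]:
    """Non-negative least squares of the target against basis curves.

    Basis members are interpolated to the target grid when needed.  Returns
    (normalised weights, global scale, reduced χ²) with
    χ²_red = Σ[(I − scale Σw_k I_k)/σ]² / (n_q − n_members).
    """
    if not basis:
        raise ValueError("empty basis")
    q, i, s = target.q, target.intensity, target.sigma
    cols = []
    for c in basis:
        if c.q.shape != q.shape or not np.allclose(c.q, q):
            c = c.interpolated_to(q)
        cols.append(c.intensity / s)
    A = np.column_stack(cols)
    coef, rnorm = _nnls(A, i / s)
    dof = max(q.size - len(basis), 1)
    redchi = float(rnorm**2) / dof
    scale = float(coef.sum())
    weights = coef / scale if scale > 0 else np.zeros_like(coef)
    return weights, scale, redchi


def _subset_chi2(pool_cols: np.ndarray, b: np.ndarray, subset: tuple[int, ...],
                 n_q: int) -> tuple[float, np.ndarray]:
    coef, rnorm = _nnls(pool_cols[:, list(subset)], b)
    dof = max(n_q - len(subset), 1)
    return float(rnorm**2) / dof, coef


def ga_select(pool: list[ScatteringCurve], target: ScatteringCurve,
              n_max: int = 5, generations: int = 100, iterations: int = 5,
              population_size: int = 64, mutation_rate: float = 0.1,
              tournament: int = 3, seed: int | np.random.Generator | None = None
              ) -> EnsembleSolution:
    """Minimal-ensemble selection by genetic algorithm.

    For each ensemble size N = 1..``n_max`` the GA evolves a population of
    index subsets (tournament selection, uniform crossover on member slots,
    per-slot mutation swapping in random pool members, elitism) whose fitness
    is the negative reduced χ² of the exact NNLS fit of the subset to the
    target.  Each of ``iterations`` restarts uses fresh random parents; the
    best subset across restarts and sizes is returned, with species-class
    fractions aggregated from member labels and NNLS weights.
    """
    n_pool = len(pool)
    if n_pool < n_max:
        raise ValueError("candidate pool smaller than requested ensemble size")
    rng = np.random.default_rng(seed)
    q, s = target.q, target.sigma
    cols = []
    for c in pool:
        if c.q.shape != q.shape or not np.allclose(c.q, q):
            c = c.interpolated_to(q)
        cols.append(c.intensity / s)
    A = np.column_stack(cols)
    b = target.intensity / s
    n_q = q.size

    cache: dict[tuple[int, ...], tuple[float, np.ndarray]] = {}

    def fitness(ind: tuple[int, ...]) -> float:
        key = tuple(sorted(ind))
        if key not in cache:
            cache[key] = _subset_chi2(A, b, key, n_q)
        return cache[key][0]

    best_overall: tuple[float, tuple[int, ...]] | None = None
    size_scan: dict[int, float] = {}
    for size in range(1, n_max + 1):
        best_size: tuple[float, tuple[int, ...]] | None = None
        for _ in range(iterations):
            popn = [tuple(rng.choice(n_pool, size=size, replace=False))
                    for _ in range(population_size)]
            scores = np.array([fitness(ind) for ind in popn])
            for _gen in range(generations):
                elite = popn[int(np.argmin(scores))]
                children = [elite]
                while len(children) < population_size:
                    picks = rng.integers(0, population_size, size=tournament)
                    p1 = popn[picks[int(np.argmin(scores[picks]))]]
                    picks = rng.integers(0, population_size, size=tournament)
                    p2 = popn[picks[int(np.argmin(scores[picks]))]]
                    # uniform crossover on slots, repairing duplicates
                    child: list[int] = []
                    for a_gene, b_gene in zip(p1, p2):
                        gene = a_gene if rng.random() < 0.5 else b_gene
                        if gene in child:
                            gene = b_gene if gene == a_gene else a_gene
                        while gene in child:
                            gene = int(rng.integers(0, n_pool))
                        child.append(int(gene))
                    # per-slot mutation
                    for slot in range(size):
                        if rng.random() < mutation_rate:
                            gene = int(rng.integers(0, n_pool))
                            while gene in child[:slot] + child[slot + 1:]:
                                gene = int(rng.integers(0, n_pool))
                            child[slot] = gene
                    children.append(tuple(child))
                popn = children
                scores = np.array([fitness(ind) for ind in popn])
            j = int(np.argmin(scores))
            if best_size is None or scores[j] < best_size[0]:
                best_size = (float(scores[j]), popn[j])
        size_scan[size] = best_size[0]
        if best_overall is None or best_size[0] < best_overall[0]:
            best_overall = best_size

    chi2, subset = best_overall[0], tuple(sorted(best_overall[1]))
    _, coef = cache[subset]
    scale = float(coef.sum())
    weights = coef / scale if scale > 0 else np.zeros_like(coef)
    labels = [pool[i].label for i in subset]
    fractions: dict[str, float] = {}
    for lab, w in zip(labels, weights):
        cls = lab.split("/")[0] if lab else "unlabeled"
        fractions[cls] = fractions.get(cls, 0.0) + float(w)
    return EnsembleSolution(members=labels, indices=list(subset),
                            weights=weights, scale=scale, redchi=chi2,
                            class_fractions=fractions, size_scan=size_scan)
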