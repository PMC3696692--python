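"""Four-pulse DEER dipolar signals: forward model and Tikhonov inversion.

The time-domain DEER signal of an isotropically oriented (powder
averaged) pair of nitroxide labels separated by distance r is

    K(t, r) = ∫₀¹ cos[(3x² − 1) ω(r) t] dx,   ω(r) = 2π D / r³,

with the dipolar constant D = 52.04 MHz·nm³.  A distance distribution
P(r) produces the dipolar evolution s(t) = ∫ K(t, r) P(r) dr; the
measured echo amplitude adds a modulation depth λ and a stretched-
exponential intermolecular background,

    V(t) = [1 − λ + λ s(t)] · exp(−k t^(d/3)).

Recovering P(r) from V(t) is ill-posed; it is solved here by Tikhonov
regularization with a second-difference roughness penalty and a
non-negativity constraint, with the regularization weight α chosen at
the corner of the L-curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import nnls
from scipy.special import fresnel

from .ensemble_io import DeerTrace

#: Dipolar coupling constant for a nitroxide pair (g ≈ g_e), MHz·nm³.
DIPOLAR_CONSTANT_MHZ_NM3 = 52.04


@dataclass(frozen=True)
class RGrid:
    """Uniform distance grid in nm."""

    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "r", r)
        if r.ndim != 1 or r.size < 2:
            raise ValueError("r grid needs at least 2 points")
        dr = np.diff(r)
        if np.any(dr <= 0):
            raise ValueError("r grid must be strictly increasing")
        if not np.allclose(dr, dr[0], rtol=1e-8, atol=1e-12):
            raise ValueError("r grid must be uniform")

    @property
    def dr(self) -> float:
        return float(self.r[1] - self.r[0])

    @property
    def n(self) -> int:
        return self.r.size


def default_rgrid(r_min: float = 1.5, r_max: float = 8.0, n: int = 256) -> RGrid:
    """The default inversion grid, 1.5–8.0 nm in 256 points."""
    return RGrid(np.linspace(r_min, r_max, n))


@dataclass
class DistanceDistribution:
    """A probability density P(r) per nm on a uniform grid."""

    grid: RGrid
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != self.grid.r.shape:
            raise ValueError("p must match the grid")
        if np.any(self.p < -1e-12):
            raise ValueError("p must be non-negative")
        self.p = np.clip(self.p, 0.0, None)

    def normalized(self) -> "DistanceDistribution":
        total = self.p.sum() * self.grid.dr
        if total <= 0:
            raise ValueError("cannot normalize an all-zero distribution")
        return DistanceDistribution(self.grid, self.p / total)

    @property
    def integral(self) -> float:
        return float(self.p.sum() * self.grid.dr)


def gaussian_mixture(grid: RGrid,
                     components: Sequence[Tuple[float, float, float]]) -> DistanceDistribution:
    """Build a normalized P(r) from (mean nm, sd nm, weight) components."""
    p = np.zeros_like(grid.r)
    for mean, sd, weight in components:
        if sd <= 0:
            raise ValueError("component sd must be positive")
        p += weight * np.exp(-0.5 * ((grid.r - mean) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
    return DistanceDistribution(grid, p).normalized()


@dataclass
class DipolarKernel:
    """K[j, k] = powder-averaged dipolar signal at time t[j], distance r[k]."""

    matrix: np.ndarray
    t: np.ndarray
    grid: RGrid
    dipolar_constant: float = DIPOLAR_CONSTANT_MHZ_NM3


@dataclass
class DeerModelParams:
    """Acquisition-level signal parameters: modulation depth λ,
    background decay rate k (µs^(-d/3)) and background dimensionality d."""

    mod_depth: float = 0.3
    bg_k: float = 0.05
    bg_dim: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mod_depth <= 1.0):
            raise ValueError("mod_depth must lie in [0, 1]")
        if self.bg_k < 0:
            raise ValueError("bg_k must be non-negative")


def _omega(r_nm: np.ndarray, dipolar_constant: float) -> np.ndarray:
    """Angular dipolar frequency, rad/µs, at distance r (nm)."""
    return 2.0 * math.pi * dipolar_constant / np.asarray(r_nm, dtype=float) ** 3


def kernel_value_fresnel(phi: np.ndarray) -> np.ndarray:
    """g(φ) = ∫₀¹ cos[(3x² − 1) φ] dx via Fresnel integrals.

    With q = sqrt(6φ/π):  g = sqrt(π/(6φ)) [cos φ · C(q) + sin φ · S(q)].
    """
    phi = np.asarray(phi, dtype=float)
    out = np.ones_like(phi)
    nz = phi > 1e-9
    ph = phi[nz]
    q = np.sqrt(6.0 * ph / math.pi)
    S, C = fresnel(q)
    out[nz] = (np.cos(ph) * C + np.sin(ph) * S) / q
    return out


def kernel_value_quadrature(phi: np.ndarray, order: int = 512) -> np.ndarray:
    """g(φ) by fixed-order Gauss–Legendre quadrature over x ∈ [0, 1]."""
    x, w = np.polynomial.legendre.leggauss(order)
    x = 0.5 * (x + 1.0)  # map [-1, 1] -> [0, 1]
    w = 0.5 * w
    phi = np.asarray(phi, dtype=float)
    # (..., order) broadcast
    arg = (3.0 * x ** 2 - 1.0) * phi[..., None]
    return np.cos(arg) @ w


def build_kernel(t: np.ndarray, grid: RGrid, method: str = "fresnel",
                 quad_order: int = 512,
                 dipolar_constant: float = DIPOLAR_CONSTANT_MHZ_NM3) -> DipolarKernel:
    """Dipolar kernel matrix on (t µs) × (r nm).

    ``method`` is ``"fresnel"`` (closed form, default) or
    ``"quadrature"`` (fixed-order Gauss–Legendre, an independent route
    to the same integral).
    """
    t = np.asarray(t, dtype=float)
    if t[0] != 0.0:
        raise ValueError("kernel time axis must start at t = 0")
    omega = _omega(grid.r, dipolar_constant)
    phi = np.abs(t[:, None] * omega[None, :])
    if method == "fresnel":
        K = kernel_value_fresnel(phi)
    elif method == "quadrature":
        K = kernel_value_quadrature(phi, order=quad_order)
    else:
        raise ValueError(f"unknown kernel method {method!r}")
    return DipolarKernel(matrix=K, t=t, grid=grid,
                         dipolar_constant=dipolar_constant)


def dipolar_signal(kernel: DipolarKernel, p: DistanceDistribution) -> np.ndarray:
    """s(t) = K P Δr for a distribution on the kernel's grid."""
    if p.grid.r.shape != kernel.grid.r.shape or not np.allclose(p.grid.r, kernel.grid.r):
        raise ValueError("distribution grid does not match kernel grid")
    return kernel.matrix @ p.p * kernel.grid.dr


def simulate_deer(p: DistanceDistribution, t: np.ndarray,
                  params: DeerModelParams = DeerModelParams(),
                  noise_sigma: float = 0.0,
                  seed: Optional[int] = None) -> DeerTrace:
    """Forward-simulate a 4-pulse DEER trace from P(r).

    V(t) = [1 − λ + λ s(t)] · exp(−k t^(d/3)) + ε,  ε ~ N(0, σ²),
    renormalized so v(0) = 1.  Noise requires an explicit seed: there is
    no hidden global random state.
    """
    t = np.asarray(t, dtype=float)
    kernel = build_kernel(t, p.grid)
    s = dipolar_signal(kernel, p.normalized())
    lam = params.mod_depth
    bg = np.exp(-params.bg_k * t ** (params.bg_dim / 3.0))
    v = (1.0 - lam + lam * s) * bg
    if noise_sigma > 0:
        if seed is None:
            raise ValueError("noisy simulation requires an explicit seed")
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sigma, size=v.shape)
    return DeerTrace(t=t, v=v / v[0])


def snr_to_sigma(snr: float) -> float:
    """Noise σ on the normalized echo amplitude for a given SNR
    (SNR = 1/σ with V(0) = 1)."""
    if snr <= 0:
        raise ValueError("SNR must be positive")
    return 1.0 / snr


# ---------------------------------------------------------------------------
# Background correction
# ---------------------------------------------------------------------------

def background_correct(trace: DeerTrace, fit_start_fraction: float = 0.6,
                       d: float = 3.0) -> Tuple[DeerTrace, float, float]:
    """Fit and divide out the intermolecular background.

    ln V over the tail window t >= fit_start_fraction * t_max is fitted
    to ln(1−λ) − k t^(d/3); the pure stretched-exponential exp(−k t^(d/3))
    is divided out, so the returned form factor starts at 1 and decays to
    its asymptote 1 − λ.  Returns (form_factor, bg_k, lambda_est).
    """
    t, v = trace.t, trace.v
    window = t >= fit_start_fraction * t[-1]
    if window.sum() < 10:
        raise ValueError("background fit window has fewer than 10 points")
    if np.any(v[window] <= 0):
        raise ValueError("non-positive amplitudes in background fit window")
    tw = t[window] ** (d / 3.0)
    A = np.column_stack([np.ones(window.sum()), -tw])
    coef, *_ = np.linalg.lstsq(A, np.log(v[window]), rcond=None)
    offset, k = float(coef[0]), float(coef[1])
    k = max(k, 0.0)
    lam = float(np.clip(1.0 - math.exp(offset), 0.0, 1.0))
    form = v / np.exp(-k * t ** (d / 3.0))
    form = form / form[0]
    return DeerTrace(t=t, v=form), k, lam


# ---------------------------------------------------------------------------
# Tikhonov inversion
# ---------------------------------------------------------------------------

@dataclass
class TikhonovResult:
    p_hat: DistanceDistribution
    alpha: float
    residual_norm: float
    penalty_norm: float
    mod_depth: float = float("nan")
    bg_k: float = float("nan")
    lcurve: List[Tuple[float, float, float]] = field(default_factory=list)


def second_difference_operator(n: int) -> np.ndarray:
    """Second-difference roughness operator with zero boundary
    (p[-1] := 0, p[n] := 0), so the grid edges are softly pinned to zero
    and no flat pedestal sits in the operator's null space."""
    L = np.zeros((n, n))
    for i in range(n):
        L[i, i] = -2.0
        if i > 0:
            L[i, i - 1] = 1.0
        if i < n - 1:
            L[i, i + 1] = 1.0
    return L


def tikhonov_invert(form_factor: DeerTrace, grid: RGrid, alpha: float,
                    kernel: Optional[DipolarKernel] = None,
                    maxiter: Optional[int] = None) -> TikhonovResult:
    """Invert a background-corrected form factor to P(r).

    The form factor is modelled as  ff(t) ≈ c₀ + K q Δr  with q ≥ 0 and
    a free non-negative intercept c₀; the regularized problem

        min_{q ≥ 0, c₀ ≥ 0} ‖c₀ + K q Δr − ff‖² + α²‖L₂ q‖²

    is solved by non-negative least squares on the stacked system.  The
    modulation depth falls out as λ = Σq Δr / (c₀ + Σq Δr) and
    P(r) = q / Σq Δr, so constant offsets and overall scale errors in
    the form factor (e.g. from normalizing at a noisy t = 0 point)
    cannot distort the recovered distribution.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if kernel is None:
        kernel = build_kernel(form_factor.t, grid)
    n = grid.n
    K = kernel.matrix * grid.dr
    L = second_difference_operator(n)
    ones = np.ones((form_factor.t.size, 1))
    A = np.vstack([np.hstack([ones, K]),
                   np.hstack([np.zeros((n, 1)), alpha * L])])
    b = np.concatenate([form_factor.v, np.zeros(n)])
    try:
        x, _ = nnls(A, b, maxiter=maxiter or 30 * n)
    except RuntimeError as exc:
        raise RuntimeError(
            f"NNLS failed to converge (alpha={alpha:g}, n={n}, "
            f"maxiter={maxiter or 30 * n}): {exc}"
        ) from exc
    c0, q = float(x[0]), x[1:]
    residual = float(np.linalg.norm(c0 + K @ q - form_factor.v))
    penalty = float(np.linalg.norm(L @ q))
    total = q.sum() * grid.dr
    lam = total / (c0 + total) if (c0 + total) > 0 else 0.0
    p_hat = DistanceDistribution(grid, q).normalized()
    return TikhonovResult(p_hat=p_hat, alpha=float(alpha),
                          residual_norm=residual, penalty_norm=penalty,
                          mod_depth=float(lam))


def default_alpha_grid(n: int = 14) -> np.ndarray:
    return np.logspace(-3, 2, n)


def select_alpha_lcurve(form_factor: DeerTrace, grid: RGrid,
                        alphas: Optional[np.ndarray] = None
                        ) -> Tuple[float, List[Tuple[float, float, float]]]:
    """Pick α at the L-curve corner (maximum curvature of log residual
    vs. log penalty over the α grid).

    Returns (alpha, lcurve) where lcurve lists (alpha, residual,
    penalty).  A degenerate curve (no curvature maximum) falls back to
    the mid-grid α with a warning.
    """
    if alphas is None:
        alphas = default_alpha_grid()
    alphas = np.sort(np.asarray(alphas, dtype=float))
    if alphas.size < 8:
        raise ValueError("need at least 8 alphas for L-curve selection")
    if np.unique(alphas).size != alphas.size:
        raise ValueError("alpha grid contains duplicate values")

    kernel = build_kernel(form_factor.t, grid)
    lcurve: List[Tuple[float, float, float]] = []
    for a in alphas:
        res = tikhonov_invert(form_factor, grid, a, kernel=kernel)
        lcurve.append((float(a), res.residual_norm, res.penalty_norm))

    eps = 1e-15
    x = np.log10(np.array([c[1] for c in lcurve]) + eps)
    y = np.log10(np.array([c[2] for c in lcurve]) + eps)
    # Curvature of the parametric curve (x(α), y(α)) by central differences.
    s_param = np.log10(alphas)
    dx = np.gradient(x, s_param)
    dy = np.gradient(y, s_param)
    ddx = np.gradient(dx, s_param)
    ddy = np.gradient(dy, s_param)
    kappa = (dx * ddy - dy * ddx) / np.power(dx * dx + dy * dy + eps, 1.5)
    interior = kappa[1:-1]
    if interior.size == 0 or not np.any(interior > 0):
        warnings.warn("degenerate L-curve: falling back to mid-grid alpha")
        return float(alphas[alphas.size // 2]), lcurve
    best = 1 + int(np.argmax(interior))
    return float(alphas[best]), lcurve


def _residual_at_k(trace: DeerTrace, k: float, K: np.ndarray, L: np.ndarray,
                   alpha: float, d: float) -> Tuple[float, float, np.ndarray]:
    """Residual of the full signal model at background rate k: divide
    exp(−k t^(d/3)) out, fit (c₀, q) by regularized NNLS, and measure
    the misfit against the raw trace."""
    t, v = trace.t, trace.v
    bg = np.exp(-k * t ** (d / 3.0))
    ff = v / bg
    ff = ff / ff[0]
    n = L.shape[0]
    ones = np.ones((t.size, 1))
    A = np.vstack([np.hstack([ones, K]),
                   np.hstack([np.zeros((n, 1)), alpha * L])])
    b = np.concatenate([ff, np.zeros(n)])
    x, _ = nnls(A, b, maxiter=30 * n)
    c0, q = float(x[0]), x[1:]
    resid = float(np.linalg.norm((c0 + K @ q) * bg - v))
    return resid, c0, q


def refine_background(trace: DeerTrace, grid: RGrid, alpha: float,
                      k_init: float, d: float = 3.0,
                      rel_tolerance: float = 0.01,
                      kernel: Optional[DipolarKernel] = None) -> float:
    """Refine the background rate k against the full trace.

    The residual of the joint (background × dipolar) model is an
    L-shaped function of k: underestimating k is cheap because the
    leftover decay is absorbed by spurious short-distance mass, while
    overestimating it is penalized sharply.  The refined k is therefore
    the largest rate whose full-model residual stays within
    ``rel_tolerance`` of the profile minimum — attribute as much decay
    as possible to the background.
    """
    from scipy.optimize import brentq, minimize_scalar

    if kernel is None:
        kernel = build_kernel(trace.t, grid)
    K = kernel.matrix * grid.dr
    L = second_difference_operator(grid.n)

    def resid(k: float) -> float:
        return _residual_at_k(trace, k, K, L, alpha, d)[0]

    k_lo, k_hi = 0.25 * k_init, 2.0 * k_init
    ks = np.linspace(k_lo, k_hi, 9)
    prof = [resid(k) for k in ks]
    i_min = int(np.argmin(prof))
    lo = ks[max(i_min - 1, 0)]
    hi = ks[min(i_min + 1, ks.size - 1)]
    opt = minimize_scalar(resid, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4 * max(k_init, 1e-6)})
    k_star, r_min = float(opt.x), float(opt.fun)
    target = (1.0 + rel_tolerance) * r_min
    if resid(k_hi) <= target:
        return k_hi
    try:
        return float(brentq(lambda k: resid(k) - target, k_star, k_hi, xtol=1e-5 * max(k_init, 1e-6)))
    except ValueError:
        return k_star


def invert_trace(trace: DeerTrace, grid: Optional[RGrid] = None,
                 alpha: Optional[float] = None, bg_dim: float = 3.0,
                 fit_start_fraction: float = 0.6,
                 refine_bg: bool = True) -> TikhonovResult:
    """Full analysis of a raw DEER trace.

    Steps: tail-window background fit, α selection by L-curve (unless
    given), full-trace refinement of the background rate, Tikhonov
    inversion of the corrected form factor.
    """
    if grid is None:
        grid = default_rgrid()
    form, bg_k, _ = background_correct(trace, fit_start_fraction, bg_dim)
    lcurve: List[Tuple[float, float, float]] = []
    if alpha is None:
        alpha, lcurve = select_alpha_lcurve(form, grid)
    if refine_bg and bg_k > 0:
        bg_k = refine_background(trace, grid, alpha, bg_k, d=bg_dim)
        ff = trace.v / np.exp(-bg_k * trace.t ** (bg_dim / 3.0))
        form = DeerTrace(t=trace.t, v=ff / ff[0])
    result = tikhonov_invert(form, grid, alpha)
    result.lcurve = lcurve
    result.bg_k = bg_k
    return result


# ---------------------------------------------------------------------------
# Distribution statistics
# ---------------------------------------------------------------------------

def distribution_stats(p: DistanceDistribution) -> Tuple[float, float, float, float]:
    """(mean nm, mode nm, fwhm nm, support width at 5% of max).

    fwhm interpolates the outermost half-maximum crossings linearly; the
    support width spans the region where P(r) >= 5% of its maximum.
    """
    dist = p.normalized()
    r, q = dist.grid.r, dist.p
    mean = float((r * q).sum() * dist.grid.dr)
    imax = int(np.argmax(q))
    mode = float(r[imax])
    fwhm = _width_at(r, q, q[imax] / 2.0)
    support = _width_at(r, q, 0.05 * q[imax])
    return mean, mode, fwhm, support


def _width_at(r: np.ndarray, q: np.ndarray, level: float) -> float:
    above = q >= level
    if not np.any(above):
        return 0.0
    first, last = np.flatnonzero(above)[[0, -1]]
    lo = r[first]
    if first > 0:
        lo = r[first - 1] + (r[first] - r[first - 1]) * (level - q[first - 1]) / (q[first] - q[first - 1])
    hi = r[last]
    if last < r.size - 1 and q[last + 1] != q[last]:
        hi = r[last] + (r[last + 1] - r[last]) * (level - q[last]) / (q[last + 1] - q[last])
    return float(hi - lo)
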