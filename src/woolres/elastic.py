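"""Elastic (SRVF) alignment of smooth curves within a flock-year group.

Phase variation is removed by representing each curve f through its square
root velocity function q = sign(f') sqrt(|f'|), finding for each animal the
monotone endpoint-preserving warp

    gamma* = argmin ||mu - (q o gamma) sqrt(gamma')||^2 + lambda R(gamma),

with R(gamma) = ||sqrt(gamma') - 1||^2 (deviation from the identity in SRVF
space), and iterating alignment with updates of the group Karcher mean mu.
The warp search is an exact dynamic program on an n x n lattice with local
slope constraints; curves are internally rescaled to [0, 1] so the penalty
weight lambda is comparable across series and groups.

The DP core is jitted with numba when available; a pure-Python fallback keeps
the module importable without it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import AlignmentConfig

__all__ = [
    "SRVFCurve",
    "WarpFunction",
    "GroupAlignment",
    "srvf_transform",
    "warp_srvf",
    "optimal_warp",
    "karcher_mean",
    "apply_warp",
    "align_group",
    "elastic_distance",
]


@dataclass
class SRVFCurve:
    grid: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.grid.size != self.q.size:
            raise ValueError("grid and q must have equal length")
        if not np.all(np.isfinite(self.q)):
            raise ValueError("SRVF values must be finite")


@dataclass
class WarpFunction:
    """Monotone endpoint-preserving reparameterization gamma of [t0, t1]."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.size != self.values.size:
            raise ValueError("grid and values must have equal length")
        t0, t1 = self.grid[0], self.grid[-1]
        span = t1 - t0
        if abs(self.values[0] - t0) > 1e-6 * span or abs(self.values[-1] - t1) > 1e-6 * span:
            raise ValueError("warp must preserve the endpoints")
        if (np.diff(self.values) < -1e-9 * span).any():
            raise ValueError("warp must be non-decreasing")

    def sup_deviation(self) -> float:
        """sup_t |gamma(t) - t|, the magnitude of the warp."""
        return float(np.max(np.abs(self.values - self.grid)))


def srvf_transform(grid: np.ndarray, values: np.ndarray) -> SRVFCurve:
    """q = sign(f') sqrt(|f'|) with the derivative by centered differences
    (one-sided at the ends)."""
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if grid.size < 3:
        raise ValueError("need at least 3 grid points")
    if (np.diff(grid) <= 0).any():
        raise ValueError("grid must be strictly increasing")
    df = np.gradient(values, grid)
    q = np.sign(df) * np.sqrt(np.abs(df))
    return SRVFCurve(grid, q)


def warp_srvf(q: np.ndarray, grid: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Group action of a warp on an SRVF: (q o gamma) sqrt(gamma')."""
    dg = np.gradient(gamma, grid)
    return np.interp(gamma, grid, q) * np.sqrt(np.maximum(dg, 0.0))


def _make_steps(window: float, max_component: int = 8) -> np.ndarray:
    """Coprime lattice steps (di, dj) with slope dj/di in [1/window, window],
    ordered by |log slope| so ties break toward the diagonal.  Components up
    to ``max_component`` give fine slope granularity inside the window."""
    steps = []
    for di in range(1, max_component + 1):
        for dj in range(1, max_component + 1):
            if math.gcd(di, dj) == 1:
                m = dj / di
                if 1.0 / window - 1e-12 <= m <= window + 1e-12:
                    steps.append((di, dj, abs(math.log(m))))
    steps.sort(key=lambda s: s[2])
    return np.array([(di, dj) for di, dj, _ in steps], dtype=np.int64)


def _dp_core_py(q1, q2, lam, steps, h):
    """DP over the n x n lattice; returns the path as index arrays."""
    n = q1.shape[0]
    INF = 1e30
    D = np.full((n, n), INF)
    Pi = np.full((n, n), -1, dtype=np.int32)
    D[0, 0] = 0.0
    n_steps = steps.shape[0]
    for i in range(1, n):
        for j in range(1, n):
            best = INF
            bs = -1
            for s in range(n_steps):
                di = steps[s, 0]
                dj = steps[s, 1]
                i0 = i - di
                j0 = j - dj
                if i0 < 0 or j0 < 0:
                    continue
                if D[i0, j0] >= INF:
                    continue
                m = dj / di
                sqm = math.sqrt(m)
                c = lam * (sqm - 1.0) ** 2 * di * h
                nsub = 2 * di  # sub-sampled data term along the edge
                for a in range(nsub):
                    u = i0 + di * (a + 0.5) / nsub
                    x = j0 + dj * (a + 0.5) / nsub
                    ku = int(u)
                    fu = u - ku
                    if ku + 1 < n:
                        q1v = q1[ku] * (1.0 - fu) + q1[ku + 1] * fu
                    else:
                        q1v = q1[n - 1]
                    k = int(x)
                    frac = x - k
                    if k + 1 < n:
                        qv = q2[k] * (1.0 - frac) + q2[k + 1] * frac
                    else:
                        qv = q2[n - 1]
                    d = q1v - qv * sqm
                    c += d * d * h * di / nsub
                tot = D[i0, j0] + c
                if tot < best - 1e-12:
                    best = tot
                    bs = s
            D[i, j] = best
            Pi[i, j] = bs
    # backtrack
    path_i = np.empty(2 * n, dtype=np.int64)
    path_j = np.empty(2 * n, dtype=np.int64)
    i, j, k = n - 1, n - 1, 0
    while i > 0 or j > 0:
        path_i[k] = i
        path_j[k] = j
        s = Pi[i, j]
        i -= steps[s, 0]
        j -= steps[s, 1]
        k += 1
    path_i[k] = 0
    path_j[k] = 0
    return path_i[: k + 1][::-1].copy(), path_j[: k + 1][::-1].copy()


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _dp_core = njit(cache=False)(_dp_core_py)
except ImportError:  # pragma: no cover
    _dp_core = _dp_core_py

_STEPS_CACHE: dict[float, np.ndarray] = {}


def _dp_warp(q_target: np.ndarray, q: np.ndarray, lam: float, window: float = 5.0) -> np.ndarray:
    """Optimal warp values on the normalized uniform grid [0, 1]."""
    n = q_target.size
    if window not in _STEPS_CACHE:
        _STEPS_CACHE[window] = _make_steps(window)
    steps = _STEPS_CACHE[window]
    h = 1.0 / (n - 1)
    pi, pj = _dp_core(
        np.ascontiguousarray(q_target, dtype=np.float64),
        np.ascontiguousarray(q, dtype=np.float64),
        float(lam), steps, h,
    )
    idx = np.arange(n, dtype=float)
    gamma = np.interp(idx, pi.astype(float), pj.astype(float)) * h
    gamma[0], gamma[-1] = 0.0, 1.0
    return np.maximum.accumulate(gamma)


def elastic_distance(q1: np.ndarray, q2: np.ndarray, h: float) -> float:
    """Discrete L2 distance between SRVFs (left Riemann sum, matching the DP
    data term so the identity-feasibility guarantee holds exactly)."""
    d = q1 - q2
    return float(np.sqrt(np.sum(d[:-1] ** 2) * h))


def optimal_warp(
    q: SRVFCurve, mu: SRVFCurve, lambda_align: float, window: float = 5.0
) -> WarpFunction:
    """Warp aligning ``q`` to the target ``mu`` on their common grid."""
    if q.grid.size != mu.grid.size or not np.allclose(q.grid, mu.grid):
        raise ValueError("q and mu must share one grid")
    if lambda_align < 0:
        raise ValueError("lambda_align must be >= 0")
    grid = q.grid
    dt = np.diff(grid)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("alignment requires a uniform grid")
    span = grid[-1] - grid[0]
    scale = math.sqrt(span)  # SRVF rescaling under domain normalization
    g01 = _dp_warp(mu.q * scale, q.q * scale, lambda_align, window)
    gamma = grid[0] + g01 * span
    return WarpFunction(grid, gamma)


def apply_warp(grid: np.ndarray, values: np.ndarray, gamma: WarpFunction) -> np.ndarray:
    """f~(t) = f(gamma(t)) by monotone (linear) interpolation."""
    if gamma.grid.size != np.asarray(grid).size:
        raise ValueError("warp grid does not match the curve grid")
    return np.interp(gamma.values, grid, values)


def karcher_mean(
    qs: list[np.ndarray],
    grid: np.ndarray,
    lambda_align: float = 0.0,
    tol: float = 1e-4,
    max_iter: int = 20,
    window: float = 5.0,
) -> dict:
    """Karcher (Fréchet) mean of a set of SRVFs with per-member warps.

    Alternates (i) DP alignment of every member to the current mean and (ii)
    mean update as the cross-member average of aligned SRVFs, with
    re-centering so the mean of the warps is the identity.  The recorded
    objective sum_i d(mu, q_i o gamma_i)^2 (+ lambda sum_i R(gamma_i)) is
    non-increasing across iterations by construction: an iteration that would
    increase it is rejected and iteration stops at the previous state.
    """
    if len(qs) < 2:
        raise ValueError("need at least 2 members")
    grid = np.asarray(grid, dtype=float)
    n = grid.size
    s = np.linspace(0.0, 1.0, n)
    h = 1.0 / (n - 1)
    span = grid[-1] - grid[0]
    scale = math.sqrt(span)
    Q = np.asarray(qs, dtype=float) * scale  # normalized-domain SRVFs

    mu = Q.mean(axis=0)
    warps = np.tile(s, (len(Q), 1))
    objective: list[float] = []
    converged = False

    def align_all(mu_cur):
        g = np.empty_like(warps)
        qa = np.empty_like(Q)
        obj = 0.0
        for i in range(len(Q)):
            g[i] = _dp_warp(mu_cur, Q[i], lambda_align, window)
            qa[i] = warp_srvf(Q[i], s, g[i])
            obj += elastic_distance(mu_cur, qa[i], h) ** 2
            sqdg = np.sqrt(np.maximum(np.gradient(g[i], s), 0.0))
            obj += lambda_align * np.sum((sqdg[:-1] - 1.0) ** 2) * h
        return g, qa, obj

    state = None
    for _ in range(max_iter):
        g, qa, obj = align_all(mu)
        if objective and obj > objective[-1] + 1e-12:
            converged = True  # alternation has bottomed out at DP resolution
            break  # keep the previous (better) state
        state = (mu.copy(), g, qa)
        objective.append(obj)
        if len(objective) >= 2 and abs(objective[-2] - obj) <= tol * max(1.0, abs(objective[-2])):
            converged = True
            break
        mu_new = qa.mean(axis=0)
        # re-center: compose everything with the inverse of the mean warp
        gbar = g.mean(axis=0)
        gbar_inv = np.interp(s, gbar, s)
        gbar_inv[0], gbar_inv[-1] = 0.0, 1.0
        mu = warp_srvf(mu_new, s, gbar_inv)

    if state is None:  # pragma: no cover - max_iter >= 1 always sets it
        raise RuntimeError("alignment produced no iterations")
    mu, g, qa = state
    if not converged and len(objective) >= max_iter:
        warnings.warn(
            f"Karcher mean did not converge in {max_iter} iterations "
            f"(final objective {objective[-1]:.6g})",
            RuntimeWarning,
        )
    gamma_out = [WarpFunction(grid, grid[0] + gi * span) for gi in g]
    return {
        "mean_q": mu / scale,
        "warps": gamma_out,
        "aligned_q": qa / scale,
        "objective": objective,
        "converged": converged,
    }


@dataclass
class GroupAlignment:
    """Alignment of one flock-year group at one warping-penalty lambda."""

    flock_year: str
    series: str
    lambda_align: float
    grid: np.ndarray
    animals: list[int]
    mean_function: np.ndarray  #: Fréchet mean in function space
    mean_q: np.ndarray
    aligned: np.ndarray  #: (n_animals, n_grid) aligned curves f o gamma*
    warps: list[WarpFunction] = field(repr=False)
    distances: np.ndarray = field(default=None, repr=False)
    objective: list[float] = field(default_factory=list, repr=False)
    converged: bool = True

    def warp_of(self, animal: int) -> WarpFunction:
        return self.warps[self.animals.index(animal)]

    def aligned_of(self, animal: int) -> np.ndarray:
        return self.aligned[self.animals.index(animal)]


def align_group(
    curves: dict[int, np.ndarray],
    grid: np.ndarray,
    lambda_align: float,
    flock_year: str = "",
    series: str = "",
    config: AlignmentConfig | None = None,
) -> GroupAlignment:
    """Elastic alignment of all curves of one flock-year group.

    ``curves`` maps animal id to curve values on the shared ``grid``.
    Computes the group Karcher mean, the per-animal optimal warps and the
    aligned curves in the original function space.
    """
    if len(curves) < 2:
        raise ValueError("group must contain at least 2 curves")
    config = config or AlignmentConfig()
    grid = np.asarray(grid, dtype=float)
    animals = list(curves)
    F = np.asarray([curves[a] for a in animals], dtype=float)
    qs = [srvf_transform(grid, f).q for f in F]
    km = karcher_mean(
        qs, grid, lambda_align=lambda_align, tol=config.tol,
        max_iter=config.max_iter, window=config.slope_window,
    )
    aligned = np.vstack([apply_warp(grid, F[i], km["warps"][i]) for i in range(len(F))])
    mean_fn = aligned.mean(axis=0)
    h = 1.0 / (grid.size - 1)
    span = grid[-1] - grid[0]
    dist = np.array(
        [
            elastic_distance(km["mean_q"] * math.sqrt(span), q * math.sqrt(span), h)
            for q in km["aligned_q"]
        ]
    )
    return GroupAlignment(
        flock_year=flock_year,
        series=series,
        lambda_align=lambda_align,
        grid=grid,
        animals=animals,
        mean_function=mean_fn,
        mean_q=km["mean_q"],
        aligned=aligned,
        warps=km["warps"],
        distances=dist,
        objective=km["objective"],
        converged=km["converged"],
    )
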