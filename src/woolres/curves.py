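"""Penalized B-spline smoothing of longitudinal records.

Each animal's raw records ``(t_j, y_j)`` on the domain ``[0, L]`` (staple
length in mm for FD, age at sampling in days for BW) are converted to a
smooth function ``x(c, t) = c' phi(t)`` by minimizing

    sum_j (y_j - x(t_j))^2 + lambda * int_0^L (x''(t))^2 dt,

with B-spline basis functions on group-level quantile knots.  The curvature
Gram matrix is computed exactly (Gauss-Legendre quadrature exact for the
piecewise-polynomial integrand), so the solution is the direct solve of
``(Phi'Phi + lambda R) c = Phi'y``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

from .config import SmoothingConfig

__all__ = [
    "SingularFitError",
    "SmoothCurve",
    "quantile_knots",
    "fit_penalized_spline",
    "evaluate_curve",
    "curvature_penalty_matrix",
    "standardize_raw",
    "bin_recording_moments",
]


class SingularFitError(np.linalg.LinAlgError):
    """Normal equations are singular (typically lambda = 0 with an
    unsupported basis function); reported rather than silently regularized."""


@dataclass
class SmoothCurve:
    """Fitted spline: coefficients + knots + order, with its evaluation grid."""

    coefficients: np.ndarray
    knots: np.ndarray  #: full (augmented) knot vector
    order: int
    domain: tuple[float, float]
    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        n_basis = len(self.knots) - self.order
        if len(self.coefficients) != n_basis:
            raise ValueError(
                f"{len(self.coefficients)} coefficients for {n_basis} basis functions"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve is not finite on its domain")

    @property
    def spline(self) -> BSpline:
        return BSpline(self.knots, self.coefficients, self.order - 1, extrapolate=False)


def quantile_knots(
    positions: np.ndarray,
    n_quantiles: int = 10,
    extra_knots: tuple[float, ...] = (),
    domain: tuple[float, float] | None = None,
) -> np.ndarray:
    """Interior knots at group-level empirical quantiles (type-7, linear
    interpolation), boundary knots at the domain ends, extra knots merged and
    deduplicated.  Returns the sorted break sequence (not yet augmented)."""
    positions = np.asarray(positions, dtype=float)
    if np.unique(positions).size < n_quantiles:
        raise ValueError(
            f"need >= {n_quantiles} distinct positions, got {np.unique(positions).size}"
        )
    lo, hi = domain if domain is not None else (positions.min(), positions.max())
    probs = np.arange(1, n_quantiles) / n_quantiles
    interior = np.quantile(positions, probs)  # type-7 linear interpolation
    breaks = np.concatenate([[lo], interior, list(extra_knots), [hi]])
    breaks = breaks[(breaks >= lo) & (breaks <= hi)]
    breaks = np.unique(np.round(breaks, 10))
    breaks[0], breaks[-1] = lo, hi  # keep the exact domain ends
    return breaks


def _augment(breaks: np.ndarray, order: int) -> np.ndarray:
    return np.concatenate(
        [np.repeat(breaks[0], order - 1), breaks, np.repeat(breaks[-1], order - 1)]
    )


def curvature_penalty_matrix(knots: np.ndarray, order: int) -> np.ndarray:
    """Exact Gram matrix R_ab = int B_a''(t) B_b''(t) dt over the domain.

    The integrand is piecewise polynomial of degree 2*(order-3) on each
    inter-knot interval, so Gauss-Legendre with ``order`` nodes per interval
    is exact.
    """
    k = order - 1  # spline degree
    n_basis = len(knots) - order
    R = np.zeros((n_basis, n_basis))
    if k < 2:
        return R  # curvature of piecewise-linear pieces is 0 a.e.
    # quadrature exact up to degree 2*order - 1 >= 2*(k - 2)
    xg, wg = np.polynomial.legendre.leggauss(order)
    uniq = np.unique(knots)
    for a, b in zip(uniq[:-1], uniq[1:]):
        mid, half = (a + b) / 2.0, (b - a) / 2.0
        pts = mid + half * xg
        D2 = _design_matrix(pts, knots, order, deriv=2)
        R += half * (D2 * wg[:, None]).T @ D2
    return R


def _design_matrix(x: np.ndarray, knots: np.ndarray, order: int, deriv: int = 0) -> np.ndarray:
    """Dense B-spline (derivative) design matrix via de Boor evaluation."""
    n_basis = len(knots) - order
    out = np.empty((len(x), n_basis))
    c = np.zeros(n_basis)
    for j in range(n_basis):
        c[j] = 1.0
        spl = BSpline(knots, c, order - 1, extrapolate=False)
        if deriv:
            spl = spl.derivative(deriv)
        out[:, j] = spl(x)
        c[j] = 0.0
    # basis functions vanish outside their support
    return np.nan_to_num(out, nan=0.0)


def fit_penalized_spline(
    positions: np.ndarray,
    values: np.ndarray,
    breaks: np.ndarray,
    config: SmoothingConfig,
    grid: np.ndarray | None = None,
) -> SmoothCurve:
    """Solve ``(Phi'Phi + lambda R) c = Phi'y`` and evaluate on the grid.

    ``breaks`` is the un-augmented break sequence (e.g. from
    :func:`quantile_knots`), clipped here to the span of this animal's data
    domain.  Raises :class:`SingularFitError` when the normal equations are
    singular (only possible at lambda = 0, whose penalty cannot regularize).
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    order = config.order
    if positions.size < order + 1:
        raise ValueError(f"need >= {order + 1} observations, got {positions.size}")
    breaks = np.asarray(breaks, dtype=float)
    lo, hi = breaks[0], breaks[-1]
    if positions.min() < lo - 1e-9 or positions.max() > hi + 1e-9:
        raise ValueError("observations outside the knot domain")
    knots = _augment(breaks, order)

    Phi = _design_matrix(positions, knots, order)
    R = curvature_penalty_matrix(knots, order)
    lam = config.lambda_smooth
    try:
        if lam == 0:
            cf = cho_factor(Phi.T @ Phi)
            coef = cho_solve(cf, Phi.T @ values)
        else:
            # stacked least-squares [Phi; sqrt(lam) E] with R = E'E solved by
            # QR: backward stable even for huge lambda, where the fit
            # collapses onto the penalty null space (the straight line)
            w, U = np.linalg.eigh(R)
            w = np.clip(w, 0.0, None)
            w[w < 1e-12 * max(w.max(), 1e-300)] = 0.0  # exact penalty null space
            E = np.sqrt(w)[:, None] * U.T
            Aug = np.vstack([Phi, np.sqrt(lam) * E])
            rhs = np.concatenate([values, np.zeros(E.shape[0])])
            coef, _, rank, _ = np.linalg.lstsq(Aug, rhs, rcond=None)
            if rank < Phi.shape[1]:
                raise SingularFitError("penalized system is rank deficient")
    except np.linalg.LinAlgError as exc:
        raise SingularFitError(str(exc)) from exc
    # cho_factor raises scipy's LinAlgError for indefinite; also catch near-singular
    if not np.all(np.isfinite(coef)):
        raise SingularFitError("non-finite spline coefficients")

    if grid is None:
        grid = np.arange(lo, hi + 0.5 * config.prediction_step, config.prediction_step)
        grid = grid[grid <= hi + 1e-9 * (hi - lo)]
    grid = np.asarray(grid, dtype=float)
    if grid.min() < lo - 1e-6 * (hi - lo) or grid.max() > hi + 1e-6 * (hi - lo):
        raise ValueError("prediction grid outside the knot domain")
    grid = np.clip(grid, lo, hi)
    spl = BSpline(knots, coef, order - 1, extrapolate=False)
    vals = spl(grid)
    return SmoothCurve(coef, knots, order, (lo, hi), np.asarray(grid, float), vals)


def evaluate_curve(
    curve: SmoothCurve, grid: np.ndarray, deriv: int = 0
) -> np.ndarray:
    """De Boor evaluation of the fitted spline (or a derivative) on a grid
    inside the domain."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = curve.domain
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        raise ValueError("grid outside the curve domain")
    spl = curve.spline
    if deriv:
        spl = spl.derivative(deriv)
    out = spl(np.clip(grid, lo, hi))
    return np.nan_to_num(out, nan=0.0)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def bin_recording_moments(days: np.ndarray, gap: float = 7.0) -> np.ndarray:
    """Cluster BW recording ages into the group's measurement occasions.

    Sorted ages are split wherever the gap to the previous age exceeds
    ``gap`` days; each record gets the integer label of its cluster.
    """
    days = np.asarray(days, dtype=float)
    order = np.argsort(days, kind="stable")
    labels = np.empty(days.size, dtype=int)
    lab = 0
    prev = None
    for idx in order:
        if prev is not None and days[idx] - prev > gap:
            lab += 1
        labels[idx] = lab
        prev = days[idx]
    return labels


def standardize_raw(
    records: pd.DataFrame,
    moment_gap: float = 7.0,
    drop_singletons: bool = False,
) -> pd.DataFrame:
    """Standardize raw records to mean 0, sd 1 (n-1 denominator) within each
    flock-year group (FD) or flock-year x recording-moment cell (BW).

    Returns a copy with ``value`` replaced by the z-score and a ``cell``
    column recording the standardization cell.  Raises on a constant cell;
    with ``drop_singletons`` single-record cells (a stray BW weighing date
    shared with no herd mate) are dropped instead of raising.
    """
    out = records.reset_index(drop=True).copy()
    cells = np.empty(len(out), dtype=object)
    fd_mask = out["series"] == "FD"
    cells[fd_mask.to_numpy()] = [
        f"{fy}" for fy in out.loc[fd_mask, "flock_year"]
    ]
    for fy, sub in out[~fd_mask].groupby("flock_year", sort=False):
        labels = bin_recording_moments(sub["position"].to_numpy(), gap=moment_gap)
        cells[sub.index.to_numpy()] = [f"{fy}:m{l}" for l in labels]
    out["cell"] = cells
    if drop_singletons:
        sizes = out.groupby("cell")["value"].transform("size")
        out = out[sizes >= 2].reset_index(drop=True)

    z = np.empty(len(out))
    for cell, sub in out.groupby("cell", sort=False):
        v = sub["value"].to_numpy(dtype=float)
        if v.size < 2:
            raise ValueError(f"standardization cell {cell!r} has fewer than 2 records")
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero within-group sd in cell {cell!r}")
        z[sub.index.to_numpy()] = (v - v.mean()) / sd
    out["value"] = z
    return out
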