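"""Relationship matrices and REML variance components for the animal model.

Univariate model:  y = Xb + Z1 a + Z2 m + e  with  var(a) = H sigma_a^2,
var(m) = I sigma_m^2 (maternal permanent environmental effect, one level per
dam), var(e) = I sigma_e^2.  H blends the pedigree numerator matrix A with
the VanRaden (method 1) genomic matrix G via G_w = alpha G + (1-alpha) A22
(alpha = 0.95) in the standard single-step construction.  Bivariate models
put an unstructured 2x2 covariance matrix on each of the three components.

Estimation is AI-REML with EM warm-up steps, working on the phenotype
covariance V(theta) = sum_i theta_i V_i, which only requires the
phenotyped-animal submatrix of H.  Likelihood, gradient and average
information all decompose over connected components of V's sparsity graph,
so designs made of unrelated families cost little even at thousands of
records.  Steps are accepted only if the restricted log-likelihood does not
decrease (step halving otherwise), which makes the recorded trajectory
monotone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .config import GeneticsConfig
from .simdata import UNKNOWN, Pedigree

__all__ = [
    "build_A",
    "build_G",
    "blend_and_build_H",
    "RelationshipSet",
    "ModelFrame",
    "make_model_frame",
    "VarianceComponents",
    "BivariateFit",
    "reml_univariate",
    "reml_bivariate",
    "significance",
]


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------

def build_A(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular (recursive) method,
    including inbreeding.  Requires the pedigree's topological order
    (parents precede offspring), which :class:`Pedigree` guarantees."""
    n = len(ped)
    A = np.zeros((n, n))
    pos = ped._pos
    for i in range(n):
        s = pos[int(ped.sire[i])] if ped.sire[i] != UNKNOWN else -1
        d = pos[int(ped.dam[i])] if ped.dam[i] != UNKNOWN else -1
        if i:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        F = 0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + F
    return A


def build_G(genotypes: np.ndarray, freqs: np.ndarray | None = None) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    G = ZZ' / (2 sum p(1-p)) with Z = M - 2p; by default p are the observed
    allele frequencies of the genotyped set.  Monomorphic SNPs are dropped.
    """
    M = np.asarray(genotypes, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a 2-D genotype matrix with >= 2 animals")
    p = M.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic")
    M, p = M[:, poly], p[poly]
    Z = M - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    return (Z @ Z.T) / denom


@dataclass
class RelationshipSet:
    """A, optional G / blended G_w, and the single-step H (with inverse)."""

    ids: np.ndarray  #: animal ids indexing the matrices
    A: np.ndarray
    G: np.ndarray | None = None
    G_w: np.ndarray | None = None
    H: np.ndarray | None = None
    H_inv: np.ndarray | None = field(default=None, repr=False)
    genotyped: np.ndarray | None = None  #: ids of genotyped animals
    alpha: float = 0.95

    def kinship(self) -> np.ndarray:
        """The relationship matrix the model should use (H if genomic
        information was blended in, else A)."""
        return self.H if self.H is not None else self.A

    def submatrix(self, ids: np.ndarray) -> np.ndarray:
        pos = {int(a): i for i, a in enumerate(self.ids)}
        idx = np.array([pos[int(a)] for a in ids])
        K = self.kinship()
        return K[np.ix_(idx, idx)]


def blend_and_build_H(
    ped: Pedigree,
    A: np.ndarray,
    G: np.ndarray | None,
    genotyped_ids: np.ndarray | None,
    alpha: float = 0.95,
) -> RelationshipSet:
    """Single-step H from A and G on the genotyped block.

    G_w = alpha G + (1 - alpha) A22;
    H^-1 = A^-1 + [[0, 0], [0, G_w^-1 - A22^-1]];
    equivalently H modifies A only in and through the genotyped block.
    With an empty genotyped set H = A exactly.
    """
    ids = ped.animal
    if G is None or genotyped_ids is None or len(genotyped_ids) == 0:
        return RelationshipSet(ids=ids, A=A, H=A.copy(), H_inv=None, alpha=alpha)
    gset = set(int(a) for a in genotyped_ids)
    if not gset <= set(int(a) for a in ids):
        raise ValueError("genotyped ids must be a subset of pedigree ids")
    g_idx = np.array([i for i, a in enumerate(ids) if int(a) in gset])
    n_idx = np.array([i for i, a in enumerate(ids) if int(a) not in gset])
    if G.shape[0] != g_idx.size:
        raise ValueError("G dimension must match the genotyped set")
    A22 = A[np.ix_(g_idx, g_idx)]
    G_w = alpha * G + (1.0 - alpha) * A22
    A22_inv = np.linalg.inv(A22)
    G_w_inv = np.linalg.inv(G_w)

    H = A.copy()
    if n_idx.size:
        A12 = A[np.ix_(n_idx, g_idx)]
        B = A12 @ A22_inv
        H[np.ix_(n_idx, n_idx)] = A[np.ix_(n_idx, n_idx)] + B @ (G_w - A22) @ B.T
        H[np.ix_(n_idx, g_idx)] = B @ G_w
        H[np.ix_(g_idx, n_idx)] = H[np.ix_(n_idx, g_idx)].T
    H[np.ix_(g_idx, g_idx)] = G_w

    H_inv = np.linalg.inv(A)
    H_inv[np.ix_(g_idx, g_idx)] += G_w_inv - A22_inv
    return RelationshipSet(
        ids=ids, A=A, G=G, G_w=G_w, H=H, H_inv=H_inv,
        genotyped=np.asarray(sorted(gset)), alpha=alpha,
    )


# ---------------------------------------------------------------------------
# model frame
# ---------------------------------------------------------------------------

@dataclass
class ModelFrame:
    """Response, fixed-effect design and random-effect maps for one trait."""

    y: np.ndarray
    X: np.ndarray
    animals: np.ndarray  #: animal id per record
    dams: np.ndarray  #: maternal level label per record
    trait: str = ""

    def __post_init__(self) -> None:
        n = self.y.size
        if self.X.shape[0] != n or self.animals.size != n or self.dams.size != n:
            raise ValueError("inconsistent record counts in model frame")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design X is rank deficient")


def make_model_frame(
    data: pd.DataFrame,
    ped: Pedigree | None = None,
    value_col: str = "value",
    covariates: list[str] | None = None,
    trait: str = "",
) -> ModelFrame:
    """Design matrices from a tidy per-animal table.

    Fixed effects: intercept, birth-rearing type (``brt``, 3 levels) and
    contemporary group (flock-year x sex), reference-level coded.  The
    maternal level is the animal's dam from the pedigree; animals with an
    unknown dam get their own singleton level.
    """
    df = data.reset_index(drop=True)
    keep = np.isfinite(df[value_col].to_numpy(dtype=float))
    df = df[keep].reset_index(drop=True)
    y = df[value_col].to_numpy(dtype=float)
    cols = [np.ones(len(df))]
    if "brt" in df:
        for lev in sorted(df["brt"].unique())[1:]:
            cols.append((df["brt"] == lev).to_numpy(dtype=float))
    if "flock_year" in df:
        sex = df["sex"] if "sex" in df else pd.Series([""] * len(df))
        cg = df["flock_year"].astype(str) + "_" + sex.astype(str)
        for lev in sorted(cg.unique())[1:]:
            cols.append((cg == lev).to_numpy(dtype=float))
    for cov in covariates or []:
        cols.append(df[cov].to_numpy(dtype=float))
    X = np.column_stack(cols)
    animals = df["animal"].to_numpy(dtype=np.int64)
    if ped is not None:
        dam_of = {int(a): int(d) for a, d in zip(ped.animal, ped.dam)}
        dams = np.array(
            [
                dam_of.get(int(a), UNKNOWN) if dam_of.get(int(a), UNKNOWN) != UNKNOWN
                else -(int(a) + 1)  # singleton level for unknown dams
                for a in animals
            ],
            dtype=np.int64,
        )
    elif "dam" in df:
        dams = df["dam"].to_numpy(dtype=np.int64)
        dams[dams == UNKNOWN] = -(animals[dams == UNKNOWN] + 1)
    else:
        dams = -(animals + 1)
    return ModelFrame(y=y, X=X, animals=animals, dams=dams, trait=trait)


def _dam_structure(dams: np.ndarray) -> np.ndarray:
    """Z2 Z2' incidence product: 1 where two records share a maternal level."""
    return (dams[:, None] == dams[None, :]).astype(float)


def _cross_structure(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a[:, None] == b[None, :]).astype(float)


# ---------------------------------------------------------------------------
# generic linear-covariance REML
# ---------------------------------------------------------------------------

class _REMLProblem:
    """Restricted likelihood of y ~ N(Xb, sum_i theta_i V_i), with all
    quantities computed per connected component of the V sparsity graph."""

    def __init__(self, y: np.ndarray, X: np.ndarray, Vs: list[np.ndarray]):
        self.n, self.p = X.shape
        pattern = np.zeros((self.n, self.n), dtype=bool)
        for V in Vs:
            pattern |= np.abs(V) > 1e-12
        _, labels = connected_components(csr_matrix(pattern), directed=False)
        self.comps = [np.where(labels == c)[0] for c in np.unique(labels)]
        self.y = [y[idx] for idx in self.comps]
        self.X = [X[idx] for idx in self.comps]
        self.Vs = [[V[np.ix_(idx, idx)] for idx in self.comps] for V in Vs]
        self.k = len(Vs)

    def evaluate(self, theta: np.ndarray, derivatives: bool = True) -> dict | None:
        """Returns loglik (and gradient + AI matrix); None if V(theta) is not
        positive definite on some component."""
        k, p = self.k, self.p
        logdetV = 0.0
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        ytViy = 0.0
        blocks = []
        for c, idx in enumerate(self.comps):
            V = sum(theta[i] * self.Vs[i][c] for i in range(k))
            try:
                cf = cho_factor(V, lower=True)
            except np.linalg.LinAlgError:
                return None
            logdetV += 2.0 * np.sum(np.log(np.diag(cf[0])))
            if derivatives:
                Vinv = cho_solve(cf, np.eye(idx.size))
                ViX = Vinv @ self.X[c]
                Viy = Vinv @ self.y[c]
            else:  # likelihood only: skip the explicit inverse
                Vinv = None
                ViX = cho_solve(cf, self.X[c])
                Viy = cho_solve(cf, self.y[c])
            XtViX += self.X[c].T @ ViX
            XtViy += self.X[c].T @ Viy
            ytViy += self.y[c] @ Viy
            blocks.append((Vinv, ViX, Viy))
        try:
            cfx = cho_factor(XtViX)
        except np.linalg.LinAlgError:
            return None
        logdetX = 2.0 * np.sum(np.log(np.diag(cfx[0])))
        w = cho_solve(cfx, XtViy)
        yPy = ytViy - XtViy @ w
        ll = -0.5 * (logdetV + logdetX + yPy)
        out = {"loglik": ll}
        if not derivatives:
            return out

        # Py per component
        Py = [blocks[c][2] - blocks[c][1] @ w for c in range(len(self.comps))]
        XtViX_inv = cho_solve(cfx, np.eye(p))
        grad = np.zeros(k)
        Wvec = [None] * k  # V_i P y per component
        trPV = np.zeros(k)
        for i in range(k):
            s_tr = 0.0
            M = np.zeros((p, p))
            yPViPy = 0.0
            wi = []
            for c in range(len(self.comps)):
                Vi = self.Vs[i][c]
                Vinv, ViX, _ = blocks[c]
                s_tr += float(np.sum(Vinv * Vi))
                M += ViX.T @ Vi @ ViX
                v = Vi @ Py[c]
                wi.append(v)
                yPViPy += float(Py[c] @ v)
            trPV[i] = s_tr - float(np.sum(XtViX_inv * M))
            grad[i] = -0.5 * (trPV[i] - yPViPy)
            Wvec[i] = wi
        # P w_i per component, then AI_ij = 0.5 w_i' P w_j
        PW = []
        for i in range(k):
            xtw = np.zeros(p)
            Viw = []
            for c in range(len(self.comps)):
                Vinv, ViX, _ = blocks[c]
                vw = Vinv @ Wvec[i][c]
                Viw.append(vw)
                xtw += self.X[c].T @ vw
            corr = cho_solve(cfx, xtw)
            PW.append([Viw[c] - blocks[c][1] @ corr for c in range(len(self.comps))])
        AI = np.zeros((k, k))
        for i in range(k):
            for j in range(i, k):
                v = sum(float(Wvec[i][c] @ PW[j][c]) for c in range(len(self.comps)))
                AI[i, j] = AI[j, i] = 0.5 * v
        # grad = -0.5 (trPV - yPViPy)  =>  yPViPy = trPV + 2 grad
        out.update(grad=grad, AI=AI, trPV=trPV, yPViPy=trPV + 2.0 * grad)
        return out


def _run_reml(
    problem: _REMLProblem,
    theta0: np.ndarray,
    var_mask: np.ndarray,
    psd_groups: list[tuple[int, int, int]],
    cfg: GeneticsConfig,
) -> dict:
    """AI-REML with EM warm-up, step halving and variance floors.

    ``var_mask`` marks variance-type parameters (floored at
    ``cfg.variance_floor``); ``psd_groups`` lists (i11, i12, i22) index
    triples whose 2x2 matrices are bent to PSD after each step.
    """
    floor = cfg.variance_floor

    def repair(theta: np.ndarray) -> np.ndarray:
        th = theta.copy()
        th[var_mask] = np.maximum(th[var_mask], floor)
        for i11, i12, i22 in psd_groups:
            lim = 0.9995 * np.sqrt(th[i11] * th[i22])
            if abs(th[i12]) > lim:
                th[i12] = np.sign(th[i12]) * lim
        return th

    theta = repair(theta0.astype(float))
    ev = problem.evaluate(theta)
    if ev is None:
        raise RuntimeError("initial variance components give a singular V")
    trajectory = [ev["loglik"]]
    converged = False
    n_iter = 0
    stall = 0
    for it in range(cfg.max_iter):
        n_iter = it + 1
        if it < cfg.em_warmup:
            new = theta.copy()
            for i in np.where(var_mask)[0]:
                if ev["trPV"][i] > 0 and ev["yPViPy"][i] > 0:
                    new[i] = theta[i] * ev["yPViPy"][i] / ev["trPV"][i]
            delta = new - theta
        else:
            # active-set: a variance stuck at the floor with a downhill
            # gradient stays there instead of bouncing forever, and a
            # covariance loses meaning once either of its variances is floored
            fixed = var_mask & (theta <= floor * 1.01) & (ev["grad"] < 0)
            for i11, i12, i22 in psd_groups:
                if theta[i11] <= floor * 1.01 or theta[i22] <= floor * 1.01:
                    fixed[i12] = True
            free = ~fixed
            AI = ev["AI"][np.ix_(free, free)] + 1e-10 * np.eye(int(free.sum()))
            try:
                d_free = np.linalg.solve(AI, ev["grad"][free])
            except np.linalg.LinAlgError:
                d_free = np.linalg.lstsq(AI, ev["grad"][free], rcond=None)[0]
            delta = np.zeros(problem.k)
            delta[free] = d_free
            # a near-singular AI can propose astronomically long steps: cap
            # each parameter's move at a few times the parameter scale so
            # step halving searches a sane range
            scale = np.maximum(np.abs(theta), 0.1 * max(np.abs(theta).max(), floor))
            factor = np.max(np.abs(delta) / scale) / 5.0
            if factor > 1.0:
                delta = delta / factor

        def try_direction(d):
            # cheap likelihood-only evaluations while halving; derivatives
            # are recomputed once for the accepted point
            step = 1.0
            for _ in range(25):
                cand = repair(theta + step * d)
                ev_c = problem.evaluate(cand, derivatives=False)
                if ev_c is not None and ev_c["loglik"] >= trajectory[-1] - 1e-10:
                    return cand, problem.evaluate(cand)
                step *= 0.5
            return None

        accepted = try_direction(delta)
        if accepted is None and it >= cfg.em_warmup:
            em = theta.copy()  # EM fallback when the AI direction fails
            for i in np.where(var_mask)[0]:
                if ev["trPV"][i] > 0 and ev["yPViPy"][i] > 0:
                    em[i] = theta[i] * ev["yPViPy"][i] / ev["trPV"][i]
            accepted = try_direction(em - theta)
        if accepted is None:
            converged = True  # no uphill direction at working precision
            break
        new_theta, ev = accepted
        active = ~(var_mask & (new_theta <= floor * 1.01))
        rel_par = np.max(
            np.abs(new_theta - theta)[active]
            / np.maximum(np.abs(theta), 1e-8)[active]
        ) if active.any() else 0.0
        rel_ll = abs(ev["loglik"] - trajectory[-1]) / max(1.0, abs(trajectory[-1]))
        theta = new_theta
        trajectory.append(ev["loglik"])
        if it >= cfg.em_warmup and rel_ll < cfg.loglik_tol:
            stall += 1
            if rel_par < cfg.param_tol or stall >= 3:
                converged = True
                break
        else:
            stall = 0
    if not converged:
        warnings.warn(
            f"REML did not converge in {cfg.max_iter} iterations "
            f"(loglik trajectory tail {trajectory[-3:]})",
            RuntimeWarning,
        )
    cov = np.linalg.pinv(ev["AI"])
    return {
        "theta": theta,
        "se": np.sqrt(np.maximum(np.diag(cov), 0.0)),
        "cov": cov,
        "loglik": trajectory[-1],
        "trajectory": trajectory,
        "converged": converged,
        "n_iter": n_iter,
    }


# ---------------------------------------------------------------------------
# univariate / bivariate front ends
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_m2: float
    sigma_e2: float
    se: np.ndarray
    h2: float
    h2_se: float
    loglik: float
    trajectory: list[float]
    converged: bool
    n_iter: int
    trait: str = ""

    def __post_init__(self) -> None:
        if min(self.sigma_a2, self.sigma_m2, self.sigma_e2) < 0:
            raise ValueError("variance components must be >= 0")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")


def _h2_delta(theta: np.ndarray, cov: np.ndarray) -> tuple[float, float]:
    total = theta.sum()
    h2 = theta[0] / total
    g = np.full(theta.size, -theta[0] / total**2)
    g[0] += 1.0 / total
    return float(h2), float(np.sqrt(max(g @ cov @ g, 0.0)))


def reml_univariate(
    frame: ModelFrame,
    K_obs: np.ndarray,
    config: GeneticsConfig | None = None,
    theta0: np.ndarray | None = None,
    include_maternal: bool = True,
) -> VarianceComponents:
    """Univariate animal model y = Xb + Z1 a + Z2 m + e.

    ``K_obs`` is the relationship (H or A) submatrix over the frame's
    records, e.g. ``rel.submatrix(frame.animals)``.  With
    ``include_maternal=False`` (or when every maternal level is a singleton,
    where Z2 Z2' = I aliases the maternal and residual components) the model
    reduces to y = Xb + Z1 a + e.
    """
    config = config or GeneticsConfig()
    n = frame.y.size
    if n < frame.X.shape[1] + 3:
        raise ValueError("too few records for the fixed effects")
    D = _dam_structure(frame.dams)
    if np.array_equal(D, np.eye(n)):
        include_maternal = False  # aliased with the residual
    Vs = [np.asarray(K_obs, dtype=float)] + ([D] if include_maternal else []) + [np.eye(n)]
    if theta0 is None:
        v = np.var(frame.y - frame.X @ np.linalg.lstsq(frame.X, frame.y, rcond=None)[0])
        v = max(v, 1e-6)
        theta0 = np.array([0.3 * v, 0.1 * v, 0.6 * v])
    if not include_maternal:
        theta0 = np.asarray(theta0)[[0, 2]] if len(theta0) == 3 else np.asarray(theta0)
    prob = _REMLProblem(frame.y, frame.X, Vs)
    res = _run_reml(prob, theta0, np.ones(len(Vs), dtype=bool), [], config)
    t, cov, se = res["theta"], res["cov"], res["se"]
    if not include_maternal:  # re-insert sigma_m2 = 0 for a uniform report
        t = np.array([t[0], 0.0, t[1]])
        cov3 = np.zeros((3, 3))
        cov3[np.ix_([0, 2], [0, 2])] = cov
        cov = cov3
        se = np.array([se[0], 0.0, se[1]])
    h2, h2_se = _h2_delta(t, cov)
    return VarianceComponents(
        sigma_a2=float(t[0]), sigma_m2=float(t[1]), sigma_e2=float(t[2]),
        se=se, h2=h2, h2_se=h2_se, loglik=res["loglik"],
        trajectory=res["trajectory"], converged=res["converged"],
        n_iter=res["n_iter"], trait=frame.trait,
    )


@dataclass
class BivariateFit:
    cov_a: np.ndarray
    cov_m: np.ndarray
    cov_e: np.ndarray
    r_g: float
    r_g_se: float
    r_p: float
    r_p_se: float
    h2: tuple[float, float]
    se: np.ndarray
    loglik: float
    converged: bool
    traits: tuple[str, str] = ("t1", "t2")

    def __post_init__(self) -> None:
        for M in (self.cov_a, self.cov_m, self.cov_e):
            if not np.allclose(M, M.T):
                raise ValueError("component covariance matrices must be symmetric")
        if abs(self.r_g) > 1 + 1e-9 or abs(self.r_p) > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def r_g_significant(self) -> bool:
        return significance(self.r_g, self.r_g_se)


def _corr_delta(c12: float, v1: float, v2: float, J: np.ndarray, cov: np.ndarray) -> tuple[float, float]:
    """Correlation and its delta-method SE.  ``J`` has rows = gradients of
    (c12, v1, v2) w.r.t. theta."""
    r = c12 / np.sqrt(v1 * v2)
    dr = np.array([
        1.0 / np.sqrt(v1 * v2),
        -0.5 * c12 / (v1 ** 1.5 * np.sqrt(v2)),
        -0.5 * c12 / (np.sqrt(v1) * v2 ** 1.5),
    ])
    g = dr @ J
    return float(r), float(np.sqrt(max(g @ cov @ g, 0.0)))


def reml_bivariate(
    frame1: ModelFrame,
    frame2: ModelFrame,
    K_maker,
    config: GeneticsConfig | None = None,
) -> BivariateFit:
    """Bivariate animal model with unstructured 2x2 additive, maternal and
    residual covariance matrices (Kronecker structure over H / I).

    ``K_maker(ids_a, ids_b)`` must return the relationship submatrix between
    two id vectors (e.g. a closure over H).  Residual and maternal
    covariances connect records of the two traits on the same animal / dam.
    """
    config = config or GeneticsConfig()
    n1, n2 = frame1.y.size, frame2.y.size
    n = n1 + n2
    y = np.concatenate([frame1.y, frame2.y])
    p1, p2 = frame1.X.shape[1], frame2.X.shape[1]
    X = np.zeros((n, p1 + p2))
    X[:n1, :p1] = frame1.X
    X[n1:, p1:] = frame2.X

    K11 = K_maker(frame1.animals, frame1.animals)
    K22 = K_maker(frame2.animals, frame2.animals)
    K12 = K_maker(frame1.animals, frame2.animals)
    D11 = _dam_structure(frame1.dams)
    D22 = _dam_structure(frame2.dams)
    D12 = _cross_structure(frame1.dams, frame2.dams)
    E12 = _cross_structure(frame1.animals, frame2.animals)

    def block(M11=None, M12=None, M22=None):
        V = np.zeros((n, n))
        if M11 is not None:
            V[:n1, :n1] = M11
        if M22 is not None:
            V[n1:, n1:] = M22
        if M12 is not None:
            V[:n1, n1:] = M12
            V[n1:, :n1] = M12.T
        return V

    # theta order: a11 a12 a22 m11 m12 m22 e11 e12 e22
    Vs = [
        block(M11=K11), block(M12=K12), block(M22=K22),
        block(M11=D11), block(M12=D12), block(M22=D22),
        block(M11=np.eye(n1)), block(M12=E12), block(M22=np.eye(n2)),
    ]
    var_mask = np.array([True, False, True, True, False, True, True, False, True])
    psd_groups = [(0, 1, 2), (3, 4, 5), (6, 7, 8)]

    v1 = max(np.var(frame1.y), 1e-6)
    v2 = max(np.var(frame2.y), 1e-6)
    theta0 = np.array([
        0.3 * v1, 0.0, 0.3 * v2,
        0.1 * v1, 0.0, 0.1 * v2,
        0.6 * v1, 0.0, 0.6 * v2,
    ])
    prob = _REMLProblem(y, X, Vs)
    res = _run_reml(prob, theta0, var_mask, psd_groups, config)
    t, cov = res["theta"], res["cov"]

    cov_a = np.array([[t[0], t[1]], [t[1], t[2]]])
    cov_m = np.array([[t[3], t[4]], [t[4], t[5]]])
    cov_e = np.array([[t[6], t[7]], [t[7], t[8]]])
    J_g = np.zeros((3, 9)); J_g[0, 1] = 1; J_g[1, 0] = 1; J_g[2, 2] = 1
    r_g, r_g_se = _corr_delta(t[1], t[0], t[2], J_g, cov)
    # phenotypic (co)variances are sums over the three components
    J_p = np.zeros((3, 9))
    J_p[0, [1, 4, 7]] = 1
    J_p[1, [0, 3, 6]] = 1
    J_p[2, [2, 5, 8]] = 1
    cp = t[1] + t[4] + t[7]
    vp1 = t[0] + t[3] + t[6]
    vp2 = t[2] + t[5] + t[8]
    r_p, r_p_se = _corr_delta(cp, vp1, vp2, J_p, cov)
    h2 = (float(t[0] / vp1), float(t[2] / vp2))
    return BivariateFit(
        cov_a=cov_a, cov_m=cov_m, cov_e=cov_e,
        r_g=float(np.clip(r_g, -1, 1)), r_g_se=r_g_se,
        r_p=float(np.clip(r_p, -1, 1)), r_p_se=r_p_se,
        h2=h2, se=res["se"], loglik=res["loglik"], converged=res["converged"],
        traits=(frame1.trait or "t1", frame2.trait or "t2"),
    )


def significance(estimate: float, se: float) -> bool:
    """Approximate 95% rule: significant iff |estimate| > 2 * SE."""
    if se < 0:
        raise ValueError("standard error must be >= 0")
    return abs(estimate) > 2.0 * se
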