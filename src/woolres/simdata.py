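"""Synthetic pedigreed cohorts with longitudinal fibre-diameter and body-weight series.

The generator emulates the data structure the downstream analysis assumes:
flock-year groups of yearling sheep linked across groups by common sires, wool
fibre diameter (FD) measured at fixed 5 mm increments along the staple (the
staple spans the animal's life from birth to wool sampling, so staple position
maps proportionally to age), body weight (BW) recorded at shared group
occasions between birth and sampling, a weaning collapse-and-recovery
disturbance plus random transient disturbances whose magnitudes scale with a
heritable latent susceptibility, individual smooth monotone phase variation,
and iid measurement noise.

Everything is driven by one seeded generator with deterministic per-module
streams, so a fixed seed reproduces the cohort bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig

__all__ = [
    "UNKNOWN",
    "Pedigree",
    "LongitudinalSeries",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_series",
    "simulate_cohort",
    "bw_template",
    "fd_template",
    "weaning_dip",
]

#: sentinel for an unknown parent
UNKNOWN = 0

# fixed stream tags so each stage draws from an independent, reproducible stream
_STREAM_PED = 1
_STREAM_GENO = 2
_STREAM_EFF = 3
_STREAM_SERIES = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class Pedigree:
    """Topologically ordered pedigree with 0 = unknown parent.

    ``cohort`` (optional) carries the phenotyped generation's group metadata
    (flock_year, sex, birth-rearing type) used downstream as fixed effects.
    """

    animal: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray
    cohort: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.animal = np.asarray(self.animal, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.generation = np.asarray(self.generation, dtype=np.int64)
        n = self.animal.size
        if not (self.sire.size == self.dam.size == self.generation.size == n):
            raise ValueError("pedigree arrays must share one length")
        if n and (np.diff(self.animal) <= 0).any():
            raise ValueError("animal ids must be strictly increasing")
        pos = {a: i for i, a in enumerate(self.animal)}
        for par in (self.sire, self.dam):
            known = par != UNKNOWN
            if known.any():
                bad = [p for p in par[known] if p not in pos]
                if bad:
                    raise ValueError(f"parent ids absent from pedigree: {bad[:5]}")
                # parents precede offspring => acyclic
                if (par[known] >= self.animal[known]).any():
                    raise ValueError("each parent id must precede its offspring id")
        self._pos = pos

    def __len__(self) -> int:
        return self.animal.size

    def rows(self, ids: np.ndarray) -> np.ndarray:
        """Row indices of the given animal ids."""
        return np.asarray([self._pos[int(a)] for a in np.asarray(ids).ravel()])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": self.animal,
                "sire": self.sire,
                "dam": self.dam,
                "generation": self.generation,
            }
        )


@dataclass
class LongitudinalSeries:
    """One animal's raw records for one series type (FD or BW)."""

    animal_id: int
    series: str
    positions: np.ndarray  #: mm from the staple tip (FD) or days of age (BW)
    values: np.ndarray  #: µm (FD) or kg (BW)
    flock_year: str
    sex: str
    birth_rearing_type: int
    weaning_age: float
    sampling_age: float
    staple_length: float | None = None  #: mm, FD only

    _FD_RANGE = (10, 27)
    _BW_RANGE = (5, 20)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.series not in ("FD", "BW"):
            raise ValueError(f"series must be FD or BW, got {self.series!r}")
        if self.positions.size != self.values.size:
            raise ValueError("positions and values must have equal length")
        if (np.diff(self.positions) <= 0).any():
            raise ValueError("positions must be strictly increasing")
        lo, hi = self._FD_RANGE if self.series == "FD" else self._BW_RANGE
        if not lo <= self.positions.size <= hi:
            raise ValueError(
                f"{self.series} record count {self.positions.size} outside [{lo}, {hi}]"
            )
        if (self.values <= 0).any():
            raise ValueError("raw values must be positive")


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Three-generation pedigree: founder generation 0, parent generation 1
    (sires partly drawn from a pool shared across flock-year groups, which
    links the groups by common sires), and the phenotyped generation 2
    assigned to flock-year groups."""
    rng = _rng(config.seed, _STREAM_PED)
    G, npg = config.n_flock_years, config.animals_per_group
    n_shared = max(1, int(round(config.n_sires_per_group * config.sire_sharing * 2)))

    records: list[tuple[int, int, int, int]] = []  # (animal, sire, dam, gen)
    next_id = 1

    def new_animal(sire: int, dam: int, gen: int) -> int:
        nonlocal next_id
        records.append((next_id, sire, dam, gen))
        next_id += 1
        return next_id - 1

    def new_gen1() -> int:
        """Generation-1 animal with two fresh generation-0 founder parents."""
        s = new_animal(UNKNOWN, UNKNOWN, 0)
        d = new_animal(UNKNOWN, UNKNOWN, 0)
        return new_animal(s, d, 1)

    shared_sires = [new_gen1() for _ in range(n_shared)]

    cohort_rows = []
    for g in range(G):
        fy = f"FY{g + 1:02d}"
        k_shared = min(n_shared, int(round(config.n_sires_per_group * config.sire_sharing)))
        sires = list(rng.choice(shared_sires, size=k_shared, replace=False)) if k_shared else []
        sires += [new_gen1() for _ in range(config.n_sires_per_group - len(sires))]
        dams = [new_gen1() for _ in range(config.n_dams_per_group)]
        sire_of = rng.choice(sires, size=npg)
        dam_of = rng.choice(dams, size=npg)
        sexes = rng.choice(["M", "F"], size=npg)
        brt = rng.choice([1, 2, 3], size=npg, p=[0.35, 0.35, 0.30])
        for i in range(npg):
            a = new_animal(int(sire_of[i]), int(dam_of[i]), 2)
            cohort_rows.append((a, fy, sexes[i], int(brt[i])))

    rec = np.array(records, dtype=np.int64)
    cohort = pd.DataFrame(cohort_rows, columns=["animal", "flock_year", "sex", "brt"])
    return Pedigree(rec[:, 0], rec[:, 1], rec[:, 2], rec[:, 3], cohort=cohort)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    ped: Pedigree,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> np.ndarray:
    """Gene-dropped SNP dosages (animals x SNPs, values 0/1/2).

    Founders are drawn from Hardy-Weinberg proportions at allele frequencies
    sampled uniformly from ``maf_range``; descendants inherit one random
    allele per parent.  Gametes from an unknown parent are drawn from the
    founder frequencies.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = _rng(seed, _STREAM_GENO)
    n = len(ped)
    p = rng.uniform(lo, hi, size=n_snps)
    hap = np.zeros((n, 2, n_snps), dtype=np.int8)
    for i in range(n):
        for which, parent in ((0, ped.sire[i]), (1, ped.dam[i])):
            if parent == UNKNOWN:
                hap[i, which] = rng.random(n_snps) < p
            else:
                j = ped._pos[int(parent)]
                pick = rng.integers(0, 2, size=n_snps)
                hap[i, which] = hap[j, pick, np.arange(n_snps)]
    return hap.sum(axis=1).astype(np.int8)


# ---------------------------------------------------------------------------
# true genetic effects
# ---------------------------------------------------------------------------

def simulate_effects(ped: Pedigree, config: SimConfig) -> pd.DataFrame:
    """True per-animal effects for each simulated trait.

    Breeding values have covariance A (x) Sigma_g, generated recursively:
    founders drawn from N(0, Sigma_g), offspring = parent mean + Mendelian
    sampling with variance (1 - n_known/4 ... ) * Sigma_g scaled for the
    number of known parents (no inbreeding correction; the simulated
    pedigrees are non-inbred).  Maternal permanent environmental effects are
    iid per dam; the residual susceptibility component is iid per animal.

    Returns a tidy frame (animal, trait, a, m, e, u, susceptibility) where
    u = a + m + e and susceptibility = exp(u - var(u)/2), a positive scalar
    with unit mean that multiplies the animal's disturbance responses.
    """
    traits = config.traits
    k = len(traits)
    sig_a = np.array([config.true_variances[t][0] for t in traits])
    sig_m = np.array([config.true_variances[t][1] for t in traits])
    sig_e = np.array([config.true_variances[t][2] for t in traits])
    d = np.sqrt(sig_a)
    cov_a = config.genetic_correlations * np.outer(d, d)
    eig = np.linalg.eigvalsh(cov_a)
    if k and eig.min() < -1e-10:
        raise ValueError("additive covariance matrix must be positive semi-definite")

    rng = _rng(config.seed, _STREAM_EFF)
    n = len(ped)
    a = np.zeros((n, k))
    if sig_a.max() > 0:
        # square root handles semidefinite (zero-variance) traits
        w, V = np.linalg.eigh(cov_a)
        root = V @ np.diag(np.sqrt(np.clip(w, 0, None))) @ V.T
        for i in range(n):
            s_id, d_id = ped.sire[i], ped.dam[i]
            mean = np.zeros(k)
            n_known = 0
            if s_id != UNKNOWN:
                mean += 0.5 * a[ped._pos[int(s_id)]]
                n_known += 1
            if d_id != UNKNOWN:
                mean += 0.5 * a[ped._pos[int(d_id)]]
                n_known += 1
            ms_scale = np.sqrt(1.0 - 0.25 * n_known)
            a[i] = mean + ms_scale * (root @ rng.standard_normal(k))

    # maternal permanent environmental effect: one draw per dam per trait;
    # animals with unknown dam get their own independent draw
    m = np.zeros((n, k))
    dam_effect: dict[int, np.ndarray] = {}
    for i in range(n):
        d_id = int(ped.dam[i])
        if d_id == UNKNOWN:
            m[i] = rng.standard_normal(k) * np.sqrt(sig_m)
        else:
            if d_id not in dam_effect:
                dam_effect[d_id] = rng.standard_normal(k) * np.sqrt(sig_m)
            m[i] = dam_effect[d_id]

    e = rng.standard_normal((n, k)) * np.sqrt(sig_e)
    u = a + m + e
    var_u = sig_a + sig_m + sig_e
    susc = np.exp(u - var_u / 2.0)

    out = []
    for j, t in enumerate(traits):
        out.append(
            pd.DataFrame(
                {
                    "animal": ped.animal,
                    "trait": t,
                    "a": a[:, j],
                    "m": m[:, j],
                    "e": e[:, j],
                    "u": u[:, j],
                    "susceptibility": susc[:, j],
                }
            )
        )
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# longitudinal series
# ---------------------------------------------------------------------------

def bw_template(t: np.ndarray, adult_weight: float = 45.0, rate: float = 0.0105) -> np.ndarray:
    """Gompertz-type growth curve (kg) with birth weight ~4.3 kg."""
    t = np.asarray(t, dtype=float)
    b = np.log(np.log(adult_weight / 4.3))  # anchors W(0) near 4.3 kg
    return adult_weight * np.exp(-np.exp(b - rate * t))


def fd_template(
    t: np.ndarray, base: float = 17.0, seasonal_amp: float = 1.3,
    phase: float = 0.0, trend: float = 0.004,
) -> np.ndarray:
    """Slow seasonal fibre-diameter trend (µm) over age in days."""
    t = np.asarray(t, dtype=float)
    return base + trend * t + seasonal_amp * np.sin(2 * np.pi * (t + phase) / 365.0)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def weaning_dip(
    t: np.ndarray,
    t_w: float,
    response_days: float,
    recovery_days: float,
    recovery_fraction: float = 0.9,
) -> np.ndarray:
    """C1 collapse-and-recovery bump, 0 before weaning, -1 at the trough,
    back up to -(1 - recovery_fraction) at the recovery crest."""
    t = np.asarray(t, dtype=float)
    down = -_smoothstep((t - t_w) / response_days)
    up = (recovery_fraction * _smoothstep((t - t_w - response_days) / recovery_days))
    return down + up


def _phase_warp(rng: np.random.Generator, phase_sd: float, span: float):
    """Random smooth monotone warp of [0, span] onto itself.

    Built as the normalized integral of exp(z) with z a smooth random
    low-order Fourier series of magnitude ``phase_sd``; this guarantees a
    valid endpoint-preserving diffeomorphism for any ``phase_sd``.
    """
    coef = rng.standard_normal(4) * phase_sd
    if phase_sd == 0:
        return lambda t: np.asarray(t, dtype=float)
    grid = np.linspace(0.0, span, 200)
    z = np.zeros_like(grid)
    for j, c in enumerate(coef, start=1):
        z += c * np.sin(np.pi * j * grid / span) / j
    g = np.exp(z)
    gam = np.concatenate([[0.0], np.cumsum((g[1:] + g[:-1]) / 2 * np.diff(grid))])
    gam *= span / gam[-1]

    def warp(t):
        return np.interp(t, grid, gam)

    return warp


def simulate_series(
    ped: Pedigree,
    effects: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw longitudinal FD/BW records for the phenotyped cohort.

    Each record is the group template evaluated at the animal's individually
    phase-warped age, plus the weaning dip and random transient disturbances
    (both scaled by the animal's susceptibility and by the series' local
    variation scale), plus iid measurement noise.

    Returns ``(records, truth)``: the long-format record table and the
    per-animal truth table (susceptibility, warp magnitude, weaning ages)
    kept for validation.
    """
    if ped.cohort is None:
        raise ValueError("pedigree has no phenotyped cohort metadata")
    rng = _rng(config.seed, _STREAM_SERIES)
    susc = {
        (int(r.animal), r.trait): float(r.susceptibility)
        for r in effects.itertuples()
    }
    series_types = [s for s in ("FD", "BW") if s in config.traits] or ["FD", "BW"]

    groups = list(dict.fromkeys(ped.cohort["flock_year"]))
    no_dip = set(groups[: config.n_groups_without_dip])

    wl, wh = config.weaning_day_range
    rows: list[tuple] = []
    truth: list[tuple] = []
    for fy, sub in ped.cohort.groupby("flock_year", sort=False):
        # group-level management and template parameters
        g_wean = float(np.clip(rng.normal(config.weaning_day_mean, 6.0), wl + 5, wh - 5))
        g_samp = float(
            np.clip(
                rng.normal(config.sampling_age_mean, 25.0), *config.sampling_age_range
            )
        )
        adult_w = rng.normal(45.0, 2.0)
        fd_base = rng.normal(17.0, 0.8)
        # seasonal phase relative to birth is similar across flock-years
        # (single lambing season): diameter peaks shortly before weaning and
        # declines gently afterwards, with modest year-to-year jitter
        fd_phase = rng.normal(20.0, 5.0)
        has_dip = fy not in no_dip
        # shared BW weighing occasions: birth, then regular from weaning to sampling
        occ = np.concatenate([[1.0], np.arange(g_wean, 400.0, 18.0)])

        for r in sub.itertuples():
            aid = int(r.animal)
            wean = float(np.clip(rng.normal(g_wean, 4.0), wl, wh))
            samp_age = float(
                np.clip(rng.normal(g_samp, 5.0), *config.sampling_age_range)
            )
            lo_L = config.fd_step * (config.fd_records_range[0] - 1) + 0.1
            hi_L = config.fd_step * config.fd_records_range[1] - 0.1
            staple = float(np.clip(samp_age * rng.normal(0.30, 0.035), lo_L, hi_L))
            warp = _phase_warp(rng, config.phase_sd, samp_age)
            warp_mag = float(np.max(np.abs(warp(np.linspace(0, samp_age, 50))
                                           - np.linspace(0, samp_age, 50))))

            # transient unknown disturbances shared within the animal's life
            n_pert = rng.poisson(config.perturbation_rate * samp_age / 100.0)
            p_center = rng.uniform(0.0, samp_age, size=n_pert)
            p_amp = np.abs(rng.normal(0.0, config.perturbation_amp, size=n_pert))
            p_amp *= np.where(rng.random(n_pert) < 0.8, -1.0, 1.0)
            p_width = config.perturbation_width_days * rng.uniform(0.6, 1.4, size=n_pert)

            def disturbance(t: np.ndarray, s: float) -> np.ndarray:
                out = np.zeros_like(np.asarray(t, dtype=float))
                if has_dip and config.dip_depth > 0:
                    out += config.dip_depth * weaning_dip(
                        t, wean, config.dip_response_days,
                        config.dip_recovery_days, config.dip_recovery_fraction,
                    )
                for c, amp, w in zip(p_center, p_amp, p_width):
                    out += amp * np.exp(-0.5 * ((t - c) / w) ** 2)
                return s * out

            for st in series_types:
                s = susc.get((aid, st), 1.0)
                if st == "FD":
                    n_rec = int(staple // config.fd_step) + 1
                    pos = np.arange(n_rec) * config.fd_step
                    ages = pos / staple * samp_age  # position 0 = birth end (tip)
                    t_eff = warp(ages)
                    base = fd_template(t_eff, base=fd_base, phase=fd_phase)
                    scale = 1.0  # µm per standardized disturbance unit
                    vals = base + scale * disturbance(t_eff, s)
                    vals = vals + rng.normal(0.0, config.noise_sd.get(st, 0.3), n_rec) * scale
                    vals = np.maximum(vals, 1.0)
                    stap = staple
                else:
                    days = occ[occ < samp_age - 2.0] + rng.normal(0.0, 1.5, size=(occ < samp_age - 2.0).sum())
                    days = np.clip(days, 0.5, samp_age)
                    keep = rng.random(days.size) > 0.08
                    keep[0] = True
                    days = np.unique(np.round(days[keep], 2))
                    lo_n, hi_n = config.bw_records_range
                    if days.size > hi_n:
                        days = days[np.sort(rng.choice(days.size, hi_n, replace=False))]
                    if days.size < lo_n:  # top up from the schedule if drops went too far
                        extra = occ[occ < samp_age - 2.0]
                        days = np.unique(np.concatenate([days, extra])[: hi_n])
                    t_eff = warp(days)
                    base = bw_template(t_eff, adult_weight=adult_w)
                    scale = 0.08 * base  # disturbances proportional to current weight
                    vals = base + scale * disturbance(t_eff, s)
                    vals = vals + rng.normal(0.0, config.noise_sd.get(st, 0.3), days.size) * scale
                    vals = np.maximum(vals, 0.5)
                    pos = days
                    stap = np.nan
                for p, v in zip(pos, vals):
                    rows.append(
                        (aid, st, float(p), float(v), fy, r.sex, r.brt, wean, stap, samp_age)
                    )
                truth.append((aid, st, fy, s, wean, samp_age, stap, warp_mag, has_dip))

    records = pd.DataFrame(
        rows,
        columns=[
            "animal", "series", "position", "value", "flock_year",
            "sex", "brt", "weaning_age", "staple_length", "sampling_age",
        ],
    )
    truth_df = pd.DataFrame(
        truth,
        columns=[
            "animal", "series", "flock_year", "susceptibility",
            "weaning_age", "sampling_age", "staple_length", "warp_sup", "has_dip",
        ],
    )
    return records, truth_df


def simulate_cohort(config: SimConfig) -> dict:
    """Convenience wrapper running pedigree -> effects -> series."""
    ped = simulate_pedigree(config)
    effects = simulate_effects(ped, config)
    records, truth = simulate_series(ped, effects, config)
    return {"pedigree": ped, "effects": effects, "records": records, "truth": truth}
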