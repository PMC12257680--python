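"""Shared fixtures: small synthetic cohorts and family designs.

Everything is generated at test time from fixed seeds; expensive end-to-end
artifacts are session-scoped so the directional-validity and sensitivity
checks reuse one pipeline run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from woolres.config import AlignmentConfig, RunConfig, SimConfig
from woolres.simdata import Pedigree
from woolres import genetics, pipeline


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture(scope="session")
def small_cohort():
    """3 flock-years x 25 animals, enough for structural checks."""
    from woolres.simdata import simulate_cohort

    cfg = SimConfig(
        n_flock_years=3, animals_per_group=25, n_sires_per_group=4,
        n_dams_per_group=12, seed=42,
    )
    out = simulate_cohort(cfg)
    out["config"] = cfg
    return out


def make_family_design(
    n_sires: int,
    dams_per_sire: int,
    progeny_per_dam: int,
    seed: int,
    sigma_a2: float = 0.1,
    sigma_m2: float = 0.05,
    sigma_e2: float = 0.85,
    n_traits: int = 1,
    r_g: float = 0.0,
    r_e: float = 0.0,
):
    """Balanced nested design of unrelated sire families with known true
    components; returns (pedigree, phenotyped ids, y matrix, dam labels)."""
    rng = np.random.default_rng(seed)
    animals, sires, dams, gen, recs = [], [], [], [], []
    aid = 0

    def add(s, d, g):
        nonlocal aid
        aid += 1
        animals.append(aid)
        sires.append(s)
        dams.append(d)
        gen.append(g)
        return aid

    for _ in range(n_sires):
        sid = add(0, 0, 0)
        for _ in range(dams_per_sire):
            did = add(0, 0, 0)
            for _ in range(progeny_per_dam):
                recs.append(add(sid, did, 1))
    ped = Pedigree(animals, sires, dams, gen)
    A = genetics.build_A(ped)
    idx = ped.rows(np.array(recs))
    A_obs = A[np.ix_(idx, idx)]
    n = len(recs)
    L = np.linalg.cholesky(A_obs + 1e-10 * np.eye(n))
    k = n_traits
    Ra = np.eye(k) + r_g * (np.ones((k, k)) - np.eye(k))
    Re = np.eye(k) + r_e * (np.ones((k, k)) - np.eye(k))
    a = (L @ rng.standard_normal((n, k))) @ np.linalg.cholesky(sigma_a2 * Ra).T
    dam_ids = ped.dam[idx]
    _, dc = np.unique(dam_ids, return_inverse=True)
    m = (rng.standard_normal((dc.max() + 1, k)) * np.sqrt(sigma_m2))[dc]
    e = rng.standard_normal((n, k)) @ np.linalg.cholesky(sigma_e2 * Re).T
    y = 1.0 + a + m + e
    return ped, np.array(recs), y, dam_ids, A_obs


@pytest.fixture(scope="session")
def fd_pipeline_run(tmp_path_factory):
    """One FD-only end-to-end run: 8 flock-years x 40 animals, three of them
    without a weaning dip, aligned at lambdas 0.2 and 0.6."""
    wd = tmp_path_factory.mktemp("fdrun")
    cfg = RunConfig(
        sim=SimConfig(
            n_flock_years=8, animals_per_group=40, n_sires_per_group=5,
            n_dams_per_group=20, seed=5, n_groups_without_dip=3,
        ),
        alignment=AlignmentConfig(lambda_grid=(0.2, 0.6)),
        series=("FD",),
        seed=5,
    )
    for stage in ("simulate", "smooth", "align", "traits"):
        pipeline.run_stage(stage, cfg, wd)
    return {
        "workdir": wd,
        "config": cfg,
        "traits": {lam: pd.read_csv(wd / f"traits_{pipeline.lambda_tag(lam)}.csv")
                   for lam in (0.2, 0.6)},
        "windows": pd.read_csv(wd / "windows_0p2.csv"),
        "truth": pd.read_csv(wd / "truth.csv"),
    }
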