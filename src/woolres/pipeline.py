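"""Stage orchestration: simulate -> standardize+smooth -> align -> traits ->
variance components -> lambda sensitivity -> report.

Each stage reads only the documented CSV/JSON artifacts of its upstream
stages from a working directory, writes its own artifacts, and records
content hashes in ``manifest.json``, so identical configurations reproduce
identical manifests and a run can resume at any stage.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import curves as curves_mod
from . import elastic, genetics, indicators, io, simdata
from .config import RunConfig, SmoothingConfig

__all__ = [
    "STAGES",
    "run_stage",
    "run_full",
    "simulate_stage",
    "smooth_stage",
    "align_stage",
    "traits_stage",
    "varcomp_stage",
    "sensitivity_stage",
    "report_stage",
    "smooth_group",
    "lambda_tag",
]

log = logging.getLogger("woolres")


def lambda_tag(lam: float) -> str:
    return f"{lam:g}".replace(".", "p")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _update_manifest(workdir: Path, stage: str, files: list[Path], config: RunConfig) -> dict:
    mpath = workdir / "manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {"stages": {}}
    entry = {
        "files": {f.name: _sha256(f) for f in sorted(files)},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": config.seed,
    }
    manifest["stages"][stage] = entry
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return entry


def _require(workdir: Path, name: str, stage: str) -> Path:
    p = workdir / name
    if not p.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs '{name}' in {workdir}; run the upstream stage first"
        )
    return p


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def simulate_stage(config: RunConfig, workdir: Path) -> dict:
    workdir.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    cohort = simdata.simulate_cohort(sim)
    io.write_pedigree(cohort["pedigree"], workdir / "pedigree.csv")
    cohort["pedigree"].cohort.to_csv(workdir / "cohort.csv", index=False)
    io.write_records(cohort["records"], workdir / "records.csv")
    io.write_table(cohort["effects"], workdir / "effects.csv")
    io.write_table(cohort["truth"], workdir / "truth.csv")
    files = [workdir / f for f in
             ("pedigree.csv", "cohort.csv", "records.csv", "effects.csv", "truth.csv")]
    return _update_manifest(workdir, "simulate", files, config)


def smooth_group(
    sub: pd.DataFrame, scfg: SmoothingConfig
) -> tuple[np.ndarray, dict[int, np.ndarray], dict]:
    """Smooth all animals of one flock-year x series onto a common grid.

    The group knot sequence is built from pooled positions normalized to the
    group-mean domain length; each animal's fit uses the group breaks scaled
    to its own domain, and the fitted curve is evaluated at the common grid
    mapped proportionally into that domain.

    The FD penalty acts on the staple's growth-time axis (1 mm of staple ~
    sampling_age/staple_length days), so one smoothing weight has the same
    meaning for both series; grids and knots stay on the mm axis.
    """
    series = sub["series"].iat[0]
    dom_col = "staple_length" if series == "FD" else "sampling_age"
    L = sub.groupby("animal")[dom_col].first()
    L_bar = float(L.mean())
    if series == "FD":  # days of wool growth per mm of staple
        axis = sub.groupby("animal")["sampling_age"].first() / L
    else:
        axis = pd.Series(1.0, index=L.index)
    pooled = (sub["position"] / sub["animal"].map(L) * L_bar).to_numpy()
    breaks = curves_mod.quantile_knots(
        pooled, scfg.n_quantile_knots, extra_knots=scfg.extra_knots, domain=(0.0, L_bar)
    )
    grid = np.arange(0.0, L_bar + 0.5 * scfg.prediction_step, scfg.prediction_step)
    grid = grid[grid <= L_bar]
    if grid[-1] < L_bar - 1e-9:
        grid = np.append(grid, L_bar)
    out: dict[int, np.ndarray] = {}
    store: dict = {}
    for animal, a_sub in sub.groupby("animal"):
        ratio = float(L[animal]) / L_bar * float(axis[animal])
        curve = curves_mod.fit_penalized_spline(
            a_sub["position"].to_numpy() * float(axis[animal]),
            a_sub["value"].to_numpy(),
            breaks * ratio, scfg, grid=grid * ratio,
        )
        out[int(animal)] = curve.values
        store[f"{int(animal)}:{a_sub['series'].iat[0]}"] = {
            "knots": curve.knots, "order": curve.order,
            "coefficients": curve.coefficients, "domain": list(curve.domain),
        }
    return grid, out, store


def smooth_stage(config: RunConfig, workdir: Path) -> dict:
    records = io.read_records(_require(workdir, "records.csv", "smooth"))
    std = curves_mod.standardize_raw(records, drop_singletons=True)
    rows = []
    store_all: dict = {}
    for (fy, series), sub in std.groupby(["flock_year", "series"], sort=True):
        if series not in config.series:
            continue
        grid, curves, store = smooth_group(sub, config.smoothing[series])
        store_all.update(store)
        for animal, vals in curves.items():
            for g, v in zip(grid, vals):
                rows.append((animal, series, fy, g, v))
    ev = pd.DataFrame(rows, columns=["animal", "series", "flock_year", "grid_position", "value"])
    io.write_table(ev, workdir / "curves_eval.csv")
    io.write_curve_store(store_all, workdir / "curve_store.json")
    io.write_table(std, workdir / "records_std.csv")
    files = [workdir / f for f in ("curves_eval.csv", "curve_store.json", "records_std.csv")]
    return _update_manifest(workdir, "smooth", files, config)


def _group_curves(ev: pd.DataFrame):
    for (fy, series), sub in ev.groupby(["flock_year", "series"], sort=True):
        grid = np.sort(sub["grid_position"].unique())
        curves = {
            int(a): s.sort_values("grid_position")["value"].to_numpy()
            for a, s in sub.groupby("animal")
        }
        yield fy, series, grid, curves


def align_stage(
    config: RunConfig, workdir: Path, lambdas: list[float] | None = None
) -> dict:
    ev = io.read_table(_require(workdir, "curves_eval.csv", "align"))
    lams = list(lambdas) if lambdas is not None else list(config.alignment.lambda_grid)
    files = []
    for lam in lams:
        al_rows, warp_rows, mean_rows = [], [], []
        for fy, series, grid, curves in _group_curves(ev):
            ga = elastic.align_group(
                curves, grid, lam, flock_year=fy, series=series, config=config.alignment
            )
            for i, animal in enumerate(ga.animals):
                for g, v, w in zip(grid, ga.aligned[i], ga.warps[i].values):
                    al_rows.append((animal, series, fy, g, v))
                    warp_rows.append((animal, series, fy, g, w))
            for g, v in zip(grid, ga.mean_function):
                mean_rows.append((series, fy, g, v))
        tag = lambda_tag(lam)
        cols = ["animal", "series", "flock_year", "grid_position", "value"]
        io.write_table(pd.DataFrame(al_rows, columns=cols), workdir / f"aligned_{tag}.csv")
        io.write_table(
            pd.DataFrame(warp_rows, columns=cols[:-1] + ["gamma"]),
            workdir / f"warps_{tag}.csv",
        )
        io.write_table(
            pd.DataFrame(mean_rows, columns=["series", "flock_year", "grid_position", "value"]),
            workdir / f"means_{tag}.csv",
        )
        files += [workdir / f"{n}_{tag}.csv" for n in ("aligned", "warps", "means")]
    return _update_manifest(workdir, "align", files, config)


def _weaning_anchor(
    meta: pd.DataFrame, series: str, grid: np.ndarray, tip_is_birth: bool = True
) -> float:
    """Group-mean weaning age mapped onto the grid (BW: days; FD: staple mm
    proportional to the group-mean staple length, from the birth end unless
    the staple orientation is reversed)."""
    wean = float(meta["weaning_age"].mean())
    if series == "BW":
        anchor = wean
    else:
        anchor = indicators.map_age_to_staple(
            wean, float(meta["sampling_age"].mean()), float(grid[-1])
        )
        if not tip_is_birth:
            anchor = float(grid[-1]) - anchor
    return float(grid[np.argmin(np.abs(grid - anchor))])


def traits_stage(
    config: RunConfig, workdir: Path, lambdas: list[float] | None = None
) -> dict:
    records = io.read_records(_require(workdir, "records.csv", "traits"))
    meta = records.groupby(["animal", "series"]).first().reset_index()
    lams = list(lambdas) if lambdas is not None else list(config.alignment.lambda_grid)
    files = []
    for lam in lams:
        tag = lambda_tag(lam)
        aligned = io.read_table(_require(workdir, f"aligned_{tag}.csv", "traits"))
        means = io.read_table(_require(workdir, f"means_{tag}.csv", "traits"))
        trait_frames, window_rows = [], []
        for (fy, series), sub in aligned.groupby(["flock_year", "series"], sort=True):
            grid = np.sort(sub["grid_position"].unique())
            m = means[(means["flock_year"] == fy) & (means["series"] == series)]
            mean_curve = m.sort_values("grid_position")["value"].to_numpy()
            gmeta = meta[(meta["flock_year"] == fy) & (meta["series"] == series)]
            anchor = _weaning_anchor(
                gmeta, series, grid, tip_is_birth=config.indicators.staple_tip_is_birth
            )
            window = indicators.detect_weaning_window(
                mean_curve, grid, anchor, flock_year=fy, series=series,
                config=config.indicators,
            )
            window_rows.append(
                (fy, series, lam, window.t_w, window.t_min, window.t_max, window.detected)
            )
            mat = {
                int(a): s.sort_values("grid_position")["value"].to_numpy()
                for a, s in sub.groupby("animal")
            }
            ga = elastic.GroupAlignment(
                flock_year=fy, series=series, lambda_align=lam, grid=grid,
                animals=list(mat), mean_function=mean_curve, mean_q=None,
                aligned=np.vstack(list(mat.values())), warps=[],
            )
            trait_frames.append(
                indicators.indicator_table(ga, window, config=config.indicators)
            )
        traits = pd.concat(trait_frames, ignore_index=True)
        traits, removal_log = indicators.remove_outliers(
            traits, sd_limit=config.indicators.outlier_sd
        )
        traits = traits.merge(
            meta[["animal", "series", "sex", "brt"]], on=["animal", "series"], how="left"
        )
        io.write_table(traits, workdir / f"traits_{tag}.csv")
        io.write_table(removal_log, workdir / f"outliers_{tag}.csv")
        io.write_table(
            pd.DataFrame(
                window_rows,
                columns=["flock_year", "series", "lambda", "t_w", "t_min", "t_max", "detected"],
            ),
            workdir / f"windows_{tag}.csv",
        )
        files += [workdir / f"{n}_{tag}.csv" for n in ("traits", "outliers", "windows")]
    return _update_manifest(workdir, "traits", files, config)


def _load_relationship(config: RunConfig, workdir: Path) -> tuple[simdata.Pedigree, genetics.RelationshipSet]:
    cohort = pd.read_csv(_require(workdir, "cohort.csv", "varcomp"))
    ped = io.read_pedigree(_require(workdir, "pedigree.csv", "varcomp"), cohort=cohort)
    A = genetics.build_A(ped)
    geno_path = workdir / "genotypes.txt"
    if geno_path.exists():
        ids, M = io.read_genotypes(geno_path)
        G = genetics.build_G(M)
        rel = genetics.blend_and_build_H(ped, A, G, ids, alpha=config.genetics.alpha)
    else:
        rel = genetics.blend_and_build_H(ped, A, None, None, alpha=config.genetics.alpha)
    return ped, rel


def varcomp_stage(config: RunConfig, workdir: Path) -> dict:
    ped, rel = _load_relationship(config, workdir)
    rows = []
    for series in config.series:
        lam = config.alignment.default_lambda.get(series, config.alignment.lambda_grid[0])
        tag = lambda_tag(lam)
        traits = io.read_table(_require(workdir, f"traits_{tag}.csv", "varcomp"))
        traits = traits[traits["series"] == series]
        for trait, sub in traits.groupby("trait", sort=True):
            sub = sub[np.isfinite(sub["value"].astype(float))]
            if len(sub) < sub["flock_year"].nunique() * 2 + 10:
                continue
            frame = genetics.make_model_frame(sub, ped=ped, trait=f"{series}_{trait}")
            vc = genetics.reml_univariate(
                frame, rel.submatrix(frame.animals), config=config.genetics
            )
            rows.append(
                (series, trait, lam, vc.sigma_a2, vc.sigma_m2, vc.sigma_e2,
                 vc.se[0], vc.se[1], vc.se[2], vc.h2, vc.h2_se,
                 vc.converged, vc.n_iter, len(sub))
            )
    out = pd.DataFrame(
        rows,
        columns=["series", "trait", "lambda", "sigma_a2", "sigma_m2", "sigma_e2",
                 "se_a", "se_m", "se_e", "h2", "h2_se", "converged", "n_iter", "n"],
    )
    io.write_table(out, workdir / "varcomp.csv")
    return _update_manifest(workdir, "varcomp", [workdir / "varcomp.csv"], config)


def sensitivity_stage(
    config: RunConfig, workdir: Path, trait: str = "Lnvar",
    lambdas: list[float] | None = None,
) -> dict:
    """Genetic/phenotypic correlations between the same indicator computed at
    different alignment lambdas (bivariate REML per lambda pair)."""
    lams = list(lambdas) if lambdas is not None else list(config.alignment.lambda_grid)
    if len(lams) < 2:
        raise ValueError("lambda sensitivity needs at least 2 lambdas")
    ped, rel = _load_relationship(config, workdir)
    K = rel.kinship()
    pos = {int(a): i for i, a in enumerate(rel.ids)}

    def K_maker(ids_a, ids_b):
        ia = np.array([pos[int(a)] for a in ids_a])
        ib = np.array([pos[int(a)] for a in ids_b])
        return K[np.ix_(ia, ib)]

    rows = []
    for series in config.series:
        tabs = {}
        for lam in lams:
            t = io.read_table(_require(workdir, f"traits_{lambda_tag(lam)}.csv", "sensitivity"))
            tabs[lam] = t[(t["series"] == series) & (t["trait"] == trait)]
        for la, lb in itertools.combinations(lams, 2):
            f1 = genetics.make_model_frame(tabs[la], ped=ped, trait=f"{trait}@{la:g}")
            f2 = genetics.make_model_frame(tabs[lb], ped=ped, trait=f"{trait}@{lb:g}")
            fit = genetics.reml_bivariate(f1, f2, K_maker, config=config.genetics)
            rows.append(
                (series, trait, la, lb, fit.r_g, fit.r_g_se, fit.r_p, fit.r_p_se,
                 fit.converged)
            )
    out = pd.DataFrame(
        rows,
        columns=["series", "trait", "lambda_1", "lambda_2",
                 "r_g", "r_g_se", "r_p", "r_p_se", "converged"],
    )
    io.write_table(out, workdir / "sensitivity.csv")
    return _update_manifest(workdir, "sensitivity", [workdir / "sensitivity.csv"], config)


def report_stage(config: RunConfig, workdir: Path) -> dict:
    """Markdown summary rendered from the run's own CSV outputs."""
    lines = ["# woolres run report", ""]
    vc_path = workdir / "varcomp.csv"
    if not vc_path.exists():
        raise FileNotFoundError(
            f"stage 'report' needs 'varcomp.csv' in {workdir}; run varcomp first"
        )
    vc = io.read_table(vc_path)
    lines.append("## Resilience indicators: descriptive statistics and heritabilities")
    lines.append("")
    lines.append("| trait | n | mean (SD) | range | h2 +/- SE |")
    lines.append("|---|---|---|---|---|")
    for series in config.series:
        lam = config.alignment.default_lambda.get(series, config.alignment.lambda_grid[0])
        tpath = workdir / f"traits_{lambda_tag(lam)}.csv"
        traits = io.read_table(tpath) if tpath.exists() else pd.DataFrame()
        for _, row in vc[vc["series"] == series].iterrows():
            name = f"{series}_{row['trait']}"
            if len(traits):
                v = traits[
                    (traits["series"] == series) & (traits["trait"] == row["trait"])
                ]["value"].astype(float).dropna()
                desc = f"{v.mean():.2f} ({v.std(ddof=1):.2f})"
                rng = f"{v.min():.2f} to {v.max():.2f}"
                nrec = len(v)
            else:  # pragma: no cover
                desc, rng, nrec = "", "", 0
            lines.append(
                f"| {name} | {nrec} | {desc} | {rng} | "
                f"{row['h2']:.2f} +/- {row['h2_se']:.2f} |"
            )
    sens_path = workdir / "sensitivity.csv"
    if sens_path.exists():
        sens = io.read_table(sens_path)
        lines += ["", "## Alignment-lambda sensitivity (same trait, different lambda)", "",
                  "| series | trait | lambda pair | r_g +/- SE | r_p +/- SE |", "|---|---|---|---|---|"]
        for _, r in sens.iterrows():
            lines.append(
                f"| {r['series']} | {r['trait']} | {r['lambda_1']:g} vs {r['lambda_2']:g} | "
                f"{r['r_g']:.2f} +/- {r['r_g_se']:.2f} | {r['r_p']:.2f} +/- {r['r_p_se']:.2f} |"
            )
    (workdir / "report.md").write_text("\n".join(lines) + "\n")
    return _update_manifest(workdir, "report", [workdir / "report.md"], config)


STAGES = {
    "simulate": simulate_stage,
    "smooth": smooth_stage,
    "align": align_stage,
    "traits": traits_stage,
    "varcomp": varcomp_stage,
    "sensitivity": sensitivity_stage,
    "report": report_stage,
}


def run_stage(name: str, config: RunConfig, workdir: str | Path, **kw) -> dict:
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; choose from {sorted(STAGES)}")
    workdir = Path(workdir)
    t0 = time.perf_counter()
    entry = STAGES[name](config, workdir, **kw)
    log.info("stage %s finished in %.1fs", name, time.perf_counter() - t0)
    return entry


def run_full(config: RunConfig, workdir: str | Path, sensitivity: bool = True) -> dict:
    workdir = Path(workdir)
    for name in ("simulate", "smooth", "align", "traits", "varcomp"):
        run_stage(name, config, workdir)
    if sensitivity and len(config.alignment.lambda_grid) >= 2:
        run_stage("sensitivity", config, workdir)
    run_stage("report", config, workdir)
    return json.loads((workdir / "manifest.json").read_text())
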