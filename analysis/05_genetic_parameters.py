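#!/usr/bin/env python
"""Estimate variance components and heritabilities of the indicators.

Fits the univariate single-step animal model y = Xb + Z1 a + Z2 m + e per
indicator (fixed effects: birth-rearing type and flock-year-sex contemporary
group; a ~ N(0, H sigma_a2) with H = A here since no genotypes are simulated
by default; m = maternal permanent environmental effect) by AI-REML, at the
per-series default alignment lambda (FD 0.2, BW 0.6).  Writes varcomp.csv
and renders the run report.
"""

import pandas as pd

from woolres import pipeline

from importlib import import_module

sim = import_module("01_simulate_cohort")


def main() -> None:
    cfg = sim.config()
    pipeline.run_stage("varcomp", cfg, sim.WORKDIR)
    vc = pd.read_csv(sim.WORKDIR / "varcomp.csv")
    cols = ["series", "trait", "sigma_a2", "sigma_m2", "sigma_e2", "h2", "h2_se", "n"]
    print(vc[cols].round(3).to_string(index=False))
    print("\nindicator heritabilities are low: the simulated susceptibility has "
          "h2 = 0.1 and the indicators observe it through sampling noise, so "
          "the indicator-level h2 is a few percent.  At this desk scale "
          "(~700 animals) many estimates sit on the zero boundary (SEs "
          "0.04-0.10); the replicated n = 3000 family-design study in the "
          "test suite shows the estimator itself is unbiased.")
    pipeline.run_stage("report", cfg, sim.WORKDIR)
    print(f"report written to {sim.WORKDIR / 'report.md'}")


if __name__ == "__main__":
    main()
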