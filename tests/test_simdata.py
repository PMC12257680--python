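"""Structure and statistical properties of the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest

from woolres.config import SimConfig
from woolres.simdata import (
    LongitudinalSeries,
    Pedigree,
    bw_template,
    fd_template,
    simulate_cohort,
    simulate_effects,
    simulate_genotypes,
    simulate_pedigree,
    simulate_series,
    weaning_dip,
)


class TestPedigree:
    def test_minimal_trio(self):
        ped = Pedigree([1, 2, 3], [0, 0, 1], [0, 0, 2], [0, 0, 1])
        assert len(ped) == 3
        assert ped.sire[2] == 1 and ped.dam[2] == 2

    def test_parent_after_offspring_rejected(self):
        with pytest.raises(ValueError, match="precede"):
            Pedigree([1, 2, 3], [0, 3, 0], [0, 0, 0], [0, 1, 0])

    def test_unknown_parent_sentinel_and_missing_parent(self):
        with pytest.raises(ValueError, match="absent"):
            Pedigree([1, 2], [0, 9], [0, 0], [0, 1])

    def test_groups_share_sires(self):
        cfg = SimConfig(
            n_flock_years=2, animals_per_group=30, n_sires_per_group=4,
            n_dams_per_group=10, sire_sharing=0.5, seed=3,
        )
        ped = simulate_pedigree(cfg)
        sires_by_group = (
            pd.DataFrame({"animal": ped.animal, "sire": ped.sire})
            .merge(ped.cohort, on="animal")
            .groupby("flock_year")["sire"]
            .agg(set)
        )
        assert len(set.intersection(*sires_by_group)) >= 1

    def test_three_generations(self):
        ped = simulate_pedigree(SimConfig(n_flock_years=2, animals_per_group=10,
                                          n_sires_per_group=2, n_dams_per_group=5, seed=0))
        assert set(np.unique(ped.generation)) == {0, 1, 2}

    def test_deterministic_under_seed(self):
        cfg = SimConfig(n_flock_years=2, animals_per_group=15, seed=7)
        p1, p2 = simulate_pedigree(cfg), simulate_pedigree(cfg)
        assert np.array_equal(p1.sire, p2.sire)
        assert np.array_equal(p1.dam, p2.dam)
        assert p1.cohort.equals(p2.cohort)


class TestGenotypes:
    def test_mendelian_homozygotes(self):
        # sire and dam both 0/0 (or 2/2) force the offspring genotype
        ped = Pedigree([1, 2, 3], [0, 0, 1], [0, 0, 2], [0, 0, 1])
        for seed in range(20):
            g = simulate_genotypes(ped, n_snps=50, maf_range=(0.5, 0.5), seed=seed)
            both0 = (g[0] == 0) & (g[1] == 0)
            both2 = (g[0] == 2) & (g[1] == 2)
            assert (g[2][both0] == 0).all()
            assert (g[2][both2] == 2).all()

    def test_founder_allele_frequency(self):
        n = 10_000
        ped = Pedigree(np.arange(1, n + 1), np.zeros(n, int), np.zeros(n, int), np.zeros(n, int))
        g = simulate_genotypes(ped, n_snps=5, maf_range=(0.5, 0.5), seed=1)
        freq = g.mean(axis=0) / 2.0
        # binomial SE of the sample frequency ~ sqrt(0.25 / (2n)) ~ 0.0035
        assert np.all(np.abs(freq - 0.5) < 0.02)

    def test_maf_validation(self):
        ped = Pedigree([1], [0], [0], [0])
        with pytest.raises(ValueError):
            simulate_genotypes(ped, 10, maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            simulate_genotypes(ped, 10, maf_range=(0.1, 0.6))


class TestEffects:
    def test_zero_additive_variance(self):
        cfg = SimConfig(
            n_flock_years=1, animals_per_group=10,
            true_variances={"FD": (0.0, 0.0, 1.0)},
            genetic_correlations=[[1.0]], seed=0,
        )
        ped = simulate_pedigree(cfg)
        eff = simulate_effects(ped, cfg)
        assert np.allclose(eff["a"], 0.0)
        assert np.allclose(eff["m"], 0.0)

    def test_full_sib_covariance(self):
        # replicate sire x dam pairs; cov(a_sib1, a_sib2) = 0.5 sigma_a2
        n_fam = 10_000
        animals, sires, dams, gen = [], [], [], []
        aid = 0
        sib_rows = []
        for _ in range(n_fam):
            s, d = aid + 1, aid + 2
            animals += [s, d, aid + 3, aid + 4]
            sires += [0, 0, s, s]
            dams += [0, 0, d, d]
            gen += [0, 0, 1, 1]
            sib_rows.append((aid + 2, aid + 3))
            aid += 4
        ped = Pedigree(animals, sires, dams, gen)
        cfg = SimConfig(
            n_flock_years=1, animals_per_group=1,
            true_variances={"FD": (1.0, 0.0, 0.0)},
            genetic_correlations=[[1.0]], seed=9,
        )
        eff = simulate_effects(ped, cfg)
        a = eff.set_index("animal")["a"]
        s1 = a.loc[[r[0] + 1 for r in sib_rows]].to_numpy()
        s2 = a.loc[[r[1] + 1 for r in sib_rows]].to_numpy()
        cov = np.cov(s1, s2)[0, 1]
        assert abs(cov - 0.5) < 4.0 / np.sqrt(n_fam)

    def test_perfect_genetic_correlation_ranks(self):
        cfg = SimConfig(
            n_flock_years=2, animals_per_group=100,
            true_variances={"FD": (1.0, 0.0, 0.0), "BW": (1.0, 0.0, 0.0)},
            genetic_correlations=[[1.0, 1.0 - 1e-9], [1.0 - 1e-9, 1.0]],
            seed=2,
        )
        ped = simulate_pedigree(cfg)
        eff = simulate_effects(ped, cfg)
        w = eff.pivot(index="animal", columns="trait", values="a")
        rho = w["FD"].corr(w["BW"], method="spearman")
        assert rho > 0.9999

    def test_breeding_value_variance_matches_sigma_a2(self):
        n = 20_000
        ped = Pedigree(np.arange(1, n + 1), np.zeros(n, int), np.zeros(n, int), np.zeros(n, int))
        cfg = SimConfig(
            n_flock_years=1, animals_per_group=1,
            true_variances={"FD": (0.25, 0.0, 0.0)}, genetic_correlations=[[1.0]],
            seed=4,
        )
        eff = simulate_effects(ped, cfg)
        assert abs(eff["a"].var() - 0.25) < 0.01


class TestSeries:
    def test_record_count_ranges(self, small_cohort):
        rec = small_cohort["records"]
        fd = rec[rec.series == "FD"].groupby("animal").size()
        bw = rec[rec.series == "BW"].groupby("animal").size()
        assert fd.between(10, 27).all()
        assert bw.between(5, 20).all()

    def test_positions_increasing_and_values_positive(self, small_cohort):
        rec = small_cohort["records"]
        for (_, _), sub in rec.groupby(["animal", "series"]):
            assert (np.diff(sub["position"]) > 0).all()
            assert (sub["value"] > 0).all()

    def test_weaning_ages_in_range(self, small_cohort):
        w = small_cohort["records"]["weaning_age"]
        assert w.between(62, 119).all()

    def test_zero_susceptibility_zero_noise_equals_template(self):
        cfg = SimConfig(
            n_flock_years=1, animals_per_group=3, n_sires_per_group=1,
            n_dams_per_group=2, phase_sd=0.0,
            noise_sd={"FD": 0.0, "BW": 0.0}, seed=11,
        )
        ped = simulate_pedigree(cfg)
        eff = simulate_effects(ped, cfg)
        eff = eff.assign(susceptibility=0.0)
        rec, truth = simulate_series(ped, eff, cfg)
        # susceptibility 0 + no noise + identity warp: FD records follow a
        # smooth seasonal template exactly (residual after removing a fitted
        # template of the generator's own family is numerically zero)
        sub = rec[(rec.series == "FD") & (rec.animal == rec.animal.iloc[0])]
        ages = sub.position / sub.staple_length * sub.sampling_age
        # the template parameters are group-level draws; fit them back
        from scipy.optimize import curve_fit

        def f(t, base, amp, phase, trend):
            return base + trend * t + amp * np.sin(2 * np.pi * (t + phase) / 365.0)

        popt, _ = curve_fit(f, ages, sub.value, p0=[17, 1.3, 20, 0.004])
        assert np.abs(f(ages, *popt) - sub.value).max() < 1e-6

    def test_phase_sd_zero_gives_identity_warp(self):
        cfg = SimConfig(n_flock_years=1, animals_per_group=5, phase_sd=0.0, seed=1)
        ped = simulate_pedigree(cfg)
        eff = simulate_effects(ped, cfg)
        _, truth = simulate_series(ped, eff, cfg)
        assert np.allclose(truth["warp_sup"], 0.0)

    def test_larger_susceptibility_larger_drop(self):
        # evaluate the disturbance component analytically via the generator's
        # own dip function: depth scales linearly with susceptibility
        t = np.linspace(0, 300, 301)
        dip_lo = 0.5 * weaning_dip(t, 90, 18, 35)
        dip_hi = 2.0 * weaning_dip(t, 90, 18, 35)
        assert dip_hi.min() < dip_lo.min() < 0

    def test_series_dataclass_validation(self):
        with pytest.raises(ValueError, match="count"):
            LongitudinalSeries(1, "FD", np.arange(5) * 5.0, np.ones(5),
                               "FY01", "F", 1, 90.0, 300.0, 60.0)
        with pytest.raises(ValueError, match="increasing"):
            LongitudinalSeries(1, "BW", np.array([1.0, 1.0, 2, 3, 4]),
                               np.ones(5), "FY01", "F", 1, 90.0, 300.0)

    def test_determinism_bitwise(self):
        cfg = SimConfig(n_flock_years=2, animals_per_group=10, seed=5)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert a["records"].equals(b["records"])
        assert a["truth"].equals(b["truth"])
        assert a["effects"].equals(b["effects"])


def test_templates_are_biologically_sane():
    t = np.linspace(0, 400, 200)
    w = bw_template(t)
    assert 3.5 < w[0] < 5.5  # birth weight
    assert (np.diff(w) > 0).all()  # monotone growth
    d = fd_template(t)
    assert np.all((d > 12) & (d < 25))
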