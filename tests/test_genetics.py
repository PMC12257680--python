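"""Relationship matrices and REML: textbook recursions, ANOVA oracles and
parameter-recovery checks."""

import numpy as np
import pandas as pd
import pytest

from woolres.config import GeneticsConfig
from woolres.genetics import (
    ModelFrame,
    blend_and_build_H,
    build_A,
    build_G,
    make_model_frame,
    reml_bivariate,
    reml_univariate,
    significance,
)
from woolres.simdata import Pedigree

from conftest import make_family_design


class TestBuildA:
    def test_trio(self):
        ped = Pedigree([1, 2, 3], [0, 0, 1], [0, 0, 2], [0, 0, 1])
        expect = np.array([[1, 0, 0.5], [0, 1, 0.5], [0.5, 0.5, 1]])
        assert np.allclose(build_A(ped), expect)

    def test_single_founder(self):
        assert np.allclose(build_A(Pedigree([1], [0], [0], [0])), [[1.0]])

    def test_full_sib_mating_inbreeding(self):
        # 1 x 2 -> 3, 4 (full sibs); 3 x 4 -> 5 with F = 0.25
        ped = Pedigree([1, 2, 3, 4, 5], [0, 0, 1, 1, 3], [0, 0, 2, 2, 4], [0, 0, 1, 1, 2])
        A = build_A(ped)
        assert A[4, 4] == pytest.approx(1.25)
        assert A[2, 3] == pytest.approx(0.5)

    def test_symmetry(self, small_cohort):
        A = build_A(small_cohort["pedigree"])
        assert np.abs(A - A.T).max() < 1e-12


class TestBuildG:
    def test_two_animals_one_snp(self):
        G = build_G(np.array([[0.0], [2.0]]))
        assert np.allclose(G, [[2, -2], [-2, 2]])

    def test_hwe_unrelated_mean_diagonal(self):
        rng = np.random.default_rng(0)
        n, m = 200, 10_000
        p = rng.uniform(0.1, 0.5, m)
        M = rng.binomial(2, p, size=(n, m)).astype(float)
        G = build_G(M)
        assert abs(np.mean(np.diag(G)) - 1.0) < 0.02
        off = G[~np.eye(n, dtype=bool)]
        assert abs(off.mean()) < 0.01

    def test_duplicated_animal_rows(self):
        rng = np.random.default_rng(1)
        M = rng.integers(0, 3, size=(4, 100)).astype(float)
        M[3] = M[0]
        G = build_G(M)
        assert np.allclose(G[0], G[3])

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            build_G(np.zeros((3, 10)))


class TestBlendH:
    @pytest.fixture
    def trio(self):
        ped = Pedigree([1, 2, 3], [0, 0, 1], [0, 0, 2], [0, 0, 1])
        return ped, build_A(ped)

    def test_empty_genotyped_set(self, trio):
        ped, A = trio
        rel = blend_and_build_H(ped, A, None, None)
        assert np.array_equal(rel.kinship(), A)

    def test_G_equals_A22_recovers_A(self, small_cohort):
        ped = small_cohort["pedigree"]
        A = build_A(ped)
        g_ids = ped.animal[ped.generation == 2][:30]
        idx = ped.rows(g_ids)
        G = A[np.ix_(idx, idx)]
        rel = blend_and_build_H(ped, A, G, g_ids, alpha=0.95)
        assert np.abs(rel.H - A).max() < 1e-10
        assert np.abs(rel.H @ rel.H_inv - np.eye(len(ped))).max() < 1e-6

    def test_H_differs_only_through_genotyped_block(self, trio):
        ped, A = trio
        G = np.array([[1.3]])  # animal 3 genotyped, G != A22
        rel = blend_and_build_H(ped, A, G, np.array([3]), alpha=0.95)
        gw = 0.95 * 1.3 + 0.05 * 1.0
        assert rel.H[2, 2] == pytest.approx(gw)
        # founders unrelated to each other stay unrelated
        assert rel.H[0, 1] == pytest.approx(A[0, 1] + 0.25 * (gw - 1.0))
        assert np.abs(rel.H - rel.H.T).max() < 1e-12

    def test_genotyped_not_in_pedigree(self, trio):
        ped, A = trio
        with pytest.raises(ValueError, match="subset"):
            blend_and_build_H(ped, A, np.eye(1), np.array([99]))


class TestModelFrame:
    def test_design_columns_and_rank(self):
        rng = np.random.default_rng(0)
        n = 40
        df = pd.DataFrame(
            {
                "animal": np.arange(1, n + 1),
                "value": rng.standard_normal(n),
                "brt": rng.integers(1, 4, n),
                "flock_year": rng.choice(["A", "B"], n),
                "sex": rng.choice(["M", "F"], n),
            }
        )
        frame = make_model_frame(df)
        # intercept + 2 brt contrasts + 3 CG contrasts (4 levels)
        assert frame.X.shape == (n, 6)
        assert np.linalg.matrix_rank(frame.X) == 6

    def test_missing_values_dropped(self):
        df = pd.DataFrame({"animal": [1, 2, 3, 4], "value": [1.0, np.nan, 3.0, 4.0]})
        frame = make_model_frame(df)
        assert frame.y.size == 3

    def test_unknown_dam_singleton_levels(self):
        ped = Pedigree([1, 2, 3, 4], [0, 0, 1, 1], [0, 0, 2, 0], [0, 0, 1, 1])
        df = pd.DataFrame({"animal": [3, 4], "value": [1.0, 2.0]})
        frame = make_model_frame(df, ped=ped)
        assert frame.dams[0] == 2
        assert frame.dams[1] < 0  # private level for the unknown dam


class TestUnivariateREML:
    def test_null_heritability_at_boundary(self):
        rng = np.random.default_rng(3)
        n = 300
        y = rng.standard_normal(n)
        frame = ModelFrame(
            y=y, X=np.ones((n, 1)), animals=np.arange(1, n + 1),
            dams=-(np.arange(1, n + 1) + 1),
        )
        vc = reml_univariate(frame, np.eye(n))
        # K = I makes sigma_a2 and sigma_e2 jointly unidentifiable in
        # direction, but h2 stays near 0 only when the fit sits at a
        # boundary; use a half-sib K instead for a well-posed null
        fam = np.repeat(np.arange(30), 10)
        K = np.where(fam[:, None] == fam[None, :], 0.25, 0.0) + 0.75 * np.eye(n)
        vc = reml_univariate(frame, K)
        assert vc.h2 < 0.08

    def test_balanced_half_sib_matches_anova(self):
        ped, recs, y, dam_ids, A_obs = make_family_design(
            n_sires=40, dams_per_sire=20, progeny_per_dam=1, seed=13,
            sigma_a2=0.4, sigma_m2=0.0, sigma_e2=0.6,
        )
        n = y.shape[0]
        prog = 20
        fam = np.repeat(np.arange(40), prog)
        yy = y[:, 0]
        ybar = np.array([yy[fam == f].mean() for f in range(40)])
        msb = prog * np.sum((ybar - yy.mean()) ** 2) / (40 - 1)
        msw = np.sum((yy - ybar[fam]) ** 2) / (n - 40)
        s2_sire = (msb - msw) / prog
        sa_anova, se_anova = 4 * s2_sire, msw - 3 * s2_sire
        frame = ModelFrame(
            y=yy, X=np.ones((n, 1)), animals=recs, dams=-(recs + 1)
        )
        vc = reml_univariate(frame, A_obs, include_maternal=False)
        assert vc.sigma_a2 == pytest.approx(sa_anova, abs=1e-6)
        assert vc.sigma_e2 == pytest.approx(se_anova, abs=1e-6)

    def test_loglik_trajectory_monotone(self):
        ped, recs, y, dam_ids, A_obs = make_family_design(
            n_sires=30, dams_per_sire=5, progeny_per_dam=2, seed=21
        )
        frame = ModelFrame(y=y[:, 0], X=np.ones((y.shape[0], 1)), animals=recs, dams=dam_ids)
        vc = reml_univariate(frame, A_obs)
        traj = vc.trajectory
        assert all(b >= a - 1e-8 for a, b in zip(traj, traj[1:]))

    def test_too_few_records(self):
        frame = ModelFrame(y=np.ones(3), X=np.ones((3, 1)), animals=np.arange(3), dams=np.arange(3))
        with pytest.raises(ValueError, match="too few"):
            reml_univariate(frame, np.eye(3))


class TestBivariateREML:
    @staticmethod
    def _K_maker(ped, A):
        def K(ids_a, ids_b):
            return A[np.ix_(ped.rows(ids_a), ped.rows(ids_b))]

        return K

    def test_identical_traits_unit_correlations(self):
        ped, recs, y, dam_ids, A_obs = make_family_design(
            n_sires=30, dams_per_sire=5, progeny_per_dam=2, seed=2,
            sigma_a2=0.3, sigma_m2=0.05, sigma_e2=0.65,
        )
        A = np.asarray(build_A(ped))
        n = y.shape[0]
        f = ModelFrame(y=y[:, 0], X=np.ones((n, 1)), animals=recs, dams=dam_ids)
        fit = reml_bivariate(f, f, self._K_maker(ped, A))
        assert abs(fit.r_g - 1.0) < 1e-3
        assert abs(fit.r_p - 1.0) < 1e-3

    def test_rg_recovery_within_two_se(self):
        ped, recs, y, dam_ids, A_obs = make_family_design(
            n_sires=100, dams_per_sire=15, progeny_per_dam=2, seed=6,
            sigma_a2=0.3, sigma_m2=0.05, sigma_e2=0.65, n_traits=2,
            r_g=0.5, r_e=0.0,
        )
        n = y.shape[0]
        f1 = ModelFrame(y=y[:, 0], X=np.ones((n, 1)), animals=recs, dams=dam_ids, trait="t1")
        f2 = ModelFrame(y=y[:, 1], X=np.ones((n, 1)), animals=recs, dams=dam_ids, trait="t2")
        A = build_A(ped)
        fit = reml_bivariate(f1, f2, self._K_maker(ped, A))
        assert abs(fit.r_g - 0.5) < 2 * fit.r_g_se
        assert fit.r_g_se < 0.5

    def test_correlation_formula(self):
        # plain arithmetic on supplied components
        assert 0.5 / np.sqrt(1.0 * 1.0) == pytest.approx(0.5)

    def test_zero_covariance_bivariate_matches_univariates(self):
        ped, recs, y, dam_ids, A_obs = make_family_design(
            n_sires=60, dams_per_sire=10, progeny_per_dam=2, seed=17,
            sigma_a2=0.3, sigma_m2=0.05, sigma_e2=0.65, n_traits=2,
            r_g=0.0, r_e=0.0,
        )
        n = y.shape[0]
        A = build_A(ped)
        f1 = ModelFrame(y=y[:, 0], X=np.ones((n, 1)), animals=recs, dams=dam_ids)
        f2 = ModelFrame(y=y[:, 1], X=np.ones((n, 1)), animals=recs, dams=dam_ids)
        u1 = reml_univariate(f1, A_obs)
        u2 = reml_univariate(f2, A_obs)
        fit = reml_bivariate(f1, f2, self._K_maker(ped, A))
        assert fit.cov_a[0, 0] == pytest.approx(u1.sigma_a2, abs=2e-3)
        assert fit.cov_a[1, 1] == pytest.approx(u2.sigma_a2, abs=2e-3)
        assert fit.cov_e[0, 0] == pytest.approx(u1.sigma_e2, abs=2e-3)


class TestSignificance:
    @pytest.mark.parametrize(
        "est,se,expect",
        [(0.30, 0.10, True), (0.15, 0.10, False), (-0.25, 0.10, True), (0.2, 0.1, False)],
    )
    def test_two_se_rule(self, est, se, expect):
        assert significance(est, se) is expect

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            significance(0.1, -0.01)
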