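import numpy as np
import pandas as pd
import pytest

import topomark as tm
from topomark import prediction as pr
from topomark.core_io import RoiMatrix
from tests.conftest import make_matrix

FAST = pr.EnetProtocol(cv_folds=3, mix_grid=(1.0,), n_lambdas=12,
                       lambda_min_ratio=1e-2, max_iter=500, tol=1e-3)
EXACT = dict(cv_folds=3, max_iter=500_000, tol=1e-14)


def _toy_design(seed=42, n=30):
    rng = np.random.default_rng(seed)
    tau = make_matrix(1 + abs(rng.standard_normal((n, 2))), "tau")
    ab = make_matrix(1 + abs(rng.standard_normal((n, 1))), "abeta", "q")
    d = pr.build_design(tau, ab)
    y = d.X @ np.array([1.0, -2.0, 0.5]) + 0.1 * rng.standard_normal(n)
    return d, y


class TestBuildDesign:
    def test_84_columns_tau_block_first(self, default_sim):
        d = pr.build_design(default_sim.tau, default_sim.abeta)
        assert d.X.shape == (46, 84)
        assert [c[0] for c in d.columns] == ["tau"] * 42 + ["abeta"] * 42
        np.testing.assert_allclose(d.X.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(d.X.std(axis=0), 1, atol=1e-12)

    def test_standardization_idempotent(self, default_sim):
        d = pr.build_design(default_sim.tau, default_sim.abeta)
        again = pr._standardize(d.X, d.columns, d.subject_ids)
        np.testing.assert_allclose(again.X, d.X, atol=1e-12)

    def test_constant_column_flagged_and_coefficient_zero(self):
        rng = np.random.default_rng(0)
        n = 25
        vals = 1 + abs(rng.standard_normal((n, 3)))
        vals[:, 1] = 1.4
        tau = make_matrix(vals, "tau")
        ab = make_matrix(1 + abs(rng.standard_normal((n, 2))), "abeta", "q")
        d = pr.build_design(tau, ab)
        assert d.zero_variance == (1,)
        y = d.X[:, 0] * 2 + 0.1 * rng.standard_normal(n)
        fit = pr.fit_enet(d, y, FAST)
        assert fit.beta[1] == 0.0


class TestOracleLimits:
    def test_vanishing_penalty_recovers_ols(self):
        d, y = _toy_design()
        proto = pr.EnetProtocol(mix_grid=(0.5,), lambdas=(1e-12,), **EXACT)
        fit = pr.fit_enet(d, y, proto)
        Xc = np.hstack([d.X, np.ones((d.n, 1))])
        beta_ols, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols[:-1], atol=1e-6)
        assert fit.intercept == pytest.approx(beta_ols[-1], abs=1e-6)

    def test_pure_ridge_matches_closed_form(self):
        d, y = _toy_design()
        lam = 0.3
        proto = pr.EnetProtocol(mix_grid=(0.0,), lambdas=(lam,), **EXACT)
        fit = pr.fit_enet(d, y, proto)
        Xm = d.X - d.X.mean(axis=0)
        yc = y - y.mean()
        beta_ridge = np.linalg.solve(Xm.T @ Xm + d.n * lam * np.eye(3),
                                     Xm.T @ yc)
        np.testing.assert_allclose(fit.beta, beta_ridge, atol=1e-8)

    def test_solution_is_a_local_minimum_of_the_objective(self):
        d, y = _toy_design()
        lam, mix = 0.05, 0.7
        proto = pr.EnetProtocol(mix_grid=(mix,), lambdas=(lam,), **EXACT)
        fit = pr.fit_enet(d, y, proto)

        def objective(beta, intercept):
            r = y - d.X @ beta - intercept
            return (r @ r / (2 * d.n) + lam * (mix * np.abs(beta).sum()
                    + (1 - mix) / 2 * beta @ beta))

        base = objective(fit.beta, fit.intercept)
        rng = np.random.default_rng(1)
        for _ in range(25):
            delta = 1e-4 * rng.standard_normal(3)
            assert objective(fit.beta + delta, fit.intercept) >= base - 1e-12


def test_standardized_beta_invariant_to_affine_rescaling():
    rng = np.random.default_rng(3)
    n = 40
    raw_t = 1 + abs(rng.standard_normal((n, 3)))
    raw_a = 1 + abs(rng.standard_normal((n, 2)))
    tau = make_matrix(raw_t, "tau")
    ab = make_matrix(raw_a, "abeta", "q")
    d1 = pr.build_design(tau, ab)
    y = d1.X[:, 0] - d1.X[:, 3] + 0.2 * rng.standard_normal(n)
    tau2 = make_matrix(raw_t * [2.0, 5.0, 0.3] + [1.0, 0.0, 4.0], "tau")
    ab2 = make_matrix(raw_a * [10.0, 0.5] + [0.2, 2.0], "abeta", "q")
    d2 = pr.build_design(tau2, ab2)
    proto = pr.EnetProtocol(mix_grid=(0.7,), lambdas=(0.05,), **EXACT)
    f1 = pr.fit_enet(d1, y, proto)
    f2 = pr.fit_enet(d2, y, proto)
    np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-8)


def test_sparse_support_recovery_at_large_n(default_sim):
    """5 active predictors of 84, high SNR: the selected support contains
    the truth with few false discoveries."""
    proto = pr.EnetProtocol(cv_folds=3, mix_grid=(1.0,), n_lambdas=20,
                            lambda_min_ratio=1e-3, max_iter=2000, tol=1e-4)
    for seed in range(3):
        tau = tm.simulate_null_matrix(500, 42, 0.2, seed=seed,
                                      modality="tau")
        ab = tm.simulate_null_matrix(500, 42, 0.2, seed=seed + 1000,
                                     modality="abeta")
        d = pr.build_design(tau, ab)
        rng = np.random.default_rng(seed)
        active = rng.choice(84, size=5, replace=False)
        beta_true = np.zeros(84)
        beta_true[active] = rng.choice([-1.5, 1.5], size=5)
        y = d.X @ beta_true + 0.3 * rng.standard_normal(500)
        fit = pr.fit_enet(d, y, proto, seed=seed)
        support = set(np.flatnonzero(fit.beta != 0))
        assert set(active) <= support
        assert len(support - set(active)) <= 10


class TestPermutationSignificance:
    def test_deterministic_outcome_maximally_significant(self):
        d, _ = _toy_design()
        y = 3.0 * d.X[:, 1]  # exact linear function, no noise
        fit = pr.permutation_significance(d, y, FAST, n_permutations=199,
                                          seed=0)
        assert fit.p_perm == pytest.approx(1.0 / 200.0)
        assert fit.z > 3

    def test_reproducible_for_fixed_seed(self):
        d, y = _toy_design()
        a = pr.permutation_significance(d, y, FAST, n_permutations=100,
                                        seed=5)
        b = pr.permutation_significance(d, y, FAST, n_permutations=100,
                                        seed=5)
        np.testing.assert_array_equal(a.perm_draws, b.perm_draws)
        assert a.p_perm == b.p_perm

    def test_coupled_csf_outcome_strongly_significant(self, default_sim):
        d = pr.build_design(default_sim.tau, default_sim.abeta)
        csf = default_sim.csf["tau"]
        common = sorted(set(csf.index) & set(d.subject_ids))
        fit = pr.permutation_significance(d.subset(common),
                                          csf.loc[common], FAST,
                                          n_permutations=199, seed=2)
        assert fit.p_perm <= 0.05
        assert fit.z > 3


class TestAttribution:
    def test_all_zero_coefficients_give_null_share(self):
        d, y = _toy_design()
        proto = pr.EnetProtocol(cv_folds=3, mix_grid=(1.0,),
                                lambdas=(1e6,))
        fit = pr.fit_enet(d, y, proto)
        att = pr.modality_attribution(fit)
        assert att["sum_abs_beta_tau"] == 0.0
        assert att["sum_abs_beta_abeta"] == 0.0
        assert att["tau_share"] is None

    def test_blocks_sum_to_total(self, default_sim):
        d = pr.build_design(default_sim.tau, default_sim.abeta)
        y = default_sim.composites["semantic"]
        common = sorted(set(y.index) & set(d.subject_ids))
        fit = pr.fit_enet(d.subset(common), y.loc[common], FAST)
        att = pr.modality_attribution(fit)
        assert (att["sum_abs_beta_tau"] + att["sum_abs_beta_abeta"]
                == pytest.approx(np.abs(fit.beta).sum()))
        assert att["n_nonzero_tau"] <= 42 and att["n_nonzero_abeta"] <= 42


class TestCompareFits:
    def test_self_comparison_r_one(self, default_sim):
        d = pr.build_design(default_sim.tau, default_sim.abeta)
        y = default_sim.csf["tau"]
        common = sorted(set(y.index) & set(d.subject_ids))
        fit = pr.fit_enet(d.subset(common), y.loc[common], FAST)
        r, p = pr.compare_topography_fits(fit, fit)
        assert r == pytest.approx(1.0)

    def test_shared_coupling_gives_correlated_topographies(self):
        # an L2 component lets correlated regions enter both models, so
        # outcomes sharing a coupling share a predictive topography
        dense = pr.EnetProtocol(cv_folds=3, mix_grid=(0.1, 0.5),
                                n_lambdas=12, lambda_min_ratio=1e-2,
                                max_iter=1000, tol=1e-3)
        rs = []
        for seed in range(5):
            sim = tm.simulate_cohort(tm.SyntheticConfig(seed=seed))
            d = pr.build_design(sim.tau, sim.abeta)
            fits = {}
            for analyte in ("tau", "ptau"):
                y = sim.csf[analyte]
                common = sorted(set(y.index) & set(d.subject_ids))
                fits[analyte] = pr.fit_enet(d.subset(common),
                                            y.loc[common], dense, seed=seed)
            r, _ = pr.compare_topography_fits(fits["tau"], fits["ptau"])
            rs.append(r)
        assert np.mean(rs) >= 0.6

    def test_zero_variance_vector_gives_null(self):
        d, y = _toy_design()
        dead = pr.fit_enet(d, y, pr.EnetProtocol(cv_folds=3,
                                                 mix_grid=(1.0,),
                                                 lambdas=(1e6,)))
        live = pr.fit_enet(d, y, FAST)
        assert pr.compare_topography_fits(dead, live) == (None, None)


class TestBattery:
    def test_single_outcome_correction_is_identity(self, default_sim):
        d = pr.build_design(default_sim.tau, default_sim.abeta)
        outcomes = default_sim.csf[["tau"]]
        res = pr.run_outcome_battery(d, outcomes, FAST, n_permutations=100,
                                     seed=0)
        assert res.p_adjusted["tau"] == pytest.approx(
            res.fits["tau"].p_perm)

    def test_battery_is_seed_reproducible(self, default_sim):
        d = pr.build_design(default_sim.tau, default_sim.abeta)
        outcomes = default_sim.composites[["semantic", "working"]]
        a = pr.run_outcome_battery(d, outcomes, FAST, n_permutations=100,
                                   seed=3)
        b = pr.run_outcome_battery(d, outcomes, FAST, n_permutations=100,
                                   seed=3)
        assert a.p_adjusted == b.p_adjusted
        assert a.significant == b.significant
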