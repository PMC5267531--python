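import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import eigh

import topomark as tm
from topomark.core_io import SchemaError
from tests.conftest import make_matrix


def gram_svd_oracle(values, center=True):
    """Independent SVD route: eigendecomposition of the centered Gram
    matrix X_c^T X_c gives singular values as root-eigenvalues."""
    Xc = values - values.mean(axis=0) if center else values
    evals, evecs = eigh(Xc.T @ Xc)
    order = np.argsort(evals)[::-1]
    svals = np.sqrt(np.clip(evals[order], 0, None))
    return svals, evecs[:, order]


def _random_suvr(rng, n, m, scale=0.5):
    return 2.0 + scale * rng.standard_normal((n, m))


class TestDecompose:
    def test_matches_gram_eigendecomposition_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            mat = make_matrix(_random_suvr(rng, 6, 5))
            topo = tm.decompose(mat)
            svals, evecs = gram_svd_oracle(mat.values)
            np.testing.assert_allclose(topo.singular_values, svals,
                                       atol=1e-8)
            for k in range(5):
                if svals[k] > 1e-8:
                    cos = abs(topo.weights[k] @ evecs[:, k])
                    assert cos == pytest.approx(1.0, abs=1e-8)

    def test_sequential_4x3_matrix_known_singular_values(self):
        # columns of 1..12 row-major are arithmetic -> rank 1 centered,
        # singular value sqrt(135)
        mat = make_matrix(np.arange(1.0, 13.0).reshape(4, 3))
        topo = tm.decompose(mat)
        np.testing.assert_allclose(
            topo.singular_values, [np.sqrt(135.0), 0.0, 0.0], atol=1e-10)

    def test_orthonormal_weights_and_score_identity(self, default_sim):
        topo = tm.decompose(default_sim.tau)
        k = topo.n_components
        np.testing.assert_allclose(topo.weights @ topo.weights.T,
                                   np.eye(k), atol=1e-8)
        Xc = default_sim.tau.values - topo.center
        np.testing.assert_allclose(topo.scores, Xc @ topo.weights.T,
                                   atol=1e-8)
        # score columns orthogonal after scaling by singular values
        nz = topo.singular_values > 1e-8
        U = topo.scores[:, nz] / topo.singular_values[nz]
        np.testing.assert_allclose(U.T @ U, np.eye(nz.sum()), atol=1e-8)
        # full reconstruction
        np.testing.assert_allclose(topo.scores @ topo.weights, Xc,
                                   atol=1e-8)

    def test_row_permutation_equivariance(self, default_sim):
        mat = default_sim.tau
        perm = np.random.default_rng(3).permutation(mat.n_subjects)
        shuffled = mat.subset([mat.subject_ids[i] for i in perm])
        a, b = tm.decompose(mat), tm.decompose(shuffled)
        np.testing.assert_allclose(b.weights, a.weights, atol=1e-8)
        np.testing.assert_allclose(b.scores, a.scores[perm], atol=1e-8)

    def test_noiseless_rank2_two_nonzero_singular_values(self):
        sim = tm.simulate_cohort(tm.SyntheticConfig(seed=2, noise_sd=0.0))
        topo = tm.decompose(sim.tau)
        s = topo.singular_values
        assert (s[:2] > 1e-6).all()
        assert (s[2:] < 1e-8 * s[0]).all()

    def test_uncentered_mode_first_component_tracks_mean_image(self,
                                                               default_sim):
        topo = tm.decompose(default_sim.tau, center=False)
        mean_img = default_sim.tau.values.mean(axis=0)
        cos = abs(topo.weights[0] @ mean_img) / np.linalg.norm(mean_img)
        assert cos >= 0.99

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_invariants_hold_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        mat = make_matrix(_random_suvr(rng, 7, 5))
        topo = tm.decompose(mat)
        assert (np.diff(topo.singular_values) <= 1e-12).all()
        assert (topo.singular_values >= 0).all()
        assert (topo.weights.sum(axis=1) >= -1e-12).all()  # sign convention
        np.testing.assert_allclose(topo.weights @ topo.weights.T,
                                   np.eye(topo.n_components), atol=1e-8)


class TestEstimateRank:
    def test_synthetic_two_component_cohort_rank_two(self):
        sim = tm.simulate_cohort(tm.SyntheticConfig(seed=4))
        for mat in (sim.tau, sim.abeta):
            rank, pvals = tm.estimate_rank(mat, n_permutations=500, seed=4)
            assert rank == 2
            assert (pvals[:2] <= 0.05).all()

    def test_noiseless_rank1_minimal_pvalue(self):
        sim = tm.simulate_cohort(tm.SyntheticConfig(seed=6, rank=1,
                                                    noise_sd=0.0))
        rank, pvals = tm.estimate_rank(sim.tau, n_permutations=199, seed=0)
        assert rank == 1
        assert pvals[0] == pytest.approx(1.0 / 200.0)

    def test_constant_matrix_rank_zero_without_error(self):
        mat = make_matrix(np.full((8, 5), 1.2))
        topo = tm.decompose(mat)
        assert np.allclose(topo.singular_values, 0)
        rank, _ = tm.estimate_rank(mat, n_permutations=100, seed=0)
        assert rank == 0

    def test_requires_minimum_permutations(self, default_sim):
        with pytest.raises(ValueError):
            tm.estimate_rank(default_sim.tau, n_permutations=10)


class TestProject:
    def test_training_matrix_reproduces_stored_scores(self, default_sim):
        topo = tm.decompose(default_sim.tau)
        np.testing.assert_allclose(tm.project(default_sim.tau, topo),
                                   topo.scores, atol=1e-10)

    def test_mean_subject_projects_to_zero(self, default_sim):
        topo = tm.decompose(default_sim.tau)
        new = make_matrix(topo.center[None, :])
        new = new.__class__(new.subject_ids, "tau", new.values,
                            topo.region_ids)
        np.testing.assert_allclose(tm.project(new, topo),
                                   np.zeros((1, topo.n_components)),
                                   atol=1e-10)

    def test_unit_displacement_along_topography_scores_c_sv(self,
                                                            default_sim):
        topo = tm.decompose(default_sim.tau)
        c = 0.3
        vec = topo.center + c * topo.singular_values[0] * topo.weights[0]
        new = make_matrix(vec[None, :]).__class__(
            ("new",), "tau", vec[None, :], topo.region_ids)
        scores = tm.project(new, topo)
        expected = np.zeros(topo.n_components)
        expected[0] = c * topo.singular_values[0]
        np.testing.assert_allclose(scores[0], expected, atol=1e-8)

    def test_region_mismatch_schema_error(self, default_sim):
        topo = tm.decompose(default_sim.tau)
        other = make_matrix(np.full((3, 42), 1.0) + 0.5)
        with pytest.raises(SchemaError):
            tm.project(other, topo)


class TestLooStability:
    def test_noiseless_rank2_perfectly_stable(self):
        sim = tm.simulate_cohort(tm.SyntheticConfig(seed=8, noise_sd=0.0))
        for k in range(2):
            res = tm.loo_stability(sim.tau, k)
            np.testing.assert_allclose(res.correlations, 1.0, atol=1e-8)

    def test_default_snr_components_stable(self):
        means = []
        for seed in range(5):
            sim = tm.simulate_cohort(tm.SyntheticConfig(seed=seed))
            for k in range(2):
                means.append(tm.loo_stability(sim.tau, k).mean)
        assert min(means) >= 0.9

    def test_pure_noise_correlations_in_unit_range(self):
        mat = tm.simulate_null_matrix(12, 8, 1.0, seed=5)
        res = tm.loo_stability(mat, 0)
        assert ((res.correlations >= 0) & (res.correlations <= 1)).all()
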