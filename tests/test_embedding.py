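import numpy as np
import pytest
import scipy.linalg
from scipy.stats import spearmanr

import gradmap as gm
from gradmap import errors
from gradmap.embedding import canonical_sign, diffusion_maps, laplacian_eigenmaps, pca_embedding


def path_graph(n):
    A = np.zeros((n, n))
    for i in range(n - 1):
        A[i, i + 1] = A[i + 1, i] = 1.0
    return A


def ring_graph(n):
    A = np.zeros((n, n))
    for i in range(n):
        A[i, (i + 1) % n] = A[(i + 1) % n, i] = 1.0
    return A


class TestPCA:
    def test_rank_one_data_explains_all_variance(self, rng):
        x = rng.standard_normal(10)
        X = np.c_[x, 2 * x]
        res = pca_embedding(gm.FeatureMatrix(X), m=2)
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-12)
        assert res.variance_explained[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_covariance_eigendecomposition_oracle(self, rng):
        X = rng.standard_normal((12, 7))
        res = pca_embedding(gm.FeatureMatrix(X), m=5)
        # oracle: eigendecomposition of the covariance of the demeaned data
        Xd = X - X.mean(axis=0)
        C = Xd.T @ Xd
        w, V = scipy.linalg.eigh(C)
        order = np.argsort(w)[::-1][:5]
        scores = canonical_sign(Xd @ V[:, order])
        np.testing.assert_allclose(res.gradients, scores, atol=1e-10, rtol=0)

    def test_duplicated_rows_give_duplicated_gradients(self, rng):
        X = rng.standard_normal((6, 5))
        X = np.vstack([X, X[0]])
        res = pca_embedding(gm.FeatureMatrix(X), m=3)
        np.testing.assert_allclose(res.gradients[0], res.gradients[-1], atol=1e-12)

    def test_m_too_large_rejected(self, rng):
        X = gm.FeatureMatrix(rng.standard_normal((5, 8)))
        with pytest.raises(errors.ComponentCountError):
            pca_embedding(X, m=5)

    def test_constant_matrix_rejected(self):
        X = gm.FeatureMatrix(np.full((5, 4), 2.0))
        with pytest.raises(errors.ConstantInputError):
            pca_embedding(X, m=2)


class TestLaplacianEigenmaps:
    def test_path_graph_p3_closed_form(self):
        # L - D = -A, so Ag = 0 at the top generalized eigenvalue: the
        # first gradient of P3 is proportional to [1, 0, -1].
        res = laplacian_eigenmaps(path_graph(3), m=2)
        np.testing.assert_allclose(sorted(np.r_[0.0, res.lambdas]), [0, 1, 2], atol=1e-10)
        g1 = res.gradients[:, 0]
        g1 = g1 / np.linalg.norm(g1)
        expect = np.array([1.0, 0.0, -1.0]) / np.sqrt(2)
        assert min(np.abs(g1 - expect).max(), np.abs(g1 + expect).max()) < 1e-10

    def test_ring_c32_matches_fourier_modes(self):
        n = 32
        res = laplacian_eigenmaps(ring_graph(n), m=2)
        k = np.arange(n)
        fourier = np.c_[np.cos(2 * np.pi * k / n), np.sin(2 * np.pi * k / n)]
        # canonical correlations between the two 2-d subspaces
        angles = scipy.linalg.subspace_angles(res.gradients, fourier)
        assert np.cos(angles).min() > 1 - 1e-6

    def test_complete_graph_eigenvalue_multiplicity(self):
        A = np.ones((4, 4)) - np.eye(4)
        res = laplacian_eigenmaps(A, m=3)
        assert np.ptp(res.lambdas) < 1e-10  # all non-trivial eigenvalues equal

    def test_generalized_eigensolve_oracle(self, rng):
        # small random connected graph: compare with direct dense
        # generalized eigensolve of (L, D)
        B = rng.random((8, 8))
        A = 0.5 * (B + B.T)
        np.fill_diagonal(A, 0.0)
        D = np.diag(A.sum(axis=1))
        L = D - A
        w, V = scipy.linalg.eigh(L, D)
        res = laplacian_eigenmaps(A, m=4)
        np.testing.assert_allclose(res.lambdas, w[1:5], atol=1e-8)
        for k in range(4):
            v = V[:, k + 1] / np.linalg.norm(V[:, k + 1])
            g = res.gradients[:, k] / np.linalg.norm(res.gradients[:, k])
            assert min(np.abs(g - v).max(), np.abs(g + v).max()) < 1e-8

    def test_disconnected_graph_error_names_components(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 1.0
        with pytest.raises(errors.DisconnectedGraphError, match="2"):
            laplacian_eigenmaps(A, m=1)

    def test_zero_degree_node_error(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        with pytest.raises(errors.ZeroDegreeError):
            laplacian_eigenmaps(A, m=1)

    def test_scale_invariance(self, rng):
        B = rng.random((10, 10))
        A = 0.5 * (B + B.T)
        np.fill_diagonal(A, 0.0)
        r1 = laplacian_eigenmaps(A, m=3)
        r2 = laplacian_eigenmaps(7.5 * A, m=3)
        np.testing.assert_allclose(r1.gradients, r2.gradients, atol=1e-10)


class TestDiffusionMaps:
    @staticmethod
    def random_affinity(rng, n=10):
        B = rng.random((n, n)) + 0.05
        A = 0.5 * (B + B.T)
        np.fill_diagonal(A, 1.0)
        return A

    def test_operator_is_row_stochastic(self, rng):
        A = self.random_affinity(rng)
        deg = A.sum(axis=1)
        W = A / np.outer(deg**0.5, deg**0.5)
        P = W / W.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_two_block_affinity_separated_by_first_gradient(self):
        A = np.full((10, 10), 0.1)
        A[:5, :5] = 1.0
        A[5:, 5:] = 1.0
        res = diffusion_maps(A, m=2, alpha=0.5)
        signs = np.sign(res.gradients[:, 0])
        assert len(set(signs[:5])) == 1 and len(set(signs[5:])) == 1
        assert signs[0] != signs[5]

    def test_diffusion_time_scaling_identity(self, rng):
        A = self.random_affinity(rng)
        t = 1.5
        r1 = diffusion_maps(A, m=3, diffusion_time=t)
        r2 = diffusion_maps(A, m=3, diffusion_time=2 * t)
        np.testing.assert_allclose(
            r2.gradients, r1.gradients * r1.lambdas**t, atol=1e-10
        )

    def test_alpha_zero_matches_random_walk_oracle(self, rng):
        A = self.random_affinity(rng)
        res = diffusion_maps(A, m=3, alpha=0.0, diffusion_time=1.0)
        # oracle: direct eigensolve of the random-walk operator D^-1 A
        P = A / A.sum(axis=1, keepdims=True)
        w, V = scipy.linalg.eig(P)
        order = np.argsort(w.real)[::-1]
        w, V = w.real[order], V[:, order].real
        np.testing.assert_allclose(res.lambdas, w[1:4], atol=1e-8)
        for k in range(3):
            v = V[:, k + 1] / np.linalg.norm(V[:, k + 1])
            g = res.gradients[:, k] / np.linalg.norm(res.gradients[:, k])
            assert min(np.abs(g - v).max(), np.abs(g + v).max()) < 1e-8

    def test_scale_invariance_fixed_t(self, rng):
        A = self.random_affinity(rng)
        r1 = diffusion_maps(A, m=3, diffusion_time=2.0)
        r2 = diffusion_maps(3.0 * A, m=3, diffusion_time=2.0)
        np.testing.assert_allclose(r1.gradients, r2.gradients, atol=1e-10)

    def test_alpha_out_of_range(self, rng):
        with pytest.raises(ValueError):
            diffusion_maps(self.random_affinity(rng), m=2, alpha=1.5)


class TestFitGradients:
    def test_planted_manifold_recovery(self):
        X, theta = gm.planted_gradient_connectome(
            n_seeds=100, noise_sd=0.0, length_scale=0.2, latent_dim=1, seed=7
        )
        res = gm.fit_gradients(
            X, gm.KernelSpec("cosine"), method="dm", m=2, keep_fraction=0.1
        )
        rho = spearmanr(res.gradients[:, 0], theta[:, 0]).statistic
        assert abs(rho) > 0.99

    def test_determinism(self):
        X, _ = gm.planted_gradient_connectome(n_seeds=40, seed=3)
        r1 = gm.fit_gradients(X, method="dm", m=3, keep_fraction=0.2)
        r2 = gm.fit_gradients(X, method="dm", m=3, keep_fraction=0.2)
        np.testing.assert_array_equal(r1.gradients, r2.gradients)
        np.testing.assert_array_equal(r1.lambdas, r2.lambdas)

    def test_m_equal_n_rejected(self):
        X, _ = gm.planted_gradient_connectome(n_seeds=20, seed=1)
        with pytest.raises(errors.ComponentCountError):
            gm.fit_gradients(X, method="dm", m=20)

    def test_permutation_equivariance(self, rng):
        X, _ = gm.planted_gradient_connectome(n_seeds=30, seed=5)
        perm = rng.permutation(30)
        Xp = gm.FeatureMatrix(X.values[np.ix_(perm, perm)])
        r = gm.fit_gradients(X, method="le", m=2, keep_fraction=0.5)
        rp = gm.fit_gradients(Xp, method="le", m=2, keep_fraction=0.5)
        # same gradients up to row permutation and per-column sign
        for k in range(2):
            a, b = r.gradients[perm, k], rp.gradients[:, k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_sign_canonicalization_is_idempotent(self, rng):
        V = rng.standard_normal((7, 3))
        C = canonical_sign(V)
        np.testing.assert_array_equal(canonical_sign(-V), C)
        np.testing.assert_array_equal(canonical_sign(C), C)


class TestIterativeSolverAgreement:
    """The iterative (large-n) eigensolver path matches the dense path."""

    def test_le_and_dm_iterative_match_dense(self, rng, monkeypatch):
        import gradmap.embedding as emb

        B = rng.random((12, 12)) + 0.05
        A = 0.5 * (B + B.T)
        np.fill_diagonal(A, 1.0)
        dense_le = laplacian_eigenmaps(A, m=3)
        dense_dm = diffusion_maps(A, m=3)
        monkeypatch.setattr(emb, "_DENSE_LIMIT", 4)  # force the iterative path
        iter_le = laplacian_eigenmaps(A, m=3)
        iter_dm = diffusion_maps(A, m=3)
        np.testing.assert_allclose(iter_le.gradients, dense_le.gradients, atol=1e-8)
        np.testing.assert_allclose(iter_le.lambdas, dense_le.lambdas, atol=1e-8)
        np.testing.assert_allclose(iter_dm.gradients, dense_dm.gradients, atol=1e-8)
        np.testing.assert_allclose(iter_dm.lambdas, dense_dm.lambdas, atol=1e-8)
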