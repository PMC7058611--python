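import numpy as np
import pytest

import gradmap as gm
from gradmap import errors
from gradmap.nulls import (
    empirical_pvalue,
    moran_basis,
    morans_i,
    msr_randomize,
    sample_rotation,
    spin_permutation,
)
from tests.conftest import brute_force_morans_i


class TestRotations:
    def test_orthogonal_with_unit_determinant(self, rng):
        for _ in range(20):
            R = sample_rotation(rng).matrix
            assert np.abs(R.T @ R - np.eye(3)).max() < 1e-12
            assert abs(np.linalg.det(R) - 1.0) < 1e-12

    def test_deterministic_given_seed(self):
        R1 = sample_rotation(42).matrix
        R2 = sample_rotation(42).matrix
        np.testing.assert_array_equal(R1, R2)

    def test_uniformity_mean_image_near_zero(self):
        # Haar-uniform rotations of a fixed vector average to ~0
        rng = np.random.default_rng(0)
        pole = np.array([0.0, 0.0, 1.0])
        images = np.array([sample_rotation(rng).matrix.T @ pole for _ in range(10_000)])
        assert np.linalg.norm(images.mean(axis=0)) < 0.05


class TestSpinPermutation:
    def test_values_drawn_from_input_multiset(self, icosphere_162, rng):
        data = gm.smooth_field(icosphere_162, 5, seed=3)
        ens = spin_permutation(data, icosphere_162, n_perm=20, rng=rng)
        assert np.isin(ens.surrogates, data.values).all()

    def test_identity_rotation_is_fixed_point(self, icosphere_162):
        from gradmap.meshops import nearest_neighbor_map

        data = gm.smooth_field(icosphere_162, 5, seed=3)
        idx = nearest_neighbor_map(
            icosphere_162.vertices @ np.eye(3), icosphere_162.vertices
        )
        np.testing.assert_array_equal(data.values[idx], data.values)

    def test_deterministic_given_seed(self, icosphere_162):
        data = gm.smooth_field(icosphere_162, 5, seed=3)
        e1 = spin_permutation(data, icosphere_162, n_perm=5, rng=11)
        e2 = spin_permutation(data, icosphere_162, n_perm=5, rng=11)
        np.testing.assert_array_equal(e1.surrogates, e2.surrogates)

    def test_mask_propagates(self, icosphere_162):
        mask = np.zeros(162, dtype=bool)
        mask[:10] = True
        data = gm.ScalarMap(gm.smooth_field(icosphere_162, 5, seed=3).values, mask=mask)
        ens = spin_permutation(data, icosphere_162, n_perm=5, rng=0)
        assert ens.masks is not None
        assert ens.masks.sum(axis=1).min() > 0  # masked sources reappear somewhere

    def test_approximately_preserves_morans_i(self, icosphere_642):
        weights = gm.build_spatial_weights(icosphere_642)
        data = gm.smooth_field(icosphere_642, 10, seed=2)
        I0 = morans_i(data, weights)
        ens = spin_permutation(data, icosphere_642, n_perm=100, rng=4)
        Is = [morans_i(z, weights) for z in ens]
        assert abs(np.mean(Is) - I0) / abs(I0) < 0.25


class TestMoranBasis:
    def test_columns_orthonormal_and_centered(self, moran_basis_162):
        M = moran_basis_162.vectors
        np.testing.assert_allclose(M.T @ M, np.eye(M.shape[1]), atol=1e-10)
        assert np.abs(M.sum(axis=0)).max() < 1e-10

    def test_at_most_l_minus_1_vectors(self, moran_basis_162):
        assert moran_basis_162.n_components <= 161

    def test_tetrahedron_matches_dense_oracle(self, tetrahedron):
        W = gm.build_spatial_weights(tetrahedron, scheme="binary").toarray()
        H = np.eye(4) - np.ones((4, 4)) / 4
        vals = np.sort(np.linalg.eigvalsh(H @ W @ H))[::-1]
        basis = moran_basis(gm.build_spatial_weights(tetrahedron, scheme="binary"))
        keep = np.abs(vals) >= 1e-10 * np.abs(vals).max()
        np.testing.assert_allclose(basis.eigenvalues, vals[keep], atol=1e-10)

    def test_too_few_vertices_rejected(self, tetrahedron):
        W = gm.build_spatial_weights(tetrahedron)
        mask = np.array([True, True, False, False])
        with pytest.raises(errors.ShapeMismatchError):
            moran_basis(W, mask=mask)


class TestMoransI:
    def test_alternating_path_matches_brute_force(self):
        # alternating +-1 on a path graph: strong negative autocorrelation
        n = 8
        verts = np.c_[np.arange(n, dtype=float), np.zeros(n), np.zeros(n)]
        faces = np.array([[i, i + 1, i + 2] for i in range(n - 2)])
        mesh = gm.TriangleMesh(verts, faces)
        W = gm.build_spatial_weights(mesh, scheme="binary")
        u = np.array([(-1.0) ** i for i in range(n)])
        expected = brute_force_morans_i(u, W.toarray())
        assert morans_i(u, W) == pytest.approx(expected, abs=1e-12)
        assert morans_i(u, W) < 0

    def test_random_field_matches_brute_force(self, icosphere_162, weights_162, rng):
        u = rng.standard_normal(162)
        expected = brute_force_morans_i(u, weights_162.toarray())
        assert morans_i(u, weights_162) == pytest.approx(expected, abs=1e-10)

    def test_permutation_null_expectation(self, weights_162, rng):
        # E[I] under random permutation is -1/(l-1)
        u = gm.smooth_field(gm.make_icosphere(2), 5, seed=1).values
        vals = [morans_i(u[rng.permutation(162)], weights_162) for _ in range(1000)]
        mc_sigma = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - (-1 / 161)) < 3 * mc_sigma

    def test_first_moran_eigenvector_is_maximal(self, weights_162, moran_basis_162):
        Is = [morans_i(moran_basis_162.vectors[:, k], weights_162)
              for k in range(0, moran_basis_162.n_components, 10)]
        assert np.argmax(Is) == 0

    def test_constant_map_rejected(self, weights_162):
        with pytest.raises(errors.ConstantMapError):
            morans_i(np.ones(162), weights_162)


class TestMSR:
    def test_singleton_preserves_morans_i_exactly(self, icosphere_162, weights_162,
                                                  moran_basis_162):
        u = gm.smooth_field(icosphere_162, 8, seed=5)
        I0 = morans_i(u, weights_162)
        ens = msr_randomize(u, moran_basis_162, "singleton", n_perm=20, rng=7)
        for z in ens:
            assert morans_i(z, weights_162) == pytest.approx(I0, abs=1e-8)

    def test_mean_and_sd_preserved(self, icosphere_162, moran_basis_162):
        u = gm.smooth_field(icosphere_162, 8, seed=5)
        ens = msr_randomize(u, moran_basis_162, "pair", n_perm=20, rng=7)
        np.testing.assert_allclose(ens.surrogates.mean(axis=1), u.values.mean(), atol=1e-10)
        np.testing.assert_allclose(
            ens.surrogates.std(axis=1, ddof=1), u.values.std(ddof=1), atol=1e-10
        )

    def test_all_positive_signs_reproduce_input(self, icosphere_162, moran_basis_162):
        class AllPositiveSigns(np.random.Generator):
            def choice(self, a, size=None):
                return np.ones(size) if size is not None else 1.0

        u = gm.smooth_field(icosphere_162, 8, seed=5)
        rng = AllPositiveSigns(np.random.PCG64(0))
        ens = msr_randomize(u, moran_basis_162, "singleton", n_perm=1, rng=rng)
        np.testing.assert_allclose(ens.surrogates[0], u.values, atol=1e-8)

    def test_pair_preserves_morans_i_approximately(self, icosphere_162, weights_162,
                                                   moran_basis_162):
        u = gm.smooth_field(icosphere_162, 8, seed=5)
        I0 = morans_i(u, weights_162)
        ens = msr_randomize(u, moran_basis_162, "pair", n_perm=200, rng=7)
        Is = np.array([morans_i(z, weights_162) for z in ens])
        assert abs(Is.mean() - I0) / abs(I0) < 0.10
        assert not np.allclose(Is, I0, atol=1e-12)  # approximate, not exact

    def test_singleton_capacity_bound(self, tetrahedron):
        W = gm.build_spatial_weights(tetrahedron)
        basis = moran_basis(W)
        u = gm.ScalarMap(np.array([1.0, 2.0, 3.0, 4.0]))
        with pytest.raises(errors.SingletonCapacityError, match="2"):
            msr_randomize(u, basis, "singleton", n_perm=9)  # 2^(4-1) = 8 max

    def test_constant_map_rejected(self, moran_basis_162):
        with pytest.raises(errors.ConstantMapError):
            msr_randomize(np.ones(162), moran_basis_162, "singleton", n_perm=1)

    def test_deterministic_given_seed(self, icosphere_162, moran_basis_162):
        u = gm.smooth_field(icosphere_162, 8, seed=5)
        e1 = msr_randomize(u, moran_basis_162, "pair", n_perm=5, rng=3)
        e2 = msr_randomize(u, moran_basis_162, "pair", n_perm=5, rng=3)
        np.testing.assert_array_equal(e1.surrogates, e2.surrogates)

    def test_masked_vertices_excluded(self, icosphere_162, weights_162):
        mask = np.zeros(162, dtype=bool)
        mask[:20] = True
        u = gm.ScalarMap(gm.smooth_field(icosphere_162, 8, seed=5).values, mask=mask)
        basis = moran_basis(weights_162, mask=mask)
        ens = msr_randomize(u, basis, "singleton", n_perm=3, rng=1)
        # masked positions keep the original values and stay flagged
        np.testing.assert_array_equal(ens.surrogates[:, :20], np.tile(u.values[:20], (3, 1)))
        assert ens.masks.all(axis=0)[:20].all()


class TestEmpiricalPvalue:
    def test_observed_beyond_all_nulls(self):
        nulls = np.linspace(-1, 1, 1000)
        assert empirical_pvalue(2.0, nulls, "right") == pytest.approx(1 / 1001)

    def test_median_observed_two_tailed_capped(self):
        nulls = np.arange(-50, 51, dtype=float)
        assert empirical_pvalue(0.0, nulls, "two") == 1.0

    def test_tie_counts_as_extreme(self):
        nulls = np.array([1.0, 2.0, 3.0])
        # observed equals one null: that null counts as at least as extreme
        assert empirical_pvalue(3.0, nulls, "right") == pytest.approx(2 / 4)

    def test_empty_nulls_rejected(self):
        with pytest.raises(errors.ShapeMismatchError):
            empirical_pvalue(0.0, [], "two")


def test_spin_rejects_non_spherical_mesh(tetrahedron):
    data = np.arange(4, dtype=float)
    verts = tetrahedron.vertices.copy()
    verts[0] *= 3.0  # push one vertex off the common radius
    stretched = gm.TriangleMesh(verts, tetrahedron.faces)
    with pytest.raises(gm.errors.NotSphericalError):
        spin_permutation(data, stretched, n_perm=1, rng=0)
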