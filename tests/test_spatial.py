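"""Spatial weights, Moran's I, the exact residual test, and SEVM filtering."""

import numpy as np
import pytest

from econetres import (
    SpatialWeights,
    build_weights,
    mem_eigenvectors,
    moran_residual_test,
    morans_i,
    select_spatial_filter,
)
from econetres.spatial import great_circle_matrix


@pytest.fixture
def scattered():
    rng = np.random.default_rng(11)
    coords = np.column_stack([rng.uniform(-20, 20, 30), rng.uniform(-40, 40, 30)])
    return coords, build_weights(coords, k=4)


class TestBuildWeights:
    def test_line_endpoints_link_inward(self):
        coords = np.array([[0.0, 0.0], [0.0, 1.0], [0.0, 2.0], [0.0, 3.0]])
        w = build_weights(coords, k=1, row_standardize=False)
        assert w.W[0, 1] == 1 and w.W[3, 2] == 1

    def test_row_standardization(self):
        coords = np.array([[0.0, 0.0], [0.0, 1.0], [0.0, 2.0], [0.0, 3.0]])
        w = build_weights(coords, k=2)
        nz = w.W.sum(axis=1)
        assert np.allclose(nz, 1.0)

    def test_k_equal_n_rejected(self):
        coords = np.zeros((4, 2)) + np.arange(4)[:, None]
        with pytest.raises(ValueError, match="k must"):
            build_weights(coords, k=4)

    def test_duplicate_coordinates_warn(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [0.0, 2.0], [0.0, 3.0]])
        with pytest.warns(UserWarning, match="duplicate"):
            build_weights(coords, k=1)

    def test_zero_diagonal_enforced(self, scattered):
        _, w = scattered
        assert np.all(np.diag(w.W) == 0)

    def test_great_circle_symmetry_and_zero_diag(self, scattered):
        coords, _ = scattered
        D = great_circle_matrix(coords)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)


class TestMoransI:
    def test_checkerboard_on_cycle_is_minus_one(self):
        W = np.array([[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]]) / 2.0
        sw = SpatialWeights(W, np.array([[0, 0], [0, 1], [1, 1], [1, 0]]), row_standardized=True)
        assert morans_i([1, -1, 1, -1], sw) == pytest.approx(-1.0)

    def test_permutation_null_mean(self, scattered, rng):
        # E[I] = -1/(n-1) under the permutation null
        _, w = scattered
        vals = rng.standard_normal(w.n)
        perms = np.array([morans_i(rng.permutation(vals), w) for _ in range(3000)])
        assert perms.mean() == pytest.approx(-1.0 / (w.n - 1), abs=3 * perms.std() / np.sqrt(3000))

    def test_constant_vector_rejected(self, scattered):
        _, w = scattered
        with pytest.raises(ValueError, match="variance"):
            morans_i(np.ones(w.n), w)

    def test_moran_eigenvector_identity(self, scattered):
        # I of a doubly-centred-W eigenvector is proportional to its eigenvalue
        _, w = scattered
        cand = mem_eigenvectors(w)
        c = w.n / w.W.sum()
        for j in (0, 1, 2):
            v = cand.basis[:, j]
            assert morans_i(v, w) == pytest.approx(c * cand.eigenvalues[j], rel=1e-8)


class TestMemEigenvectors:
    def test_orthogonal_to_constant(self, scattered):
        _, w = scattered
        cand = mem_eigenvectors(w)
        assert np.all(np.abs(cand.basis.sum(axis=0)) < 1e-8)

    def test_columns_orthogonal(self, scattered):
        _, w = scattered
        B = mem_eigenvectors(w).basis
        assert np.allclose(B.T @ B, np.eye(B.shape[1]), atol=1e-8)

    def test_leading_vector_maximizes_moran(self, scattered, rng):
        _, w = scattered
        cand = mem_eigenvectors(w)
        top = morans_i(cand.basis[:, 0], w)
        n = w.n
        for _ in range(300):
            v = rng.standard_normal(n)
            v -= v.mean()
            assert morans_i(v, w) <= top + 1e-10

    def test_at_most_n_minus_1_positive(self, scattered):
        _, w = scattered
        cand = mem_eigenvectors(w, eigenvalue_ratio_floor=0.0)
        assert cand.q <= w.n - 1


class TestMoranResidualTest:
    def test_null_p_values_uniform(self, scattered, rng):
        _, w = scattered
        n = w.n
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        ps = [moran_residual_test(X, rng.standard_normal(n), w).p_value for _ in range(300)]
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_detects_planted_spatial_structure(self, scattered, rng):
        _, w = scattered
        n = w.n
        X = np.ones((n, 1))
        cand = mem_eigenvectors(w)
        y = 2.0 * cand.basis[:, 0] + 0.3 * rng.standard_normal(n)
        res = moran_residual_test(X, y, w)
        assert res.p_value < 0.01
        assert res.I > res.expected_I

    def test_exact_agrees_with_permutation(self, scattered, rng):
        _, w = scattered
        n = w.n
        for _ in range(10):
            X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
            y = rng.standard_normal(n)
            pe = moran_residual_test(X, y, w, method="exact").p_value
            pp = moran_residual_test(
                X, y, w, method="permutation", n_permutations=30000, rng=rng
            ).p_value
            assert pe == pytest.approx(pp, abs=0.02)

    def test_exact_agrees_with_normal_approximation(self, scattered, rng):
        _, w = scattered
        n = w.n
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = rng.standard_normal(n)
        pe = moran_residual_test(X, y, w, method="exact").p_value
        pn = moran_residual_test(X, y, w, method="normal").p_value
        assert pe == pytest.approx(pn, abs=0.05)

    def test_two_sided_doubles_smaller_tail(self, scattered, rng):
        _, w = scattered
        n = w.n
        X = np.ones((n, 1))
        y = rng.standard_normal(n)
        g = moran_residual_test(X, y, w, alternative="greater").p_value
        t = moran_residual_test(X, y, w, alternative="two_sided").p_value
        assert t == pytest.approx(min(1.0, 2 * min(g, 1 - g)))

    def test_rank_deficient_design_rejected(self, scattered):
        _, w = scattered
        n = w.n
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="rank"):
            moran_residual_test(X, np.arange(n, dtype=float), w)


class TestSelectSpatialFilter:
    def test_planted_eigenvector_selected_first(self, scattered, rng):
        _, w = scattered
        n = w.n
        cand = mem_eigenvectors(w)
        y = 2.0 * cand.basis[:, 0] + 0.3 * rng.standard_normal(n)
        filt = select_spatial_filter(np.ones((n, 1)), y, w)
        assert filt.q >= 1
        assert filt.selection_order[0] == 0

    def test_iid_response_gives_empty_filter(self, scattered, rng):
        _, w = scattered
        y = rng.standard_normal(w.n)
        filt = select_spatial_filter(np.ones((w.n, 1)), y, w)
        if moran_residual_test(np.ones((w.n, 1)), y, w).p_value >= 0.05:
            assert filt.q == 0 and filt.converged

    def test_selected_basis_orthonormal(self, scattered, rng):
        _, w = scattered
        cand = mem_eigenvectors(w)
        y = cand.basis[:, :3] @ np.array([2.0, 1.5, 1.0]) + 0.2 * rng.standard_normal(w.n)
        filt = select_spatial_filter(np.ones((w.n, 1)), y, w)
        if filt.q:
            assert np.allclose(filt.basis.T @ filt.basis, np.eye(filt.q), atol=1e-10)

    def test_autocorrelation_never_increases_along_path(self, scattered, rng):
        _, w = scattered
        n = w.n
        cand = mem_eigenvectors(w)
        y = cand.basis[:, :3] @ np.array([2.0, 1.5, 1.0]) + 0.2 * rng.standard_normal(n)
        X = np.ones((n, 1))
        filt = select_spatial_filter(X, y, w)
        devs = []
        for q in range(filt.q + 1):
            Xq = np.column_stack([X, filt.basis[:, :q]]) if q else X
            t = moran_residual_test(Xq, y, w)
            devs.append(abs(t.I - t.expected_I))
        assert all(a >= b - 1e-9 for a, b in zip(devs, devs[1:]))
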