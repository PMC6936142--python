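import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from manialign import (
    align_linear,
    align_nonparametric,
    alignment_loss,
    cca_align,
    identity_correspondence,
    joint_system,
    knn_graph,
    make_paired_manifold,
    make_warp_pair,
    manifold_warp,
)
from manialign.alignment import TRIVIAL_EIGENVALUE


def random_joint_system(rng, m_x=None, m_y=None, mu=0.5):
    """A random connected joint system for oracle comparisons."""
    m_x = m_x or int(rng.integers(4, 10))
    m_y = m_y or int(rng.integers(4, 10))
    WX = knn_graph(rng.normal(size=(m_x, 3)), k=2)
    WY = knn_graph(rng.normal(size=(m_y, 3)), k=2)
    W = (rng.random((m_x, m_y)) < 0.3).astype(float)
    W[0, 0] = 1.0  # guarantee coupling
    return joint_system(WX, WY, W, mu=mu)


def dense_generalized_oracle(L, D_vec, d):
    """Full-spectrum generalized eigensolver via the non-symmetric QZ route.

    Independent of the package's symmetric solver path; returns the d
    smallest nontrivial eigenpairs, D-normalized.
    """
    vals, vecs = scipy.linalg.eig(L, np.diag(D_vec))
    vals = vals.real
    order = np.argsort(vals)
    vals, vecs = vals[order], vecs.real[:, order]
    keep = vals >= TRIVIAL_EIGENVALUE
    idx = np.flatnonzero(keep)[:d]
    out_vecs = vecs[:, idx]
    for k in range(out_vecs.shape[1]):
        v = out_vecs[:, k]
        v = v / np.sqrt(v @ (D_vec * v))
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        out_vecs[:, k] = v
    return vals[idx], out_vecs


class TestJointSystem:
    def test_single_gene_hand_example(self):
        S = joint_system(np.zeros((1, 1)), np.zeros((1, 1)), np.ones((1, 1)), mu=0.5)
        np.testing.assert_allclose(S.similarity, [[0, 0.5], [0.5, 0]])
        np.testing.assert_allclose(S.laplacian, [[0.5, -0.5], [-0.5, 0.5]])

    def test_mu_one_decouples_datasets(self):
        rng = np.random.default_rng(0)
        S = random_joint_system(rng, 5, 6, mu=1.0)
        m_x = 5
        assert np.all(S.similarity[:m_x, m_x:] == 0)

    def test_mu_zero_keeps_only_correspondence(self):
        rng = np.random.default_rng(0)
        S = random_joint_system(rng, 5, 6, mu=0.0)
        assert np.all(S.similarity[:5, :5] == 0)
        assert np.all(S.similarity[5:, 5:] == 0)

    def test_mu_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="mu"):
            joint_system(np.zeros((1, 1)), np.zeros((1, 1)), np.ones((1, 1)), mu=1.5)

    def test_laplacian_rows_sum_to_zero(self):
        rng = np.random.default_rng(1)
        S = random_joint_system(rng)
        np.testing.assert_allclose(S.laplacian.sum(axis=1), 0, atol=1e-10)


class TestAlignNonparametric:
    def test_identical_datasets_embed_identically(self):
        # manifold-structured data: both copies must land on the same coords
        t = np.linspace(0, 1, 20)
        X = np.column_stack([t, t**2, np.sin(2 * t), np.cos(t)])
        WX = knn_graph(X, k=3)
        S = joint_system(WX, WX, np.eye(20))
        emb = align_nonparametric(S, d=2)
        assert np.abs(emb.x_coords - emb.y_coords).max() < 1e-6

    def test_matches_dense_generalized_eigensolver_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            S = random_joint_system(rng)
            if (S.degree <= 0).any():
                continue
            emb = align_nonparametric(S, d=2)
            vals, vecs = dense_generalized_oracle(S.laplacian, S.degree, 2)
            np.testing.assert_allclose(emb.eigenvalues, vals, atol=1e-8)
            np.testing.assert_allclose(emb.coords, vecs, atol=1e-6)

    def test_embedding_satisfies_degree_orthonormality(self):
        rng = np.random.default_rng(4)
        S = random_joint_system(rng)
        emb = align_nonparametric(S, d=3)
        gram = emb.coords.T @ (S.degree[:, None] * emb.coords)
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-6)

    def test_zero_degree_vertex_rejected(self):
        WX = np.zeros((2, 2))
        WY = np.zeros((2, 2))
        W = np.zeros((2, 2))
        W[0, 0] = 1.0  # second gene of each dataset isolated
        S = joint_system(WX, WY, W)
        with pytest.raises(ValueError, match="zero degree"):
            align_nonparametric(S, d=1)

    def test_deterministic_given_inputs(self):
        rng = np.random.default_rng(5)
        S = random_joint_system(rng)
        e1 = align_nonparametric(S, d=2)
        e2 = align_nonparametric(S, d=2)
        np.testing.assert_array_equal(e1.coords, e2.coords)

    def test_decoupling_limit_reproduces_per_graph_eigenmaps(self):
        # with mu=1 the joint graph is block diagonal, so its nontrivial
        # spectrum is the union of the two graphs' own eigenmap spectra
        rng = np.random.default_rng(6)
        WX = knn_graph(rng.normal(size=(7, 3)), k=2)
        WY = knn_graph(rng.normal(size=(9, 3)), k=3)
        S = joint_system(WX, WY, np.zeros((7, 9)), mu=1.0)
        emb = align_nonparametric(S, d=2)
        from manialign.graph import laplacian

        expected = []
        for Wg in (WX, WY):
            L, deg = laplacian(Wg)
            vals = scipy.linalg.eigh(L, np.diag(deg), eigvals_only=True)
            expected.extend(v for v in vals if v >= TRIVIAL_EIGENVALUE)
        expected = np.sort(expected)[:2]
        np.testing.assert_allclose(np.sort(emb.eigenvalues), expected, atol=1e-8)

    def test_loss_not_beaten_by_random_feasible_embeddings(self):
        # optimality spot-check: the returned coordinates minimize the
        # alignment objective over D-orthonormal embeddings
        rng = np.random.default_rng(7)
        WX = knn_graph(rng.normal(size=(12, 3)), k=3)
        WY = knn_graph(rng.normal(size=(11, 3)), k=3)
        W = np.zeros((12, 11))
        W[np.arange(8), np.arange(8)] = 1.0
        S = joint_system(WX, WY, W)
        emb = align_nonparametric(S, d=2)
        loss_opt = alignment_loss(
            WX * 1.0, WY * 1.0, W, emb.x_coords, emb.y_coords, mu=0.5
        )
        D = S.degree
        m = D.size
        for _ in range(100):
            M = rng.normal(size=(m, 2))
            # Gram-Schmidt in the D inner product
            for k in range(2):
                for prev in range(k):
                    M[:, k] -= (M[:, k] @ (D * M[:, prev])) * M[:, prev]
                M[:, k] /= np.sqrt(M[:, k] @ (D * M[:, k]))
            loss_rand = alignment_loss(WX, WY, W, M[:12], M[12:], mu=0.5)
            assert loss_opt <= loss_rand + 1e-9

    def test_loss_equals_joint_trace_identity(self):
        rng = np.random.default_rng(8)
        S = random_joint_system(rng, 6, 5)
        emb = align_nonparametric(S, d=2)
        WX = S.similarity[:6, :6] / S.mu
        WY = S.similarity[6:, 6:] / S.mu
        W = S.similarity[:6, 6:] / (1 - S.mu)
        loss = alignment_loss(WX, WY, W, emb.x_coords, emb.y_coords, mu=S.mu)
        trace = np.trace(emb.coords.T @ S.laplacian @ emb.coords)
        assert loss == pytest.approx(trace, abs=1e-9)


class TestAlignLinear:
    def test_identical_datasets_embed_identically(self):
        t = np.linspace(0, 1, 20)
        X = pd.DataFrame(np.column_stack([t, t**2, np.sin(2 * t), np.cos(t)]))
        WX = knn_graph(X, k=3)
        S = joint_system(WX, WX, np.eye(20))
        emb = align_linear(S, X, X, d=2)
        assert np.abs(emb.x_coords - emb.y_coords).max() < 1e-6

    def test_projection_shapes(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(8, 3))
        Y = rng.normal(size=(9, 5))
        S = joint_system(
            knn_graph(X, k=2), knn_graph(Y, k=2), np.ones((8, 9)) * 0.1
        )
        emb = align_linear(S, X, Y, d=2)
        assert emb.F.shape == (3, 2)
        assert emb.G.shape == (5, 2)
        np.testing.assert_allclose(emb.x_coords, X @ emb.F)

    def test_matches_dense_eigensolver_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(4, 2))
        Y = rng.normal(size=(4, 2))
        S = joint_system(knn_graph(X, k=2), knn_graph(Y, k=2), np.eye(4))
        emb = align_linear(S, X, Y, d=2)
        Z = scipy.linalg.block_diag(X, Y)
        A = Z.T @ S.laplacian @ Z
        B = Z.T @ np.diag(S.degree) @ Z
        vals = scipy.linalg.eig(A, B)[0].real
        vals = np.sort(vals[vals >= TRIVIAL_EIGENVALUE])[:2]
        np.testing.assert_allclose(emb.eigenvalues, vals, atol=1e-8)


class TestManifoldWarp:
    def test_identical_sequences_converge_to_diagonal(self):
        sc = make_warp_pair(n_timepoints_X=20, n_timepoints_Y=20, warp="identity")
        result = manifold_warp(sc.X, sc.X, k=3, d=2)
        assert result.converged
        assert result.path.steps == tuple((i, i) for i in range(20))
        assert result.path.total_cost == pytest.approx(0.0, abs=1e-9)

    def test_final_cost_no_worse_than_first_iteration(self):
        sc = make_warp_pair(
            n_timepoints_X=24, n_timepoints_Y=16, warp="quadratic", seed=3
        )
        first = manifold_warp(sc.X, sc.Y, k=3, d=2, max_iter=1)
        final = manifold_warp(sc.X, sc.Y, k=3, d=2, max_iter=10)
        assert final.path.total_cost <= first.path.total_cost + 1e-9

    def test_max_iter_one_returns_unconverged_single_pass(self):
        sc = make_warp_pair(n_timepoints_X=15, n_timepoints_Y=12, warp="sqrt", seed=1)
        result = manifold_warp(sc.X, sc.Y, k=3, d=2, max_iter=1)
        assert result.n_iter == 1
        assert not result.converged


class TestCcaAlign:
    def test_self_alignment_has_perfect_first_correlation(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 5))
        emb = cca_align(X, X, np.eye(30), d=2)
        r = np.corrcoef(emb.x_coords[:, 0], emb.y_coords[:, 0])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_output_dimensionality(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(20, 6))
        Y = rng.normal(size=(25, 4))
        W = np.zeros((20, 25))
        W[np.arange(10), np.arange(10)] = 1
        emb = cca_align(X, Y, W, d=3)
        assert emb.x_coords.shape == (20, 3)
        assert emb.y_coords.shape == (25, 3)

    def test_too_few_pairs_rejected(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(5, 3))
        W = np.zeros((5, 5))
        W[0, 0] = 1
        with pytest.raises(ValueError, match="pairs"):
            cca_align(X, X, W, d=2)

    def test_nonlinear_fixture_favors_manifold_alignment(self):
        # on the S-curve fixture the nonlinear embedding brings corresponded
        # genes closer than the linear CCA baseline
        from manialign import RunConfig, run_pipeline

        wins = 0
        for seed in range(3):
            sc = make_paired_manifold(seed=seed)
            d_m = run_pipeline(
                RunConfig(method="alignment_nonparametric", n_modules=4, seed=seed),
                X=sc.X, Y=sc.Y, pairs=sc.pairs,
            ).evaluation["total_pair_distance"]
            d_c = run_pipeline(
                RunConfig(method="cca", n_modules=4, seed=seed),
                X=sc.X, Y=sc.Y, pairs=sc.pairs,
            ).evaluation["total_pair_distance"]
            wins += d_m < d_c
        assert wins == 3
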