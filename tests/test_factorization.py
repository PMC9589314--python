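"""Objective, multiplicative updates and fitting drivers."""

import numpy as np
import pytest

from hyperjnmf import (
    DiagnosisVector,
    FactorizationParams,
    ValidationError,
    build_cross_adjacency,
    build_knn_hypergraph,
    fit,
    hypergraph_laplacian,
    jnmf_fit,
    objective,
    relative_error,
    standardize_columns,
    update_step,
)
from hyperjnmf.factorization import gradients


def _loop_objective(X1, X2, d, A, B1, B2, W, H1, H2, p):
    """Scalar re-implementation of every objective term with explicit loops."""
    n, K = W.shape
    omega = [float(x) ** 2 for x in d]  # squared diagnosis weights
    total = 0.0
    for X, H in ((X1, H1), (X2, H2)):
        for s in range(n):
            for j in range(X.shape[1]):
                r = X[s, j] - sum(W[s, k] * H[k, j] for k in range(K))
                total += omega[s] * r * r
    # cross-modality reward: -alpha * tr(H1 A H2^T)
    tr = 0.0
    for k in range(K):
        for j1 in range(H1.shape[1]):
            for j2 in range(H2.shape[1]):
                tr += H1[k, j1] * A[j1, j2] * H2[k, j2]
    total -= p.alpha * tr
    # hypergraph smoothness: lambda * tr(H B H^T)
    for H, B, lam in ((H1, B1, p.lambda1), (H2, B2, p.lambda2)):
        acc = 0.0
        for k in range(K):
            for i in range(H.shape[1]):
                for j in range(H.shape[1]):
                    acc += H[k, i] * B[i, j] * H[k, j]
        total += lam * acc
    # soft orthogonality: beta * ||H H^T - I||_F^2
    for H, beta in ((H1, p.beta1), (H2, p.beta2)):
        acc = 0.0
        for k1 in range(K):
            for k2 in range(K):
                g = sum(H[k1, j] * H[k2, j] for j in range(H.shape[1]))
                acc += (g - (1.0 if k1 == k2 else 0.0)) ** 2
        total += beta * acc
    total += p.gamma1 * sum(abs(v) for v in W.ravel())
    total += p.gamma2 * (sum(abs(v) for v in H1.ravel()) + sum(abs(v) for v in H2.ravel()))
    return total


class TestObjective:
    def test_perfect_fit_zero_weights_gives_zero(self, rng):
        W = rng.uniform(1, 2, (8, 3))
        H1, H2 = rng.uniform(1, 2, (3, 6)), rng.uniform(1, 2, (3, 5))
        p = FactorizationParams(K=3)
        total, comp = objective(W @ H1, W @ H2, None, None, None, None, W, H1, H2, p)
        assert total == pytest.approx(0.0, abs=1e-18)

    def test_zero_factors_leave_weighted_data_norm(self, rng):
        X1, X2 = rng.uniform(1, 2, (6, 5)), rng.uniform(1, 2, (6, 4))
        Z_w, Z_h1, Z_h2 = np.zeros((6, 2)), np.zeros((2, 5)), np.zeros((2, 4))
        p = FactorizationParams(K=2)
        total, _ = objective(X1, X2, None, None, None, None, Z_w, Z_h1, Z_h2, p)
        assert total == pytest.approx(np.sum(X1**2) + np.sum(X2**2), rel=1e-12)
        # with orthogonality on, each modality adds beta * ||-I||^2 = beta * K
        p2 = FactorizationParams(K=2, beta1=0.5, beta2=0.25)
        total2, _ = objective(X1, X2, None, None, None, None, Z_w, Z_h1, Z_h2, p2)
        expected = np.sum(X1**2) + np.sum(X2**2) + 0.5 * 2 + 0.25 * 2
        assert total2 == pytest.approx(expected, rel=1e-12)

    def test_matches_scalar_loop_oracle_with_all_terms(self, rng):
        n, p1, p2, K = 8, 6, 5, 3
        X1 = rng.uniform(0.1, 1, (n, p1))
        X2 = rng.uniform(0.1, 1, (n, p2))
        labels = DiagnosisVector(rng.integers(1, 3, n))
        x1s, x2s = standardize_columns(X1), standardize_columns(X2)
        A = build_cross_adjacency(x1s, x2s, 0.3, binary=False)
        B1 = hypergraph_laplacian(build_knn_hypergraph(x1s, 2))
        B2 = hypergraph_laplacian(build_knn_hypergraph(x2s, 2))
        W = rng.uniform(0.1, 1, (n, K))
        H1, H2 = rng.uniform(0.1, 1, (K, p1)), rng.uniform(0.1, 1, (K, p2))
        p = FactorizationParams(
            K=K, alpha=0.01, lambda1=0.01, lambda2=0.01, beta1=0.01, beta2=0.01,
            gamma1=0.01, gamma2=0.01,
        )
        total, comp = objective(x1s, x2s, labels, A, B1, B2, W, H1, H2, p)
        expected = _loop_objective(
            x1s.values, x2s.values, labels.labels, A.weights, B1.matrix, B2.matrix, W, H1, H2, p
        )
        assert total == pytest.approx(expected, rel=1e-10)
        assert total == pytest.approx(sum(comp.values()), rel=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        p = FactorizationParams(K=2)
        with pytest.raises(ValidationError, match="shapes"):
            objective(
                rng.uniform(size=(5, 4)), rng.uniform(size=(5, 3)), None, None, None, None,
                rng.uniform(size=(5, 3)), rng.uniform(size=(2, 4)), rng.uniform(size=(2, 3)), p,
            )


class TestUpdateStep:
    def test_exact_factorization_is_fixed_point(self, rng):
        W = rng.uniform(1, 2, (10, 3))
        H1, H2 = rng.uniform(1, 2, (3, 8)), rng.uniform(1, 2, (3, 6))
        Wn, H1n, H2n = update_step(
            W @ H1, W @ H2, None, None, None, None, W, H1, H2, FactorizationParams(K=3)
        )
        np.testing.assert_allclose(Wn, W, atol=1e-9)
        np.testing.assert_allclose(H1n, H1, atol=1e-9)
        np.testing.assert_allclose(H2n, H2, atol=1e-9)

    def test_nonnegativity_preserved_over_many_seeded_runs(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X1, X2 = rng.uniform(0, 1, (7, 5)), rng.uniform(0, 1, (7, 4))
            p = FactorizationParams(
                K=3, alpha=0.01, lambda1=0.01, lambda2=0.01, beta1=0.01, beta2=0.01,
                gamma1=0.01, gamma2=0.01, max_iter=20, tol=0.0, seed=seed,
            )
            x1s, x2s = standardize_columns(X1), standardize_columns(X2)
            A = build_cross_adjacency(x1s, x2s, 0.3)
            B1 = hypergraph_laplacian(build_knn_hypergraph(x1s, 2))
            B2 = hypergraph_laplacian(build_knn_hypergraph(x2s, 2))
            res = fit(x1s, x2s, None, A, B1, B2, p)
            assert (res.W >= 0).all() and (res.H1 >= 0).all() and (res.H2 >= 0).all()


class TestFit:
    def test_objective_monotone_with_all_constraints(self, regularized_inputs, mixed_params):
        ds, x1, x2, a, b1, b2 = regularized_inputs
        res = fit(x1, x2, ds.labels, a, b1, b2, mixed_params)
        tr = res.objective_trace
        rel_increase = (tr[1:] - tr[:-1]) / np.maximum(np.abs(tr[:-1]), 1e-12)
        assert rel_increase.max() <= 1e-8

    def test_reduction_to_plain_jnmf_is_bit_identical(self, small_dataset, mixed_params):
        ds = small_dataset
        from hyperjnmf import svd_init
        from dataclasses import replace

        init = svd_init(ds.x1, ds.x2, 5, 0)
        plain = replace(
            mixed_params, alpha=0.0, lambda1=0.0, lambda2=0.0, beta1=0.0, beta2=0.0,
            gamma1=0.0, gamma2=0.0,
        )
        via_fit = fit(ds.x1, ds.x2, None, None, None, None, plain, init=init)
        via_jnmf = jnmf_fit(ds.x1, ds.x2, mixed_params, init=init)
        np.testing.assert_array_equal(via_fit.objective_trace, via_jnmf.objective_trace)
        np.testing.assert_array_equal(via_fit.W, via_jnmf.W)

    def test_infinite_tol_stops_after_one_iteration(self, small_dataset):
        res = jnmf_fit(small_dataset.x1, small_dataset.x2, FactorizationParams(K=5, tol=np.inf))
        assert res.n_iter == 1 and res.converged

    def test_rank_one_data_fit_exactly_at_k1(self, rng):
        w = rng.uniform(1, 2, 9)
        x1, x2 = np.outer(w, rng.uniform(1, 2, 6)), np.outer(w, rng.uniform(1, 2, 5))
        res = jnmf_fit(x1, x2, FactorizationParams(K=1, max_iter=200))
        assert relative_error(x1, x2, res.W, res.H1, res.H2) < 1e-6

    def test_kkt_stationarity_at_convergence(self, rng):
        x1 = standardize_columns(rng.uniform(0.1, 1, (10, 8)))
        x2 = standardize_columns(rng.uniform(0.1, 1, (10, 6)))
        p = FactorizationParams(K=2, max_iter=20000, tol=0.0)
        res = jnmf_fit(x1, x2, p)
        gW, g1, g2 = gradients(x1, x2, None, None, None, None, res.W, res.H1, res.H2, p)
        residual = max(
            np.abs(np.minimum(res.W, np.abs(gW))).max(),
            np.abs(np.minimum(res.H1, np.abs(g1))).max(),
            np.abs(np.minimum(res.H2, np.abs(g2))).max(),
        )
        assert residual < 1e-3

    def test_surgical_weighting_pulls_fit_toward_weighted_sample(self, small_dataset):
        """Up-weighting one sample (label 2 vs 1) must not worsen its residual."""
        ds = small_dataset
        base = np.ones(ds.x1.n_samples, dtype=int)
        lab1 = DiagnosisVector(base.copy())
        lab2 = DiagnosisVector(np.where(np.arange(base.size) == 0, 2, 1))
        p = FactorizationParams(K=3, max_iter=300)
        r1 = fit(ds.x1, ds.x2, lab1, None, None, None, p)
        r2 = fit(ds.x1, ds.x2, lab2, None, None, None, p)

        def sample0_residual(r):
            e1 = ds.x1.values[0] - r.W[0] @ r.H1
            e2 = ds.x2.values[0] - r.W[0] @ r.H2
            return np.sum(e1**2) + np.sum(e2**2)

        assert sample0_residual(r2) <= sample0_residual(r1) * (1 + 1e-6)


class TestRelativeError:
    def test_perfect_and_zero_factorizations(self, rng):
        W = rng.uniform(1, 2, (6, 2))
        H1, H2 = rng.uniform(1, 2, (2, 5)), rng.uniform(1, 2, (2, 4))
        X1, X2 = W @ H1, W @ H2
        assert relative_error(X1, X2, W, H1, H2) == 0.0
        assert relative_error(X1, X2, np.zeros_like(W), H1, H2) == pytest.approx(1.0)

    def test_matches_elementwise_loop(self, rng):
        X1, X2 = rng.uniform(size=(5, 4)), rng.uniform(size=(5, 3))
        W = rng.uniform(size=(5, 2))
        H1, H2 = rng.uniform(size=(2, 4)), rng.uniform(size=(2, 3))
        num = den = 0.0
        for X, H in ((X1, H1), (X2, H2)):
            R = X - W @ H
            for s in range(X.shape[0]):
                for j in range(X.shape[1]):
                    num += R[s, j] ** 2
                    den += X[s, j] ** 2
        assert relative_error(X1, X2, W, H1, H2) == pytest.approx(np.sqrt(num / den), rel=1e-12)

    def test_zero_norm_input_rejected(self):
        with pytest.raises(ValidationError, match="zero norm"):
            relative_error(np.zeros((3, 2)), None, np.zeros((3, 1)), np.zeros((1, 2)), None)


def test_monotone_traces_across_seeded_regularized_runs():
    """Mixed-weight runs on small instances keep a non-increasing objective."""
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        x1 = standardize_columns(rng.uniform(0.05, 1, (20, 15)))
        x2 = standardize_columns(rng.uniform(0.05, 1, (20, 12)))
        lab = DiagnosisVector(rng.integers(1, 3, 20))
        a = build_cross_adjacency(x1, x2, 0.5)
        b1 = hypergraph_laplacian(build_knn_hypergraph(x1, 4))
        b2 = hypergraph_laplacian(build_knn_hypergraph(x2, 4))
        p = FactorizationParams(
            K=5, alpha=0.1, lambda1=0.001, lambda2=0.001, beta1=0.1, beta2=0.1,
            gamma1=0.001, gamma2=0.1, max_iter=60, tol=0.0, seed=seed,
        )
        res = fit(x1, x2, lab, a, b1, b2, p)
        tr = res.objective_trace
        rel = (tr[1:] - tr[:-1]) / np.maximum(np.abs(tr[:-1]), 1e-12)
        assert rel.max() <= 1e-8, f"seed {seed}: objective rose by {rel.max():.2e}"
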