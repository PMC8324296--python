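"""Likelihood, penalty and gradient contracts of the spatial GMRF model."""

import numpy as np
import pytest

import migsurf as ms
from migsurf.freq import FrequencyData
from migsurf.model import penalty, penalty_grad, soft_logmap

from conftest import random_weights


def dense_marginal_covariance(graph, w, sigma2, n, observed):
    """Oracle: V through the explicit dense Laplacian pseudo-inverse."""
    Lp = np.linalg.pinv(ms.laplacian(graph, w).toarray(), rcond=1e-10)
    o = len(observed)
    A = np.zeros((o, graph.n_nodes))
    A[np.arange(o), observed] = 1.0
    return A @ Lp @ A.T + sigma2 * np.diag(1.0 / np.asarray(n, dtype=float))


def dense_nll(graph, w, sigma2, data, C):
    M = C @ dense_marginal_covariance(
        graph, w, sigma2, data.n, data.observed_ids
    ) @ C.T
    S = C @ data.Sigma_hat @ C.T
    p = data.n_snps
    return p * (np.trace(np.linalg.solve(M, S)) + np.linalg.slogdet(M)[1])


def small_dataset(graph, seed=0, p=200, observed=None, sigma2=0.3):
    rng = np.random.default_rng(seed)
    w = random_weights(rng, graph.n_edges) * 5.0
    F, n, obs = ms.simulate_frequency_data(
        graph, w, p=p, sigma2=sigma2, n_per_node=8, rng=rng, observed_ids=observed
    )
    return FrequencyData.from_frequencies(F, n, obs, check_bounds=False)


class TestMarginalCovariance:
    def test_single_edge_resistance_identity(self):
        g = ms.SpatialGraph(np.zeros((2, 2)), np.array([[0, 1]]))
        w = np.array([0.4])
        V = ms.marginal_covariance(g, w, 0.0, np.array([1, 1]), np.array([0, 1]))
        assert V[0, 0] - 2 * V[0, 1] + V[1, 1] == pytest.approx(1 / 0.4)

    def test_infinite_weight_limit_leaves_only_residual_term(self, lattice_4x5):
        obs = np.arange(lattice_4x5.n_nodes)
        n = np.full(len(obs), 3)
        w = np.full(lattice_4x5.n_edges, 1e9)
        V = ms.marginal_covariance(lattice_4x5, w, 0.7, n, obs)
        C = ms.contrast_basis(len(obs))
        target = 0.7 * C @ np.diag(1.0 / n) @ C.T
        np.testing.assert_allclose(C @ V @ C.T, target, atol=1e-8)

    def test_matches_dense_oracle_with_unobserved_nodes(self):
        rng = np.random.default_rng(0)
        g = ms.build_rectangle_lattice(3, 4, 40.0)  # d = 12
        w = random_weights(rng, g.n_edges)
        observed = np.sort(rng.choice(g.n_nodes, size=5, replace=False))
        n = rng.integers(1, 6, size=5)
        V = ms.marginal_covariance(g, w, 0.2, n, observed)
        oracle = dense_marginal_covariance(g, w, 0.2, n, observed)
        assert np.max(np.abs(V - oracle)) / np.max(np.abs(oracle)) < 1e-8


class TestNegLogLik:
    def test_s_equal_m_reduces_to_dimension_plus_logdet(self, lattice_4x5):
        data = small_dataset(lattice_4x5, seed=1)
        model = ms.SpatialMigrationModel(lattice_4x5, data)
        w = np.full(lattice_4x5.n_edges, 2.0)
        V = ms.marginal_covariance(
            lattice_4x5, w, 0.3, data.n, data.observed_ids
        )
        M = model.C @ V @ model.C.T
        model.S = M  # force S = M
        p, o = data.n_snps, data.n_observed
        expected = p * (o - 1) + p * np.linalg.slogdet(M)[1]
        assert model.neg_loglik(w, 0.3) == pytest.approx(expected, rel=1e-10)

    def test_two_observed_nodes_closed_form(self):
        g = ms.SpatialGraph(np.zeros((2, 2)), np.array([[0, 1]]))
        rng = np.random.default_rng(2)
        F = rng.uniform(0.3, 0.7, size=(2, 60))
        data = FrequencyData.from_frequencies(F, [4, 2], [0, 1])
        model = ms.SpatialMigrationModel(g, data)
        w, s2 = np.array([0.8]), 0.15
        # 1x1 contrast projection by hand: c = (1,-1)/sqrt(2)
        m_scalar = 0.5 * (1 / w[0] + s2 * (1 / 4 + 1 / 2))
        Sig = data.Sigma_hat
        s_scalar = 0.5 * (Sig[0, 0] - 2 * Sig[0, 1] + Sig[1, 1])
        expected = data.n_snps * (s_scalar / m_scalar + np.log(m_scalar))
        assert model.neg_loglik(w, s2) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = ms.build_rectangle_lattice(3 + seed % 2, 4, 40.0)
        observed = np.sort(
            rng.choice(g.n_nodes, size=g.n_nodes - 3, replace=False)
        )
        data = small_dataset(g, seed=seed, observed=observed)
        model = ms.SpatialMigrationModel(g, data)
        w = random_weights(rng, g.n_edges)
        fast = model.neg_loglik(w, 0.25)
        oracle = dense_nll(g, w, 0.25, data, model.C)
        assert abs(fast - oracle) / abs(oracle) < 1e-8

    def test_contrast_basis_invariance(self, lattice_4x5):
        data = small_dataset(lattice_4x5, seed=3)
        model = ms.SpatialMigrationModel(lattice_4x5, data)
        w = random_weights(np.random.default_rng(3), lattice_4x5.n_edges)
        ref = model.neg_loglik(w, 0.2)
        # rotate the contrast basis by a random orthogonal matrix
        rng = np.random.default_rng(99)
        Q, _ = np.linalg.qr(rng.standard_normal((model.o - 1, model.o - 1)))
        model.C = Q @ model.C
        model.S = model.C @ data.Sigma_hat @ model.C.T
        rotated = model.neg_loglik(w, 0.2)
        assert abs(ref - rotated) / abs(ref) < 1e-8

    def test_singular_projected_covariance_errors(self):
        from migsurf.model import _chol_contrast

        with pytest.raises(np.linalg.LinAlgError, match="residual-variance"):
            _chol_contrast(np.zeros((3, 3)), 3)


class TestResistancePrior:
    def test_prior_variance_of_differences_is_resistance(self, lattice_4x5):
        """Under f ~ N(mu 1, mu(1-mu) L†), E[(f_k - f_l)^2]/(mu(1-mu)) = r_kl."""
        w = random_weights(np.random.default_rng(5), lattice_4x5.n_edges)
        mu = 0.3
        Cov = mu * (1 - mu) * np.linalg.pinv(
            ms.laplacian(lattice_4x5, w).toarray(), rcond=1e-10
        )
        R = ms.resistance_distance(lattice_4x5, w)
        for k, l in [(0, 1), (0, 19), (5, 12)]:
            second_moment = Cov[k, k] - 2 * Cov[k, l] + Cov[l, l]
            assert abs(second_moment / (mu * (1 - mu)) - R[k, l]) < 1e-10


class TestPenalty:
    def test_constant_weights_give_exact_zero(self, lattice_4x5):
        inc = ms.edge_pair_incidence(lattice_4x5)
        w = np.full(lattice_4x5.n_edges, 2.3)
        assert penalty(w, lam=5.0, alpha=0.7, incidence=inc) == 0.0

    def test_lambda_zero_gives_zero(self, lattice_4x5):
        inc = ms.edge_pair_incidence(lattice_4x5)
        w = random_weights(np.random.default_rng(6), lattice_4x5.n_edges)
        assert penalty(w, 0.0, 1.0, inc) == 0.0

    def test_two_edge_path_hand_computation(self):
        # g(ln 2) = log(e^{ln 2} - 1) = 0;  g(ln(1+e)) = log(e) = 1
        g = ms.SpatialGraph(np.zeros((3, 2)), np.array([[0, 1], [1, 2]]))
        inc = ms.edge_pair_incidence(g)
        w = np.array([np.log(2.0), np.log(1.0 + np.e)])
        assert penalty(w, lam=2.0, alpha=1.0, incidence=inc) == pytest.approx(1.0)

    def test_nonpositive_weight_errors(self, triangle):
        inc = ms.edge_pair_incidence(triangle)
        with pytest.raises(ValueError, match="positive"):
            penalty(np.array([1.0, -0.5, 1.0]), 1.0, 1.0, inc)

    def test_large_weight_regime_is_linear_scale(self, lattice_4x5):
        """For w >> 1/alpha the penalty approaches (lam alpha^2 / 2)||Delta w||^2."""
        inc = ms.edge_pair_incidence(lattice_4x5)
        rng = np.random.default_rng(7)
        alpha, lam = 1.0, 3.0
        w = 50.0 + rng.uniform(0, 5.0, lattice_4x5.n_edges)
        exact = penalty(w, lam, alpha, inc)
        dw = inc @ w
        approx = 0.5 * lam * alpha**2 * float(dw @ dw)
        assert abs(exact - approx) / approx < 0.01

    def test_small_weight_regime_is_log_scale(self, lattice_4x5):
        """For w << 1/alpha the penalty approaches (lam/2)||Delta log w||^2."""
        inc = ms.edge_pair_incidence(lattice_4x5)
        rng = np.random.default_rng(8)
        alpha, lam = 1.0, 3.0
        w = 1e-4 * np.exp(rng.uniform(-1.0, 1.0, lattice_4x5.n_edges))
        exact = penalty(w, lam, alpha, inc)
        dlog = inc @ np.log(w)
        approx = 0.5 * lam * float(dlog @ dlog)
        assert abs(exact - approx) / approx < 0.01

    def test_soft_logmap_stable_at_extremes(self):
        w = np.array([1e-8, 1.0, 500.0])
        g = soft_logmap(w, alpha=1.0)
        assert np.all(np.isfinite(g))
        assert g[0] == pytest.approx(np.log(1e-8), rel=1e-6)
        assert g[2] == pytest.approx(500.0)


class TestGradient:
    def test_penalty_gradient_zero_at_constant_weights(self, lattice_4x5):
        inc = ms.edge_pair_incidence(lattice_4x5)
        w = np.full(lattice_4x5.n_edges, 1.7)
        np.testing.assert_allclose(penalty_grad(w, 2.0, 0.9, inc), 0.0, atol=1e-14)

    @pytest.mark.parametrize("seed", range(3))
    def test_objective_gradient_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed)
        g = ms.build_rectangle_lattice(3, 4, 40.0)
        observed = np.sort(rng.choice(g.n_nodes, size=8, replace=False))
        data = small_dataset(g, seed=seed, observed=observed)
        model = ms.SpatialMigrationModel(g, data)
        w = random_weights(rng, g.n_edges)
        lam, alpha, s2 = 1.3, 0.8, 0.2
        analytic = model.objective_grad(w, s2, lam, alpha)
        numeric = np.empty_like(w)
        for i in range(len(w)):
            h = 1e-6 * max(abs(w[i]), 1.0)
            wp, wm = w.copy(), w.copy()
            wp[i] += h
            wm[i] -= h
            numeric[i] = (
                model.objective(wp, s2, lam, alpha)
                - model.objective(wm, s2, lam, alpha)
            ) / (2 * h)
        rel = np.abs(analytic - numeric) / np.maximum(np.abs(numeric), 1e-6)
        assert rel.max() < 1e-5
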