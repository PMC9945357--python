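"""Graphical lasso, EBIC selection and partial-correlation conversion."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, optimize

from symptomnet import (
    EBICGraphicalLasso,
    correlation_matrix,
    ebic_score,
    estimate_network,
    graphical_lasso,
    lambda_grid,
    precision_to_partial,
)
from symptomnet.glasso import kkt_residual, n_edges


def lbfgs_glasso_oracle(S: np.ndarray, alpha: float) -> np.ndarray:
    """Independent numerical solver of the off-diagonal-penalized objective.

    Splits each off-diagonal precision entry into a difference of nonnegative
    parts so the L1 term becomes smooth-bounded, then runs L-BFGS-B.  Only
    viable for tiny p; used purely as an oracle.
    """
    p = len(S)
    iu = np.triu_indices(p, k=1)
    m = len(iu[0])

    def unpack(z):
        d, a, b = z[:p], z[p : p + m], z[p + m :]
        K = np.zeros((p, p))
        K[iu] = a - b
        K = K + K.T
        K[np.diag_indices(p)] = d
        return K, a, b

    def fun(z):
        K, a, b = unpack(z)
        sign, logdet = np.linalg.slogdet(K)
        if sign <= 0:
            return 1e10
        return -logdet + float(np.sum(S * K)) + 2.0 * alpha * float(np.sum(a + b))

    z0 = np.concatenate([np.ones(p), np.zeros(2 * m)])
    bounds = [(1e-8, None)] * p + [(0.0, None)] * (2 * m)
    res = optimize.minimize(fun, z0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    return unpack(res.x)[0]


class TestCorrelationInput:
    def test_duplicated_column_has_unit_correlation(self):
        x = np.arange(10.0)
        S, n, _ = correlation_matrix(np.column_stack([x, x, -x]))
        assert S[0, 1] == pytest.approx(1.0)
        assert S[0, 2] == pytest.approx(-1.0)
        assert n == 10

    def test_independent_columns_nearly_uncorrelated(self):
        rng = np.random.default_rng(42)
        S, _, _ = correlation_matrix(rng.standard_normal((10000, 2)))
        assert abs(S[0, 1]) < 0.05

    def test_hand_computed_toy(self):
        # deviations give sum(dx*dz)=4, sum(dx^2)=sum(dz^2)=5 -> r = 4/5
        X = pd.DataFrame({"x": [1, 2, 3, 4], "z": [1, 3, 2, 4]})
        S, _, ids = correlation_matrix(X)
        assert S[0, 1] == pytest.approx(0.8)
        assert ids == ["x", "z"]

    def test_constant_column_fatal_names_node(self):
        X = pd.DataFrame({"ok": [1, 2, 3], "flat": [2, 2, 2]})
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(X)

    def test_spearman_is_rank_based(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.exp(x)  # monotone but nonlinear
        S, _, _ = correlation_matrix(np.column_stack([x, y]), method="spearman")
        assert S[0, 1] == pytest.approx(1.0)


class TestLambdaGrid:
    def test_endpoints_forced(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        grid = lambda_grid(S, n_lambda=2, min_ratio=0.01)
        np.testing.assert_allclose(grid, [0.5, 0.005])

    def test_log_uniform_descending(self):
        S = np.array([[1.0, 0.3, 0.1], [0.3, 1.0, -0.6], [0.1, -0.6, 1.0]])
        grid = lambda_grid(S, n_lambda=25)
        assert np.all(np.diff(grid) < 0)
        ratios = grid[1:] / grid[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-10)

    def test_identity_gives_degenerate_grid(self):
        with pytest.warns(UserWarning, match="zero"):
            grid = lambda_grid(np.eye(3))
        np.testing.assert_array_equal(grid, [0.0])


class TestGraphicalLasso:
    def test_unpenalized_limit_is_matrix_inverse(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 4))
        S, _, _ = correlation_matrix(X)
        K, _ = graphical_lasso(S, 0.0)
        np.testing.assert_allclose(K, linalg.inv(S), atol=1e-6)

    def test_full_shrinkage_limit_is_diagonal(self):
        S = np.array([[1.0, 0.4, -0.2], [0.4, 1.0, 0.3], [-0.2, 0.3, 1.0]])
        K, _ = graphical_lasso(S, 0.4)
        np.testing.assert_allclose(K, np.eye(3), atol=1e-5)

    def test_p2_soft_threshold_closed_form(self):
        # off-diagonal of the penalized covariance is sign(s12)*(|s12|-alpha)
        S = np.array([[1.0, 0.6], [0.6, 1.0]])
        K, _ = graphical_lasso(S, 0.2)
        expected = linalg.inv(np.array([[1.0, 0.4], [0.4, 1.0]]))
        np.testing.assert_allclose(K, expected, atol=1e-4)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_optimizer(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 5))
        X = rng.standard_normal((50, p))
        S, _, _ = correlation_matrix(X)
        alpha = float(rng.uniform(0.02, 0.4))
        K, _ = graphical_lasso(S, alpha)
        assert kkt_residual(K, S, alpha) < 1e-4
        K_oracle = lbfgs_glasso_oracle(S, alpha)
        np.testing.assert_allclose(K, K_oracle, atol=1e-3)

    def test_edge_count_monotone_along_path(self):
        rng = np.random.default_rng(3)
        S, _, _ = correlation_matrix(rng.standard_normal((100, 8)))
        counts, partial_ok = [], True
        K = None
        for a in lambda_grid(S, n_lambda=40):
            K, _ = graphical_lasso(S, a, K_init=K)
            counts.append(n_edges(K))
            W = precision_to_partial(K)
            partial_ok &= bool(np.all(np.abs(W) <= 1 + 1e-10))
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert partial_ok

    def test_singular_matrix_rejected_at_zero_penalty(self):
        S = np.ones((2, 2))
        with pytest.raises(ValueError, match="invertible"):
            graphical_lasso(S, 0.0)


class TestEBIC:
    def test_gamma_zero_reduces_to_bic(self):
        S = np.array([[1.0, 0.3], [0.3, 1.0]])
        K, _ = graphical_lasso(S, 0.05)
        n = 100
        sign, logdet = np.linalg.slogdet(K)
        ll = 0.5 * n * (logdet - np.sum(S * K))
        assert ebic_score(K, S, n, gamma=0.0) == pytest.approx(-2 * ll + 1 * np.log(n))

    def test_one_edge_difference_changes_score_by_penalty(self):
        # two precision matrices with identical likelihood terms, one extra edge
        K1 = np.eye(3)
        K2 = K1.copy()
        n, p, gamma = 100, 3, 0.5
        base = ebic_score(K1, np.eye(3), n, gamma)
        K2[0, 1] = K2[1, 0] = 1e-9  # an "edge" with negligible likelihood effect
        delta = ebic_score(K2, np.eye(3), n, gamma) - base
        assert delta == pytest.approx(np.log(n) + 4 * gamma * np.log(p), abs=1e-4)

    def test_hand_specified_p3_formula(self):
        K = np.array([[1.2, -0.3, 0.0], [-0.3, 1.1, 0.2], [0.0, 0.2, 0.9]])
        S = np.array([[1.0, 0.4, 0.1], [0.4, 1.0, -0.2], [0.1, -0.2, 1.0]])
        n, gamma = 100, 0.5
        ll = 0.5 * n * (np.linalg.slogdet(K)[1] - np.trace(S @ K))
        expected = -2 * ll + 2 * np.log(n) + 4 * gamma * 2 * np.log(3)
        assert ebic_score(K, S, n, gamma) == pytest.approx(expected)


class TestPartialConversion:
    def test_2x2_closed_form(self):
        K = np.array([[2.0, -1.0], [-1.0, 2.0]])
        W = precision_to_partial(K)
        assert W[0, 1] == pytest.approx(0.5)
        assert W[0, 0] == 0.0

    def test_diagonal_precision_gives_empty_network(self):
        W = precision_to_partial(np.diag([2.0, 3.0, 0.5]))
        np.testing.assert_array_equal(W, np.zeros((3, 3)))

    def test_matches_residualization_identity(self):
        # partial r12 given 3 from zero-order correlations (regression oracle)
        R = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.6], [0.3, 0.6, 1.0]])
        expected = (R[0, 1] - R[0, 2] * R[1, 2]) / np.sqrt((1 - R[0, 2] ** 2) * (1 - R[1, 2] ** 2))
        W = precision_to_partial(linalg.inv(R))
        assert W[0, 1] == pytest.approx(expected)

    def test_zero_pattern_preserved(self):
        K = np.array([[1.5, 0.0, -0.4], [0.0, 1.2, 0.0], [-0.4, 0.0, 1.1]])
        W = precision_to_partial(K)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_array_equal(W[off] == 0, K[off] == 0)
        assert W[0, 1] == 0 and W[1, 2] == 0 and W[0, 2] != 0


class TestNetworkSelection:
    def test_independent_variables_give_empty_network(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((5000, 4)), columns=list("abcd"))
        net = estimate_network(X)
        assert net.n_edges == 0
        assert net.sparsity == 1.0

    def test_strong_pair_gives_single_positive_edge(self):
        rng = np.random.default_rng(11)
        z = rng.standard_normal(5000)
        x = z
        y = 0.8 * z + np.sqrt(1 - 0.64) * rng.standard_normal(5000)
        net = estimate_network(pd.DataFrame({"x": x, "y": y}))
        assert net.n_edges == 1
        assert net.weights[0, 1] > 0

    def test_ebic_tie_prefers_larger_penalty(self):
        # at the top of the path several penalties give the same (empty) model
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((30, 5)))
        est = EBICGraphicalLasso(n_alphas=30).fit(X)
        path = est.path_
        ties = path[path["ebic"] == path["ebic"].min()]
        assert est.alpha_ == ties["alpha"].max()

    def test_sparsity_bookkeeping_exact(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((200, 6)))
        est = EBICGraphicalLasso(n_alphas=30).fit(X)
        E = n_edges(est.precision_)
        assert est.sparsity_ == 1 - E / (6 * 5 / 2)

    def test_small_sample_warns(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((6, 6)))
        with pytest.warns(UserWarning, match="n ="):
            EBICGraphicalLasso(n_alphas=10, alpha_min_ratio=0.3).fit(X)
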