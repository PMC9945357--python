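"""Sparse Gaussian graphical model estimation via the graphical lasso.

The estimand is the matrix of regularized partial correlations
``w_ij = -k_ij / sqrt(k_ii * k_jj)`` where K is the L1-penalized maximum
likelihood precision matrix of a correlation matrix S::

    minimize_K   -log det K + tr(S K) + alpha * sum_{i != j} |k_ij|

with the penalty on off-diagonal entries only, so the fully shrunk solution
(alpha >= max off-diagonal |s_ij|) is exactly diagonal with k_ii = 1/s_ii.
The penalty alpha is chosen on a log-spaced path by the extended Bayesian
information criterion (EBIC).

The solver is a proximal-gradient iteration (soft-thresholding of the
off-diagonal entries after a gradient step on the smooth part, with a
Barzilai-Borwein trial step and backtracking that maintains positive
definiteness) stopped on the KKT residual of the penalized objective.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Raised when the graphical-lasso iteration does not reach tolerance."""


# ---------------------------------------------------------------------------
# correlation input


def correlation_matrix(
    X, method: str = "pearson", variable_ids: Sequence[str] | None = None
) -> tuple[np.ndarray, int, list[str]]:
    """Product-moment (or rank) correlation matrix of a sample matrix.

    Returns ``(S, n, ids)``.  Requires n >= 3 rows; a constant column is a
    fatal error naming the offending node.
    """
    if isinstance(X, pd.DataFrame):
        ids = list(X.columns.astype(str))
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        ids = list(variable_ids) if variable_ids is not None else [f"V{i + 1}" for i in range(arr.shape[1])]
    if arr.ndim != 2:
        raise ValueError("expected a 2-D participant x node matrix")
    n, p = arr.shape
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    sd = arr.std(axis=0)
    if np.any(sd == 0):
        bad = ids[int(np.argmax(sd == 0))]
        raise ValueError(f"node {bad!r} is constant; correlations undefined")
    if method == "spearman":
        arr = np.apply_along_axis(stats.rankdata, 0, arr)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    S = np.corrcoef(arr, rowvar=False)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S, n, ids


def _check_correlation(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(S, S.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(S), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.max(np.abs(S)) > 1 + 1e-8:
        raise ValueError("correlation entries must lie in [-1, 1]")
    return (S + S.T) / 2.0


# ---------------------------------------------------------------------------
# path construction


def lambda_grid(S: np.ndarray, n_lambda: int = 100, min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced descending penalty grid from lambda_max = max off-diag |s_ij|.

    An all-zero off-diagonal yields the degenerate single-point grid {0} with a
    warning (nothing to shrink).
    """
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    if not 0 < min_ratio < 1:
        raise ValueError("min_ratio must lie in (0, 1)")
    S = _check_correlation(S)
    off = np.abs(S[~np.eye(len(S), dtype=bool)])
    lam_max = float(off.max()) if off.size else 0.0
    if lam_max == 0.0:
        warnings.warn("all off-diagonal correlations are zero; penalty grid is {0}")
        return np.array([0.0])
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambda)


# ---------------------------------------------------------------------------
# solver


def _smooth_objective(K: np.ndarray, S: np.ndarray) -> tuple[float, np.ndarray]:
    """-log det K + tr(SK) and its Cholesky factor; +inf if K not PD."""
    try:
        L = linalg.cholesky(K, lower=True)
    except linalg.LinAlgError:
        return np.inf, None
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return -logdet + float(np.sum(S * K)), L


def kkt_residual(K: np.ndarray, S: np.ndarray, alpha: float) -> float:
    """Max violation of the stationarity conditions of the penalized objective.

    With W = K^-1: diagonal requires w_ii = s_ii; an active off-diagonal entry
    requires s_ij - w_ij + alpha*sign(k_ij) = 0; an inactive one requires
    |s_ij - w_ij| <= alpha.
    """
    W = linalg.inv(K)
    G = S - W
    p = len(S)
    off = ~np.eye(p, dtype=bool)
    active = off & (K != 0.0)
    inactive = off & (K == 0.0)
    res = float(np.max(np.abs(np.diag(G))))
    if active.any():
        res = max(res, float(np.max(np.abs(G[active] + alpha * np.sign(K[active])))))
    if inactive.any():
        res = max(res, float(np.max(np.maximum(np.abs(G[inactive]) - alpha, 0.0))))
    return res


def _soft_offdiag(M: np.ndarray, t: float) -> np.ndarray:
    out = np.sign(M) * np.maximum(np.abs(M) - t, 0.0)
    np.fill_diagonal(out, np.diag(M))
    return out


def graphical_lasso(
    S: np.ndarray,
    alpha: float,
    tol: float = 1e-5,
    max_iter: int = 5000,
    K_init: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Solve the off-diagonal-penalized graphical lasso for one penalty value.

    Returns ``(K, n_iter)`` with K symmetric positive definite and exact zeros
    in the shrunk entries.  ``K_init`` warm-starts the iteration (used along a
    penalty path).  Raises :class:`ConvergenceError` after ``max_iter``
    iterations above tolerance.
    """
    S = _check_correlation(S)
    p = len(S)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0.0:
        try:
            K = linalg.inv(S)
        except linalg.LinAlgError as exc:
            raise ValueError("alpha = 0 requires an invertible correlation matrix") from exc
        return (K + K.T) / 2.0, 0

    if K_init is not None and _smooth_objective(K_init, S)[0] < np.inf:
        K = K_init.copy()
    else:
        K = np.diag(1.0 / np.diag(S)).copy()
    f, _ = _smooth_objective(K, S)
    t = 1.0
    K_prev = None
    G_prev = None
    for it in range(1, max_iter + 1):
        W = linalg.inv(K)
        G = S - W  # gradient of the smooth part
        if kkt_residual(K, S, alpha) < tol:
            return (K + K.T) / 2.0, it - 1
        if K_prev is not None:
            dK = K - K_prev
            dG = G - G_prev
            denom = float(np.sum(dK * dG))
            if denom > 0:
                t = float(np.sum(dK * dK)) / denom
        K_prev, G_prev = K, G
        for _ in range(60):
            K_new = _soft_offdiag(K - t * G, t * alpha)
            K_new = (K_new + K_new.T) / 2.0
            f_new, L = _smooth_objective(K_new, S)
            if L is not None:
                D = K_new - K
                quad = f + float(np.sum(G * D)) + float(np.sum(D * D)) / (2.0 * t)
                if f_new <= quad + 1e-12:
                    break
            t *= 0.5
        else:
            raise ConvergenceError(f"backtracking failed at iteration {it} (alpha={alpha:g})")
        K, f = K_new, f_new
    raise ConvergenceError(
        f"graphical lasso did not converge in {max_iter} iterations "
        f"(alpha={alpha:g}, residual={kkt_residual(K, S, alpha):.3g}, tol={tol:g})"
    )


# ---------------------------------------------------------------------------
# model selection and conversion


def n_edges(K: np.ndarray) -> int:
    """Count of nonzero upper-triangle off-diagonal entries."""
    iu = np.triu_indices_from(K, k=1)
    return int(np.count_nonzero(K[iu]))


def ebic_score(K: np.ndarray, S: np.ndarray, n: int, gamma: float = 0.5) -> float:
    """Extended BIC of a fitted precision matrix.

    ``EBIC = -2 l(K) + E log n + 4 E gamma log p`` with Gaussian log-likelihood
    ``l(K) = (n/2)(log det K - tr(SK))`` and E the number of edges (nonzero
    upper-triangle off-diagonal entries).  gamma = 0 recovers the ordinary BIC.
    """
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise ValueError("precision matrix must be positive definite")
    p = len(S)
    ll = 0.5 * n * (logdet - float(np.sum(S * K)))
    E = n_edges(K)
    return -2.0 * ll + E * np.log(n) + 4.0 * E * gamma * np.log(p)


def precision_to_partial(K: np.ndarray) -> np.ndarray:
    """Partial correlations ``w_ij = -k_ij / sqrt(k_ii k_jj)``, zero diagonal."""
    d = np.sqrt(np.diag(K))
    if np.any(np.diag(K) <= 0):
        raise ValueError("precision diagonal must be positive")
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2.0


# ---------------------------------------------------------------------------
# estimators


class GraphicalLassoEstimator(BaseEstimator):
    """Graphical lasso at one fixed penalty, scikit-learn style.

    Parameters
    ----------
    alpha : float
        L1 penalty on off-diagonal precision entries.
    correlation : {'pearson', 'spearman'}
        Correlation computed from the sample matrix passed to :meth:`fit`.
    tol, max_iter :
        Solver stopping rule (KKT residual) and iteration cap.
    """

    def __init__(self, alpha: float = 0.1, correlation: str = "pearson",
                 tol: float = 1e-5, max_iter: int = 5000):
        self.alpha = alpha
        self.correlation = correlation
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        S, n, ids = correlation_matrix(X, method=self.correlation)
        return self._fit_S(S, n, ids)

    def fit_correlation(self, S, n_samples: int, variable_ids=None):
        S = _check_correlation(S)
        ids = list(variable_ids) if variable_ids is not None else [f"V{i + 1}" for i in range(len(S))]
        return self._fit_S(S, n_samples, ids)

    def _fit_S(self, S, n, ids):
        K, n_iter = graphical_lasso(S, self.alpha, tol=self.tol, max_iter=self.max_iter)
        self.correlation_ = S
        self.n_samples_ = n
        self.variable_ids_ = ids
        self.precision_ = K
        self.n_iter_ = n_iter
        self.partial_corr_ = precision_to_partial(K)
        return self


class EBICGraphicalLasso(BaseEstimator):
    """EBIC-selected graphical lasso over a log-spaced penalty path.

    Fits the off-diagonal-penalized graphical lasso at ``n_alphas`` penalties
    from lambda_max down to ``alpha_min_ratio * lambda_max`` (warm-started),
    scores each by EBIC with hyperparameter ``gamma`` and keeps the minimizer;
    on ties the larger penalty (sparser model) wins.

    Attributes (after ``fit``)
    --------------------------
    partial_corr_ : ndarray of shape (p, p)
        Selected regularized partial-correlation matrix (the network weights).
    precision_ : ndarray
        Selected precision matrix.
    alpha_, ebic_ : float
        Selected penalty and its EBIC.
    path_ : DataFrame with columns (alpha, n_edges, ebic)
    sparsity_ : float
        Fraction of the p(p-1)/2 node pairs with zero weight.
    """

    def __init__(self, gamma: float = 0.5, n_alphas: int = 100,
                 alpha_min_ratio: float = 0.01, correlation: str = "pearson",
                 tol: float = 1e-5, max_iter: int = 5000):
        self.gamma = gamma
        self.n_alphas = n_alphas
        self.alpha_min_ratio = alpha_min_ratio
        self.correlation = correlation
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        S, n, ids = correlation_matrix(X, method=self.correlation)
        return self._fit_S(S, n, ids)

    def fit_correlation(self, S, n_samples: int, variable_ids=None):
        """Fit from a precomputed correlation matrix and its sample count."""
        S = _check_correlation(S)
        ids = list(variable_ids) if variable_ids is not None else [f"V{i + 1}" for i in range(len(S))]
        return self._fit_S(S, n_samples, ids)

    def _fit_S(self, S: np.ndarray, n: int, ids: list[str]):
        p = len(S)
        if n <= p:
            warnings.warn(f"n = {n} <= p = {p}: regularized estimates only, interpret with care")
        alphas = lambda_grid(S, n_lambda=self.n_alphas, min_ratio=self.alpha_min_ratio)
        best = None
        K_warm = None
        path = []
        for a in alphas:
            K, _ = graphical_lasso(S, a, tol=self.tol, max_iter=self.max_iter, K_init=K_warm)
            K_warm = K
            score = ebic_score(K, S, n, gamma=self.gamma)
            path.append((a, n_edges(K), score))
            # strict < keeps the earlier (larger, sparser) alpha on exact ties
            if best is None or score < best[0]:
                best = (score, a, K)
        self.correlation_ = S
        self.n_samples_ = n
        self.variable_ids_ = ids
        self.alphas_ = np.asarray(alphas)
        self.path_ = pd.DataFrame(path, columns=["alpha", "n_edges", "ebic"])
        self.ebic_, self.alpha_, self.precision_ = best
        self.partial_corr_ = precision_to_partial(self.precision_)
        pairs = p * (p - 1) // 2
        self.sparsity_ = 1.0 - n_edges(self.precision_) / pairs if pairs else 0.0
        return self
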