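"""Non-metric multidimensional scaling by majorization (SMACOF).

Embeds a symmetric dissimilarity matrix in the plane so that inter-point
distances reproduce the *rank order* of the dissimilarities, minimizing
Kruskal's stress-1::

    stress_1 = sqrt( sum_{i<j} (d_ij - dhat_ij)^2 / sum_{i<j} d_ij^2 )

where d are configuration distances and dhat the monotone-regressed
disparities.  Each iteration alternates an isotonic regression of distances
on the dissimilarity order (primary tie approach: tied dissimilarities may
keep distinct disparities) with a Guttman transform of the configuration.
Several random starts are run and the lowest-stress solution kept.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator


def _check_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("dissimilarity matrix must have zero diagonal")
    if np.any(D < 0):
        raise ValueError("dissimilarities must be nonnegative")
    return (D + D.T) / 2.0


def _disparities(d: np.ndarray, order: np.ndarray, metric: bool, delta: np.ndarray) -> np.ndarray:
    if metric:
        denom = float(np.sum(delta**2))
        s = float(np.sum(d * delta)) / denom if denom > 0 else 0.0
        return s * delta
    dhat = np.empty_like(d)
    dhat[order] = isotonic_regression(d[order]).x
    # fix total size so the alternation cannot collapse the configuration
    ss = float(np.sum(dhat**2))
    if ss > 0:
        dhat = dhat * np.sqrt(np.sum(d**2) / ss)
    return dhat


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(d**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


class NonmetricMDS(BaseEstimator):
    """2-D (by default) non-metric MDS with Kruskal stress-1, SMACOF iterations.

    Parameters
    ----------
    n_components : int
        Embedding dimension.
    metric : bool
        If True, disparities are an optimally scaled copy of the
        dissimilarities (ratio MDS) instead of a monotone regression.
    n_init : int
        Random starts; the lowest-stress solution is kept.
    max_iter, tol :
        Per-start iteration cap and stopping threshold on the stress-1 drop.
    random_state : int
        Seed for the random starts.

    Attributes
    ----------
    embedding_ : (n, n_components) array, centered at the origin.
    stress_ : float — final Kruskal stress-1 of the best start.
    stress_trace_ : list of per-iteration stress-1 values of the best start.
    n_iter_, best_init_ : iterations used and index of the winning start.
    """

    def __init__(self, n_components: int = 2, metric: bool = False, n_init: int = 10,
                 max_iter: int = 3000, tol: float = 1e-12, random_state: int = 0):
        self.n_components = n_components
        self.metric = metric
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _run_single(self, delta: np.ndarray, X0: np.ndarray):
        n = X0.shape[0]
        X = X0 - X0.mean(axis=0)
        trace = []
        stress_prev = np.inf
        for _ in range(self.max_iter):
            d = pdist(X)
            # primary tie approach: sort by dissimilarity, break ties by the
            # current distances, so tied dissimilarities may stay untied
            order = np.lexsort((d, delta))
            dhat = _disparities(d, order, self.metric, delta)
            stress = _stress1(d, dhat)
            trace.append(stress)
            if stress_prev - stress < self.tol or stress < 1e-15:
                break
            stress_prev = stress
            # Guttman transform
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, dhat / d, 0.0)
            Bmat = -squareform(ratio)
            np.fill_diagonal(Bmat, -Bmat.sum(axis=1))
            X = (Bmat @ X) / n
        return X, trace

    def fit(self, X, y=None):
        """Fit to a square dissimilarity matrix."""
        delta_m = _check_dissimilarity(X)
        n = len(delta_m)
        if n < 3:
            raise ValueError("need at least 3 objects")
        delta = squareform(delta_m, checks=False)
        rng = np.random.default_rng(self.random_state)
        best = None
        for init in range(self.n_init):
            X0 = rng.standard_normal((n, self.n_components))
            Xf, trace = self._run_single(delta, X0)
            if best is None or trace[-1] < best[0]:
                best = (trace[-1], Xf, trace, init)
        if best is None or not np.all(np.isfinite(best[1])):
            raise RuntimeError(f"MDS failed to converge in any start; stress trace {best[2] if best else None}")
        self.stress_, emb, self.stress_trace_, self.best_init_ = best
        self.embedding_ = emb - emb.mean(axis=0)
        self.n_iter_ = len(self.stress_trace_)
        self.dissimilarity_matrix_ = delta_m
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return self.embedding_
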