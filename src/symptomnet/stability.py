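"""Centrality stability under case dropping (subset bootstrap, CS coefficient).

The question answered here: if a fraction q of participants is removed and
the whole network + centrality procedure re-run, how strongly do the subset
centralities still correlate with the full-sample ones?  The CS coefficient
summarizes this as the largest q at which at least 95% of bootstrap
replicates keep that correlation above 0.7.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .centrality import node_centrality
from .instruments import NodeScores
from .network import estimate_network

logger = logging.getLogger(__name__)

#: 0.05, 0.10, ..., 0.75 — the span conventional for case-drop stability plots
DEFAULT_DROP_GRID = tuple(np.round(np.arange(1, 16) * 0.05, 2))


def make_centrality_estimator(
    communities: Mapping[str, str],
    gamma: float = 0.5,
    n_alphas: int = 100,
    alpha_min_ratio: float = 0.01,
    correlation: str = "pearson",
) -> Callable[[pd.DataFrame], pd.DataFrame]:
    """The default re-estimation procedure: EBIC-glasso network + node centrality."""

    def _estimate(X: pd.DataFrame) -> pd.DataFrame:
        net = estimate_network(
            X,
            communities=dict(communities),
            gamma=gamma,
            n_alphas=n_alphas,
            alpha_min_ratio=alpha_min_ratio,
            correlation=correlation,
        )
        return node_centrality(net)

    return _estimate


@dataclass
class StabilityResult:
    """Bootstrap correlation distributions over a case-drop grid."""

    indices: tuple[str, ...]
    drop_proportions: np.ndarray  # ascending, in (0, 1)
    correlations: np.ndarray  # shape (n_indices, n_grid, B); NaN = undefined
    B: int
    seed: int
    n_failures: np.ndarray = field(default=None)  # per grid point

    def to_frame(self) -> pd.DataFrame:
        """Long format: (index, drop_proportion, replicate, correlation)."""
        rows = []
        for a, name in enumerate(self.indices):
            for g, q in enumerate(self.drop_proportions):
                for b in range(self.B):
                    rows.append((name, float(q), b, self.correlations[a, g, b]))
        return pd.DataFrame(rows, columns=["index", "drop_proportion", "replicate", "correlation"])

    def summary(self) -> pd.DataFrame:
        """Per (index, proportion): 2.5% quantile, mean, 97.5% quantile of correlations."""
        rows = []
        for a, name in enumerate(self.indices):
            for g, q in enumerate(self.drop_proportions):
                vals = self.correlations[a, g]
                vals = vals[np.isfinite(vals)]
                if vals.size:
                    rows.append(
                        (name, float(q), np.quantile(vals, 0.025), vals.mean(), np.quantile(vals, 0.975))
                    )
                else:
                    rows.append((name, float(q), np.nan, np.nan, np.nan))
        return pd.DataFrame(rows, columns=["index", "drop_proportion", "q025", "mean", "q975"])


def _safe_corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        return np.nan
    if method == "spearman":
        from scipy.stats import rankdata

        x, y = rankdata(x), rankdata(y)
        if x.std() == 0 or y.std() == 0:
            return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def case_drop_bootstrap(
    scores: NodeScores | pd.DataFrame,
    estimator: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
    grid: Sequence[float] = DEFAULT_DROP_GRID,
    B: int = 1000,
    seed: int = 0,
    correlation: str = "pearson",
) -> StabilityResult:
    """Case-dropping bootstrap of centrality indices.

    For every drop proportion q and replicate b, retain ``ceil((1-q)*n)``
    participants sampled without replacement, re-run the full network +
    centrality estimator, and correlate each index vector with the
    full-sample vector.  Failed fits are recorded as undefined (NaN) and
    counted; a failure rate above 5% at any proportion triggers a warning.
    Identical (data, estimator, grid, B, seed) give a bit-identical result.
    """
    if isinstance(scores, NodeScores):
        X = scores.scores
        if estimator is None:
            estimator = make_centrality_estimator(
                dict(zip(scores.nodes["node_id"], scores.nodes["community"]))
            )
    else:
        X = scores
        if estimator is None:
            estimator = make_centrality_estimator({str(c): "all" for c in X.columns})
    if B < 1:
        raise ValueError("B must be >= 1")
    grid = np.asarray(sorted(float(q) for q in grid))
    if np.any(grid < 0) or np.any(grid >= 1):
        raise ValueError("drop proportions must lie in [0, 1)")
    n, p = X.shape
    min_keep = math.ceil((1 - grid.max()) * n)
    if min_keep < p + 1:
        raise ValueError(
            f"largest drop proportion leaves {min_keep} cases; need at least p+1 = {p + 1}"
        )

    full = estimator(X)
    indices = tuple(full.columns)
    full_vals = {name: full[name].to_numpy(dtype=float) for name in indices}

    rng = np.random.default_rng(seed)
    corrs = np.full((len(indices), len(grid), B), np.nan)
    n_failures = np.zeros(len(grid), dtype=int)
    # per-replicate disconnectedness chatter is not actionable; keep the
    # full-sample warnings above, silence the refits
    cent_logger = logging.getLogger("symptomnet.centrality")
    old_level = cent_logger.level
    cent_logger.setLevel(logging.ERROR)
    for g, q in enumerate(grid):
        keep = math.ceil((1 - q) * n)
        for b in range(B):
            rows = rng.choice(n, size=keep, replace=False) if keep < n else np.arange(n)
            try:
                sub = estimator(X.iloc[np.sort(rows)])
            except Exception as exc:  # failed refit: undefined, counted
                n_failures[g] += 1
                logger.debug("refit failed at q=%.2f replicate %d: %s", q, b, exc)
                continue
            sub = sub.reindex(full.index)
            for a, name in enumerate(indices):
                corrs[a, g, b] = _safe_corr(
                    sub[name].to_numpy(dtype=float), full_vals[name], correlation
                )
        if n_failures[g] > 0.05 * B:
            warnings.warn(
                f"estimator failed on {n_failures[g]}/{B} replicates at drop proportion {q:.2f}"
            )
    cent_logger.setLevel(old_level)
    return StabilityResult(
        indices=indices,
        drop_proportions=grid,
        correlations=corrs,
        B=B,
        seed=seed,
        n_failures=n_failures,
    )


def cs_coefficient(
    result: StabilityResult, threshold: float = 0.7, certainty: float = 0.95
) -> dict[str, float]:
    """Correlation-stability coefficient per index.

    CS is the largest drop proportion q on the grid such that at q *and every
    smaller grid proportion* at least ``certainty`` of the defined bootstrap
    correlations are >= ``threshold`` (the monotone-prefix reading, which
    makes CS unique even when qualification is non-monotone); 0 if already
    the smallest proportion fails.
    """
    out: dict[str, float] = {}
    for a, name in enumerate(result.indices):
        cs = 0.0
        for g, q in enumerate(result.drop_proportions):
            vals = result.correlations[a, g]
            defined = vals[np.isfinite(vals)]
            if defined.size == 0:
                raise ValueError(
                    f"all correlations undefined for index {name!r} at drop proportion {q:.2f}"
                )
            if np.mean(defined >= threshold) >= certainty:
                cs = float(q)
            else:
                break
        out[name] = cs
    return out
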