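"""The estimated partial-correlation network and its exports."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .glasso import EBICGraphicalLasso
from .instruments import NodeScores


@dataclass
class GGMNetwork:
    """A symmetric weighted network of regularized partial correlations.

    ``weights[i, j]`` is the edge between nodes i and j (zero diagonal,
    entries in [-1, 1]); ``communities`` assigns each node to a symptom
    community (e.g. anxiety / depression / DER).
    """

    node_ids: list[str]
    communities: dict[str, str]
    weights: np.ndarray
    alpha_selected: float | None = None
    gamma: float | None = None
    path: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        p = len(self.node_ids)
        if W.shape != (p, p):
            raise ValueError(f"weight matrix shape {W.shape} != ({p}, {p})")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        if not np.allclose(np.diag(W), 0.0, atol=1e-12):
            raise ValueError("weight matrix must have zero diagonal")
        if np.max(np.abs(W)) > 1 + 1e-8:
            raise ValueError("partial correlations must lie in [-1, 1]")
        if set(self.communities) != set(self.node_ids):
            raise ValueError("communities must cover exactly the node set")
        self.weights = (W + W.T) / 2.0

    @property
    def p(self) -> int:
        return len(self.node_ids)

    @property
    def n_potential_edges(self) -> int:
        return self.p * (self.p - 1) // 2

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    @property
    def sparsity(self) -> float:
        """Fraction of node pairs with zero weight."""
        return 1.0 - self.n_edges / self.n_potential_edges

    @property
    def community_vector(self) -> list[str]:
        return [self.communities[v] for v in self.node_ids]

    def edge_list(self) -> pd.DataFrame:
        """Nonzero edges as (node_i, node_j, weight), upper triangle order."""
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = self.weights[i, j]
                if w != 0.0:
                    rows.append({"node_i": self.node_ids[i], "node_j": self.node_ids[j], "weight": w})
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    def weight_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.node_ids, columns=self.node_ids)

    def to_networkx(self):
        import networkx as nx

        G = nx.Graph()
        for v in self.node_ids:
            G.add_node(v, community=self.communities[v])
        for _, row in self.edge_list().iterrows():
            G.add_edge(row["node_i"], row["node_j"], weight=float(row["weight"]))
        return G

    def write_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


def estimate_network(
    scores: NodeScores | pd.DataFrame,
    communities: dict[str, str] | None = None,
    gamma: float = 0.5,
    n_alphas: int = 100,
    alpha_min_ratio: float = 0.01,
    correlation: str = "pearson",
) -> GGMNetwork:
    """Estimate the EBIC-glasso network from a participant x node score matrix.

    ``scores`` is either a :class:`NodeScores` bundle (communities taken from
    its node table) or a plain DataFrame plus an explicit community mapping.
    """
    if isinstance(scores, NodeScores):
        X = scores.scores
        communities = dict(zip(scores.nodes["node_id"], scores.nodes["community"]))
    else:
        X = scores
        if communities is None:
            communities = {str(c): "all" for c in X.columns}
    est = EBICGraphicalLasso(
        gamma=gamma, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio, correlation=correlation
    ).fit(X)
    return GGMNetwork(
        node_ids=est.variable_ids_,
        communities={str(k): str(v) for k, v in communities.items()},
        weights=est.partial_corr_,
        alpha_selected=est.alpha_,
        gamma=gamma,
        path=est.path_,
        meta={
            "n_samples": est.n_samples_,
            "correlation": correlation,
            "n_alphas": n_alphas,
            "alpha_min_ratio": alpha_min_ratio,
            "ebic": est.ebic_,
        },
    )


def network_from_weights(
    weights: np.ndarray | pd.DataFrame, communities: dict[str, str], node_ids=None
) -> GGMNetwork:
    """Wrap a precomputed weight matrix (e.g. a ground-truth network)."""
    if isinstance(weights, pd.DataFrame):
        node_ids = list(weights.columns.astype(str))
        weights = weights.to_numpy(dtype=float)
    elif node_ids is None:
        node_ids = [f"V{i + 1}" for i in range(len(weights))]
    return GGMNetwork(node_ids=list(node_ids), communities=communities, weights=np.asarray(weights, float))
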