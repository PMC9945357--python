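"""Node centrality and bridge centrality for weighted symptom networks.

Conventions of the psychometric-network tradition: an edge of weight w has
length 1/|w| for path-based indices; strength is the sum of absolute incident
weights and expected influence the signed sum; closeness is the reciprocal of
the total shortest-path distance to the other (reachable) nodes; betweenness
counts shortest paths through a node with fractional credit when several
paths tie.  Bridge variants restrict each index to connections toward nodes
outside the node's own community.

Shortest paths and path counts come from an in-package Dijkstra routine so
the plain and bridge indices share one code path; ties in path length are
detected with a small relative tolerance.
"""

from __future__ import annotations

import heapq
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import GGMNetwork

logger = logging.getLogger(__name__)

_TIE_RTOL = 1e-10

CENTRALITY_INDICES = ("strength", "closeness", "betweenness", "expected_influence")
BRIDGE_INDICES = (
    "bridge_strength",
    "bridge_closeness",
    "bridge_betweenness",
    "bridge_expected_influence",
)


def _edge_lengths(weights: np.ndarray) -> np.ndarray:
    """Edge lengths 1/|w| (inf for absent edges)."""
    W = np.abs(np.asarray(weights, dtype=float))
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, np.inf)
    np.fill_diagonal(L, np.inf)
    return L


def _dijkstra_counts(L: np.ndarray, source: int) -> tuple[np.ndarray, np.ndarray]:
    """Distances and shortest-path counts from one source (tie-tolerant)."""
    p = L.shape[0]
    dist = np.full(p, np.inf)
    sigma = np.zeros(p)
    dist[source] = 0.0
    sigma[source] = 1.0
    done = np.zeros(p, dtype=bool)
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        row = L[u]
        for v in np.flatnonzero(np.isfinite(row)):
            if done[v]:
                continue
            nd = d + row[v]
            tol = _TIE_RTOL * (1.0 + abs(dist[v]) if np.isfinite(dist[v]) else 1.0)
            if nd < dist[v] - tol:
                dist[v] = nd
                sigma[v] = sigma[u]
                heapq.heappush(heap, (nd, v))
            elif abs(nd - dist[v]) <= tol:
                sigma[v] += sigma[u]
    return dist, sigma


def _all_pairs(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    L = _edge_lengths(weights)
    p = L.shape[0]
    D = np.empty((p, p))
    Sigma = np.empty((p, p))
    for s in range(p):
        D[s], Sigma[s] = _dijkstra_counts(L, s)
    return D, Sigma


def shortest_path_lengths(net: GGMNetwork | np.ndarray) -> pd.DataFrame:
    """All-pairs shortest-path distances with edge lengths 1/|w| (inf when unreachable)."""
    if isinstance(net, GGMNetwork):
        D, _ = _all_pairs(net.weights)
        return pd.DataFrame(D, index=net.node_ids, columns=net.node_ids)
    D, _ = _all_pairs(np.asarray(net, dtype=float))
    return pd.DataFrame(D)


def _betweenness(D: np.ndarray, Sigma: np.ndarray, pair_mask: np.ndarray) -> np.ndarray:
    """Fractional-credit betweenness over the unordered pairs in ``pair_mask``."""
    p = D.shape[0]
    iu = np.triu(np.ones((p, p), dtype=bool), k=1)
    out = np.zeros(p)
    finite = np.isfinite(D)
    for i in range(p):
        through = D[:, i][:, None] + D[i, :][None, :]
        with np.errstate(invalid="ignore"):
            on_path = np.abs(through - D) <= _TIE_RTOL * (1.0 + np.where(finite, D, 0.0))
        mask = pair_mask & iu & finite & on_path & np.isfinite(through)
        mask[i, :] = False
        mask[:, i] = False
        if mask.any():
            contrib = Sigma[:, i][:, None] * Sigma[i, :][None, :]
            out[i] = float(np.sum(contrib[mask] / Sigma[mask]))
    return out


def node_centrality(net: GGMNetwork) -> pd.DataFrame:
    """Raw strength, closeness, betweenness and expected influence per node.

    Closeness sums distances over reachable peers only (0 for an isolated
    node, with a disconnectedness warning when any pair is unreachable).
    """
    W = net.weights
    p = net.p
    D, Sigma = _all_pairs(W)
    strength = np.abs(W).sum(axis=1)
    expected_influence = W.sum(axis=1)
    offdiag = ~np.eye(p, dtype=bool)
    if not np.all(np.isfinite(D[offdiag])):
        logger.warning("network is disconnected; closeness computed over reachable peers only")
    closeness = np.zeros(p)
    for i in range(p):
        d = D[i, offdiag[i]]
        reach = d[np.isfinite(d)]
        closeness[i] = 1.0 / reach.sum() if reach.size and reach.sum() > 0 else 0.0
    betweenness = _betweenness(D, Sigma, np.ones((p, p), dtype=bool))
    return pd.DataFrame(
        {
            "strength": strength,
            "closeness": closeness,
            "betweenness": betweenness,
            "expected_influence": expected_influence,
        },
        index=pd.Index(net.node_ids, name="node"),
    )


def scale_relative_to_max(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each index by its maximum absolute value across nodes.

    A column whose maximum absolute value is zero is left at zero (warned).
    """
    out = table.copy().astype(float)
    for col in out.columns:
        m = out[col].abs().max()
        if m == 0:
            logger.warning("index %r is identically zero; scaled values set to 0", col)
        else:
            out[col] = out[col] / m
    return out


def bridge_centrality(
    net: GGMNetwork, partition: Mapping[str, str] | Sequence[str] | None = None
) -> pd.DataFrame:
    """Bridge strength, closeness, betweenness and expected influence.

    Bridge strength/expected influence sum |w| (resp. w) over edges leaving
    the node's community; bridge closeness is the reciprocal of the summed
    distance to all other-community nodes (0 if any is unreachable, logged);
    bridge betweenness counts shortest paths between node pairs from two
    different communities passing through the node.
    """
    if partition is None:
        comm = np.asarray(net.community_vector)
    elif isinstance(partition, Mapping):
        comm = np.asarray([partition[v] for v in net.node_ids])
    else:
        comm = np.asarray(list(partition))
        if len(comm) != net.p:
            raise ValueError("partition length must match the node count")
    if len(set(comm)) < 2:
        raise ValueError("bridge indices undefined for a single community")

    W = net.weights
    p = net.p
    other = comm[:, None] != comm[None, :]
    bridge_strength = (np.abs(W) * other).sum(axis=1)
    bridge_ei = (W * other).sum(axis=1)

    D, Sigma = _all_pairs(W)
    bridge_closeness = np.zeros(p)
    for i in range(p):
        d = D[i, other[i]]
        if d.size == 0:
            continue
        if not np.all(np.isfinite(d)):
            logger.warning(
                "node %s cannot reach every other-community node; bridge closeness set to 0",
                net.node_ids[i],
            )
            continue
        bridge_closeness[i] = 1.0 / d.sum() if d.sum() > 0 else 0.0
    bridge_betweenness = _betweenness(D, Sigma, other)

    return pd.DataFrame(
        {
            "bridge_strength": bridge_strength,
            "bridge_closeness": bridge_closeness,
            "bridge_betweenness": bridge_betweenness,
            "bridge_expected_influence": bridge_ei,
            "community": comm,
        },
        index=pd.Index(net.node_ids, name="node"),
    )


def centrality_table(net: GGMNetwork) -> pd.DataFrame:
    """Raw and max-scaled centralities, ordered by scaled expected influence."""
    raw = node_centrality(net)
    scaled = scale_relative_to_max(raw).add_suffix("_scaled")
    out = pd.concat([raw, scaled], axis=1)
    out.insert(0, "community", net.community_vector)
    return out.sort_values("expected_influence_scaled", ascending=False)


def bridge_table(net: GGMNetwork, partition=None) -> pd.DataFrame:
    """Raw and max-scaled bridge centralities, ordered by scaled bridge expected influence."""
    raw = bridge_centrality(net, partition)
    comm = raw.pop("community")
    scaled = scale_relative_to_max(raw).add_suffix("_scaled")
    out = pd.concat([raw, scaled], axis=1)
    out.insert(0, "community", comm)
    return out.sort_values("bridge_expected_influence_scaled", ascending=False)
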