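"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from symptomnet import (
    GGMNetwork,
    InstrumentDefinition,
    benchmark_config,
    estimate_network,
    generate_true_network,
    network_from_weights,
    sample_responses,
)
from symptomnet.instruments import Item

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")

_PATH_TOL = 1e-9


# ---------------------------------------------------------------------------
# brute-force path oracles (exhaustive enumeration; only for tiny graphs)


def brute_shortest_paths(weights: np.ndarray, s: int, t: int):
    """All simple s-t paths of minimal 1/|w| length: (min_length, list of paths)."""
    p = len(weights)
    best = (np.inf, [])
    stack = [(s, [s], 0.0)]
    while stack:
        node, path, length = stack.pop()
        if node == t:
            if length < best[0] - _PATH_TOL:
                best = (length, [path])
            elif abs(length - best[0]) <= _PATH_TOL:
                best = (best[0], best[1] + [path])
            continue
        for v in range(p):
            if weights[node, v] != 0 and v not in path:
                stack.append((v, path + [v], length + 1.0 / abs(weights[node, v])))
    return best


def brute_distance_matrix(weights: np.ndarray) -> np.ndarray:
    p = len(weights)
    D = np.zeros((p, p))
    for s in range(p):
        for t in range(p):
            if s != t:
                D[s, t] = brute_shortest_paths(weights, s, t)[0]
    return D


def brute_betweenness(weights: np.ndarray, pair_filter=None) -> np.ndarray:
    """Fractional-credit betweenness by path enumeration.

    ``pair_filter(s, t)`` restricts the unordered endpoint pairs (used for
    the bridge variant); default counts every pair.
    """
    p = len(weights)
    out = np.zeros(p)
    for s, t in itertools.combinations(range(p), 2):
        if pair_filter is not None and not pair_filter(s, t):
            continue
        length, paths = brute_shortest_paths(weights, s, t)
        if not np.isfinite(length) or not paths:
            continue
        for i in range(p):
            if i in (s, t):
                continue
            out[i] += sum(i in path for path in paths) / len(paths)
    return out


def random_weighted_graph(seed: int, p: int | None = None, edge_prob: float = 0.5) -> np.ndarray:
    """Random signed weight matrix for oracle comparisons."""
    rng = np.random.default_rng(seed)
    if p is None:
        p = int(rng.integers(3, 8))
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < edge_prob:
                W[i, j] = rng.uniform(0.1, 0.9) * rng.choice([-1.0, 1.0])
    return W + W.T


def as_network(W: np.ndarray, communities=None) -> GGMNetwork:
    p = len(W)
    ids = [f"V{i + 1}" for i in range(p)]
    if communities is None:
        comm = {v: "all" for v in ids}
    elif isinstance(communities, dict):
        comm = communities
    else:
        comm = dict(zip(ids, communities))
    return network_from_weights(W, comm, node_ids=ids)


# ---------------------------------------------------------------------------
# small instrument fixtures


@pytest.fixture
def toy_instruments() -> list[InstrumentDefinition]:
    """A 2-item per-item scale (0-3) and a 4-item two-subscale scale (1-5)."""
    sym = InstrumentDefinition(
        name="SYM",
        items=[Item("s1", "first symptom", 0, 3, node="S1"), Item("s2", "second symptom", 0, 3, node="S2")],
        subscales={"sym": ["s1", "s2"]},
        reverse=frozenset({"s2"}),
        node_granularity="per_item",
        communities={"sym": "symptoms"},
    )
    reg = InstrumentDefinition(
        name="REG",
        items=[Item(f"r{i}", f"regulation item {i}", 1, 5) for i in (1, 2, 3, 4)],
        subscales={"A": ["r1", "r2"], "B": ["r3", "r4"]},
        reverse=frozenset({"r3"}),
        node_granularity="per_subscale",
        subscale_nodes={"A": "RA", "B": "RB"},
        communities={"A": "regulation", "B": "regulation"},
    )
    return [sym, reg]


@pytest.fixture
def toy_csv(tmp_path, toy_instruments):
    def _write(rows: list[dict], name: str = "toy.csv"):
        path = tmp_path / name
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    return _write


# ---------------------------------------------------------------------------
# the (expensive) recovery benchmark, shared across tests in one session


@pytest.fixture(scope="session")
def benchmark():
    """Planted-truth benchmark: 7/7/6 communities, 4 bridge edges, n=2000."""
    cfg = benchmark_config(seed=12345, n=2000)
    truth = generate_true_network(cfg)
    scores, _ = sample_responses(truth, cfg)
    net = estimate_network(scores, gamma=0.5)
    return cfg, truth, scores, net
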