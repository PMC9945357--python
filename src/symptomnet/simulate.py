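"""Synthetic questionnaire data with a known partial-correlation network.

The generator plants a sparse Gaussian graphical model over 20 node
variables in three communities (7 anxiety-like, 7 depression-like, 6 emotion
-regulation components), with a handful of designated bridge edges crossing
community boundaries, draws multivariate-normal participant scores from the
implied correlation matrix, and optionally discretizes them onto Likert
scales (4 levels for the HADS-like symptom nodes).  Because the true network
is known, estimation can be scored for edge recovery, weight accuracy and
centrality-rank recovery.

Truth is parameterized directly in partial-correlation space: a candidate
partial matrix is drawn, converted to a unit-diagonal precision matrix
(k_ij = -p_ij), and its off-diagonals shrunk proportionally until the
smallest eigenvalue reaches 0.05, so the recorded truth is exactly the
estimand of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .glasso import precision_to_partial
from .instruments import NodeScores
from .network import GGMNetwork

ANXIETY_NODES = ("Tns", "Afr", "Wrr", "Rlx", "Btt", "Rst", "Pnc")
DEPRESSION_NODES = ("Enj", "Fnn", "Chr", "Slw", "App", "Frw", "Bok")
DER_NODES = ("NNC", "GOL", "IMP", "AWR", "STR", "CLR")
DEFAULT_NODE_IDS = ANXIETY_NODES + DEPRESSION_NODES + DER_NODES

#: cross-community edges always present in the planted truth: Rlx-Chr and
#: Wrr-Slw tie the two symptom communities together, STR-Wrr and STR-Chr
#: make the strategies component the conduit from emotion regulation to both
DEFAULT_BRIDGE_EDGES = ((3, 9), (2, 10), (18, 2), (18, 9))

MIN_EIGENVALUE = 0.05


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults emulate a clinical questionnaire
    sample of the shape this pipeline targets (209 participants, 20 nodes
    in communities of 7/7/6)."""

    community_sizes: tuple[int, ...] = (7, 7, 6)
    community_names: tuple[str, ...] = ("anxiety", "depression", "DER")
    p_within: float = 0.3
    p_between: float = 0.03
    bridge_edges: tuple[tuple[int, int], ...] = DEFAULT_BRIDGE_EDGES
    weight_range: tuple[float, float] = (0.2, 0.45)
    negative_prob: float = 0.25
    n: int = 209
    #: Likert levels per community; None = continuous scores
    likert_levels: tuple[int | None, ...] = (4, 4, None)
    node_ids: tuple[str, ...] | None = DEFAULT_NODE_IDS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_within <= 1 and 0 <= self.p_between <= 1):
            raise ValueError("edge probabilities must lie in [0, 1]")
        lo, hi = self.weight_range
        if not 0 <= lo <= hi:
            raise ValueError("weight_range must satisfy 0 <= low <= high")
        if len(self.community_sizes) != len(self.community_names):
            raise ValueError("community_sizes and community_names must align")
        if len(self.likert_levels) != len(self.community_sizes):
            raise ValueError("one likert_levels entry per community")
        if self.node_ids is not None and len(self.node_ids) != self.p:
            raise ValueError("node_ids length must equal the node count")
        comm = self.community_index
        for i, j in self.bridge_edges:
            if not (0 <= i < self.p and 0 <= j < self.p) or i == j:
                raise ValueError(f"invalid bridge edge ({i}, {j})")
            if comm[i] == comm[j]:
                raise ValueError(f"bridge edge ({i}, {j}) does not cross communities")

    @property
    def p(self) -> int:
        return int(sum(self.community_sizes))

    @property
    def community_index(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.community_sizes)), self.community_sizes)

    @property
    def communities(self) -> dict[str, str]:
        ids = self.node_ids or tuple(f"V{i + 1}" for i in range(self.p))
        names = np.asarray(self.community_names)[self.community_index]
        return dict(zip(ids, names))


@dataclass
class GroundTruth:
    """The planted network: true partials, adjacency, precision and correlation."""

    partial: np.ndarray
    adjacency: np.ndarray
    precision: np.ndarray
    correlation: np.ndarray
    config: SyntheticConfig = field(repr=False, default=None)

    @property
    def node_ids(self) -> tuple[str, ...]:
        return self.config.node_ids or tuple(f"V{i + 1}" for i in range(len(self.partial)))

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices_from(self.adjacency, k=1)
        return int(self.adjacency[iu].sum())

    def as_network(self) -> GGMNetwork:
        return GGMNetwork(
            node_ids=list(self.node_ids), communities=self.config.communities, weights=self.partial
        )


def generate_true_network(config: SyntheticConfig) -> GroundTruth:
    """Sample a sparse positive-definite partial-correlation truth."""
    rng = np.random.default_rng(config.seed)
    p = config.p
    comm = config.community_index
    A = np.zeros((p, p), dtype=bool)
    for i in range(p):
        for j in range(i + 1, p):
            prob = config.p_within if comm[i] == comm[j] else config.p_between
            A[i, j] = rng.random() < prob
    for i, j in config.bridge_edges:
        A[min(i, j), max(i, j)] = True
    A = A | A.T

    lo, hi = config.weight_range
    mag = rng.uniform(lo, hi, size=(p, p))
    sign = np.where(rng.random((p, p)) < config.negative_prob, -1.0, 1.0)
    P = np.triu(mag * sign, k=1)
    P = (P + P.T) * A

    shrink = 1.0
    for _ in range(200):
        K = np.eye(p) - shrink * P
        if np.linalg.eigvalsh(K).min() >= MIN_EIGENVALUE:
            break
        shrink *= 0.95
    else:
        raise RuntimeError("could not shrink the partial matrix to a positive definite precision")
    partial = shrink * P
    K = np.eye(p) - partial
    cov = linalg.inv(K)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    assert np.allclose(precision_to_partial(K), partial, atol=1e-10)
    return GroundTruth(partial=partial, adjacency=A, precision=K, correlation=corr, config=config)


def _discretize(z: np.ndarray, levels: int) -> np.ndarray:
    """Equal-probability thresholds on the standard-normal scale -> 0..levels-1."""
    cuts = stats.norm.ppf(np.arange(1, levels) / levels)
    return np.searchsorted(cuts, z).astype(float)


def sample_responses(
    truth: GroundTruth, config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[NodeScores, GroundTruth]:
    """Draw n participant score vectors from the truth-implied correlations.

    Likert communities are discretized by standard-normal quantile thresholds
    into the configured number of levels; continuous communities pass
    through.  ``seed`` overrides the config-derived sampling seed (used for
    replicate draws from one truth).
    """
    config = config or truth.config
    rng = np.random.default_rng((config.seed, 104729) if seed is None else seed)
    p = config.p
    L = linalg.cholesky(truth.correlation, lower=True)
    Z = rng.standard_normal((config.n, p)) @ L.T
    comm = config.community_index
    X = Z.copy()
    for c, levels in enumerate(config.likert_levels):
        if levels is not None:
            cols = comm == c
            X[:, cols] = _discretize(Z[:, cols], int(levels))
    ids = list(truth.node_ids)
    scores = pd.DataFrame(
        X, columns=ids, index=pd.Index([f"P{i + 1}" for i in range(config.n)], name="participant_id")
    )
    communities = config.communities
    nodes = pd.DataFrame(
        {"node_id": ids, "label": ids, "community": [communities[v] for v in ids]}
    )
    return NodeScores(scores=scores, nodes=nodes), truth


def sample_item_table(
    truth: GroundTruth,
    defs: Sequence | None = None,
    loading: float = 0.7,
    demographic_missing: float = 0.03,
    seed: int | None = None,
) -> pd.DataFrame:
    """Item-level mode: emit the raw CSV schema the scoring front-end reads.

    HADS-like nodes become single items (0-3); each emotion-regulation node
    spawns its subscale's items as ``loading * node + noise`` discretized to
    1-5.  Reverse-coded items are stored un-corrected so that scoring with
    the shipped definitions reproduces the latent node structure.  A small
    block of demographics with some missing values is appended.
    """
    from .instruments import default_instruments

    config = truth.config
    defs = list(defs) if defs is not None else default_instruments()
    hads, ders = defs[0], defs[1]
    rng = np.random.default_rng((config.seed, 224737) if seed is None else seed)
    scores, _ = sample_responses(truth, config, seed=int(rng.integers(2**31)))
    latent, _ = sample_responses(
        GroundTruth(truth.partial, truth.adjacency, truth.precision, truth.correlation,
                    SyntheticConfig(**{**config.__dict__, "likert_levels": (None,) * len(config.community_sizes)})),
        seed=int(rng.integers(2**31)),
    )
    Z = latent.scores
    n = len(Z)
    out = {}

    # HADS: one item per node, community order anxiety then depression
    node_of_item = {it.node or it.id: it for it in hads.items}
    for node in ANXIETY_NODES + DEPRESSION_NODES:
        it = node_of_item[node]
        vals = _discretize(Z[node].to_numpy(), 4)
        if it.id in hads.reverse:
            vals = (it.min + it.max) - vals
        out[it.id] = vals.astype(int)

    # DERS: subscale node + item noise, 5 levels
    node_of_sub = {ders.subscale_nodes.get(s, s): s for s in ders.subscales}
    for node in DER_NODES:
        members = ders.subscales[node_of_sub[node]]
        z = Z[node].to_numpy()
        z = (z - z.mean()) / z.std()
        for iid in members:
            item_latent = loading * z + np.sqrt(1 - loading**2) * rng.standard_normal(n)
            vals = _discretize(item_latent, 5) + 1  # 1..5
            it = ders.item_map[iid]
            if iid in ders.reverse:
                vals = (it.min + it.max) - vals
            out[iid] = vals.astype(int)

    table = pd.DataFrame(out, index=Z.index)
    # column order: instrument definition order
    table = table[[it.id for it in hads.items] + [it.id for it in ders.items]]
    demo = pd.DataFrame(
        {
            "sex": rng.choice(["female", "male"], size=n),
            "age": rng.integers(12, 19, size=n),
            "family_structure": rng.choice(["nuclear", "single_parent", "extended"], size=n, p=[0.6, 0.25, 0.15]),
            "location": rng.choice(["urban", "rural"], size=n),
            "economic_status": rng.choice(["low", "middle", "high"], size=n, p=[0.3, 0.55, 0.15]),
        },
        index=Z.index,
    )
    mask = rng.random(demo.shape) < demographic_missing
    demo = demo.mask(mask)
    return pd.concat([table, demo], axis=1).reset_index()


def recovery_metrics(estimated: GGMNetwork, truth: GroundTruth) -> dict[str, float]:
    """Edge-recovery scores of an estimate against the planted truth.

    sensitivity = recovered true edges / true edges; specificity =
    correctly-absent / truly-absent; weight_correlation = product-moment
    correlation of estimated vs true weights over the union of true and
    estimated edges.  Undefined ratios are returned as NaN.
    """
    if list(estimated.node_ids) != list(truth.node_ids):
        raise ValueError("estimated and true networks must share the node set")
    W = estimated.weights
    iu = np.triu_indices_from(W, k=1)
    est_edge = W[iu] != 0
    true_edge = truth.adjacency[iu]
    tp = int(np.sum(est_edge & true_edge))
    tn = int(np.sum(~est_edge & ~true_edge))
    n_true = int(true_edge.sum())
    n_absent = int((~true_edge).sum())
    union = est_edge | true_edge
    w_est, w_true = W[iu][union], truth.partial[iu][union]
    if union.sum() >= 2 and w_est.std() > 0 and w_true.std() > 0:
        wc = float(np.corrcoef(w_est, w_true)[0, 1])
    elif union.sum() >= 1 and np.allclose(w_est, w_true):
        wc = 1.0
    else:
        wc = np.nan
    return {
        "sensitivity": tp / n_true if n_true else np.nan,
        "specificity": tn / n_absent if n_absent else np.nan,
        "weight_correlation": wc,
    }


def benchmark_config(seed: int = 0, n: int = 2000) -> SyntheticConfig:
    """The continuous-data recovery benchmark configuration."""
    return SyntheticConfig(
        n=n, likert_levels=(None, None, None), weight_range=(0.15, 0.35), seed=seed
    )
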