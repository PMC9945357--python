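"""Node placement: grouped-circle layout and MDS layout.

The grouped-circle layout is deterministic: community centers sit equally
spaced on a master circle of radius 1 (first center at 90 degrees), and each
community's nodes sit equally spaced on a sub-circle of radius 0.45 around
their center, in the node order given.  The MDS layout embeds the network so
that strongly associated nodes appear close together: dissimilarities are
``max_kl |w_kl| - |w_ij|`` (so absent edges get the maximal dissimilarity)
and the embedding minimizes Kruskal stress-1 (see :mod:`symptomnet.mds`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mds import NonmetricMDS
from .network import GGMNetwork

MASTER_RADIUS = 1.0
SUB_RADIUS = 0.45


@dataclass
class LayoutCoordinates:
    """Planar node coordinates plus layout metadata."""

    coords: pd.DataFrame  # columns: node, x, y
    layout_kind: str  # "circle_grouped" or "mds"
    stress_1: float | None = None
    n_iter: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        xy = self.coords[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("layout produced non-finite coordinates")

    def frame(self) -> pd.DataFrame:
        out = self.coords.copy()
        out["layout_kind"] = self.layout_kind
        return out


def _separate_ties(xy: np.ndarray) -> np.ndarray:
    """Deterministically nudge exactly coincident points apart."""
    scale = max(np.abs(xy).max(), 1.0)
    for i in range(len(xy)):
        for j in range(i + 1, len(xy)):
            if np.all(xy[i] == xy[j]):
                ang = 2 * np.pi * (j / len(xy))
                xy[j] = xy[j] + 1e-9 * scale * np.array([np.cos(ang), np.sin(ang)])
    return xy


def circular_group_layout(
    nodes: Sequence[str], partition: Mapping[str, str] | Sequence[str]
) -> LayoutCoordinates:
    """Grouped-circle layout; repeated invocation gives identical coordinates."""
    nodes = list(nodes)
    if isinstance(partition, Mapping):
        comm = [partition[v] for v in nodes]
    else:
        comm = list(partition)
        if len(comm) != len(nodes):
            raise ValueError("partition length must match node count")
    groups: dict[str, list[str]] = {}
    for v, c in zip(nodes, comm):
        groups.setdefault(c, []).append(v)
    m = len(groups)
    rows = []
    for k, (c, members) in enumerate(groups.items()):
        theta = np.pi / 2 + 2 * np.pi * k / m  # first community center at 90 degrees
        cx, cy = MASTER_RADIUS * np.cos(theta), MASTER_RADIUS * np.sin(theta)
        for s, v in enumerate(members):
            phi = 2 * np.pi * s / len(members)  # first node at the 0-degree point
            rows.append({"node": v, "x": cx + SUB_RADIUS * np.cos(phi), "y": cy + SUB_RADIUS * np.sin(phi)})
    coords = pd.DataFrame(rows).set_index("node").loc[nodes].reset_index()
    xy = _separate_ties(coords[["x", "y"]].to_numpy())
    coords[["x", "y"]] = xy
    return LayoutCoordinates(coords=coords, layout_kind="circle_grouped")


def weight_dissimilarities(net: GGMNetwork) -> np.ndarray:
    """``delta_ij = max_kl |w_kl| - |w_ij|``; bounded, zero on the diagonal."""
    A = np.abs(net.weights)
    delta = A.max() - A
    np.fill_diagonal(delta, 0.0)
    return delta


def mds_layout(
    net: GGMNetwork,
    seed: int = 0,
    n_init: int = 10,
    metric: bool = False,
    dissimilarity: np.ndarray | None = None,
) -> LayoutCoordinates:
    """Non-metric MDS layout of the network.

    ``dissimilarity`` overrides the default edge-weight transform (e.g. to
    use zero-order correlations instead).
    """
    if net.p < 3:
        raise ValueError("MDS layout needs at least 3 nodes")
    delta = weight_dissimilarities(net) if dissimilarity is None else np.asarray(dissimilarity, float)
    model = NonmetricMDS(n_components=2, metric=metric, n_init=n_init, random_state=seed)
    xy = model.fit_transform(delta)
    scale = np.abs(xy).max()
    if scale > 0:
        xy = xy / scale  # into the unit square; stress-1 is scale-invariant
    xy = _separate_ties(xy)
    coords = pd.DataFrame({"node": net.node_ids, "x": xy[:, 0], "y": xy[:, 1]})
    return LayoutCoordinates(
        coords=coords,
        layout_kind="mds",
        stress_1=model.stress_,
        n_iter=model.n_iter_,
        meta={
            "seed": seed,
            "n_init": n_init,
            "metric": metric,
            "best_init": model.best_init_,
            "transform": "max_abs_weight_minus_abs_weight" if dissimilarity is None else "custom",
        },
    )
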