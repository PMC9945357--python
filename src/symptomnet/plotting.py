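"""Minimal static figure writers (network, centrality profiles, stability bands)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .layout import LayoutCoordinates
from .network import GGMNetwork

_COMMUNITY_COLORS = ("#4daf4a", "#377eb8", "#e41a1c", "#984ea3", "#ff7f00")


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_network(net: GGMNetwork, layout: LayoutCoordinates, path: str | Path) -> None:
    """Edges green (positive) / red (negative), width by |weight|."""
    plt = _mpl()
    coords = layout.coords.set_index("node")
    fig, ax = plt.subplots(figsize=(6, 6))
    wmax = max(np.abs(net.weights).max(), 1e-12)
    for _, row in net.edge_list().iterrows():
        x = [coords.loc[row["node_i"], "x"], coords.loc[row["node_j"], "x"]]
        y = [coords.loc[row["node_i"], "y"], coords.loc[row["node_j"], "y"]]
        w = row["weight"]
        ax.plot(x, y, color="#2ca02c" if w > 0 else "#d62728", lw=3 * abs(w) / wmax, zorder=1)
    comms = list(dict.fromkeys(net.community_vector))
    cmap = {c: _COMMUNITY_COLORS[i % len(_COMMUNITY_COLORS)] for i, c in enumerate(comms)}
    for v in net.node_ids:
        x, y = coords.loc[v, "x"], coords.loc[v, "y"]
        ax.scatter([x], [y], s=420, color=cmap[net.communities[v]], edgecolor="k", zorder=2)
        ax.annotate(v, (x, y), ha="center", va="center", fontsize=7, zorder=3)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"{layout.layout_kind} layout")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_centrality(table: pd.DataFrame, path: str | Path) -> None:
    """Scaled centrality profiles, nodes ordered by expected influence."""
    plt = _mpl()
    cols = [c for c in table.columns if c.endswith("_scaled")]
    fig, axes = plt.subplots(1, len(cols), figsize=(3 * len(cols), 6), sharey=True)
    for ax, col in zip(np.atleast_1d(axes), cols):
        ax.plot(table[col].to_numpy(), range(len(table)), "o-", ms=3)
        ax.set_yticks(range(len(table)))
        ax.set_yticklabels(table.index)
        ax.invert_yaxis()
        ax.set_title(col.replace("_scaled", ""), fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_stability(summary: pd.DataFrame, path: str | Path) -> None:
    """Mean subset-to-full correlations with 2.5-97.5% bands per index."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, block in summary.groupby("index"):
        block = block.sort_values("drop_proportion")
        ax.plot(block["drop_proportion"], block["mean"], label=name)
        ax.fill_between(block["drop_proportion"], block["q025"], block["q975"], alpha=0.2)
    ax.axhline(0.7, color="gray", ls="--", lw=0.8)
    ax.set_xlabel("proportion of cases dropped")
    ax.set_ylabel("correlation with full sample")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
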