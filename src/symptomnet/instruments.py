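"""Instrument definitions, response loading and node scoring.

A questionnaire instrument is described by a small YAML document (items with
response ranges, subscale membership, reverse-coded items, and whether each
item or each subscale becomes one network node).  Ready-made definitions for
the HADS (14 items, 0-3, one node per item) and the DERS (36 items, 1-5, six
subscale-sum nodes) ship with the package and are editable copies, not
hard-coded tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

DEMOGRAPHIC_FIELDS = ("sex", "age", "family_structure", "location", "economic_status")


@dataclass(frozen=True)
class Item:
    """One questionnaire item with its admissible response range."""

    id: str
    label: str
    min: int
    max: int
    node: str | None = None  # short node id for per-item instruments

    def reverse(self, value):
        """Reverse-correct a response: r -> (min + max) - r (an involution)."""
        return (self.min + self.max) - value


@dataclass
class InstrumentDefinition:
    """A scored questionnaire: items, subscales, reverse list, node granularity."""

    name: str
    items: list[Item]
    subscales: dict[str, list[str]]
    reverse: frozenset[str] = frozenset()
    node_granularity: str = "per_subscale"  # or "per_item"
    subscale_nodes: dict[str, str] = field(default_factory=dict)
    communities: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.node_granularity not in ("per_item", "per_subscale"):
            raise ValueError(f"unknown node_granularity {self.node_granularity!r}")
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.name}: duplicate item ids")
        known = set(ids)
        for sub, members in self.subscales.items():
            missing = set(members) - known
            if missing:
                raise ValueError(f"{self.name}: subscale {sub} references unknown items {sorted(missing)}")
        assigned = [i for members in self.subscales.values() for i in members]
        if len(assigned) != len(set(assigned)):
            raise ValueError(f"{self.name}: an item appears in more than one subscale")
        if not self.reverse <= known:
            raise ValueError(f"{self.name}: reverse list references unknown items")
        if self.node_granularity == "per_subscale" and set(assigned) != known:
            raise ValueError(f"{self.name}: per-subscale scoring requires every item in a subscale")

    @property
    def item_ids(self) -> list[str]:
        return [it.id for it in self.items]

    @property
    def item_map(self) -> dict[str, Item]:
        return {it.id: it for it in self.items}

    def node_table(self) -> pd.DataFrame:
        """Node metadata (node_id, label, community) in instrument order."""
        rows = []
        if self.node_granularity == "per_item":
            sub_of = {i: s for s, members in self.subscales.items() for i in members}
            for it in self.items:
                sub = sub_of.get(it.id, "")
                rows.append(
                    {
                        "node_id": it.node or it.id,
                        "label": it.label,
                        "community": self.communities.get(sub, sub),
                    }
                )
        else:
            for sub in self.subscales:
                rows.append(
                    {
                        "node_id": self.subscale_nodes.get(sub, sub),
                        "label": sub,
                        "community": self.communities.get(sub, self.name),
                    }
                )
        return pd.DataFrame(rows)


def load_instrument(path: str | Path) -> InstrumentDefinition:
    """Read an instrument definition from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    items = [
        Item(id=d["id"], label=d.get("label", d["id"]), min=int(d["min"]), max=int(d["max"]),
             node=d.get("node"))
        for d in doc["items"]
    ]
    return InstrumentDefinition(
        name=doc["instrument"],
        items=items,
        subscales={k: list(v) for k, v in doc.get("subscales", {}).items()},
        reverse=frozenset(doc.get("reverse", []) or []),
        node_granularity=doc.get("node_granularity", "per_subscale"),
        subscale_nodes=dict(doc.get("nodes", {}) or {}),
        communities=dict(doc.get("communities", {}) or {}),
    )


def default_instruments() -> list[InstrumentDefinition]:
    """The bundled HADS and DERS definitions (HADS first)."""
    defs = []
    for fname in ("hads.yaml", "ders.yaml"):
        with resources.as_file(resources.files("symptomnet.data") / fname) as p:
            defs.append(load_instrument(p))
    return defs


@dataclass
class ItemResponseTable:
    """Validated item responses (one row per participant) plus demographics."""

    responses: pd.DataFrame  # index: participant_id, columns: item ids
    demographics: pd.DataFrame  # index: participant_id, may contain NaN
    n_dropped: int = 0

    @property
    def participant_ids(self) -> pd.Index:
        return self.responses.index

    @property
    def n(self) -> int:
        return len(self.responses)


def load_responses(
    path: str | Path,
    defs: Sequence[InstrumentDefinition],
    id_column: str = "participant_id",
) -> ItemResponseTable:
    """Load a participant x item CSV and validate it against the definitions.

    Rows with any missing *item* response are dropped (listwise deletion) and
    counted; missing demographics are retained as NaN.  An out-of-range
    response or a missing item column is a fatal error.
    """
    raw = pd.read_csv(path)
    if id_column in raw.columns:
        raw = raw.set_index(id_column)
        raw.index = raw.index.astype(str)
    else:
        raw.index = pd.Index([f"P{i + 1}" for i in range(len(raw))], name=id_column)
    if not raw.index.is_unique:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate participant id {dup!r}")

    item_ids = [i for d in defs for i in d.item_ids]
    missing_cols = [c for c in item_ids if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"missing item column(s): {', '.join(missing_cols)}")

    responses = raw[item_ids].apply(pd.to_numeric, errors="coerce")
    complete = responses.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("dropped %d participant(s) with missing item responses", n_dropped)
    responses = responses.loc[complete].astype(int)

    for d in defs:
        for it in d.items:
            col = responses[it.id]
            bad = col[(col < it.min) | (col > it.max)]
            if len(bad):
                pid = bad.index[0]
                raise ValueError(
                    f"response {bad.iloc[0]} of participant {pid!r} on item {it.id} "
                    f"outside [{it.min}, {it.max}]"
                )

    demo_cols = [c for c in DEMOGRAPHIC_FIELDS if c in raw.columns]
    demographics = raw.loc[complete, demo_cols].copy()
    return ItemResponseTable(responses=responses, demographics=demographics, n_dropped=n_dropped)


@dataclass
class NodeScores:
    """Participant x node score matrix with node metadata."""

    scores: pd.DataFrame  # index: participant_id, columns: node ids
    nodes: pd.DataFrame  # columns: node_id, label, community

    @property
    def node_ids(self) -> list[str]:
        return list(self.nodes["node_id"])

    @property
    def communities(self) -> pd.Series:
        return self.nodes.set_index("node_id")["community"]

    def validate_structure(self, expected: dict[str, int] | None = None) -> None:
        """Check node-count structure, e.g. {'anxiety': 7, 'depression': 7, 'DER': 6}."""
        counts = self.nodes["community"].value_counts().to_dict()
        if expected is not None and counts != expected:
            raise ValueError(f"community sizes {counts} != expected {expected}")


class NodeScorer(TransformerMixin, BaseEstimator):
    """Transformer mapping item responses to node scores.

    Per-item instruments contribute one node per (reverse-corrected) item;
    per-subscale instruments contribute the sum of reverse-corrected items in
    each subscale.  Stateless apart from the definitions; ``fit`` only
    validates column presence.
    """

    def __init__(self, defs: Sequence[InstrumentDefinition] | None = None):
        self.defs = defs

    def _definitions(self) -> list[InstrumentDefinition]:
        return list(self.defs) if self.defs is not None else default_instruments()

    def fit(self, X: pd.DataFrame, y=None):
        defs = self._definitions()
        for d in defs:
            missing = [i for i in d.item_ids if i not in X.columns]
            if missing:
                raise ValueError(f"{d.name}: item column(s) absent from table: {missing}")
        self.defs_ = defs
        self.nodes_ = pd.concat([d.node_table() for d in defs], ignore_index=True)
        if self.nodes_["node_id"].duplicated().any():
            raise ValueError("duplicate node ids across instruments")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "defs_")
        cols = {}
        for d in self.defs_:
            corrected = X[d.item_ids].copy()
            for iid in d.reverse:
                corrected[iid] = d.item_map[iid].reverse(corrected[iid])
            if d.node_granularity == "per_item":
                for it in d.items:
                    cols[it.node or it.id] = corrected[it.id]
            else:
                for sub, members in d.subscales.items():
                    cols[d.subscale_nodes.get(sub, sub)] = corrected[members].sum(axis=1)
        return pd.DataFrame(cols, index=X.index)


def score_nodes(table: ItemResponseTable, defs: Sequence[InstrumentDefinition]) -> NodeScores:
    """Score item responses into the node variables the network is built on."""
    scorer = NodeScorer(defs).fit(table.responses)
    return NodeScores(scores=scorer.transform(table.responses), nodes=scorer.nodes_)


def instrument_totals(table: ItemResponseTable, defs: Sequence[InstrumentDefinition]) -> pd.DataFrame:
    """Per-participant subscale and instrument totals (reverse-corrected sums)."""
    out = {}
    for d in defs:
        corrected = table.responses[d.item_ids].copy()
        for iid in d.reverse:
            corrected[iid] = d.item_map[iid].reverse(corrected[iid])
        for sub, members in d.subscales.items():
            out[f"{d.name}_{sub}"] = corrected[members].sum(axis=1)
        out[f"{d.name}_total"] = corrected.sum(axis=1)
    return pd.DataFrame(out, index=table.responses.index)


def summarize_by_group(
    measures: pd.DataFrame,
    demographics: pd.DataFrame,
    grouping: str,
) -> pd.DataFrame:
    """Descriptive table (group, measure, N, mean, SD) for one demographic field.

    SD uses the n-1 denominator; a single-participant group gets SD = NaN (the
    undefined marker, never 0).  Participants missing the grouping field are
    excluded and counted in the log.
    """
    if grouping not in demographics.columns:
        raise KeyError(f"grouping field {grouping!r} not present in demographics")
    g = demographics[grouping].reindex(measures.index)
    n_missing = int(g.isna().sum())
    if n_missing:
        logger.warning("%d participant(s) missing %r excluded from descriptives", n_missing, grouping)
    if n_missing == len(g):
        logger.warning("grouping field %r entirely missing; descriptives table is empty", grouping)
        return pd.DataFrame(columns=["group", "measure", "n", "mean", "sd"])
    keep = g.notna()
    rows = []
    for level, idx in measures.loc[keep].groupby(g[keep]).groups.items():
        block = measures.loc[idx]
        for col in measures.columns:
            vals = block[col].astype(float)
            rows.append(
                {
                    "group": level,
                    "measure": col,
                    "n": len(vals),
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)
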