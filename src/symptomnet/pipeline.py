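"""One-command orchestration of the full analysis.

load (or simulate) data -> score nodes -> estimate the EBIC-glasso network
-> centrality + bridge centrality + both layouts -> case-drop stability ->
write every tabular artifact and a run manifest sufficient to reproduce the
run byte-for-byte (all randomness flows from one master seed expanded into
per-stage seeds that are recorded in the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centrality import bridge_table, centrality_table
from .instruments import (
    NodeScores,
    default_instruments,
    instrument_totals,
    load_instrument,
    load_responses,
    score_nodes,
    summarize_by_group,
)
from .layout import circular_group_layout, mds_layout
from .network import estimate_network
from .simulate import SyntheticConfig, generate_true_network, sample_item_table, sample_responses
from .stability import case_drop_bootstrap, cs_coefficient, make_centrality_estimator

logger = logging.getLogger(__name__)

EXPECTED_STRUCTURE = {"anxiety": 7, "depression": 7, "DER": 6}


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated settings for one pipeline run."""

    output_dir: str
    input_path: str | None = None
    instrument_paths: list[str] | None = None
    synthetic: SyntheticConfig | None = None
    synthetic_mode: str = "node"  # "node" or "item"
    seed: int = 0
    gamma: float = 0.5
    n_lambda: int = 100
    min_ratio: float = 0.01
    correlation: str = "pearson"
    run_stability: bool = True
    stability_grid: list[float] = field(default_factory=lambda: [0.1, 0.2, 0.3, 0.4, 0.5])
    stability_B: int = 100
    cs_threshold: float = 0.7
    cs_certainty: float = 0.95
    layout_n_init: int = 10
    layout_metric: bool = False
    descriptive_grouping: str | None = "sex"
    enforce_structure: bool = False
    figures: bool = False

    def validate(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_path and synthetic must be set")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ValueError(f"input path {self.input_path!r} does not exist")
        if self.instrument_paths:
            for p in self.instrument_paths:
                if not Path(p).exists():
                    raise ValueError(f"instrument definition {p!r} does not exist")
        if self.synthetic_mode not in ("node", "item"):
            raise ValueError("synthetic_mode must be 'node' or 'item'")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an explicit integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if "synthetic" in doc and doc["synthetic"] is not None:
            syn = dict(doc["synthetic"])
            for key in ("community_sizes", "community_names", "node_ids"):
                if key in syn and syn[key] is not None:
                    syn[key] = tuple(syn[key])
            if "bridge_edges" in syn and syn["bridge_edges"] is not None:
                syn["bridge_edges"] = tuple(tuple(e) for e in syn["bridge_edges"])
            if "likert_levels" in syn:
                syn["likert_levels"] = tuple(syn["likert_levels"])
            doc["synthetic"] = SyntheticConfig(**syn)
        return cls(**doc)


def _stage_seeds(master: int) -> dict[str, int]:
    state = np.random.SeedSequence(master).generate_state(4)
    names = ("synthetic", "stability", "layout", "spare")
    return {name: int(s % (2**31)) for name, s in zip(names, state)}


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index)


def _write_json(obj: Any, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and write all artifacts; returns paths and objects."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    artifacts: dict[str, Any] = {"output_dir": str(out)}
    counts: dict[str, Any] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                raise StageError(name, exc) from exc
            logger.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
            return result

        return deco

    defs = (
        [load_instrument(p) for p in config.instrument_paths]
        if config.instrument_paths
        else default_instruments()
    )

    truth = None
    responses = None

    @stage("data")
    def _data():
        nonlocal truth, responses
        if config.synthetic is not None:
            syn = dataclasses.replace(config.synthetic, seed=seeds["synthetic"])
            truth = generate_true_network(syn)
            _write_csv(
                pd.DataFrame(truth.partial, index=truth.node_ids, columns=truth.node_ids),
                out / "true_weights.csv",
                index=True,
            )
            if config.synthetic_mode == "item":
                table = sample_item_table(truth, defs=defs)
                table.to_csv(out / "item_responses.csv", index=False)
                responses = load_responses(out / "item_responses.csv", defs)
                return score_nodes(responses, defs)
            scores, _ = sample_responses(truth, syn)
            return scores
        responses = load_responses(config.input_path, defs)
        return score_nodes(responses, defs)

    scores: NodeScores = _data
    if config.enforce_structure:
        scores.validate_structure(EXPECTED_STRUCTURE)
    counts["n_participants"], counts["n_nodes"] = scores.scores.shape
    _write_csv(scores.scores, out / "node_scores.csv", index=True)
    _write_csv(scores.nodes, out / "nodes.csv")

    @stage("descriptives")
    def _descriptives():
        if responses is None or config.descriptive_grouping is None:
            return None
        if config.descriptive_grouping not in responses.demographics.columns:
            return None
        totals = instrument_totals(responses, defs)
        table = summarize_by_group(totals, responses.demographics, config.descriptive_grouping)
        _write_csv(table, out / "descriptives.csv")
        return table

    artifacts["descriptives"] = _descriptives

    @stage("network")
    def _network():
        return estimate_network(
            scores,
            gamma=config.gamma,
            n_alphas=config.n_lambda,
            alpha_min_ratio=config.min_ratio,
            correlation=config.correlation,
        )

    net = _network
    counts["n_edges"] = net.n_edges
    _write_csv(net.edge_list(), out / "edge_list.csv")
    _write_csv(net.weight_frame(), out / "weight_matrix.csv", index=True)
    _write_csv(net.path, out / "ebic_path.csv")
    net.write_graphml(out / "network.graphml")

    @stage("centrality")
    def _centrality():
        cent = centrality_table(net)
        bridge = bridge_table(net)
        _write_csv(cent, out / "centrality.csv", index=True)
        _write_csv(bridge, out / "bridge_centrality.csv", index=True)
        return cent, bridge

    cent, bridge = _centrality

    @stage("layout")
    def _layout():
        circ = circular_group_layout(net.node_ids, net.communities)
        mds = mds_layout(net, seed=seeds["layout"], n_init=config.layout_n_init, metric=config.layout_metric)
        _write_csv(circ.frame(), out / "layout_circle.csv")
        _write_csv(mds.frame(), out / "layout_mds.csv")
        _write_json(
            {"stress_1": mds.stress_1, "n_iter": mds.n_iter, **mds.meta}, out / "layout_mds_meta.json"
        )
        return circ, mds

    circ, mds = _layout

    stability_res = None
    cs = None
    if config.run_stability:

        @stage("stability")
        def _stability():
            estimator = make_centrality_estimator(
                net.communities,
                gamma=config.gamma,
                n_alphas=config.n_lambda,
                alpha_min_ratio=config.min_ratio,
                correlation=config.correlation,
            )
            res = case_drop_bootstrap(
                scores.scores,
                estimator=estimator,
                grid=config.stability_grid,
                B=config.stability_B,
                seed=seeds["stability"],
            )
            cs_vals = cs_coefficient(res, threshold=config.cs_threshold, certainty=config.cs_certainty)
            _write_csv(res.to_frame(), out / "stability_correlations.csv")
            _write_csv(res.summary(), out / "stability_summary.csv")
            _write_json(cs_vals, out / "cs_coefficients.json")
            return res, cs_vals

        stability_res, cs = _stability

    if config.figures:

        @stage("figures")
        def _figures():
            from .plotting import plot_centrality, plot_network, plot_stability

            plot_network(net, circ, out / "fig_network_circle.png")
            plot_network(net, mds, out / "fig_network_mds.png")
            plot_centrality(cent, out / "fig_centrality.png")
            if stability_res is not None:
                plot_stability(stability_res.summary(), out / "fig_stability.png")

        _figures

    input_hash = None
    if config.input_path is not None:
        input_hash = hashlib.sha256(Path(config.input_path).read_bytes()).hexdigest()
    else:
        input_hash = hashlib.sha256((out / "node_scores.csv").read_bytes()).hexdigest()

    manifest = {
        "package_version": __version__,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "settings": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("synthetic",)
        },
        "synthetic": dataclasses.asdict(config.synthetic) if config.synthetic else None,
        "counts": counts,
        "input_sha256": input_hash,
        "cs_coefficients": cs,
        "mds_stress_1": mds.stress_1,
        "sparsity": net.sparsity,
        "alpha_selected": net.alpha_selected,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    _write_json(_jsonable(manifest), out / "manifest.json")
    artifacts.update(
        {
            "scores": scores,
            "network": net,
            "centrality": cent,
            "bridge": bridge,
            "layout_circle": circ,
            "layout_mds": mds,
            "stability": stability_res,
            "cs": cs,
            "truth": truth,
            "manifest": manifest,
        }
    )
    return artifacts


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
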