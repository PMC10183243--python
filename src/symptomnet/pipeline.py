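"""End-to-end orchestration: data -> network -> description -> stability.

`run_pipeline` executes the two analysis phases (network estimation, then
network description with stability checks) and writes the run artifacts:
an edge list, a per-node metrics table (centrality plus predictability),
bootstrap stability draws, and a summary JSON whose every number can be
recomputed from the stage outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import centrality as ct
from .data import (
    CommunityMap,
    ItemResponseMatrix,
    load_community_map,
    read_responses,
)
from .ggm import DEFAULT_GAMMA, DEFAULT_LAMBDA_MIN_RATIO, DEFAULT_N_LAMBDA, select_network
from .predictability import node_predictability
from .stability import (
    DEFAULT_B,
    DEFAULT_CONFIDENCE,
    DEFAULT_COR_THRESHOLD,
    DEFAULT_DROP_GRID,
    case_drop_bootstrap,
    cs_coefficient,
    interpret_cs,
)
from .transform import correlation_matrix, npn_transform

logger = logging.getLogger(__name__)

#: Below this sample size the case-dropping bootstrap is statistically
#: meaningless and is skipped unless forced.
MIN_N_FOR_STABILITY = 100


@dataclass(frozen=True)
class RunConfig:
    input: str | Path
    communities: str | Path = "dass21"
    item_ids: Sequence[str] | None = None
    gamma: float = DEFAULT_GAMMA
    n_lambda: int = DEFAULT_N_LAMBDA
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO
    drop_grid: Sequence[float] = DEFAULT_DROP_GRID
    boots: int = DEFAULT_B
    cor_threshold: float = DEFAULT_COR_THRESHOLD
    confidence: float = DEFAULT_CONFIDENCE
    stability_indices: Sequence[str] = ("strength", "bridge_strength", "predictability")
    seed: int = 0
    out: str | Path = "symptomnet_run"
    run_stability: bool = True
    force_stability: bool = False
    write_graphml: bool = False
    write_plot: bool = False


class PipelineError(RuntimeError):
    """Stage-tagged failure; partial outputs have been removed."""


def _fail(stage: str, exc: Exception, written: list[Path]) -> None:
    for f in written:
        try:
            f.unlink()
        except OSError:
            pass
    raise PipelineError(f"[{stage}] {exc}") from exc


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages and write artifacts under ``cfg.out``.

    Returns the summary dictionary (also written to ``summary.json``).
    """
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("symptomnet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("resolved config: %s", dataclasses.asdict(cfg))

        try:
            item_ids = tuple(cfg.item_ids) if cfg.item_ids else None
            cm: CommunityMap = load_community_map(cfg.communities)
            if item_ids is None:
                item_ids = tuple(
                    i for c in cm.communities for i in cm.members(c)
                )
            x: ItemResponseMatrix = read_responses(cfg.input, item_ids)
            cm.labels_for(x.item_ids)  # validate coverage early
        except Exception as exc:
            _fail("data_io", exc, written)

        try:
            z = npn_transform(x)
            r = correlation_matrix(z)
        except Exception as exc:
            _fail("transform", exc, written)

        try:
            net = select_network(
                r,
                gamma=cfg.gamma,
                n_lambda=cfg.n_lambda,
                lambda_min_ratio=cfg.lambda_min_ratio,
            )
            edge_csv = out / "edges.csv"
            net.to_edge_csv(edge_csv)
            written.append(edge_csv)
            if cfg.write_graphml:
                gpath = out / "network.graphml"
                net.to_graphml(gpath, cm)
                written.append(gpath)
            if cfg.write_plot:
                ppath = out / "network.png"
                _plot_network(net, cm, ppath)
                written.append(ppath)
        except Exception as exc:
            _fail("ggm", exc, written)

        try:
            metrics = ct.node_metrics(net, cm)
        except Exception as exc:
            _fail("centrality", exc, written)

        try:
            pred = node_predictability(z)
            metrics = metrics.merge(
                pred.table.rename(columns={"r2": "predictability"}), on="node"
            )
            metrics_csv = out / "node_metrics.csv"
            metrics.to_csv(metrics_csv, index=False)
            written.append(metrics_csv)
        except Exception as exc:
            _fail("predictability", exc, written)

        stability_summary: dict[str, dict] = {}
        do_stability = cfg.run_stability and (
            x.n >= MIN_N_FOR_STABILITY or cfg.force_stability
        )
        if cfg.run_stability and not do_stability:
            logger.warning(
                "n = %d < %d: stability stage skipped (force_stability to override)",
                x.n, MIN_N_FOR_STABILITY,
            )
        if do_stability:
            try:
                frames = []
                for index in cfg.stability_indices:
                    res = case_drop_bootstrap(
                        x,
                        index,
                        cm=cm,
                        proportions=cfg.drop_grid,
                        B=cfg.boots,
                        seed=cfg.seed,
                        gamma=cfg.gamma,
                        n_lambda=cfg.n_lambda,
                    )
                    cs = cs_coefficient(res, cfg.cor_threshold, cfg.confidence)
                    stability_summary[index] = {
                        "cs": cs,
                        "label": interpret_cs(cs),
                    }
                    frames.append(res.to_frame())
                stab_csv = out / "stability.csv"
                pd.concat(frames, ignore_index=True).to_csv(stab_csv, index=False)
                written.append(stab_csv)
            except Exception as exc:
                _fail("stability", exc, written)

        summary = {
            "n_read": x.n + x.n_dropped,
            "n_dropped": x.n_dropped,
            "n_retained": x.n,
            "p": x.p,
            "gamma": cfg.gamma,
            "selected_lambda": net.lam,
            "ebic": net.ebic,
            "n_edges": net.n_edges,
            "mean_predictability": pred.mean_r2,
            "stability": stability_summary,
            "seed": cfg.seed,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()


def _plot_network(net, cm: CommunityMap, path: Path) -> None:
    """Minimal static rendering: communities colored, width = |weight|."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import networkx as nx

    g = net.to_networkx(cm)
    pos = nx.spring_layout(g, seed=0, weight="weight")
    comms = list(cm.communities)
    cmap = plt.get_cmap("Set2")
    colors = [cmap(comms.index(g.nodes[v].get("community", comms[0]))) for v in g]
    widths = [6 * abs(g[u][v]["weight"]) for u, v in g.edges]
    fig, ax = plt.subplots(figsize=(7, 7))
    nx.draw_networkx(g, pos, ax=ax, node_color=colors, width=widths,
                     font_size=7, node_size=450)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
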