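"""End-to-end pipeline: sweep -> persistence -> hierarchy."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .graph_io import RunConfig, WeightedGraph
from .hierarchy import HierarchyDAG, build_dag
from .persistence import (
    CommunityGraph,
    PersistentCommunity,
    build_community_graph,
    extract_persistent,
)
from .resolution_sweep import ResolutionProfile, sweep

logger = logging.getLogger("mscd")

__all__ = ["PipelineResult", "run"]


@dataclass
class PipelineResult:
    """Everything the three phases produce, for inspection and output."""

    hierarchy: HierarchyDAG
    persistent_communities: list[PersistentCommunity]
    profile: ResolutionProfile
    community_graph: CommunityGraph


def run(g: WeightedGraph, cfg: RunConfig | None = None, repeats: int = 1) -> PipelineResult:
    """Run the full persistent-community workflow on a graph."""
    if cfg is None:
        cfg = RunConfig()
    profile = sweep(g, cfg, repeats=repeats)
    cg = build_community_graph(profile, cfg.tau)
    pcs = extract_persistent(
        cg, cfg.chi, cfg.p_percent, cfg.min_community_size, node_names=g.nodes
    )
    logger.info("retained %d persistent communities", len(pcs))
    h = build_dag(pcs, all_nodes=g.nodes, sigma=cfg.sigma, tau=cfg.tau)
    return PipelineResult(
        hierarchy=h, persistent_communities=pcs, profile=profile, community_graph=cg
    )
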