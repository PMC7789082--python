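"""Phase II: pan-resolution community graph and persistence scoring.

Every community detected at any resolution becomes a vertex of the
community graph G_C; edges join instances from two *different*,
gamma-proximal resolutions whose member sets have Jaccard similarity
strictly above tau.  A connected component of G_C is a family of similar
communities spanning resolutions; its persistence is the number of
distinct resolutions it covers.  Components at least chi resolutions deep
yield a consensus "persistent community": the nodes present in strictly
more than p% of the component's instances.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .resolution_sweep import ResolutionGrid, ResolutionProfile

logger = logging.getLogger("mscd")

__all__ = [
    "CommunityInstance",
    "CommunityGraph",
    "PersistentCommunity",
    "jaccard",
    "build_community_graph",
    "extract_persistent",
]


def jaccard(a, b) -> float:
    """Jaccard similarity |a & b| / |a | b| of two nonempty node sets."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("jaccard is undefined for empty sets")
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


@dataclass(frozen=True)
class CommunityInstance:
    """One community from one resolution's partition."""

    gamma: float
    gamma_index: int
    local_index: int
    members: frozenset


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1


@dataclass
class CommunityGraph:
    """G_C: community instances, Jaccard edges, connected components."""

    instances: list[CommunityInstance]
    sim_edges: list[tuple[int, int, float]]
    component_of: np.ndarray

    def components(self) -> list[list[int]]:
        comps: dict[int, list[int]] = {}
        for i, c in enumerate(self.component_of):
            comps.setdefault(int(c), []).append(i)
        return list(comps.values())

    def component_persistence(self, instance_ids) -> int:
        return len({self.instances[i].gamma_index for i in instance_ids})


@dataclass(frozen=True)
class PersistentCommunity:
    """Consensus community of one persistent component of G_C."""

    members: frozenset
    persistence: int
    n_instances: int
    source_component: int

    def __len__(self) -> int:
        return len(self.members)


def build_community_graph(
    profile: ResolutionProfile, tau: float, grid: ResolutionGrid | None = None
) -> CommunityGraph:
    """Assemble G_C from a resolution profile.

    Cross-resolution Jaccard similarities are accumulated per proximal
    resolution pair by counting co-assigned nodes from the two label
    vectors (equivalent to, but much cheaper than, all-pairs set
    comparison: communities within one resolution never overlap).
    """
    if grid is None:
        grid = profile.grid
    if not profile.partitions:
        raise ValueError("empty resolution profile")

    instances: list[CommunityInstance] = []
    inst_id: dict[tuple[int, int], int] = {}
    sizes: list[int] = []
    for gi, part in enumerate(profile.partitions):
        for local, idx in enumerate(part.community_indices()):
            inst_id[(gi, local)] = len(instances)
            instances.append(
                CommunityInstance(
                    gamma=part.gamma, gamma_index=gi, local_index=local,
                    members=frozenset(int(x) for x in idx),
                )
            )
            sizes.append(len(idx))

    uf = _UnionFind(len(instances))
    sim_edges: list[tuple[int, int, float]] = []
    for gi, gj in grid.proximal_pairs():
        li = profile.partitions[gi].labels
        lj = profile.partitions[gj].labels
        overlap = Counter(zip(li.tolist(), lj.tolist()))
        for (a, b), inter in overlap.items():
            ia, ib = inst_id[(gi, a)], inst_id[(gj, b)]
            union = sizes[ia] + sizes[ib] - inter
            j = inter / union
            if j > tau:  # strict, per definition
                sim_edges.append((ia, ib, j))
                uf.union(ia, ib)

    component_of = np.array([uf.find(i) for i in range(len(instances))], dtype=int)
    return CommunityGraph(instances=instances, sim_edges=sim_edges, component_of=component_of)


def extract_persistent(
    cg: CommunityGraph,
    chi: int,
    p_percent: float,
    min_size: int = 1,
    node_names=None,
) -> list[PersistentCommunity]:
    """Consensus communities of components with persistence >= chi.

    A node belongs to the consensus iff it appears in strictly more than
    ``p_percent`` % of the component's instances.  Components whose
    consensus is empty or smaller than ``min_size`` are dropped (logged).
    The result is sorted by descending persistence, then descending size,
    then lexicographic smallest member.
    """
    out: list[PersistentCommunity] = []
    n_dropped = 0
    for comp in cg.components():
        pers = cg.component_persistence(comp)
        if pers < chi:
            continue
        n_inst = len(comp)
        counts: Counter = Counter()
        for i in comp:
            counts.update(cg.instances[i].members)
        consensus = {v for v, c in counts.items() if c * 100.0 > p_percent * n_inst}
        if node_names is not None:
            consensus = {node_names[v] for v in consensus}
        if len(consensus) < max(1, min_size):
            n_dropped += 1
            continue
        out.append(
            PersistentCommunity(
                members=frozenset(consensus),
                persistence=pers,
                n_instances=n_inst,
                source_component=int(cg.component_of[comp[0]]),
            )
        )
    if n_dropped:
        logger.info(
            "dropped %d persistent components with consensus smaller than %d",
            n_dropped, min_size,
        )
    out.sort(key=lambda pc: (-pc.persistence, -len(pc.members), min(map(str, pc.members))))
    return out
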