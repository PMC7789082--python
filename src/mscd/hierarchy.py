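"""Phase III: assemble persistent communities into a containment DAG.

Parent-child candidates are scored by the containment index
CI(v, w) = |v & w| / |w| — the fraction of w contained in v.  Mutual
containment at the Jaccard threshold tau (CI >= tau both ways) merges the
pair into its union; remaining ordered pairs get an edge v -> w when
CI(v, w) > sigma and v is strictly larger than w.  A root holding every
graph node is attached above all parentless vertices, redundant edges are
removed by transitive reduction, and each vertex's membership is expanded
with all of its descendants' members.

With tau-linked communities (J < tau pairwise, guaranteed by Phase II),
sigma >= 2*tau/(1+tau) makes even the un-oriented CI relation acyclic;
the relaxed default sigma = tau admits more containment relations and the
size-ordered orientation used here keeps the result acyclic regardless.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .persistence import PersistentCommunity

logger = logging.getLogger("mscd")

__all__ = [
    "HierarchyDAG",
    "containment_index",
    "containment_edges",
    "build_dag",
    "transitive_reduction",
    "expand_membership",
]


def containment_index(v, w) -> float:
    """Fraction of w's members shared with v: |v & w| / |w|."""
    v, w = set(v), set(w)
    if not w:
        raise ValueError("containment index undefined for empty containee")
    return len(v & w) / len(w)


@dataclass
class HierarchyDAG:
    """Rooted DAG of communities with member sets and persistence scores.

    ``members`` maps vertex id -> frozenset of node names; the root's
    member set covers every graph node and its persistence is recorded
    as 0.  Edges point from parent (container) to child (contained).
    """

    members: dict[str, frozenset]
    persistence: dict[str, int]
    edges: set[tuple[str, str]]
    root: str = "root"

    def vertices(self) -> list[str]:
        return list(self.members)

    def communities(self) -> list[str]:
        """Non-root vertex ids sorted by (persistence desc, size desc, member)."""
        return sorted(
            (v for v in self.members if v != self.root),
            key=lambda v: (
                -self.persistence[v],
                -len(self.members[v]),
                min(self.members[v]) if self.members[v] else "",
            ),
        )

    @property
    def n_communities(self) -> int:
        return len(self.members) - 1

    def children(self, v: str) -> list[str]:
        return [b for a, b in self.edges if a == v]

    def parents(self, v: str) -> list[str]:
        return [a for a, b in self.edges if b == v]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for v in self.members:
            g.add_node(v, members=self.members[v], persistence=self.persistence[v])
        g.add_edges_from(self.edges)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def depth(self, v: str) -> int:
        """Longest-path distance from the root."""
        g = self.to_networkx()
        order = nx.topological_sort(g)
        dist = {u: (0 if u == self.root else -1) for u in g}
        for u in order:
            if dist[u] < 0:
                continue
            for w in g.successors(u):
                dist[w] = max(dist[w], dist[u] + 1)
        return dist[v]

    def validate(self) -> None:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("hierarchy contains a cycle")
        reachable = {self.root} | nx.descendants(g, self.root)
        if reachable != set(g.nodes):
            raise ValueError("root does not reach every vertex")


def containment_edges(
    sets: list, sigma: float, require_larger_parent: bool = True
) -> list[tuple[int, int]]:
    """Directed containment relation over member sets.

    Edge i -> j iff CI(sets[i], sets[j]) > sigma, optionally (default)
    further requiring |sets[i]| > |sets[j]| so parents are strictly
    larger; the relaxed form exposes the raw threshold relation.
    """
    sets = [set(s) for s in sets]
    edges = []
    for i, vi in enumerate(sets):
        for j, vj in enumerate(sets):
            if i == j or not vj:
                continue
            if require_larger_parent and len(vi) <= len(vj):
                continue
            if len(vi & vj) > sigma * len(vj):
                edges.append((i, j))
    return edges


def transitive_reduction(h: HierarchyDAG) -> HierarchyDAG:
    """Minimal edge set with the same reachability (unique for a DAG)."""
    g = h.to_networkx()
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("transitive reduction requires an acyclic input")
    reduced = nx.transitive_reduction(g)
    return HierarchyDAG(
        members=dict(h.members),
        persistence=dict(h.persistence),
        edges=set(reduced.edges()),
        root=h.root,
    )


def expand_membership(h: HierarchyDAG) -> HierarchyDAG:
    """Expand each vertex to include all descendants' members.

    Computed in reverse topological order so each vertex unions its
    (already expanded) children; afterwards child members are a subset of
    parent members along every edge.
    """
    g = h.to_networkx()
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("membership expansion requires an acyclic input")
    expanded = {v: set(h.members[v]) for v in h.members}
    for v in reversed(list(nx.topological_sort(g))):
        for w in g.successors(v):
            expanded[v] |= expanded[w]
    return HierarchyDAG(
        members={v: frozenset(s) for v, s in expanded.items()},
        persistence=dict(h.persistence),
        edges=set(h.edges),
        root=h.root,
    )


def _merge_mutual_containments(
    pool: list[tuple[frozenset, int]], tau: float
) -> list[tuple[frozenset, int]]:
    """Union pairs with CI >= tau in both directions, to a fixed point."""
    pool = list(pool)
    merged = True
    while merged:
        merged = False
        n = len(pool)
        for i in range(n):
            vi, pi = pool[i]
            for j in range(i + 1, n):
                vj, pj = pool[j]
                inter = len(vi & vj)
                if inter >= tau * len(vi) and inter >= tau * len(vj):
                    union = vi | vj
                    logger.info(
                        "mutual containment: merging communities of sizes %d and %d "
                        "into their union (size %d)", len(vi), len(vj), len(union),
                    )
                    pool[i] = (union, max(pi, pj))
                    del pool[j]
                    merged = True
                    break
            if merged:
                break
    return pool


def build_dag(
    communities: Iterable[PersistentCommunity] | Iterable[tuple],
    all_nodes: Iterable,
    sigma: float | None = None,
    tau: float = 0.75,
) -> HierarchyDAG:
    """Build the rooted, reduced, membership-expanded hierarchy.

    ``communities`` may be PersistentCommunity objects or (members,
    persistence) pairs.  Exact duplicate member sets merge first (keeping
    the larger persistence); mutual containments union iteratively; edges
    then go from strictly larger to strictly smaller sets with
    CI > sigma; equal-size non-identical sets never get an edge.
    """
    if sigma is None:
        sigma = tau
    if sigma < tau:
        warnings.warn(
            f"sigma={sigma} < tau={tau}: hierarchy acyclicity not guaranteed",
            stacklevel=2,
        )
    all_nodes = frozenset(all_nodes)

    dedup: dict[frozenset, int] = {}
    for c in communities:
        members, pers = (c.members, c.persistence) if isinstance(c, PersistentCommunity) else c
        members = frozenset(members)
        if not members:
            continue
        if members in dedup:
            logger.info("duplicate community of size %d: keeping max persistence", len(members))
        dedup[members] = max(dedup.get(members, 0), int(pers))

    pool = _merge_mutual_containments(list(dedup.items()), tau)

    ids = [f"v{i}" for i in range(len(pool))]
    members = {vid: mem for vid, (mem, _) in zip(ids, pool)}
    persistence = {vid: pers for vid, (_, pers) in zip(ids, pool)}

    edges: set[tuple[str, str]] = set()
    for i, vid in enumerate(ids):
        vi = members[vid]
        for j, wid in enumerate(ids):
            if i == j:
                continue
            wj = members[wid]
            if len(vi) <= len(wj):
                continue
            if len(vi & wj) > sigma * len(wj):
                edges.add((vid, wid))

    h = HierarchyDAG(members=members, persistence=persistence, edges=edges, root="root")
    # strictly-size-decreasing edges cannot form a cycle; assert anyway
    if not h.is_acyclic():  # pragma: no cover - unreachable by construction
        raise RuntimeError("containment relation unexpectedly cyclic after union pass")

    h.members["root"] = all_nodes
    h.persistence["root"] = 0
    parented = {b for _, b in h.edges}
    for vid in ids:
        if vid not in parented:
            h.edges.add(("root", vid))

    h = transitive_reduction(h)
    h = expand_membership(h)
    h.validate()
    return h
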