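"""Core weighted-graph container, run configuration, and on-disk formats.

The input to the whole pipeline is a plain-text edge list describing an
undirected similarity network (cells, proteins, or any other entities).
The main output is a rooted DAG of nested/overlapping communities, written
as a pair of TSV files (``<prefix>.nodes`` / ``<prefix>.edges``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger("mscd")

__all__ = [
    "WeightedGraph",
    "RunConfig",
    "ParseError",
    "read_edge_list",
    "write_edge_list",
    "write_hierarchy",
    "read_hierarchy",
    "read_labels",
    "read_embeddings",
    "write_gml",
]


class ParseError(ValueError):
    """Raised when an input file violates the expected format."""


class WeightedGraph:
    """Undirected weighted graph with string-named nodes.

    Nodes are kept in first-appearance order.  Self-loops are dropped and
    duplicate edges collapse by summing their weights; both events are
    logged.  Degrees are strengths (sums of incident edge weights) and the
    total weight ``m`` generalizes the edge count, so unweighted graphs
    reduce to the usual degree/edge-count semantics.
    """

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[tuple] = ()):
        self.nodes: list[str] = []
        self._index: dict[str, int] = {}
        self._adj: list[dict[int, float]] = []
        self._n_self_loops = 0
        self._n_duplicates = 0
        for name in nodes:
            self.add_node(name)
        for e in edges:
            if len(e) == 2:
                u, v = e
                w = 1.0
            else:
                u, v, w = e
            self.add_edge(u, v, w)

    # -- construction -------------------------------------------------

    def add_node(self, name: str) -> int:
        idx = self._index.get(name)
        if idx is None:
            idx = len(self.nodes)
            self._index[name] = idx
            self.nodes.append(name)
            self._adj.append({})
        return idx

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> None:
        if weight <= 0:
            raise ValueError(f"edge weight must be positive, got {weight!r}")
        iu = self.add_node(u)
        iv = self.add_node(v)
        if iu == iv:
            self._n_self_loops += 1
            logger.warning("dropping self-loop on node %r", u)
            return
        if iv in self._adj[iu]:
            self._n_duplicates += 1
            logger.info("duplicate edge (%r, %r): summing weights", u, v)
        self._adj[iu][iv] = self._adj[iu].get(iv, 0.0) + weight
        self._adj[iv][iu] = self._adj[iv].get(iu, 0.0) + weight

    # -- queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj) // 2

    def index(self, name: str) -> int:
        return self._index[name]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def has_edge(self, u: str, v: str) -> bool:
        iu, iv = self._index.get(u), self._index.get(v)
        return iu is not None and iv is not None and iv in self._adj[iu]

    def weight(self, u: str, v: str) -> float:
        return self._adj[self._index[u]].get(self._index[v], 0.0)

    def neighbors(self, name: str) -> list[str]:
        return [self.nodes[j] for j in self._adj[self._index[name]]]

    def degree(self, name: str) -> float:
        return sum(self._adj[self._index[name]].values())

    def strengths(self) -> np.ndarray:
        """Weighted degree (strength) of every node, in node order."""
        return np.array([sum(nbrs.values()) for nbrs in self._adj], dtype=float)

    @property
    def total_weight(self) -> float:
        """m: sum of all edge weights (edge count for unit weights)."""
        return sum(sum(nbrs.values()) for nbrs in self._adj) / 2.0

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for iu, nbrs in enumerate(self._adj):
            for iv, w in nbrs.items():
                if iu < iv:
                    yield self.nodes[iu], self.nodes[iv], w

    def edges_indexed(self) -> Iterator[tuple[int, int, float]]:
        for iu, nbrs in enumerate(self._adj):
            for iv, w in nbrs.items():
                if iu < iv:
                    yield iu, iv, w

    def connected_components(self) -> list[set[str]]:
        seen = [False] * self.n_nodes
        comps: list[set[str]] = []
        for start in range(self.n_nodes):
            if seen[start]:
                continue
            stack, comp = [start], set()
            seen[start] = True
            while stack:
                i = stack.pop()
                comp.add(self.nodes[i])
                for j in self._adj[i]:
                    if not seen[j]:
                        seen[j] = True
                        stack.append(j)
            comps.append(comp)
        return comps

    def subgraph(self, keep: Iterable[str]) -> "WeightedGraph":
        """Induced subgraph on ``keep`` (nodes retained even if isolated)."""
        keep_set = set(keep)
        sub = WeightedGraph()
        for name in self.nodes:
            if name in keep_set:
                sub.add_node(name)
        for u, v, w in self.edges():
            if u in keep_set and v in keep_set:
                sub.add_edge(u, v, w)
        return sub

    def to_igraph(self):
        import igraph

        g = igraph.Graph(n=self.n_nodes, directed=False)
        g.vs["name"] = list(self.nodes)
        es = list(self.edges_indexed())
        if es:
            g.add_edges([(u, v) for u, v, _ in es])
            g.es["weight"] = [w for _, _, w in es]
        return g

    def __repr__(self) -> str:  # pragma: no cover
        return f"WeightedGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges}, m={self.total_weight:g})"


@dataclass
class RunConfig:
    """Parameters of the resolution sweep, persistence scoring and hierarchy.

    Defaults follow the settings used throughout the protein-network and
    simulated-network analyses: resolution range [1e-3, 50], Jaccard
    threshold tau = 0.75, persistence threshold chi = 5, consensus
    membership threshold p = 75 %, containment threshold sigma = tau, and
    a minimum reported community size of 4.
    """

    gamma_min: float = 0.001
    gamma_max: float = 50.0
    log_step: float = 0.02
    proximity_radius: float = 0.1
    min_proximal: int = 10
    tau: float = 0.75
    chi: int = 5
    p_percent: float = 75.0
    sigma: float | None = None  # defaults to tau
    seed: int = 42
    min_community_size: int = 4

    def __post_init__(self) -> None:
        if self.gamma_min <= 0 or self.gamma_max <= 0:
            raise ValueError("resolution bounds must be positive")
        if self.gamma_min > self.gamma_max:
            raise ValueError("gamma_min must be <= gamma_max")
        if not (0 < self.tau < 1):
            raise ValueError("tau must be in (0, 1)")
        if self.log_step <= 0 or self.proximity_radius <= 0:
            raise ValueError("log_step and proximity_radius must be positive")
        if self.chi < 1 or self.min_proximal < 0:
            raise ValueError("chi must be >= 1 and min_proximal >= 0")
        if not (0 < self.p_percent < 100):
            raise ValueError("p_percent must be in (0, 100)")
        if self.sigma is None:
            self.sigma = self.tau
        elif self.sigma < self.tau:
            warnings.warn(
                f"sigma={self.sigma} < tau={self.tau}: acyclicity of the "
                "containment hierarchy is no longer guaranteed",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(path, delimiter: str | None = None) -> WeightedGraph:
    """Read an undirected edge list.

    Each non-comment line holds ``source target [weight]``; fields are
    separated by ``delimiter`` (any whitespace when None).  Lines starting
    with ``#`` and blank lines are skipped.  Self-loops are dropped and
    duplicate edges collapse to one edge with summed weight.
    """
    g = WeightedGraph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) not in (2, 3):
                raise ParseError(
                    f"{path}, line {lineno}: expected 2 or 3 fields, got {len(parts)}"
                )
            w = 1.0
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}, line {lineno}: non-numeric weight {parts[2]!r}"
                    ) from exc
                if not np.isfinite(w) or w <= 0:
                    raise ParseError(
                        f"{path}, line {lineno}: weight must be positive, got {parts[2]!r}"
                    )
            g.add_edge(parts[0], parts[1], w)
    if g.n_nodes == 0:
        raise ParseError(f"{path}: empty graph (no edges found)")
    return g


def write_edge_list(g: WeightedGraph, path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for u, v, w in g.edges():
            if w == 1.0:
                fh.write(f"{u}{delimiter}{v}\n")
            else:
                fh.write(f"{u}{delimiter}{v}{delimiter}{w:g}\n")


# ---------------------------------------------------------------------------
# hierarchy files


def _canonical_names(h) -> dict[str, str]:
    """Map internal vertex ids to output names.

    Communities are named ``C<i>`` with ``i`` zero-padded, assigned after
    sorting by (descending size, lexicographic smallest member); the root
    is always named ``root``.  This makes outputs deterministic regardless
    of construction order.
    """
    comms = [v for v in h.vertices() if v != h.root]
    keyed = sorted(
        comms, key=lambda v: (-len(h.members[v]), min(h.members[v]) if h.members[v] else "")
    )
    width = len(str(len(keyed))) if keyed else 1
    names = {h.root: "root"}
    for i, v in enumerate(keyed, 1):
        names[v] = f"C{i:0{width}d}"
    return names


def write_hierarchy(h, prefix) -> tuple[str, str]:
    """Write a hierarchy as ``<prefix>.nodes`` and ``<prefix>.edges`` TSVs.

    The nodes table has columns [name, size, members (comma-joined,
    sorted), persistence]; the edges table has [parent, child].
    """
    names = _canonical_names(h)
    nodes_path, edges_path = f"{prefix}.nodes", f"{prefix}.edges"
    order = [h.root] + sorted((v for v in h.vertices() if v != h.root), key=lambda v: names[v])
    with open(nodes_path, "w") as fh:
        for v in order:
            members = ",".join(sorted(h.members[v]))
            fh.write(f"{names[v]}\t{len(h.members[v])}\t{members}\t{h.persistence[v]}\n")
    with open(edges_path, "w") as fh:
        for parent, child in sorted((names[a], names[b]) for a, b in h.edges):
            fh.write(f"{parent}\t{child}\n")
    return nodes_path, edges_path


def read_hierarchy(prefix):
    """Read back a hierarchy written by :func:`write_hierarchy`."""
    from .hierarchy import HierarchyDAG

    members: dict[str, frozenset] = {}
    persistence: dict[str, int] = {}
    with open(f"{prefix}.nodes") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{prefix}.nodes, line {lineno}: expected 4 columns")
            name, size, mems, pers = parts
            members[name] = frozenset(mems.split(",")) if mems else frozenset()
            if len(members[name]) != int(size):
                raise ParseError(
                    f"{prefix}.nodes, line {lineno}: size {size} != member count"
                )
            persistence[name] = int(float(pers))
    edges: set[tuple[str, str]] = set()
    with open(f"{prefix}.edges") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{prefix}.edges, line {lineno}: expected 2 columns")
            edges.add((parts[0], parts[1]))
    if "root" not in members:
        raise ParseError(f"{prefix}.nodes: missing root vertex")
    return HierarchyDAG(members=members, persistence=persistence, edges=edges, root="root")


def write_gml(h, path) -> None:
    """Export a hierarchy as a GML file (single-file alternative)."""
    import networkx as nx

    g = h.to_networkx()
    out = nx.DiGraph()
    for v, data in g.nodes(data=True):
        out.add_node(v, size=len(data["members"]), persistence=int(data["persistence"]),
                     members=",".join(sorted(data["members"])))
    out.add_edges_from(g.edges())
    nx.write_gml(out, path)


# ---------------------------------------------------------------------------
# label tables and embeddings


def read_labels(path, delimiter: str = "\t") -> dict[str, set[str]]:
    """Read a two-column (node, label) TSV into label -> node-set form."""
    refs: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2:
                raise ParseError(f"{path}, line {lineno}: expected >= 2 columns")
            node, label = parts[0], parts[1]
            refs.setdefault(label, set()).add(node)
    if not refs:
        raise ParseError(f"{path}: no labels found")
    return refs


def read_embeddings(path, delimiter: str = "\t") -> tuple[list[str], np.ndarray]:
    """Read an embedding TSV (first column node name, rest coordinates)."""
    names: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2:
                raise ParseError(f"{path}, line {lineno}: expected node + coordinates")
            names.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: non-numeric coordinate") from exc
    if not names:
        raise ParseError(f"{path}: empty embedding file")
    mat = np.asarray(rows, dtype=float)
    if mat.ndim != 2 or len({len(r) for r in rows}) != 1:
        raise ParseError(f"{path}: rows have inconsistent dimensionality")
    return names, mat
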