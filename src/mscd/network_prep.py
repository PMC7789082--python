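"""Input-preparation utilities: seed expansion, enrichment, SNN graphs.

These cover the standard pre/post-processing around the core pipeline:
growing a subnetwork around a seed list (e.g. virus-interacting host
proteins), testing communities for seed enrichment with an odds ratio,
and turning an embedding matrix into a shared-nearest-neighbor (SNN)
similarity graph suitable as pipeline input.
"""

from __future__ import annotations

import logging
from typing import Iterable, NamedTuple

import numpy as np

from .graph_io import WeightedGraph

logger = logging.getLogger("mscd")

__all__ = [
    "expand_seed_subnetwork",
    "seed_enrichment_odds_ratio",
    "EnrichmentResult",
    "build_snn_graph",
]

ENRICHMENT_ODDS_THRESHOLD = 1.5


def expand_seed_subnetwork(
    g: WeightedGraph, seeds: Iterable[str], min_links: int = 2
) -> WeightedGraph:
    """Induced subgraph on seeds plus well-connected non-seed neighbors.

    Keeps every seed present in the graph and every non-seed node adjacent
    to at least ``min_links`` distinct seeds; returns the induced subgraph
    (isolated seeds are retained).  Seeds absent from the graph are logged
    and ignored.
    """
    if min_links < 1:
        raise ValueError("min_links must be >= 1")
    seeds = set(seeds)
    present = {s for s in seeds if s in g}
    missing = len(seeds) - len(present)
    if missing:
        logger.warning("%d seed nodes not found in the graph; ignored", missing)
    keep = set(present)
    for node in g.nodes:
        if node in present:
            continue
        n_seed_nbrs = sum(1 for nb in g.neighbors(node) if nb in present)
        if n_seed_nbrs >= min_links:
            keep.add(node)
    if not keep:
        raise ValueError("seed expansion produced an empty subnetwork")
    return g.subgraph(keep)


class EnrichmentResult(NamedTuple):
    odds_ratio: float
    enriched: bool
    table: tuple  # (a, b, c, d) possibly Haldane-corrected


def seed_enrichment_odds_ratio(
    community: Iterable[str], seeds: Iterable[str], universe: Iterable[str]
) -> EnrichmentResult:
    """Odds ratio of seed membership inside vs outside a community.

    2x2 table: a = seeds in community, b = non-seeds in community,
    c = seeds outside, d = non-seeds outside.  When any cell is zero the
    Haldane correction (+0.5 to every cell) is applied (logged).  The
    ``enriched`` flag uses the conventional odds-ratio > 1.5 cutoff.
    """
    community, seeds, universe = set(community), set(seeds), set(universe)
    if not community:
        raise ValueError("community must be nonempty")
    if not community <= universe:
        raise ValueError("community must be a subset of the universe")
    a = len(community & seeds)
    b = len(community - seeds)
    c = len((seeds & universe) - community)
    d = len(universe - community - seeds)
    cells = (a, b, c, d)
    if 0 in cells:
        logger.info("zero cell in contingency table %s: applying Haldane correction", cells)
        cells = tuple(x + 0.5 for x in cells)
    a, b, c, d = cells
    odds = (a * d) / (b * c)
    return EnrichmentResult(odds_ratio=float(odds), enriched=odds > ENRICHMENT_ODDS_THRESHOLD, table=cells)


def build_snn_graph(
    embeddings, k: int = 20, prune: float = 1.0 / 15.0
) -> WeightedGraph:
    """Shared-nearest-neighbor graph from a node embedding.

    ``embeddings`` is either a mapping node -> vector or a pair
    (names, matrix).  Each node's neighborhood is itself plus its k
    nearest neighbors by Euclidean distance; the SNN weight of a node
    pair is the Jaccard overlap of their neighborhoods, and edges with
    weight below ``prune`` are discarded (Seurat-style defaults k = 20,
    prune = 1/15).
    """
    from scipy import sparse
    from sklearn.neighbors import NearestNeighbors

    if isinstance(embeddings, dict):
        names = list(embeddings)
        mat = np.asarray([embeddings[n] for n in names], dtype=float)
    else:
        names, mat = embeddings
        mat = np.asarray(mat, dtype=float)
    n = len(names)
    if n < 2:
        raise ValueError("need at least 2 embedded nodes")
    if n < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} nodes, got {n}")
    if mat.ndim != 2 or mat.shape[0] != n:
        raise ValueError("embedding matrix shape does not match node count")

    nn = NearestNeighbors(n_neighbors=k + 1).fit(mat)
    _, idx = nn.kneighbors(mat)  # row i: i itself plus k nearest (self excluded below)
    neigh = np.empty((n, k + 1), dtype=int)
    for i in range(n):
        row = [j for j in idx[i] if j != i][:k]
        neigh[i] = [i] + row

    indptr = np.arange(0, (n + 1) * (k + 1), k + 1)
    data = np.ones(n * (k + 1))
    B = sparse.csr_matrix((data, neigh.ravel(), indptr), shape=(n, n))
    inter = (B @ B.T).tocoo()

    g = WeightedGraph(nodes=names)
    set_size = k + 1
    for i, j, c in zip(inter.row, inter.col, inter.data):
        if i >= j:
            continue
        w = c / (2 * set_size - c)
        if w >= prune:
            g.add_edge(names[i], names[j], float(w))
    return g
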