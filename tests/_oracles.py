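"""Independent brute-force oracles used to validate the implementation."""

from __future__ import annotations

import itertools

import numpy as np

from mscd.graph_io import WeightedGraph
from mscd.resolution_sweep import Partition


def set_partitions(items):
    """Yield every partition of ``items`` (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def modularity_pairsum(g: WeightedGraph, labels, gamma: float) -> float:
    """Naive O(n^2) ordered-pair evaluation of generalized modularity."""
    n = g.n_nodes
    A = np.zeros((n, n))
    for iu, iv, w in g.edges_indexed():
        A[iu, iv] = A[iv, iu] = w
    k = A.sum(axis=1)
    m = A.sum() / 2.0
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i, j] - gamma * k[i] * k[j] / (2.0 * m)
    return q


def best_partition_bruteforce(g: WeightedGraph, gamma: float):
    """Exhaustive-search modularity optimum over all partitions (tiny n)."""
    best_q, best_labels = -np.inf, None
    for blocks in set_partitions(range(g.n_nodes)):
        labels = np.empty(g.n_nodes, dtype=int)
        for lab, block in enumerate(blocks):
            for i in block:
                labels[i] = lab
        q = modularity_pairsum(g, labels, gamma)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels


def labels_to_blocks(labels) -> set[frozenset]:
    blocks: dict[int, set] = {}
    for i, lab in enumerate(labels):
        blocks.setdefault(int(lab), set()).add(i)
    return {frozenset(b) for b in blocks.values()}


def reachability_matrix(n_vertices: int, edges) -> np.ndarray:
    """All-pairs reachability by repeated squaring of the adjacency closure."""
    R = np.zeros((n_vertices, n_vertices), dtype=bool)
    for a, b in edges:
        R[a, b] = True
    for _ in range(n_vertices):
        nxt = R | (R @ R)
        if (nxt == R).all():
            break
        R = nxt
    return R


def bfs_components(n_items: int, edges) -> set[frozenset]:
    """Connected components of an undirected relation, by plain BFS."""
    adj: dict[int, list[int]] = {i: [] for i in range(n_items)}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    seen, comps = set(), set()
    for start in range(n_items):
        if start in seen:
            continue
        comp, stack = set(), [start]
        seen.add(start)
        while stack:
            x = stack.pop()
            comp.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        comps.add(frozenset(comp))
    return comps


def brute_force_average_f1(refs: dict, detected: list) -> float:
    """Double loop over (reference, detected) pairs, max per reference."""
    total = 0.0
    for ref in refs.values():
        best = 0.0
        for det in detected:
            inter = len(set(ref) & set(det))
            if inter == 0 or not det:
                score = 0.0
            else:
                p, r = inter / len(det), inter / len(ref)
                score = 2 * p * r / (p + r)
            best = max(best, score)
        total += best
    return total / len(refs)


def random_multicomponent_graph(rng: np.random.Generator, n_components: int) -> WeightedGraph:
    """Random graph with exactly ``n_components`` connected components."""
    g = WeightedGraph()
    offset = 0
    for c in range(n_components):
        size = int(rng.integers(3, 9))
        names = [f"c{c}_{i}" for i in range(size)]
        # spanning path guarantees connectivity, then random extra edges
        for i in range(size - 1):
            g.add_edge(names[i], names[i + 1])
        for _ in range(int(rng.integers(0, size))):
            i, j = rng.integers(size, size=2)
            if i != j and not g.has_edge(names[i], names[j]):
                g.add_edge(names[int(i)], names[int(j)])
        offset += size
    return g
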