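"""Planted two-level benchmark graphs (LFR-style) with ground truth.

Generates networks with power-law degrees and two nested levels of
planted communities: macro blocks partition the vertices and micro
blocks partition each macro block.  Two mixing fractions control how
strongly the planted structure is violated: a fraction ``mu_c`` of each
node's edge stubs leaves its macro community entirely, a further
``mu_f - mu_c`` stays inside the macro block but crosses micro
boundaries, and the remaining ``1 - mu_f`` is matched inside the node's
own micro community.  Both label maps are returned so downstream
detection can be scored against known truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .graph_io import WeightedGraph

logger = logging.getLogger("mscd")

__all__ = ["BenchmarkParams", "PlantedBenchmark", "sample_sizes", "generate_benchmark"]


@dataclass
class BenchmarkParams:
    """Benchmark generator settings.

    Defaults match the standard two-level LFR regime: 1000 vertices,
    mean degree 10 with power-law (exponent 2) tail truncated at 40,
    micro community sizes 5-20 and macro sizes 50-100 drawn from a
    power law with exponent 1 (so sizes within a level are comparable).
    """

    n: int = 1000
    k_avg: float = 10.0
    k_max: int = 40
    min_micro: int = 5
    max_micro: int = 20
    min_macro: int = 50
    max_macro: int = 100
    t1: float = 2.0
    t2: float = 1.0
    mu_c: float = 0.1
    mu_f: float = 0.2
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0 < self.min_micro <= self.max_micro <= self.min_macro <= self.max_macro <= self.n):
            raise ValueError("size bounds must satisfy minc <= maxc <= minC <= maxC <= N")
        if not (0 <= self.mu_c <= self.mu_f < 1):
            raise ValueError("mixing fractions must satisfy 0 <= mu_c <= mu_f < 1")
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("power-law exponents must be positive")
        if self.k_avg <= 1 or self.k_max < self.k_avg:
            raise ValueError("need k_avg > 1 and k_max >= k_avg")


@dataclass
class PlantedBenchmark:
    """Generated graph plus ground-truth labels at both levels."""

    graph: WeightedGraph
    macro_labels: dict[str, int]
    micro_labels: dict[str, int]

    def label_sets(self, level: str) -> dict[str, set[str]]:
        labels = self.macro_labels if level == "macro" else self.micro_labels
        out: dict[str, set[str]] = {}
        for node, lab in labels.items():
            out.setdefault(f"{level}{lab}", set()).add(node)
        return out


def _power_draw(rng: np.random.Generator, lo: float, hi: float, exponent: float, size=None):
    """Inverse-CDF draw from a continuous power law p(x) ~ x^-exponent on [lo, hi]."""
    u = rng.random(size)
    if abs(exponent - 1.0) < 1e-12:
        return lo * (hi / lo) ** u
    a = 1.0 - exponent
    return (lo**a + u * (hi**a - lo**a)) ** (1.0 / a)


def sample_sizes(total: int, smin: int, smax: int, exponent: float, rng) -> list[int]:
    """Community sizes from a truncated power law, summing exactly to total.

    Sizes are drawn from p(s) ~ s^-exponent on [smin, smax]; the draw is
    constrained so the remainder always stays reachable, and any final
    deficit smaller than ``smin`` is redistributed over earlier sizes
    within bounds.
    """
    if smin > smax or smin <= 0:
        raise ValueError("need 0 < smin <= smax")
    if total < smin:
        raise ValueError(f"total {total} smaller than minimum size {smin}")
    sizes: list[int] = []
    remaining = total
    attempts = 0
    while remaining > 0:
        if remaining <= smax:
            if remaining >= smin:
                sizes.append(remaining)
                remaining = 0
            else:
                # remainder too small to be a community: spread it out
                deficit = remaining
                remaining = 0
                for i in range(len(sizes)):
                    add = min(smax - sizes[i], deficit)
                    sizes[i] += add
                    deficit -= add
                    if deficit == 0:
                        break
                if deficit > 0:
                    raise ValueError(
                        f"cannot partition {total} into sizes within [{smin}, {smax}]"
                    )
            break
        s = int(_power_draw(rng, smin, smax + 1 - 1e-9, exponent))
        s = min(max(s, smin), smax)
        if remaining - s >= smin or remaining - s == 0:
            sizes.append(s)
            remaining -= s
            attempts = 0
        else:
            attempts += 1
            if attempts > 1000:
                s = remaining - smin
                sizes.append(min(max(s, smin), smax))
                remaining -= sizes[-1]
                attempts = 0
    return sizes


def _sample_degrees(params: BenchmarkParams, rng: np.random.Generator) -> np.ndarray:
    """Integer degrees from a truncated power law with mean ~ k_avg.

    The lower truncation bound is solved by bisection so the continuous
    truncated law has mean k_avg, then degrees are rounded and clipped.
    """
    hi = float(params.k_max)
    alpha = params.t1

    def mean_of(lo: float) -> float:
        if abs(alpha - 2.0) < 1e-12:
            c = 1.0 / (1.0 / lo - 1.0 / hi)
            return c * np.log(hi / lo)
        if abs(alpha - 1.0) < 1e-12:
            return (hi - lo) / np.log(hi / lo)
        a1, a2 = 1.0 - alpha, 2.0 - alpha
        return (a1 / a2) * (hi**a2 - lo**a2) / (hi**a1 - lo**a1)

    lo_lo, lo_hi = 1.0, hi - 1e-6
    if mean_of(lo_lo) > params.k_avg:
        lo = lo_lo
    else:
        for _ in range(100):
            mid = 0.5 * (lo_lo + lo_hi)
            if mean_of(mid) < params.k_avg:
                lo_lo = mid
            else:
                lo_hi = mid
        lo = 0.5 * (lo_lo + lo_hi)
    draws = _power_draw(rng, lo, hi, alpha, size=params.n)
    degrees = np.clip(np.rint(draws).astype(int), 1, params.k_max)
    return degrees


def _match_degree_sequence(
    nodes: np.ndarray, targets: np.ndarray, rng: np.random.Generator
) -> tuple[list[tuple[int, int]], int]:
    """Realize a simple graph on ``nodes`` with degrees close to ``targets``.

    Havel-Hakimi greedy construction (targets clipped to pool size - 1,
    parity fixed on the largest target), followed by randomizing
    double-edge swaps that preserve the degree sequence.  Returns the
    edges and the number of target stubs that could not be realized.
    Dense pools (nearly complete subgraphs) are matched exactly where
    random stub pairing would thrash.
    """
    n = len(nodes)
    want = int(targets.sum())
    d = np.minimum(targets.astype(int), n - 1)
    if d.sum() % 2:
        d[int(np.argmax(d))] -= 1
    adj: list[set[int]] = [set() for _ in range(n)]
    residual = d.copy()
    while True:
        i = int(np.argmax(residual))
        if residual[i] <= 0:
            break
        # connect i to the residual[i] highest-residual non-neighbors
        order = sorted(
            (j for j in range(n) if j != i and j not in adj[i] and residual[j] > 0),
            key=lambda j: -residual[j],
        )
        picks = order[: residual[i]]
        if not picks:
            residual[i] = 0  # unrealizable remainder
            continue
        for j in picks:
            adj[i].add(j)
            adj[j].add(i)
            residual[j] -= 1
        residual[i] -= len(picks)
    edges = {(i, j) for i in range(n) for j in adj[i] if i < j}
    # degree-preserving double-edge swaps to randomize the deterministic greedy
    edge_list = list(edges)
    for _ in range(4 * len(edge_list)):
        if len(edge_list) < 2:
            break
        a, b = rng.integers(len(edge_list), size=2)
        if a == b:
            continue
        (u, v), (x, y) = edge_list[a], edge_list[b]
        if rng.random() < 0.5:
            x, y = y, x
        if len({u, v, x, y}) < 4:
            continue
        if x in adj[u] or y in adj[v]:
            continue
        adj[u].discard(v); adj[v].discard(u)
        adj[x].discard(y); adj[y].discard(x)
        adj[u].add(x); adj[x].add(u)
        adj[v].add(y); adj[y].add(v)
        edge_list[a] = (min(u, x), max(u, x))
        edge_list[b] = (min(v, y), max(v, y))
    out = [(int(nodes[i]), int(nodes[j])) for i, j in edge_list]
    return out, want - 2 * len(edge_list)


def _pair_stubs(
    stubs: list[int],
    rng: np.random.Generator,
    edge_set: set[tuple[int, int]],
    forbid_same: dict[int, int] | None = None,
    max_passes: int = 20,
) -> tuple[list[tuple[int, int]], int]:
    """Randomly pair stubs avoiding self-loops, multi-edges and (optionally)
    pairs whose endpoints share a group in ``forbid_same``.

    Returns the new edges and the number of stubs that could not be
    matched (dropped).
    """
    pool = list(stubs)
    edges: list[tuple[int, int]] = []
    for _ in range(max_passes):
        if len(pool) < 2:
            break
        rng.shuffle(pool)
        leftover: list[int] = []
        i = 0
        while i + 1 < len(pool):
            u, v = pool[i], pool[i + 1]
            i += 2
            if u == v:
                leftover.extend((u, v))
                continue
            if forbid_same is not None and forbid_same[u] == forbid_same[v]:
                leftover.extend((u, v))
                continue
            key = (min(u, v), max(u, v))
            if key in edge_set:
                leftover.extend((u, v))
                continue
            edge_set.add(key)
            edges.append(key)
        if i < len(pool):
            leftover.append(pool[i])
        if len(leftover) == len(pool):  # no progress possible
            pool = leftover
            break
        pool = leftover
    return edges, len(pool)


def generate_benchmark(params: BenchmarkParams) -> PlantedBenchmark:
    """Generate a planted two-level benchmark network.

    Each node's degree is split into within-micro, within-macro (but
    cross-micro) and external stub counts by rounding ``mu_c * k`` and
    ``(mu_f - mu_c) * k``, with the rounding remainder going to the
    within-micro pool.  Stubs are matched at random inside their pool;
    stubs that cannot be matched without self-loops or multi-edges (for
    example when a hub exceeds its micro community's capacity) are
    dropped and counted in the log.
    """
    rng = np.random.default_rng(params.seed)

    macro_sizes = sample_sizes(params.n, params.min_macro, params.max_macro, params.t2, rng)
    micro_of_macro: list[list[int]] = [
        sample_sizes(s, params.min_micro, params.max_micro, params.t2, rng)
        for s in macro_sizes
    ]

    # flat list of micro communities with their macro id and capacity
    micro_macro: list[int] = []
    micro_size: list[int] = []
    for mac, sizes in enumerate(micro_of_macro):
        for s in sizes:
            micro_macro.append(mac)
            micro_size.append(s)

    degrees = _sample_degrees(params, rng)
    ext = np.rint(params.mu_c * degrees).astype(int)
    cross = np.rint((params.mu_f - params.mu_c) * degrees).astype(int)
    within = degrees - ext - cross  # rounding remainder -> within-micro pool

    # assign nodes to micro communities, hubs first, preferring communities
    # that can still absorb the node's within-micro stubs
    order = np.argsort(-within, kind="stable")
    slots = list(micro_size)
    micro_label = np.full(params.n, -1, dtype=int)
    open_micro = set(range(len(slots)))
    for node in order:
        feasible = [c for c in open_micro if micro_size[c] - 1 >= within[node]]
        candidates = feasible if feasible else list(open_micro)
        # among candidates prefer the roomiest, break ties randomly
        max_slot = max(slots[c] for c in candidates)
        best = [c for c in candidates if slots[c] == max_slot]
        choice = best[rng.integers(len(best))]
        micro_label[node] = choice
        slots[choice] -= 1
        if slots[choice] == 0:
            open_micro.discard(choice)
    macro_label = np.array([micro_macro[c] for c in micro_label])

    edge_set: set[tuple[int, int]] = set()
    all_edges: list[tuple[int, int]] = []
    dropped = 0

    # within-micro pools: dense, so realize the degree sequence directly
    for c in range(len(micro_size)):
        nodes_c = np.flatnonzero(micro_label == c)
        edges, lost = _match_degree_sequence(nodes_c, within[nodes_c], rng)
        for u, v in edges:
            edge_set.add((min(u, v), max(u, v)))
        all_edges.extend(edges)
        dropped += lost

    # within-macro, cross-micro pools
    micro_map = {i: int(micro_label[i]) for i in range(params.n)}
    for mac in range(len(macro_sizes)):
        nodes_m = np.flatnonzero(macro_label == mac)
        stubs = [int(v) for v in nodes_m for _ in range(cross[v])]
        edges, lost = _pair_stubs(stubs, rng, edge_set, forbid_same=micro_map)
        all_edges.extend(edges)
        dropped += lost

    # external pool, cross-macro
    macro_map = {i: int(macro_label[i]) for i in range(params.n)}
    stubs = [int(v) for v in range(params.n) for _ in range(ext[v])]
    edges, lost = _pair_stubs(stubs, rng, edge_set, forbid_same=macro_map)
    all_edges.extend(edges)
    dropped += lost

    if dropped:
        logger.info("benchmark: dropped %d unmatched stubs (of %d)", dropped, int(degrees.sum()))

    names = [f"v{i}" for i in range(params.n)]
    graph = WeightedGraph(nodes=names, edges=[(names[u], names[v]) for u, v in all_edges])
    return PlantedBenchmark(
        graph=graph,
        macro_labels={names[i]: int(macro_label[i]) for i in range(params.n)},
        micro_labels={names[i]: int(micro_label[i]) for i in range(params.n)},
    )
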