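"""Phase I: log-uniform resolution sampling and per-resolution detection.

The resolution parameter gamma multiplies the configuration-model null
term of the generalized modularity

    Q(G, gamma) = sum_ij (A_ij - gamma * k_i k_j / 2m) * delta(i, j)

so larger gamma favors smaller communities.  Resolutions are sampled
densely enough on a log10 grid that every interior point has at least
``min_proximal`` gamma-proximal neighbors (|log10 ratio| < 0.1 decades),
which is what makes cross-resolution community matching in Phase II
meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graph_io import RunConfig, WeightedGraph

logger = logging.getLogger("mscd")

__all__ = [
    "ResolutionGrid",
    "Partition",
    "ResolutionProfile",
    "sample_resolutions",
    "generalized_modularity",
    "detect_partition",
    "sweep",
]

# strictness guard for |dlog10| < radius comparisons on a float grid
_STRICT = 1.0 - 1e-9


@dataclass(frozen=True)
class ResolutionGrid:
    """Sorted resolutions with the gamma-proximity relation."""

    gammas: np.ndarray
    log10_gammas: np.ndarray
    proximity_radius: float = 0.1
    min_proximal: int = 10

    def __len__(self) -> int:
        return len(self.gammas)

    def proximal(self, i: int, j: int) -> bool:
        """True when grid points i and j are gamma-proximal (and distinct)."""
        return i != j and (
            abs(self.log10_gammas[i] - self.log10_gammas[j])
            < self.proximity_radius * _STRICT
        )

    def proximal_pairs(self) -> list[tuple[int, int]]:
        """All index pairs (i < j) of distinct gamma-proximal resolutions."""
        L = self.log10_gammas
        pairs = []
        for i in range(len(L)):
            j = i + 1
            while j < len(L) and L[j] - L[i] < self.proximity_radius * _STRICT:
                pairs.append((i, j))
                j += 1
        return pairs

    def n_proximal(self, i: int) -> int:
        L = self.log10_gammas
        r = self.proximity_radius * _STRICT
        lo = np.searchsorted(L, L[i] - r, side="right")
        hi = np.searchsorted(L, L[i] + r, side="left")
        return int(hi - lo - 1)


@dataclass(frozen=True)
class Partition:
    """A hard partition of the graph's nodes at one resolution.

    ``labels[i]`` is the community label of node i (graph node order);
    labels are contiguous integers 0..K-1 in first-appearance order.
    """

    gamma: float
    labels: np.ndarray

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def community_indices(self) -> list[np.ndarray]:
        order = np.argsort(self.labels, kind="stable")
        bounds = np.searchsorted(self.labels[order], np.arange(self.n_communities + 1))
        return [order[bounds[k]: bounds[k + 1]] for k in range(self.n_communities)]

    def member_sets(self, g: WeightedGraph) -> list[frozenset[str]]:
        nodes = np.asarray(g.nodes, dtype=object)
        return [frozenset(nodes[idx]) for idx in self.community_indices()]


@dataclass(frozen=True)
class ResolutionProfile:
    """One detected partition per sampled resolution."""

    grid: ResolutionGrid
    partitions: list[Partition]


def _uniform_log_grid(gamma_min: float, gamma_max: float, log_step: float) -> np.ndarray:
    """Endpoint-inclusive log10-uniform grid (last point clamped)."""
    lo, hi = np.log10(gamma_min), np.log10(gamma_max)
    n = int(np.ceil((hi - lo) / log_step - 1e-9))
    if n <= 0:
        return np.array([lo])
    pts = lo + log_step * np.arange(n + 1)
    pts[-1] = hi
    return pts


def sample_resolutions(
    gamma_min: float,
    gamma_max: float,
    log_step: float = 0.02,
    proximity_radius: float = 0.1,
    min_proximal: int = 10,
) -> ResolutionGrid:
    """Sample resolutions log-uniformly, refining to honor proximal density.

    If the requested ``log_step`` leaves some interior grid point with
    fewer than ``min_proximal`` gamma-proximal neighbors, the step is
    halved until the density criterion holds (logged).  Grids too short to
    contain ``min_proximal + 1`` points, or with no interior point, are
    accepted as-is.
    """
    if gamma_min <= 0 or gamma_max <= 0:
        raise ValueError("resolution bounds must be positive")
    if gamma_min > gamma_max:
        raise ValueError("gamma_min must be <= gamma_max")
    if log_step <= 0:
        raise ValueError("log_step must be positive")

    step = float(log_step)
    for _ in range(30):
        L = _uniform_log_grid(gamma_min, gamma_max, step)
        grid = ResolutionGrid(
            gammas=10.0 ** L, log10_gammas=L,
            proximity_radius=proximity_radius, min_proximal=min_proximal,
        )
        if len(L) < min_proximal + 1:
            break
        interior = [
            i for i in range(len(L))
            if L[i] - L[0] >= proximity_radius * _STRICT
            and L[-1] - L[i] >= proximity_radius * _STRICT
        ]
        if not interior or all(grid.n_proximal(i) >= min_proximal for i in interior):
            break
        step /= 2.0
        logger.info(
            "log_step refined to %g to satisfy >= %d gamma-proximal neighbors",
            step, min_proximal,
        )
    # rebuild with exact endpoint gammas to avoid 10**log10 round-trip noise
    gammas = 10.0 ** grid.log10_gammas
    gammas[0], gammas[-1] = gamma_min, gamma_max
    return ResolutionGrid(
        gammas=gammas, log10_gammas=grid.log10_gammas,
        proximity_radius=proximity_radius, min_proximal=min_proximal,
    )


def generalized_modularity(
    g: WeightedGraph, part: Partition, gamma: float, normalized: bool = False
) -> float:
    """Reichardt-Bornholdt generalized modularity of a partition.

    Computed in the per-community aggregate form
    ``sum_c [2 * W_c - gamma * S_c^2 / (2m)]`` where ``W_c`` is the
    intra-community edge weight and ``S_c`` the summed strengths — exactly
    the double sum over ordered node pairs (diagonal included, A_ii = 0).
    The canonical value is unnormalized; ``normalized=True`` divides by 2m
    (which never changes the argmax partition).
    """
    labels = part.labels
    if len(labels) != g.n_nodes:
        raise ValueError(
            f"partition covers {len(labels)} nodes but graph has {g.n_nodes}"
        )
    m = g.total_weight
    if m <= 0:
        raise ValueError("graph has no edges (m = 0)")
    K = part.n_communities
    intra = np.zeros(K)
    for iu, iv, w in g.edges_indexed():
        if labels[iu] == labels[iv]:
            intra[labels[iu]] += w
    S = np.bincount(labels, weights=g.strengths(), minlength=K)
    q = 2.0 * intra.sum() - gamma * np.sum(S * S) / (2.0 * m)
    return q / (2.0 * m) if normalized else float(q)


def _relabel_contiguous(membership: np.ndarray) -> np.ndarray:
    """Relabel to contiguous ints in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(len(membership), dtype=int)
    for i, lab in enumerate(membership):
        out[i] = mapping.setdefault(int(lab), len(mapping))
    return out


def detect_partition(g: WeightedGraph, gamma: float, seed: int = 42) -> Partition:
    """Detect the partition maximizing generalized modularity at one gamma.

    Uses the Leiden refinement of the Louvain move/aggregate scheme under
    the Reichardt-Bornholdt configuration null.  Deterministic for a given
    (graph, gamma, seed); isolated nodes form singleton communities.
    """
    import leidenalg

    if g.n_nodes == 0:
        raise ValueError("cannot partition an empty graph")
    ig = g.to_igraph()
    kwargs = {}
    if ig.ecount() > 0:
        kwargs["weights"] = ig.es["weight"]
    part = leidenalg.find_partition(
        ig,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=float(gamma),
        seed=int(seed),
        n_iterations=2,
        **kwargs,
    )
    labels = _relabel_contiguous(np.asarray(part.membership))
    return Partition(gamma=float(gamma), labels=labels)


def _derive_seed(seed: int, i: int) -> int:
    return (seed * 69069 + 7919 * i) % (2**31 - 1)


def sweep(g: WeightedGraph, cfg: RunConfig, repeats: int = 1) -> ResolutionProfile:
    """Run community detection at every sampled resolution.

    Per-resolution seeds derive deterministically from ``cfg.seed`` and the
    grid index.  With ``repeats > 1`` the best-Q partition of that many
    independently seeded runs is kept.
    """
    if g.total_weight <= 0:
        raise ValueError("graph passed to sweep must have positive total weight")
    grid = sample_resolutions(
        cfg.gamma_min, cfg.gamma_max, cfg.log_step,
        cfg.proximity_radius, cfg.min_proximal,
    )
    logger.info("sweeping %d resolutions in [%g, %g]", len(grid), cfg.gamma_min, cfg.gamma_max)
    partitions: list[Partition] = []
    for i, gamma in enumerate(grid.gammas):
        best = None
        best_q = -np.inf
        for r in range(max(1, repeats)):
            part = detect_partition(g, gamma, _derive_seed(cfg.seed, i * 1000 + r))
            if repeats > 1:
                q = generalized_modularity(g, part, gamma)
                if q > best_q:
                    best, best_q = part, q
            else:
                best = part
        partitions.append(best)
    return ResolutionProfile(grid=grid, partitions=partitions)
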