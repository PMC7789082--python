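"""scikit-learn-style estimator wrapping the full pipeline.

``PersistentCommunityDetector`` treats the input as a precomputed
similarity/adjacency structure (square dense or sparse matrix, or a
:class:`~mscd.graph_io.WeightedGraph`) and, on :meth:`fit`, exposes the
persistent communities and their containment hierarchy as fitted
attributes.  It composes with scikit-learn model selection through the
standard ``get_params`` / ``set_params`` protocol.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator

from . import pipeline
from .graph_io import RunConfig, WeightedGraph

__all__ = ["PersistentCommunityDetector"]


def _as_weighted_graph(X) -> WeightedGraph:
    if isinstance(X, WeightedGraph):
        return X
    if sparse.issparse(X):
        X = X.tocoo()
        n = X.shape[0]
        if X.shape[0] != X.shape[1]:
            raise ValueError("adjacency matrix must be square")
        g = WeightedGraph(nodes=[str(i) for i in range(n)])
        for i, j, w in zip(X.row, X.col, X.data):
            if i < j and w != 0:
                if w < 0:
                    raise ValueError("adjacency weights must be non-negative")
                g.add_edge(str(i), str(j), float(w))
        return g
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError("adjacency matrix must be square")
    if not np.allclose(X, X.T, rtol=1e-8, atol=1e-10):
        raise ValueError("adjacency matrix must be symmetric (undirected graph)")
    if (X < 0).any():
        raise ValueError("adjacency weights must be non-negative")
    n = X.shape[0]
    g = WeightedGraph(nodes=[str(i) for i in range(n)])
    for i in range(n):
        for j in range(i + 1, n):
            if X[i, j] != 0:
                g.add_edge(str(i), str(j), float(X[i, j]))
    return g


class PersistentCommunityDetector(BaseEstimator):
    """Detect persistent multiscale communities and their hierarchy.

    Parameters mirror the pipeline configuration: the resolution range
    and log-step of the sweep, the Jaccard threshold ``tau`` linking
    similar communities across proximal resolutions, the persistence
    threshold ``chi``, the consensus membership percentage ``p_percent``,
    and the containment threshold ``sigma`` (defaults to ``tau``).

    Attributes (after ``fit``)
    --------------------------
    communities_ : list of frozenset
        Persistent community member sets (hierarchy order, root excluded).
    persistence_ : ndarray of int
        Persistence score of each community in ``communities_``.
    hierarchy_ : HierarchyDAG
        Rooted containment DAG over the communities.
    n_communities_ : int
        Number of persistent communities (root excluded).
    gammas_ : ndarray
        The sampled resolution grid.
    """

    def __init__(
        self,
        gamma_min: float = 0.001,
        gamma_max: float = 50.0,
        log_step: float = 0.02,
        proximity_radius: float = 0.1,
        min_proximal: int = 10,
        tau: float = 0.75,
        chi: int = 5,
        p_percent: float = 75.0,
        sigma: float | None = None,
        min_community_size: int = 4,
        repeats: int = 1,
        random_state: int = 42,
    ):
        self.gamma_min = gamma_min
        self.gamma_max = gamma_max
        self.log_step = log_step
        self.proximity_radius = proximity_radius
        self.min_proximal = min_proximal
        self.tau = tau
        self.chi = chi
        self.p_percent = p_percent
        self.sigma = sigma
        self.min_community_size = min_community_size
        self.repeats = repeats
        self.random_state = random_state

    def _config(self) -> RunConfig:
        return RunConfig(
            gamma_min=self.gamma_min,
            gamma_max=self.gamma_max,
            log_step=self.log_step,
            proximity_radius=self.proximity_radius,
            min_proximal=self.min_proximal,
            tau=self.tau,
            chi=self.chi,
            p_percent=self.p_percent,
            sigma=self.sigma,
            seed=self.random_state,
            min_community_size=self.min_community_size,
        )

    def fit(self, X, y=None):
        """Run the sweep/persistence/hierarchy pipeline on a graph.

        ``X`` is a square symmetric (sparse) adjacency matrix or a
        WeightedGraph; ``y`` is ignored.
        """
        g = _as_weighted_graph(X)
        if g.total_weight <= 0:
            raise ValueError("input graph has no edges")
        result = pipeline.run(g, self._config(), repeats=self.repeats)
        h = result.hierarchy
        order = h.communities()
        self.graph_ = g
        self.result_ = result
        self.hierarchy_ = h
        self.communities_ = [h.members[v] for v in order]
        self.persistence_ = np.array([h.persistence[v] for v in order], dtype=int)
        self.n_communities_ = len(order)
        self.gammas_ = result.profile.grid.gammas
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit, then label each node by its smallest containing community.

        Returns an integer label per node (-1 for nodes in no persistent
        community); a convenience flat view of the overlapping result.
        """
        self.fit(X)
        n = self.graph_.n_nodes
        labels = np.full(n, -1, dtype=int)
        # communities_ is sorted by descending persistence/size; iterate
        # smallest-last so the smallest containing community wins
        for ci in np.argsort([-len(c) for c in self.communities_], kind="stable"):
            for name in self.communities_[ci]:
                labels[self.graph_.index(name)] = ci
        return labels
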