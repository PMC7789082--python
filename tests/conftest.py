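import numpy as np
import pytest

from mscd.graph_io import WeightedGraph


@pytest.fixture
def triangle() -> WeightedGraph:
    return WeightedGraph(edges=[("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def two_triangle_bridge() -> WeightedGraph:
    """Two triangles joined by a single bridge edge (m = 7)."""
    return WeightedGraph(
        edges=[
            ("a", "b"), ("b", "c"), ("a", "c"),
            ("d", "e"), ("e", "f"), ("d", "f"),
            ("c", "d"),
        ]
    )


@pytest.fixture
def k4() -> WeightedGraph:
    return WeightedGraph(
        edges=[("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
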