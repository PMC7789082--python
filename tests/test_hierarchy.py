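import networkx as nx
import numpy as np
import pytest

from mscd.hierarchy import (
    HierarchyDAG,
    build_dag,
    containment_edges,
    containment_index,
    expand_membership,
    transitive_reduction,
)

from _oracles import reachability_matrix


def random_sets(rng, n_sets=8, universe=20, max_size=12):
    universe_items = [f"n{i}" for i in range(universe)]
    out = []
    for _ in range(n_sets):
        size = int(rng.integers(1, max_size))
        out.append(frozenset(rng.choice(universe_items, size=size, replace=False)))
    return universe_items, out


class TestContainmentIndex:
    def test_subset_gives_one(self):
        assert containment_index({"a", "b", "c"}, {"a", "b"}) == 1.0

    def test_disjoint_gives_zero(self):
        assert containment_index({"a"}, {"b"}) == 0.0

    def test_partial_overlap(self):
        v, w = {"a", "b", "c"}, {"b", "c", "d"}
        assert containment_index(v, w) == pytest.approx(2 / 3)
        assert containment_index(w, v) == pytest.approx(2 / 3)

    def test_empty_containee_rejected(self):
        with pytest.raises(ValueError):
            containment_index({"a"}, set())


class TestBuildDag:
    def test_single_community(self):
        h = build_dag([(frozenset("ab"), 6)], all_nodes="abc")
        assert h.n_communities == 1
        (c,) = h.communities()
        assert h.members[c] == frozenset("ab")
        assert h.edges == {("root", c)}
        assert h.members["root"] == frozenset("abc")
        assert h.persistence["root"] == 0

    def test_nested_chain_is_reduced(self):
        a, b, c = frozenset("abcdefgh"), frozenset("abcd"), frozenset("ab")
        h = build_dag([(a, 5), (b, 6), (c, 7)], all_nodes="abcdefghij")
        ids = {h.members[v]: v for v in h.communities()}
        assert h.edges == {
            ("root", ids[a]), (ids[a], ids[b]), (ids[b], ids[c])
        }
        assert h.depth(ids[c]) == 3

    def test_mutual_containment_merges_to_union(self):
        v, w = frozenset("abcd"), frozenset("abce")
        h = build_dag([(v, 5), (w, 9)], all_nodes="abcdefg", tau=0.75)
        assert h.n_communities == 1
        (c,) = h.communities()
        assert h.members[c] == frozenset("abcde")
        assert h.persistence[c] == 9  # max of the merged pair

    def test_exact_duplicates_merge_keeping_max_persistence(self):
        h = build_dag([(frozenset("abcd"), 5), (frozenset("abcd"), 8)], all_nodes="abcdef")
        (c,) = h.communities()
        assert h.persistence[c] == 8

    def test_equal_size_non_mutual_pairs_get_no_edge(self):
        # CI = 2/3 each way (< tau): no union, no edge between them
        v, w = frozenset("abc"), frozenset("bcd")
        with pytest.warns(UserWarning, match="sigma"):
            h = build_dag([(v, 5), (w, 5)], all_nodes="abcde", sigma=0.5, tau=0.75)
        ids = {h.members[x] for x in h.communities()}
        assert ids == {v, w}
        assert h.edges == {("root", x) for x in h.communities()}

    def test_every_vertex_reachable_and_parented(self, rng):
        for _ in range(20):
            universe, sets = random_sets(rng)
            h = build_dag({s: 5 for s in sets}.items(), all_nodes=universe)
            h.validate()
            for v in h.communities():
                assert len(h.parents(v)) >= 1
            # depth-1 vertices are exactly those whose sole parent is root
            for v in h.communities():
                if h.depth(v) == 1:
                    assert h.parents(v) == ["root"]

    def test_child_members_subset_of_parent_after_expansion(self, rng):
        for _ in range(20):
            universe, sets = random_sets(rng)
            h = build_dag({s: 5 for s in sets}.items(), all_nodes=universe)
            for a, b in h.edges:
                assert h.members[b] <= h.members[a]
                assert containment_index(h.members[a], h.members[b]) == 1.0


class TestAcyclicity:
    def test_sigma_bound_guarantees_acyclic_relation(self, rng):
        """With pairwise J < tau, sigma = 2 tau/(1+tau) forbids cycles even
        without the size-ordering rule."""
        tau = 0.75
        sigma = 2 * tau / (1 + tau)
        for _ in range(200):
            _, candidates = random_sets(rng, n_sets=10)
            kept = []
            for s in candidates:
                if all(
                    len(s & t) / len(s | t) < tau for t in kept
                ):
                    kept.append(s)
            edges = containment_edges(kept, sigma, require_larger_parent=False)
            g = nx.DiGraph()
            g.add_nodes_from(range(len(kept)))
            g.add_edges_from(edges)
            assert nx.is_directed_acyclic_graph(g)

    def test_relaxed_sigma_full_build_is_acyclic(self, rng):
        for _ in range(200):
            universe, sets = random_sets(rng)
            h = build_dag({s: 5 for s in sets}.items(), all_nodes=universe,
                          sigma=0.75, tau=0.75)
            assert h.is_acyclic()


def make_dag(n, edges):
    return HierarchyDAG(
        members={f"v{i}": frozenset({f"n{i}"}) for i in range(n)},
        persistence={f"v{i}": 1 for i in range(n)},
        edges={(f"v{a}", f"v{b}") for a, b in edges},
        root="v0",
    )


class TestTransitiveReduction:
    def test_textbook_triangle(self):
        h = make_dag(3, [(0, 1), (1, 2), (0, 2)])
        r = transitive_reduction(h)
        assert r.edges == {("v0", "v1"), ("v1", "v2")}

    def test_idempotent(self):
        h = make_dag(4, [(0, 1), (1, 2), (0, 2), (0, 3)])
        once = transitive_reduction(h)
        twice = transitive_reduction(once)
        assert once.edges == twice.edges

    def test_cyclic_input_rejected(self):
        h = make_dag(2, [(0, 1), (1, 0)])
        with pytest.raises(ValueError):
            transitive_reduction(h)

    def test_preserves_reachability_on_random_dags(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 12))
            edges = [
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.35
            ]
            h = make_dag(n, edges)
            r = transitive_reduction(h)
            idx = {f"v{i}": i for i in range(n)}
            before = reachability_matrix(n, [(idx[a], idx[b]) for a, b in h.edges])
            after = reachability_matrix(n, [(idx[a], idx[b]) for a, b in r.edges])
            assert (before == after).all()
            assert r.edges <= h.edges


class TestExpandMembership:
    def test_parent_absorbs_child(self):
        h = HierarchyDAG(
            members={"p": frozenset("ab"), "c": frozenset("bc")},
            persistence={"p": 1, "c": 1},
            edges={("p", "c")},
            root="p",
        )
        e = expand_membership(h)
        assert e.members["p"] == frozenset("abc")

    def test_chain_of_disjoint_singletons(self):
        h = HierarchyDAG(
            members={"x": frozenset("a"), "y": frozenset("b"), "z": frozenset("c")},
            persistence={"x": 1, "y": 1, "z": 1},
            edges={("x", "y"), ("y", "z")},
            root="x",
        )
        e = expand_membership(h)
        assert e.members["x"] == frozenset("abc")
        assert e.members["y"] == frozenset("bc")
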