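import numpy as np
import pytest

from mscd.benchmark_sim import BenchmarkParams, generate_benchmark
from mscd.evaluation import average_f1
from mscd.graph_io import RunConfig, WeightedGraph
from mscd.resolution_sweep import (
    Partition,
    _uniform_log_grid,
    detect_partition,
    generalized_modularity,
    sample_resolutions,
    sweep,
)

from _oracles import (
    best_partition_bruteforce,
    labels_to_blocks,
    modularity_pairsum,
    random_multicomponent_graph,
)


class TestSampleResolutions:
    def test_equal_bounds_degenerate(self):
        grid = sample_resolutions(1, 1, 0.02, 0.1, 10)
        np.testing.assert_allclose(grid.gammas, [1.0])

    def test_uniform_grid_point_count(self):
        # log10 span of [1e-3, 50] is ~4.699 decades: 235 steps of 0.02 + 1
        assert len(_uniform_log_grid(0.001, 50, 0.02)) == 236

    def test_refinement_to_meet_proximal_density(self):
        # step 0.02 gives interior points only 8 strict neighbors within
        # 0.1 decades; one halving (step 0.01) gives 18
        grid = sample_resolutions(0.001, 50, 0.02, 0.1, 10)
        assert len(grid) == 471
        L = grid.log10_gammas
        interior = [
            i for i in range(len(L)) if L[i] - L[0] >= 0.1 - 1e-12 and L[-1] - L[i] >= 0.1 - 1e-12
        ]
        counts = {grid.n_proximal(i) for i in interior}
        assert counts == {18}

    def test_proximal_counts_match_brute_force(self):
        grid = sample_resolutions(0.1, 10, 0.03, 0.1, 4)
        L = grid.log10_gammas
        for i in range(len(L)):
            brute = sum(
                1 for j in range(len(L)) if j != i and abs(L[j] - L[i]) < 0.1 * (1 - 1e-9)
            )
            assert grid.n_proximal(i) == brute

    def test_proximal_pairs_cross_different_gammas_only(self):
        grid = sample_resolutions(0.1, 10, 0.05, 0.1, 2)
        for i, j in grid.proximal_pairs():
            assert i < j
            assert abs(grid.log10_gammas[i] - grid.log10_gammas[j]) < 0.1

    def test_endpoints_exact(self):
        grid = sample_resolutions(0.001, 50, 0.02)
        assert grid.gammas[0] == 0.001 and grid.gammas[-1] == 50.0
        assert (np.diff(grid.gammas) > 0).all()

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            sample_resolutions(0, 1)
        with pytest.raises(ValueError):
            sample_resolutions(2, 1)


class TestGeneralizedModularity:
    def test_single_community_at_unit_resolution_is_zero(self, two_triangle_bridge):
        part = Partition(1.0, np.zeros(6, dtype=int))
        assert generalized_modularity(two_triangle_bridge, part, 1.0) == pytest.approx(0.0)

    def test_triangle_singletons(self, triangle):
        part = Partition(1.0, np.arange(3))
        assert generalized_modularity(triangle, part, 1.0) == pytest.approx(-2.0)

    def test_two_triangle_bridge_value(self, two_triangle_bridge):
        part = Partition(1.0, np.array([0, 0, 0, 1, 1, 1]))
        assert generalized_modularity(two_triangle_bridge, part, 1.0) == pytest.approx(5.0)

    def test_matches_pair_loop_oracle_on_random_weighted_graphs(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 20))
            g = WeightedGraph(nodes=[str(i) for i in range(n)])
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        g.add_edge(str(i), str(j), float(rng.uniform(0.1, 3.0)))
            if g.total_weight == 0:
                continue
            labels = rng.integers(0, 3, size=n)
            labels = np.unique(labels, return_inverse=True)[1]
            gamma = float(rng.uniform(0.1, 5.0))
            part = Partition(gamma, labels)
            assert generalized_modularity(g, part, gamma) == pytest.approx(
                modularity_pairsum(g, labels, gamma), abs=1e-9
            )

    def test_normalized_variant_divides_by_2m(self, two_triangle_bridge):
        part = Partition(1.0, np.array([0, 0, 0, 1, 1, 1]))
        q = generalized_modularity(two_triangle_bridge, part, 1.0)
        qn = generalized_modularity(two_triangle_bridge, part, 1.0, normalized=True)
        assert qn == pytest.approx(q / 14.0)

    def test_node_count_mismatch_rejected(self, triangle):
        with pytest.raises(ValueError):
            generalized_modularity(triangle, Partition(1.0, np.zeros(4, dtype=int)), 1.0)


class TestDetectPartition:
    def test_low_gamma_recovers_connected_components(self):
        g = WeightedGraph(edges=[("a", "b"), ("b", "c"), ("x", "y"), ("y", "z")])
        part = detect_partition(g, 0.001, seed=1)
        assert labels_to_blocks(part.labels) == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_two_triangle_bridge_attains_global_optimum(self, two_triangle_bridge):
        part = detect_partition(two_triangle_bridge, 1.0, seed=3)
        best_q, best_labels = best_partition_bruteforce(two_triangle_bridge, 1.0)
        assert labels_to_blocks(part.labels) == labels_to_blocks(best_labels)
        assert generalized_modularity(two_triangle_bridge, part, 1.0) == pytest.approx(best_q)

    def test_k4_single_community_is_optimal(self, k4):
        part = detect_partition(k4, 1.0, seed=5)
        assert part.n_communities == 1
        best_q, _ = best_partition_bruteforce(k4, 1.0)
        assert generalized_modularity(k4, part, 1.0) == pytest.approx(best_q)

    def test_near_optimal_on_random_tiny_graphs(self, rng):
        """Detected Q reaches >= 95% of the exhaustive-search optimum."""
        for trial in range(10):
            n = int(rng.integers(4, 8))
            g = WeightedGraph(nodes=[str(i) for i in range(n)])
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.6:
                        g.add_edge(str(i), str(j))
            if g.total_weight == 0:
                continue
            gamma = float(rng.uniform(0.5, 2.0))
            part = detect_partition(g, gamma, seed=trial)
            q = generalized_modularity(g, part, gamma)
            best_q, _ = best_partition_bruteforce(g, gamma)
            assert q >= best_q - 0.05 * abs(best_q) - 1e-9

    def test_deterministic_given_seed(self, two_triangle_bridge):
        a = detect_partition(two_triangle_bridge, 1.0, seed=11)
        b = detect_partition(two_triangle_bridge, 1.0, seed=11)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestSweep:
    def _small_cfg(self, **kw):
        base = dict(gamma_min=0.05, gamma_max=5.0, log_step=0.1, min_proximal=2, seed=7)
        base.update(kw)
        return RunConfig(**base)

    def test_one_partition_per_resolution(self, two_triangle_bridge):
        cfg = self._small_cfg()
        profile = sweep(two_triangle_bridge, cfg)
        assert len(profile.partitions) == len(profile.grid)
        for gamma, part in zip(profile.grid.gammas, profile.partitions):
            assert part.gamma == gamma

    def test_community_count_trend_with_resolution(self, rng):
        g = random_multicomponent_graph(rng, 1)
        profile = sweep(g, self._small_cfg())
        assert profile.partitions[-1].n_communities >= profile.partitions[0].n_communities

    def test_gamma_min_counts_components(self, rng):
        for trial in range(5):
            g = random_multicomponent_graph(rng, int(rng.integers(2, 5)))
            profile = sweep(g, self._small_cfg(gamma_min=0.001, gamma_max=0.01))
            n_comp = len(g.connected_components())
            assert profile.partitions[0].n_communities == n_comp

    def test_benchmark_sweep_hits_both_planted_levels(self):
        """Some resolution recovers the macro level, some the micro level."""
        bench = generate_benchmark(BenchmarkParams(seed=3))
        cfg = RunConfig(gamma_min=0.2, gamma_max=5.0, log_step=0.1, min_proximal=2, seed=3)
        profile = sweep(bench.graph, cfg)
        best = {"macro": 0.0, "micro": 0.0}
        for part in profile.partitions:
            dets = part.member_sets(bench.graph)
            for level in best:
                score = average_f1(bench.label_sets(level), dets).average_f1
                best[level] = max(best[level], score)
        assert best["macro"] >= 0.8
        assert best["micro"] >= 0.8
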