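"""Louvain optimizer: examples, determinism, local optimality, gain audit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from multiplexcd import (
    Graph,
    GraphError,
    LouvainConfig,
    Multiplex,
    SBMSpec,
    SPARSE_PROBS,
    adjusted_rand_index,
    balanced_sizes,
    communities,
    louvain,
    louvain_multiplex,
    modularity,
    multiplex_modularity,
    simulate_multiplex,
    single_move_gain,
)

from _oracles import exhaustive_max_modularity, random_graph


def as_sets(partition):
    return {frozenset(members) for members in communities(partition).values()}


class TestMonoplexExamples:
    def test_two_disjoint_triangles(self, two_triangles):
        part = louvain(two_triangles, LouvainConfig(seed=0))
        assert as_sets(part) == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}
        best_q, _ = exhaustive_max_modularity(two_triangles)
        assert modularity(two_triangles, part) == pytest.approx(best_q, abs=1e-12)

    def test_single_edge_merges(self):
        part = louvain(Graph([("a", "b")]))
        assert part["a"] == part["b"]

    def test_complete_graph_single_community(self):
        k5 = Graph([(u, v) for u in range(5) for v in range(u + 1, 5)])
        part = louvain(k5, LouvainConfig(seed=0))
        assert len(as_sets(part)) == 1

    def test_empty_graph_raises(self):
        with pytest.raises(GraphError):
            louvain(Graph(nodes=[1, 2]))


class TestMultiplexExamples:
    def test_single_layer_equals_monoplex(self, two_triangles):
        cfg = LouvainConfig(seed=7)
        assert louvain_multiplex(Multiplex([two_triangles]), cfg) == louvain(
            two_triangles, cfg
        )

    def test_identical_copies_equal_single_layer(self, two_triangles):
        cfg = LouvainConfig(seed=3)
        single = louvain(two_triangles, cfg)
        for g_count in (2, 4):
            net = Multiplex([two_triangles] * g_count)
            assert louvain_multiplex(net, cfg) == single

    def test_two_triangle_layers(self, two_triangles):
        net = Multiplex([two_triangles, two_triangles])
        part = louvain_multiplex(net, LouvainConfig(seed=0))
        assert as_sets(part) == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_all_layers_empty_raises(self):
        with pytest.raises(GraphError):
            louvain_multiplex(Multiplex([Graph(nodes=[1, 2])]))

    def test_isolated_everywhere_stays_singleton(self):
        g1 = Graph([(0, 1), (1, 2), (0, 2)], nodes=range(4))
        g2 = Graph([(0, 1)], nodes=range(4))
        part = louvain_multiplex(Multiplex([g1, g2]), LouvainConfig(seed=0))
        assert sum(1 for u in part if part[u] == part[3]) == 1


class TestDeterminismAndOptimality:
    def test_seed_determinism(self, rng):
        spec = SBMSpec(100, balanced_sizes(100, 4), (SPARSE_PROBS,) * 2, seed=5)
        net, _ = simulate_multiplex(spec)
        a = louvain_multiplex(net, LouvainConfig(seed=11))
        b = louvain_multiplex(net, LouvainConfig(seed=11))
        assert a == b

    @given(seed=st.integers(0, 10**4))
    @settings(max_examples=15)
    def test_local_optimality_verified_by_full_reevaluation(self, seed):
        """No single-vertex move to a neighbouring community improves the
        multiplex-modularity of the returned partition (checked against full
        objective recomputation, not the optimizer's own bookkeeping)."""
        rng = np.random.default_rng(seed)
        layers = [random_graph(rng, n=12, p=0.3) for _ in range(2)]
        net = Multiplex(layers)
        gamma = float(rng.choice([0.7, 1.0, 2.0]))
        part = louvain_multiplex(net, LouvainConfig(gamma=gamma, seed=seed))
        q0 = multiplex_modularity(net, part, gamma)
        for u in net.nodes:
            neighbour_labels = set()
            for layer in net.layers:
                row = layer.adjacency.getrow(net.nodes.index(u))
                neighbour_labels.update(part[net.nodes[j]] for j in row.indices)
            for lab in neighbour_labels - {part[u]}:
                moved = dict(part)
                moved[u] = lab
                q1 = multiplex_modularity(net, moved, gamma)
                assert q1 - q0 <= LouvainConfig().min_gain + 1e-9

    @given(seed=st.integers(0, 10**4))
    @settings(max_examples=20)
    def test_incremental_gain_matches_full_objective_difference(self, seed):
        rng = np.random.default_rng(seed)
        net = Multiplex([random_graph(rng, n=10, p=0.4, weighted=True) for _ in range(2)])
        part = {u: int(rng.integers(0, 3)) for u in net.nodes}
        gamma = 1.5
        u = net.nodes[int(rng.integers(0, 10))]
        target = int(rng.integers(0, 3))
        fast = single_move_gain(net, part, u, target, gamma)
        moved = dict(part)
        moved[u] = target
        slow = multiplex_modularity(net, moved, gamma) - multiplex_modularity(net, part, gamma)
        assert fast == pytest.approx(slow, abs=1e-9)

    def test_objective_nondecreasing_with_restarts(self, two_triangles):
        g = Graph(
            [(u, v) for u in range(6) for v in range(u + 1, 6) if (u + v) % 3],
            nodes=range(6),
        )
        q1 = modularity(g, louvain(g, LouvainConfig(seed=2)))
        q10 = modularity(g, louvain(g, LouvainConfig(seed=2, restarts=10)))
        assert q10 >= q1 - 1e-12


class TestRecovery:
    def test_mean_ari_increases_with_layers(self):
        """On sparse planted-partition draws, recovery improves with the
        number of layers (positive Spearman trend over 1..9)."""
        reps = 5
        master = np.random.default_rng(123)
        mean_aris = []
        for n_layers in range(1, 10):
            aris = []
            for _ in range(reps):
                spec = SBMSpec(
                    300,
                    balanced_sizes(300, 6),
                    (SPARSE_PROBS,) * n_layers,
                    seed=int(master.integers(2**31)),
                )
                net, planted = simulate_multiplex(spec)
                found = louvain_multiplex(
                    net, LouvainConfig(seed=int(master.integers(2**31)))
                )
                aris.append(adjusted_rand_index(planted, found))
            mean_aris.append(np.mean(aris))
        rho, _ = spearmanr(range(1, 10), mean_aris)
        assert rho > 0
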