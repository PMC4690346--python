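"""Data model, edge-list I/O and aggregation operators."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from multiplexcd import (
    Graph,
    GraphError,
    Multiplex,
    ParseError,
    aggregate,
    build_multiplex,
    read_layer,
    read_multiplex_file,
    read_partition,
    write_layer,
    write_partition,
    write_partition_blocks,
)

from _oracles import random_graph


def _write(tmp_path, text, name="layer.txt"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadLayer:
    def test_reversed_duplicate_collapses_to_one_edge(self, tmp_path):
        g = read_layer(_write(tmp_path, "a b\nb a\n"))
        assert g.edge_set() == {("a", "b")}
        assert g.m == 1

    def test_weighted_duplicates_sum(self, tmp_path):
        g = read_layer(_write(tmp_path, "a b 2\nb c 1\n"), weighted=True)
        assert g.m == 3
        assert g.degree("b") == 3

    def test_self_loop_dropped_with_warning(self, tmp_path):
        with pytest.warns(UserWarning, match="self-loop"):
            g = read_layer(_write(tmp_path, "a a\n"))
        assert g.number_of_edges == 0
        assert g.self_loops_dropped == 1
        assert g.nodes == ("a",)

    def test_comments_and_blank_lines_skipped(self, tmp_path):
        g = read_layer(_write(tmp_path, "# header\n\na b # trailing\n"))
        assert g.edge_set() == {("a", "b")}

    @pytest.mark.parametrize(
        "text", ["a\n", "a b c d\n", "a b notanumber\n"], ids=["1col", "4col", "badw"]
    )
    def test_malformed_line_names_line_number(self, tmp_path, text):
        with pytest.raises(ParseError, match="line 1"):
            read_layer(_write(tmp_path, text), weighted=True)

    def test_nonpositive_weight_rejected(self, tmp_path):
        with pytest.raises(ParseError, match="positive"):
            read_layer(_write(tmp_path, "a b -1\n"), weighted=True)

    def test_unweighted_read_ignores_third_column(self, tmp_path):
        g = read_layer(_write(tmp_path, "a b 7\n"), weighted=False)
        assert g.weight("a", "b") == 1.0

    def test_roundtrip_is_identity(self, tmp_path, rng):
        for weighted in (False, True):
            g = random_graph(rng, n=7, weighted=weighted)
            path = tmp_path / f"rt_{weighted}.txt"
            write_layer(g, path)
            g2 = read_layer(path, weighted=weighted)
            assert set(g2.edges()) == {(str(u), str(v), w) for u, v, w in g.edges()}

    def test_multilayer_file_blank_line_dialect(self, tmp_path):
        path = _write(tmp_path, "a b\nb c\n\nc d\n\n\na d\n")
        layers = read_multiplex_file(path)
        assert [g.edge_set() for g in layers] == [
            {("a", "b"), ("b", "c")},
            {("c", "d")},
            {("a", "d")},
        ]


class TestMultiplex:
    def test_universe_is_union_with_zero_padding(self):
        net = build_multiplex([Graph([("a", "b")]), Graph([("b", "c")])])
        assert net.nodes == ("a", "b", "c")
        assert net.layers[1].degree("a") == 0

    def test_single_layer_identity(self):
        g = Graph([(1, 2), (2, 3)])
        net = build_multiplex([g])
        assert net.n_layers == 1
        assert net.layers[0].edge_set() == g.edge_set()

    def test_three_copies(self):
        g = Graph([(1, 2)])
        net = build_multiplex([g, g, g])
        assert net.n_layers == 3
        assert all(layer.edge_set() == {(1, 2)} for layer in net.layers)

    def test_empty_list_rejected(self):
        with pytest.raises(GraphError):
            build_multiplex([])


class TestAggregate:
    def two_layer_net(self):
        return build_multiplex(
            [Graph([("a", "b")], nodes="abc"), Graph([("b", "c")], nodes="abc")]
        )

    def test_union_is_disjunction(self):
        assert aggregate(self.two_layer_net(), "union").edge_set() == {
            ("a", "b"),
            ("b", "c"),
        }

    def test_intersection_is_conjunction(self):
        assert aggregate(self.two_layer_net(), "intersection").edge_set() == set()

    def test_sum_counts_layers(self):
        net = build_multiplex([Graph([("a", "b")]), Graph([("a", "b")])])
        agg = aggregate(net, "sum")
        assert agg.weight("a", "b") == 2

    def test_weighted_layers_rejected_for_set_modes(self):
        net = build_multiplex([Graph([("a", "b", 2.0)])])
        for mode in ("union", "intersection"):
            with pytest.raises(GraphError, match="unweighted"):
                aggregate(net, mode)
        assert aggregate(net, "sum").weight("a", "b") == 2.0

    def test_unknown_mode(self):
        with pytest.raises(GraphError, match="unknown aggregation"):
            aggregate(self.two_layer_net(), "xor")

    @given(seed=st.integers(0, 10**6), n_layers=st.integers(1, 4))
    def test_nesting_and_total_weight(self, seed, n_layers):
        """intersection ⊆ each layer ⊆ union; sum total = Σ m^g; single-layer
        aggregation returns the layer."""
        rng = np.random.default_rng(seed)
        layers = [random_graph(rng, n=6, p=0.4, ensure_edge=False) for _ in range(n_layers)]
        net = build_multiplex(layers)
        inter = aggregate(net, "intersection").edge_set()
        union = aggregate(net, "union").edge_set()
        for layer in net.layers:
            assert inter <= layer.edge_set() <= union
        total = aggregate(net, "sum")
        assert total.m == pytest.approx(sum(layer.m for layer in net.layers))
        if n_layers == 1:
            assert union == net.layers[0].edge_set() == inter


class TestPartitionIO:
    def test_tsv_roundtrip(self, tmp_path):
        part = {"a": "1", "b": "1", "c": "2"}
        path = tmp_path / "p.tsv"
        write_partition(part, path)
        assert read_partition(path) == part

    def test_block_format(self, tmp_path):
        path = tmp_path / "p.txt"
        write_partition_blocks({"a": 0, "b": 0, "c": 1}, path)
        text = path.read_text()
        assert "# community 0\na\nb\n" in text
        assert "# community 1\nc\n" in text


class TestGraphInvariants:
    @given(seed=st.integers(0, 10**6))
    def test_m_is_half_degree_sum(self, seed):
        g = random_graph(np.random.default_rng(seed), weighted=True)
        assert g.m == pytest.approx(g.degrees().sum() / 2)

    def test_duplicate_edges_sum_and_loops_counted(self):
        g = Graph([(1, 2, 1.5), (2, 1, 0.5), (3, 3)])
        assert g.weight(1, 2) == 2.0
        assert g.self_loops_dropped == 1

    def test_zero_weight_rejected(self):
        with pytest.raises(GraphError, match="positive"):
            Graph([(1, 2, 0.0)])
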