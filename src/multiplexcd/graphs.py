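"""Graph and multiplex-network data model, edge-list I/O and layer aggregation.

A :class:`Graph` is a simple undirected graph with strictly positive edge
weights and no self-loops, stored as a symmetric sparse adjacency matrix over
an ordered vertex list.  A :class:`Multiplex` is an ordered collection of
layers sharing one vertex universe: a vertex absent from a layer's input is
kept in that layer with degree 0 ("not interacting" in that layer), which is
the missing-data semantics used throughout the package.

Three aggregation operators collapse a multiplex into a monoplex graph:
``union`` (edge present in at least one layer), ``intersection`` (edge present
in every layer) and ``sum`` (edge weight = number of layers containing the
edge, or the sum of its per-layer weights).  Union and intersection are
defined for presence/absence only and reject weighted layers.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Graph",
    "Multiplex",
    "GraphError",
    "ParseError",
    "read_layer",
    "read_multiplex_file",
    "write_layer",
    "build_multiplex",
    "aggregate",
    "read_partition",
    "write_partition",
    "write_partition_blocks",
    "partition_codes",
    "check_partition",
    "communities",
]

AGGREGATION_MODES = ("union", "intersection", "sum")


class GraphError(ValueError):
    """Invalid graph, multiplex or partition input."""


class ParseError(GraphError):
    """Malformed edge-list or partition file."""


class Graph:
    """Undirected weighted graph without self-loops.

    Parameters
    ----------
    edges:
        Iterable of ``(u, v)`` or ``(u, v, w)`` tuples.  Duplicate pairs
        (in either orientation) have their weights summed; self-loops are
        dropped and counted in :attr:`self_loops_dropped`.
    nodes:
        Extra vertex identifiers to include even if isolated.

    Vertices are kept in sorted order, which fixes a canonical edge order
    for serialization and reproducibility.
    """

    __slots__ = ("_nodes", "_index", "_adj", "self_loops_dropped")

    def __init__(self, edges: Iterable[tuple] = (), nodes: Iterable = ()):
        us, vs, ws = [], [], []
        nodeset = set(nodes)
        loops = 0
        for edge in edges:
            if len(edge) == 2:
                u, v = edge
                w = 1.0
            elif len(edge) == 3:
                u, v, w = edge
                w = float(w)
            else:
                raise GraphError(f"edge must be (u, v) or (u, v, w), got {edge!r}")
            if w <= 0:
                raise GraphError(f"edge weight must be positive, got {w!r} for ({u!r}, {v!r})")
            nodeset.add(u)
            nodeset.add(v)
            if u == v:
                loops += 1
                continue
            us.append(u)
            vs.append(v)
            ws.append(w)
        node_list = sorted(nodeset)
        index = {u: i for i, u in enumerate(node_list)}
        n = len(node_list)
        ui = np.fromiter((index[u] for u in us), dtype=np.int64, count=len(us))
        vi = np.fromiter((index[v] for v in vs), dtype=np.int64, count=len(vs))
        data = np.asarray(ws + ws, dtype=np.float64)
        rows = np.concatenate([ui, vi])
        cols = np.concatenate([vi, ui])
        adj = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
        adj.sum_duplicates()
        self._nodes = tuple(node_list)
        self._index = index
        self._adj = adj
        self.self_loops_dropped = loops

    @classmethod
    def _from_parts(cls, nodes: tuple, adj: sp.csr_matrix, self_loops_dropped: int = 0) -> "Graph":
        g = cls.__new__(cls)
        g._nodes = tuple(nodes)
        g._index = {u: i for i, u in enumerate(g._nodes)}
        g._adj = adj.tocsr()
        g.self_loops_dropped = self_loops_dropped
        return g

    @classmethod
    def from_index_arrays(
        cls,
        nodes: Sequence,
        u: np.ndarray,
        v: np.ndarray,
        w: np.ndarray | None = None,
    ) -> "Graph":
        """Build a graph from integer-index edge arrays over ``nodes``.

        Fast path used by the simulator and the aggregators; assumes
        ``u != v`` element-wise and positive weights.
        """
        n = len(nodes)
        if w is None:
            w = np.ones(len(u), dtype=np.float64)
        data = np.concatenate([w, w]).astype(np.float64)
        rows = np.concatenate([u, v])
        cols = np.concatenate([v, u])
        adj = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
        adj.sum_duplicates()
        return cls._from_parts(tuple(nodes), adj)

    # -- basic accessors -------------------------------------------------
    @property
    def nodes(self) -> tuple:
        return self._nodes

    @property
    def n_vertices(self) -> int:
        return len(self._nodes)

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric CSR adjacency (weights; zero diagonal)."""
        return self._adj

    @property
    def m(self) -> float:
        """Total edge weight (edge count for an unweighted graph)."""
        return float(self._adj.sum()) / 2.0

    @property
    def number_of_edges(self) -> int:
        return int(sp.triu(self._adj, k=1).nnz)

    def degrees(self) -> np.ndarray:
        """Per-vertex sum of incident edge weights, in node order."""
        return np.asarray(self._adj.sum(axis=1)).ravel()

    def degree(self, u) -> float:
        return float(self.degrees()[self._index[u]])

    @property
    def is_unweighted(self) -> bool:
        return bool(np.all(self._adj.data == 1.0))

    def has_edge(self, u, v) -> bool:
        return self._adj[self._index[u], self._index[v]] != 0

    def weight(self, u, v) -> float:
        return float(self._adj[self._index[u], self._index[v]])

    def edges(self) -> Iterator[tuple]:
        """Yield ``(u, v, w)`` in canonical (lexicographic) order."""
        upper = sp.triu(self._adj, k=1).tocoo()
        order = np.lexsort((upper.col, upper.row))
        for k in order:
            yield (self._nodes[upper.row[k]], self._nodes[upper.col[k]], float(upper.data[k]))

    def edge_set(self) -> set:
        return {(u, v) for u, v, _ in self.edges()}

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        g.add_weighted_edges_from(self.edges())
        return g

    @classmethod
    def from_networkx(cls, g) -> "Graph":
        return cls(
            ((u, v, d.get("weight", 1.0)) for u, v, d in g.edges(data=True)),
            nodes=g.nodes(),
        )

    def __repr__(self) -> str:
        return f"Graph(n={self.n_vertices}, edges={self.number_of_edges}, m={self.m:g})"


class Multiplex:
    """Ordered collection of graph layers over a shared vertex universe.

    The universe is the union of all layer vertex sets; every layer is padded
    with isolated vertices so all layers index the same node list.
    """

    __slots__ = ("_nodes", "_index", "_layers")

    def __init__(self, layers: Sequence[Graph]):
        if not layers:
            raise GraphError("a multiplex network needs at least one layer")
        first_nodes = layers[0].nodes
        if all(g.nodes == first_nodes for g in layers):
            universe = first_nodes
            padded = list(layers)
        else:
            universe = tuple(sorted(set().union(*(set(g.nodes) for g in layers))))
            index = {u: i for i, u in enumerate(universe)}
            n = len(universe)
            padded = []
            for g in layers:
                coo = g.adjacency.tocoo()
                remap = np.fromiter((index[u] for u in g.nodes), dtype=np.int64, count=g.n_vertices)
                adj = sp.coo_matrix(
                    (coo.data, (remap[coo.row], remap[coo.col])), shape=(n, n)
                ).tocsr()
                padded.append(Graph._from_parts(universe, adj))
        self._nodes = tuple(universe)
        self._index = {u: i for i, u in enumerate(self._nodes)}
        self._layers = tuple(
            g if g.nodes == self._nodes else Graph._from_parts(self._nodes, g.adjacency)
            for g in padded
        )

    @classmethod
    def from_index_arrays(
        cls, nodes: Sequence, layer_edges: Sequence[tuple]
    ) -> "Multiplex":
        """Fast construction from per-layer ``(u_idx, v_idx)`` or
        ``(u_idx, v_idx, w)`` integer edge arrays over a fixed node list."""
        layers = [Graph.from_index_arrays(nodes, *arrs) for arrs in layer_edges]
        return cls(layers)

    @property
    def nodes(self) -> tuple:
        return self._nodes

    @property
    def n_vertices(self) -> int:
        return len(self._nodes)

    @property
    def layers(self) -> tuple:
        return self._layers

    @property
    def n_layers(self) -> int:
        return len(self._layers)

    def __repr__(self) -> str:
        return f"Multiplex(layers={self.n_layers}, n={self.n_vertices})"


def build_multiplex(graphs: Sequence[Graph]) -> Multiplex:
    """Assemble layers into a :class:`Multiplex` over the union universe."""
    return Multiplex(graphs)


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

def _parse_edge_line(parts: list, lineno: int, weighted: bool):
    if len(parts) not in (2, 3):
        raise ParseError(f"line {lineno}: expected 'u v [w]', got {len(parts)} fields")
    u, v = parts[0], parts[1]
    w = 1.0
    if len(parts) == 3:
        try:
            w = float(parts[2])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: weight {parts[2]!r} is not a number") from exc
        if w <= 0:
            raise ParseError(f"line {lineno}: weight must be positive, got {w}")
        if not weighted:
            w = 1.0
    return u, v, w


def _edges_to_graph(raw_edges: list, weighted: bool, loops: int, nodes=()) -> Graph:
    if not weighted:
        # "u v" and "v u" duplicates collapse to a single unit edge
        dedup = {}
        for u, v, _ in raw_edges:
            key = (u, v) if u <= v else (v, u)
            dedup[key] = 1.0
        raw_edges = [(u, v, w) for (u, v), w in dedup.items()]
    g = Graph(raw_edges, nodes=nodes)
    g.self_loops_dropped += loops
    if loops:
        warnings.warn(f"dropped {loops} self-loop line(s)", stacklevel=3)
    return g


def read_layer(path, weighted: bool = False) -> Graph:
    """Read one graph layer from a whitespace-separated edge list.

    Lines are ``u v`` or ``u v w``; ``#`` starts a comment.  Duplicate edges
    collapse (weights summed when ``weighted``, deduplicated otherwise);
    self-loop lines are dropped with a warning.
    """
    raw_edges = []
    seen: set = set()
    loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            u, v, w = _parse_edge_line(line.split(), lineno, weighted)
            seen.add(u)
            seen.add(v)
            if u == v:
                loops += 1
                continue
            raw_edges.append((u, v, w))
    return _edges_to_graph(raw_edges, weighted, loops, nodes=seen)


def read_multiplex_file(path, weighted: bool = False) -> list:
    """Read a single-file multi-layer edge list (blank lines separate layers)."""
    blocks: list[list] = [[]]
    loop_counts = [0]
    block_nodes: list[set] = [set()]
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                if blocks[-1] or block_nodes[-1]:
                    blocks.append([])
                    loop_counts.append(0)
                    block_nodes.append(set())
                continue
            u, v, w = _parse_edge_line(stripped.split(), lineno, weighted)
            block_nodes[-1].update((u, v))
            if u == v:
                loop_counts[-1] += 1
                continue
            blocks[-1].append((u, v, w))
    if not blocks[-1] and not block_nodes[-1] and len(blocks) > 1:
        blocks.pop()
        loop_counts.pop()
        block_nodes.pop()
    return [
        _edges_to_graph(b, weighted, c, nodes=s)
        for b, c, s in zip(blocks, loop_counts, block_nodes)
    ]


def write_layer(graph: Graph, path, weighted: bool | None = None) -> None:
    """Write a layer as an edge list in canonical (lexicographic) order."""
    if weighted is None:
        weighted = not graph.is_unweighted
    with open(path, "w") as fh:
        for u, v, w in graph.edges():
            if weighted:
                fh.write(f"{u}\t{v}\t{w:g}\n")
            else:
                fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate(net: Multiplex, mode: str) -> Graph:
    """Collapse a multiplex into one monoplex graph.

    ``union`` and ``intersection`` are presence/absence operators and are
    rejected on weighted layers; ``sum`` accumulates weights and yields a
    weighted graph.
    """
    if mode not in AGGREGATION_MODES:
        raise GraphError(f"unknown aggregation mode {mode!r}; expected one of {AGGREGATION_MODES}")
    mats = [layer.adjacency for layer in net.layers]
    if mode == "sum":
        total = mats[0].copy()
        for a in mats[1:]:
            total = total + a
        return Graph._from_parts(net.nodes, total.tocsr())
    if any(not layer.is_unweighted for layer in net.layers):
        raise GraphError(f"{mode}-aggregation is defined for unweighted layers only")
    if mode == "union":
        stacked = mats[0].copy()
        for a in mats[1:]:
            stacked = stacked + a
        result = (stacked > 0).astype(np.float64)
    else:  # intersection
        result = (mats[0] > 0).astype(np.float64)
        for a in mats[1:]:
            result = result.multiply((a > 0).astype(np.float64))
    return Graph._from_parts(net.nodes, result.tocsr())


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------

def check_partition(partition: Mapping, nodes: Iterable) -> None:
    """Raise if any of ``nodes`` is missing from the partition."""
    missing = [u for u in nodes if u not in partition]
    if missing:
        raise GraphError(
            f"partition is missing {len(missing)} vertex(es), e.g. {missing[0]!r}"
        )


def partition_codes(partition: Mapping, nodes: Sequence) -> np.ndarray:
    """Integer community codes aligned with ``nodes`` (labels stay opaque).

    Codes follow the sorted order of the string form of the labels, which
    makes them deterministic regardless of dict insertion order.
    """
    check_partition(partition, nodes)
    labels = [partition[u] for u in nodes]
    uniq = sorted(set(labels), key=lambda x: (str(type(x)), str(x)))
    code_of = {lab: i for i, lab in enumerate(uniq)}
    return np.fromiter((code_of[lab] for lab in labels), dtype=np.int64, count=len(labels))


def communities(partition: Mapping) -> dict:
    """Group vertices by community label."""
    out: dict = {}
    for u, lab in partition.items():
        out.setdefault(lab, set()).add(u)
    return out


def read_partition(path) -> dict:
    """Read a two-column ``vertex<TAB>community`` TSV."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ParseError(f"line {lineno}: expected 'vertex<TAB>community'")
            out[parts[0]] = parts[1]
    return out


def write_partition(partition: Mapping, path) -> None:
    with open(path, "w") as fh:
        for u in sorted(partition, key=str):
            fh.write(f"{u}\t{partition[u]}\n")


def write_partition_blocks(partition: Mapping, path) -> None:
    """Write one community per paragraph, for human reading."""
    groups = communities(partition)
    with open(path, "w") as fh:
        for i, lab in enumerate(sorted(groups, key=str)):
            if i:
                fh.write("\n")
            fh.write(f"# community {lab}\n")
            for u in sorted(groups[lab], key=str):
                fh.write(f"{u}\n")
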