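"""Independent brute-force oracles used to validate the implementation.

Everything here is computed by direct enumeration (ordered-pair sums, set
partitions, pair counting, exact hypergeometric tails) and never calls the
code paths it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np


def brute_modularity(graph, partition, gamma=1.0):
    """Term-by-term ordered-pair evaluation of the diagonal-excluded
    modularity sum."""
    nodes = list(graph.nodes)
    m = graph.m
    k = {u: graph.degree(u) for u in nodes}
    total = 0.0
    for u in nodes:
        for v in nodes:
            if u == v or partition[u] != partition[v]:
                continue
            total += graph.weight(u, v) - gamma * k[u] * k[v] / (2.0 * m)
    return total / (2.0 * m)


def brute_multiplex_modularity(net, partition, gamma=1.0):
    return sum(
        brute_modularity(layer, partition, gamma) for layer in net.layers if layer.m > 0
    )


def restricted_growth_strings(n):
    """All set partitions of range(n) as label tuples (Bell(n) of them)."""
    def rec(prefix, maxlab):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for lab in range(maxlab + 2):
            yield from rec(prefix + [lab], max(maxlab, lab))
    yield from rec([0], 0)


@lru_cache(maxsize=None)
def _all_partition_labels(n) -> np.ndarray:
    return np.array(list(restricted_growth_strings(n)), dtype=np.int64)


def exhaustive_max_modularity(graph, gamma=1.0):
    """Global maximum of the modularity over every partition, with one
    maximizing partition; vectorized over all restricted-growth strings."""
    n = graph.n_vertices
    labels = _all_partition_labels(n)
    adj = graph.adjacency
    import scipy.sparse as sp

    upper = sp.triu(adj, k=1).tocoo()
    k = graph.degrees()
    two_m = k.sum()
    same = labels[:, upper.row] == labels[:, upper.col]
    within = 2.0 * (same @ upper.data)
    onehot = labels[:, :, None] == np.arange(n)[None, None, :]
    comm_deg = np.einsum("pnc,n->pc", onehot, k)
    null = ((comm_deg**2).sum(axis=1) - (k**2).sum()) / two_m
    q = (within - gamma * null) / two_m
    best = int(np.argmax(q))
    partition = {u: int(lab) for u, lab in zip(graph.nodes, labels[best])}
    return float(q[best]), partition


def brute_adjusted_rand_index(p1, p2):
    """Pair-counting ARI over all unordered vertex pairs."""
    nodes = sorted(p1, key=str)
    a11 = a10 = a01 = a00 = 0
    for u, v in itertools.combinations(nodes, 2):
        s1 = p1[u] == p1[v]
        s2 = p2[u] == p2[v]
        if s1 and s2:
            a11 += 1
        elif s1:
            a10 += 1
        elif s2:
            a01 += 1
        else:
            a00 += 1
    num = 2 * (a11 * a00 - a10 * a01)
    den = (a11 + a10) * (a10 + a00) + (a11 + a01) * (a01 + a00)
    if den == 0:
        return 1.0
    return num / den


def hypergeom_upper_tail(x, n_universe, n_term, n_comm):
    """Exact P(X >= x) for X hypergeometric, via integer arithmetic."""
    total = comb(n_universe, n_comm)
    upper = min(n_term, n_comm)
    s = sum(comb(n_term, i) * comb(n_universe - n_term, n_comm - i) for i in range(x, upper + 1))
    return float(Fraction(s, total))


def random_graph(rng, n=None, p=0.5, weighted=False, ensure_edge=True):
    """Seeded Erdos–Renyi helper returning a multiplexcd Graph."""
    from multiplexcd import Graph

    if n is None:
        n = int(rng.integers(3, 9))
    while True:
        edges = []
        for u in range(n):
            for v in range(u + 1, n):
                if rng.random() < p:
                    w = float(rng.integers(1, 5)) if weighted else 1.0
                    edges.append((u, v, w))
        if edges or not ensure_edge:
            return Graph(edges, nodes=range(n))


def random_partition(rng, nodes, max_communities=4):
    return {u: int(rng.integers(0, max_communities)) for u in nodes}
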