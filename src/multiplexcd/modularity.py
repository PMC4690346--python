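"""Newman–Girvan modularity and its multiplex extension.

For a graph :math:`X` with total edge weight :math:`m`, degrees :math:`k_i`
and a partition :math:`\\mathbf{c}`, the (resolution-parametrized) modularity
implemented here is

.. math::

    Q_\\gamma(X, \\mathbf{c}) = \\frac{1}{2m} \\sum_{i \\neq j}
        \\left( X_{ij} - \\gamma \\frac{k_i k_j}{2m} \\right)
        \\delta_{c_i, c_j},

a sum over *ordered* pairs of distinct vertices: each undirected edge is
counted twice and the diagonal terms :math:`i = j` are excluded.  Relative to
the diagonal-inclusive textbook form, the exclusion only subtracts the
partition-independent constant :math:`\\gamma \\sum_i k_i^2 / (2m)^2`, so the
two conventions rank partitions identically; we keep the exclusion so that a
fully-within-community partition attains exactly 1 for the first term.  For
weighted graphs, :math:`X_{ij}` is the edge weight and :math:`m, k_i` are
weight sums.  The resolution parameter :math:`\\gamma > 0` scales only the
null-model term; larger values favour smaller communities.

The multiplex-modularity of a partition shared by all layers
:math:`(X^{(g)})_g` sums the per-community within-layer contributions and
equals the sum of the per-layer modularities:

.. math::

    Q^M_\\gamma = \\sum_g Q_\\gamma(X^{(g)}, \\mathbf{c}).
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import scipy.sparse as sp

from .graphs import Graph, GraphError, Multiplex, partition_codes

__all__ = ["modularity", "multiplex_modularity"]


def _check_gamma(gamma: float) -> float:
    gamma = float(gamma)
    if gamma <= 0:
        raise GraphError(f"resolution parameter gamma must be positive, got {gamma}")
    return gamma


def _layer_arrays(adj: sp.csr_matrix, codes: np.ndarray):
    """Degrees, per-community internal weights and degree sums for one layer."""
    k = np.asarray(adj.sum(axis=1)).ravel()
    n_comm = int(codes.max()) + 1 if codes.size else 0
    upper = sp.triu(adj, k=1).tocoo()
    same = codes[upper.row] == codes[upper.col]
    internal = np.bincount(
        codes[upper.row[same]], weights=upper.data[same], minlength=n_comm
    )
    comm_degree = np.bincount(codes, weights=k, minlength=n_comm)
    comm_sq_degree = np.bincount(codes, weights=k * k, minlength=n_comm)
    return k, internal, comm_degree, comm_sq_degree


def modularity(graph: Graph, partition: Mapping, gamma: float = 1.0) -> float:
    """Resolution-parametrized Newman–Girvan modularity of a partition.

    Parameters
    ----------
    graph:
        Graph with positive total edge weight (an empty graph has undefined
        modularity and raises).
    partition:
        Mapping vertex -> community label covering every vertex of ``graph``.
    gamma:
        Resolution parameter (> 0, default 1 recovers the classic measure).
    """
    gamma = _check_gamma(gamma)
    if graph.m == 0:
        raise GraphError("empty graph has undefined modularity")
    codes = partition_codes(partition, graph.nodes)
    k, internal, comm_degree, comm_sq_degree = _layer_arrays(graph.adjacency, codes)
    two_m = k.sum()
    within = 2.0 * internal.sum()
    null = (comm_degree @ comm_degree - comm_sq_degree.sum()) / two_m
    return float((within - gamma * null) / two_m)


def multiplex_modularity(net: Multiplex, partition: Mapping, gamma: float = 1.0) -> float:
    """Multiplex-modularity of one partition shared across all layers.

    Accumulates, community by community, each layer's proportion of
    within-community edges minus its degree-null expectation, with the same
    partition and the same ``gamma`` applied to every layer.  A layer with no
    edges (possible after heavy vertex withdrawal) contributes 0, with a
    warning.
    """
    gamma = _check_gamma(gamma)
    codes = partition_codes(partition, net.nodes)
    n_comm = int(codes.max()) + 1
    per_community = np.zeros(n_comm)
    n_empty = 0
    for layer in net.layers:
        two_m = 2.0 * layer.m
        if two_m == 0:
            n_empty += 1
            continue
        _, internal, comm_degree, comm_sq_degree = _layer_arrays(layer.adjacency, codes)
        per_community += 2.0 * internal / two_m
        per_community -= gamma * (comm_degree**2 - comm_sq_degree) / two_m**2
    if n_empty == net.n_layers:
        raise GraphError("empty graph has undefined modularity (all layers have no edges)")
    if n_empty:
        warnings.warn(
            f"{n_empty} layer(s) with no edges contribute 0 to the multiplex-modularity",
            stacklevel=2,
        )
    return float(per_community.sum())
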