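"""Consensus clustering baseline.

Each layer is clustered independently with the standard Louvain algorithm;
every resulting partition is turned into an unweighted co-membership graph
(an edge joins two distinct vertices assigned to the same community); the
co-membership graphs are sum-aggregated into one weighted graph whose edge
weights count, for each pair, the number of layers grouping it together;
weighted Louvain on that graph yields the consensus partition.  The
procedure is single-pass: it is not iterated to convergence and applies no
co-membership threshold.
"""

from __future__ import annotations

import logging

import numpy as np

from .graphs import Graph, GraphError, Multiplex, partition_codes
from .louvain import LouvainConfig, louvain

__all__ = ["co_membership_graph", "consensus_cluster"]

logger = logging.getLogger(__name__)


def co_membership_graph(partition, nodes) -> Graph:
    """Unweighted graph joining every pair of distinct vertices that share a
    community; a partition with community sizes ``s_a`` yields exactly
    ``sum_a s_a (s_a - 1) / 2`` edges."""
    codes = partition_codes(partition, nodes)
    order = np.argsort(codes, kind="stable")
    us, vs = [], []
    start = 0
    sorted_codes = codes[order]
    for end in range(1, len(order) + 1):
        if end == len(order) or sorted_codes[end] != sorted_codes[start]:
            members = order[start:end]
            if len(members) > 1:
                a, b = np.triu_indices(len(members), k=1)
                us.append(members[a])
                vs.append(members[b])
            start = end
    u = np.concatenate(us) if us else np.empty(0, np.int64)
    v = np.concatenate(vs) if vs else np.empty(0, np.int64)
    return Graph.from_index_arrays(tuple(nodes), u, v)


def consensus_cluster(net: Multiplex, config: LouvainConfig = LouvainConfig()) -> dict:
    """Single-pass consensus partition of a multiplex network.

    Per-layer runs use the same gamma as the outer call, with seeds offset
    by the layer index so a single-layer consensus reproduces the plain
    monoplex run at the same seed.  Raises if every per-layer partition is
    all-singletons (empty consensus graph).
    """
    from dataclasses import replace

    co_graphs = []
    for g, layer in enumerate(net.layers):
        layer_partition = louvain(layer, replace(config, seed=config.seed + g, restarts=1))
        co_graphs.append(co_membership_graph(layer_partition, net.nodes))
    consensus_adj = co_graphs[0].adjacency.copy()
    for cg in co_graphs[1:]:
        consensus_adj = consensus_adj + cg.adjacency
    if consensus_adj.nnz == 0:
        raise GraphError("empty consensus graph: every per-layer partition is all-singletons")
    weighted = Graph._from_parts(net.nodes, consensus_adj.tocsr())
    logger.debug(
        "consensus graph: %d edges, max weight %g", weighted.number_of_edges,
        weighted.adjacency.data.max(),
    )
    return louvain(weighted, config)
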