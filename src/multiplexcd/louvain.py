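"""Louvain heuristic for modularity and multiplex-modularity maximization.

The algorithm starts from the all-singletons partition, repeatedly tries to
move each vertex into a neighbouring community, keeping only moves that
increase the objective, then contracts communities into super-vertices and
iterates until stability.  The multiplex adaptation optimizes the
multiplex-modularity :math:`Q^M_\\gamma = \\sum_g Q_\\gamma(X^{(g)}, c)`:
move gains are accumulated layer by layer (each layer keeps its own total
weight :math:`m^g` and degrees) and the contraction step collapses *all*
layers with the same community map.

The move gain for transferring vertex ``i`` from community ``c`` to ``d`` is
the exact objective difference

.. math::

    \\Delta = \\sum_g \\left[ \\frac{w_i^g(d) - w_i^g(c \\setminus i)}{m^g}
        - \\gamma \\frac{k_i^g\\,(K_d^g - K_{c \\setminus i}^g)}{2 (m^g)^2}
      \\right]

where :math:`w_i^g(S)` is the weight from ``i`` to ``S`` in layer ``g`` and
:math:`K_S^g` the total degree of ``S``.  Because the diagonal terms are
excluded from the objective, a vertex's own degree never enters its gain and
vertices isolated in every layer stay singletons.

Sweeps visit vertices in a random permutation re-drawn from the seeded RNG
each sweep; ties between equally-gaining targets keep the current community,
otherwise the lowest community label wins, so results are fully determined
by the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import scipy.sparse as sp
from numba import njit

from .graphs import Graph, GraphError, Multiplex, partition_codes
from .modularity import multiplex_modularity

__all__ = ["LouvainConfig", "louvain", "louvain_multiplex", "single_move_gain"]

logger = logging.getLogger(__name__)

_TIE_EPS = 1e-13
_MAX_SWEEPS = 1000


@dataclass(frozen=True)
class LouvainConfig:
    """Tunable parameters of the Louvain runs.

    gamma: resolution parameter (> 0) applied to every layer's null term.
    seed: RNG seed governing sweep orders (and restart seeds).
    max_passes: cap on local-move + contraction cycles.
    min_gain: minimal objective improvement to accept a move (guards
        against floating-point oscillation).
    restarts: independent runs; the partition with the best objective wins.
    """

    gamma: float = 1.0
    seed: int = 0
    max_passes: int = 100
    min_gain: float = 1e-10
    restarts: int = 1

    def __post_init__(self):
        if self.gamma <= 0:
            raise GraphError("gamma must be positive")
        if self.max_passes < 1:
            raise GraphError("max_passes must be at least 1")
        if self.min_gain < 0:
            raise GraphError("min_gain must be non-negative")
        if self.restarts < 1:
            raise GraphError("restarts must be at least 1")


@njit(cache=True)
def _sweep(order, comm, indptr, indices, weights, deg, inv_m, half_inv_m2, gamma, comm_deg, min_gain):
    """One local-move sweep over ``order``; returns the number of moves.

    ``indptr`` has shape (L, n+1) and indexes the concatenated per-layer CSR
    ``indices``/``weights``; ``comm_deg`` (L, C) holds per-layer community
    degree totals and is updated in place, as is ``comm``.
    """
    n_layers = deg.shape[0]
    n_comm = comm_deg.shape[1]
    w_comm = np.zeros((n_layers, n_comm))
    seen = np.zeros(n_comm, np.uint8)
    touched = np.empty(n_comm, np.int64)
    moved = 0
    for t in range(order.shape[0]):
        i = order[t]
        ci = comm[i]
        n_touch = 0
        for g in range(n_layers):
            for p in range(indptr[g, i], indptr[g, i + 1]):
                j = indices[p]
                if j == i:
                    continue
                cj = comm[j]
                if seen[cj] == 0:
                    seen[cj] = 1
                    touched[n_touch] = cj
                    n_touch += 1
                w_comm[g, cj] += weights[p]
        # take i out of its community before scoring candidate targets
        for g in range(n_layers):
            comm_deg[g, ci] -= deg[g, i]
        base = 0.0
        for g in range(n_layers):
            base += w_comm[g, ci] * inv_m[g] - gamma * deg[g, i] * comm_deg[g, ci] * half_inv_m2[g]
        best = base
        best_d = ci
        for a in range(n_touch):
            d = touched[a]
            if d == ci:
                continue
            val = 0.0
            for g in range(n_layers):
                val += w_comm[g, d] * inv_m[g] - gamma * deg[g, i] * comm_deg[g, d] * half_inv_m2[g]
            if val > best + _TIE_EPS:
                best = val
                best_d = d
            elif best_d != ci and val >= best - _TIE_EPS and d < best_d:
                best_d = d
        if best_d != ci and best - base > min_gain:
            comm[i] = best_d
            moved += 1
        else:
            best_d = ci
        for g in range(n_layers):
            comm_deg[g, best_d] += deg[g, i]
        for a in range(n_touch):
            d = touched[a]
            seen[d] = 0
            for g in range(n_layers):
                w_comm[g, d] = 0.0
    return moved


def _stack_layers(mats):
    """Concatenate per-layer CSR arrays for the jitted sweep."""
    n_layers = len(mats)
    n = mats[0].shape[0]
    indptr = np.zeros((n_layers, n + 1), dtype=np.int64)
    idx_parts, w_parts = [], []
    offset = 0
    for g, a in enumerate(mats):
        a = a.tocsr()
        indptr[g] = a.indptr.astype(np.int64) + offset
        idx_parts.append(a.indices.astype(np.int64))
        w_parts.append(a.data.astype(np.float64))
        offset += a.nnz
    indices = np.concatenate(idx_parts) if idx_parts else np.empty(0, np.int64)
    weights = np.concatenate(w_parts) if w_parts else np.empty(0, np.float64)
    deg = np.vstack([np.asarray(a.sum(axis=1)).ravel() for a in mats])
    return indptr, indices, weights, deg


def _contract(mat: sp.csr_matrix, comm_map: np.ndarray, n_comm: int) -> sp.csr_matrix:
    """Collapse vertices by community; self-loop diagonals carry twice the
    internal weight so that row sums remain the super-vertex degrees."""
    coo = mat.tocoo()
    out = sp.coo_matrix(
        (coo.data, (comm_map[coo.row], comm_map[coo.col])), shape=(n_comm, n_comm)
    ).tocsr()
    out.sum_duplicates()
    return out


def _local_phase(stacked, comm, comm_deg, gamma, rng, min_gain) -> int:
    """Sweep vertices in seeded random order until no move improves; the
    community assignment and per-layer community degrees update in place."""
    indptr, indices, weights, deg, inv_m, half_inv_m2 = stacked
    n = comm.shape[0]
    total = 0
    for _ in range(_MAX_SWEEPS):
        order = rng.permutation(n).astype(np.int64)
        moved = _sweep(
            order, comm, indptr, indices, weights, deg,
            inv_m, half_inv_m2, gamma, comm_deg, min_gain,
        )
        total += moved
        if moved == 0:
            break
    return total


def _stacked(mats):
    indptr, indices, weights, deg = _stack_layers(mats)
    m_layer = deg.sum(axis=1) / 2.0
    safe = np.where(m_layer > 0, m_layer, 1.0)
    inv_m = np.where(m_layer > 0, 1.0 / safe, 0.0)
    return indptr, indices, weights, deg, inv_m, 0.5 * inv_m**2


def _louvain_codes(mats, gamma, rng, max_passes, min_gain):
    """Run Louvain on CSR layers; returns community codes per vertex.

    Each pass first refines the current partition with single-vertex moves
    on the original graphs (so the result is locally optimal at the vertex
    level, not merely for super-vertices), then contracts communities and
    optimizes super-vertex moves level by level.  Stops when a full pass
    changes nothing or after ``max_passes`` passes.
    """
    mats = [a.tocsr() for a in mats]
    n = mats[0].shape[0]
    stacked0 = _stacked(mats)
    deg0 = stacked0[3]
    mapping = np.arange(n, dtype=np.int64)
    for pass_no in range(max_passes):
        # vertex-level local moves from the current partition
        comm = mapping.copy()
        n_comm = int(comm.max()) + 1
        comm_deg = np.vstack(
            [np.bincount(comm, weights=deg0[g], minlength=n_comm) for g in range(len(mats))]
        )
        refine_moves = _local_phase(stacked0, comm, comm_deg, gamma, rng, min_gain)
        labels, mapping = np.unique(comm, return_inverse=True)
        mapping = mapping.astype(np.int64)
        n_before = labels.size
        # coarsening: contract all layers by the partition and optimize
        # super-vertex moves, re-contracting until the level count is stable
        current = [_contract(a, mapping, n_before) for a in mats]
        n_cur = n_before
        while True:
            stacked = _stacked(current)
            comm = np.arange(n_cur, dtype=np.int64)
            comm_deg = stacked[3].copy()
            _local_phase(stacked, comm, comm_deg, gamma, rng, min_gain)
            labels, comm_map = np.unique(comm, return_inverse=True)
            if labels.size == n_cur:
                break
            comm_map = comm_map.astype(np.int64)
            mapping = comm_map[mapping]
            current = [_contract(a, comm_map, labels.size) for a in current]
            n_cur = labels.size
        logger.debug(
            "pass %d: %d refinement moves, %d -> %d communities",
            pass_no + 1, refine_moves, n_before, n_cur,
        )
        if refine_moves == 0 and n_cur == n_before:
            break
    return mapping


def _run(mats, nodes, cfg: LouvainConfig, net_for_objective: Multiplex | None):
    if all(a.sum() == 0 for a in mats):
        raise GraphError("cannot cluster: every layer has no edges")
    best_partition = None
    best_q = -np.inf
    for r in range(cfg.restarts):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(r,)))
        codes = _louvain_codes(mats, cfg.gamma, rng, cfg.max_passes, cfg.min_gain)
        partition = {u: int(c) for u, c in zip(nodes, codes)}
        if cfg.restarts == 1:
            return partition
        q = multiplex_modularity(net_for_objective, partition, gamma=cfg.gamma)
        logger.debug("restart %d: objective %.6f", r, q)
        if q > best_q:
            best_q = q
            best_partition = partition
    return best_partition


def louvain(graph: Graph, config: LouvainConfig = LouvainConfig()) -> dict:
    """Louvain community detection on one (possibly weighted) graph.

    Returns a vertex -> community-label dict; labels are small ints.
    """
    if graph.m == 0:
        raise GraphError("cannot cluster an empty graph")
    return _run([graph.adjacency], graph.nodes, config, Multiplex([graph]))


def louvain_multiplex(net: Multiplex, config: LouvainConfig = LouvainConfig()) -> dict:
    """Louvain adapted to multiplex networks.

    Optimizes the parametrized multiplex-modularity: local moves score the
    summed per-layer gains and the coarsening step contracts all layers by
    the same community map, each layer retaining its own edge weights.
    """
    return _run([layer.adjacency for layer in net.layers], net.nodes, config, net)


def single_move_gain(net: Multiplex, partition: Mapping, vertex, target, gamma: float = 1.0) -> float:
    """Exact multiplex-modularity change from moving ``vertex`` to the
    community labelled ``target`` (computed incrementally; used to audit the
    optimizer's internal gain bookkeeping against full re-evaluations)."""
    codes = partition_codes(partition, net.nodes)
    index = {u: i for i, u in enumerate(net.nodes)}
    i = index[vertex]
    ci = codes[i]
    target_code = None
    for u, lab in partition.items():
        if lab == target:
            target_code = codes[index[u]]
            break
    if target_code is None:
        raise GraphError(f"no community labelled {target!r} in partition")
    if target_code == ci:
        return 0.0
    gain = 0.0
    for layer in net.layers:
        m = layer.m
        if m == 0:
            continue
        adj = layer.adjacency
        k = np.asarray(adj.sum(axis=1)).ravel()
        row = adj.getrow(i)
        w_to = np.bincount(codes[row.indices], weights=row.data, minlength=int(codes.max()) + 1)
        comm_deg = np.bincount(codes, weights=k, minlength=int(codes.max()) + 1)
        gain += (w_to[target_code] - w_to[ci]) / m
        gain -= gamma * k[i] * (comm_deg[target_code] - (comm_deg[ci] - k[i])) / (2.0 * m * m)
    return float(gain)
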