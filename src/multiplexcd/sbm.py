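"""Multiplex stochastic-block-model simulator with vertex-withdrawal missing data.

Layers are independent draws of a planted-partition SBM sharing one community
structure: each unordered pair of distinct vertices is an edge of layer ``g``
with probability ``p_I`` if the two vertices share a planted community and
``p_E`` otherwise.  Missing data is modelled by withdrawing each (vertex,
layer) independently with a fixed probability: the vertex's incident edges in
that layer are deleted but the vertex stays in the universe with degree 0
there.  The planted partition is returned alongside the network so that
recovery experiments never have to re-infer it.

Default probability regimes follow the benchmark conditions used throughout
the package: sparse layers use (p_I, p_E) = (0.1, 0.01), dense layers
(0.5, 0.2), and "mixed" multiplexes draw each layer's pair uniformly from
those two options.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .graphs import GraphError, Multiplex

__all__ = [
    "SBMSpec",
    "SPARSE_PROBS",
    "DENSE_PROBS",
    "balanced_sizes",
    "sample_mixed_layer_probs",
    "simulate_multiplex",
]

SPARSE_PROBS = (0.1, 0.01)
DENSE_PROBS = (0.5, 0.2)


def balanced_sizes(n: int, n_communities: int) -> tuple:
    """Split ``n`` vertices into ``n_communities`` near-equal communities;
    a remainder spreads one extra vertex per leading community."""
    if n_communities < 1 or n < n_communities:
        raise GraphError("need 1 <= n_communities <= n")
    base, rem = divmod(n, n_communities)
    return tuple(base + 1 if q < rem else base for q in range(n_communities))


@dataclass(frozen=True)
class SBMSpec:
    """Parameters of a multiplex planted-partition draw.

    community_sizes define the planted partition (must sum to n);
    layer_probs is one (p_I, p_E) pair per layer; withdrawal_prob is the
    per-(vertex, layer) absence probability.
    """

    n: int
    community_sizes: tuple
    layer_probs: tuple
    withdrawal_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "community_sizes", tuple(int(s) for s in self.community_sizes))
        object.__setattr__(
            self, "layer_probs", tuple((float(a), float(b)) for a, b in self.layer_probs)
        )
        if any(s <= 0 for s in self.community_sizes):
            raise GraphError("community sizes must be positive")
        if sum(self.community_sizes) != self.n:
            raise GraphError(
                f"community sizes sum to {sum(self.community_sizes)}, expected n={self.n}"
            )
        if not self.layer_probs:
            raise GraphError("need at least one layer")
        for p_i, p_e in self.layer_probs:
            if not (0 <= p_i <= 1 and 0 <= p_e <= 1):
                raise GraphError("edge probabilities must lie in [0, 1]")
        if not 0 <= self.withdrawal_prob <= 1:
            raise GraphError("withdrawal probability must lie in [0, 1]")

    @property
    def n_layers(self) -> int:
        return len(self.layer_probs)

    def planted_labels(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.community_sizes)), self.community_sizes)


def sample_mixed_layer_probs(rng, n_layers: int) -> list:
    """Assign each layer (0.1, 0.01) or (0.5, 0.2) with probability 1/2."""
    if n_layers < 1:
        raise GraphError("need at least one layer")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    picks = rng.integers(0, 2, size=n_layers)
    return [SPARSE_PROBS if p == 0 else DENSE_PROBS for p in picks]


def simulate_multiplex(spec: SBMSpec, rng=None):
    """Draw one multiplex network and return ``(network, planted_partition)``.

    Layers are sampled independently; withdrawal is applied after edge
    generation, per layer, deleting the incident edges of absent vertices.
    With ``rng`` unset, randomness is governed by ``spec.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    labels = spec.planted_labels()
    n = spec.n
    iu, iv = np.triu_indices(n, k=1)
    same = labels[iu] == labels[iv]
    layer_edges = []
    for p_i, p_e in spec.layer_probs:
        prob = np.where(same, p_i, p_e)
        keep = rng.random(iu.size) < prob
        u, v = iu[keep], iv[keep]
        if spec.withdrawal_prob > 0:
            absent = rng.random(n) < spec.withdrawal_prob
            retained = ~(absent[u] | absent[v])
            u, v = u[retained], v[retained]
        layer_edges.append((u.astype(np.int64), v.astype(np.int64)))
    net = Multiplex.from_index_arrays(np.arange(n), layer_edges)
    partition = {i: int(labels[i]) for i in range(n)}
    return net, partition
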