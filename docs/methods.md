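# Methods

## Model and measures

A multiplex network is an ordered collection of undirected graph layers
`(X^(g))_g` over one shared vertex universe.  Layers are matched by vertex
*identifier*, not position; a vertex absent from a layer's input file is kept
in that layer with degree 0, i.e. "not interacting there".  This single
convention carries all missing-data semantics in the package, and it is why
isolated vertices are retained everywhere (partitions must cover the full
universe for ARI comparisons).

The monoplex modularity is computed over ordered pairs of *distinct*
vertices:

    Q_γ(X, c) = (1/2m) Σ_{i≠j} (X_ij − γ k_i k_j / 2m) δ(c_i, c_j).

Excluding the diagonal differs from the diagonal-inclusive textbook form by
the partition-independent constant `γ Σ_i k_i² / (2m)²` (tested against
networkx's implementation plus that constant), so both conventions rank
partitions identically; we keep the exclusion so the first term is exactly
the proportion of within-community edges.  Weighted graphs substitute weight
sums for counts.  The resolution parameter γ multiplies only the null term;
it is applied with the same value to every layer (there is no per-layer γ).

The multiplex-modularity is `Q^M_γ = Σ_g Q_γ(X^(g), c)` with one shared
partition.  It is implemented as a per-community accumulation across layers,
and the identity with the sum of independently computed per-layer
modularities is enforced in tests to 1e-12.  A layer left without edges
(possible after heavy vertex withdrawal) contributes 0 with a warning rather
than aborting, which keeps missing-data simulations runnable; if *every*
layer is empty the measure is undefined and raises.

## Optimizer

The Louvain adaptation maximizes `Q^M_γ` directly.  Per-layer adjacency is
held in CSR arrays; the local-move sweep is a numba-compiled kernel over the
stacked layers.  The gain of moving vertex `i` from community `c` to `d` is
accumulated per layer as

    Δ = Σ_g [ (w_i^g(d) − w_i^g(c∖i)) / m^g
              − γ k_i^g (K_d^g − K_{c∖i}^g) / (2 (m^g)²) ],

the exact difference of the objective (audited in tests against full
re-evaluations to 1e-9).  Because the diagonal is excluded, a vertex's own
degree never enters its gain, and a vertex isolated in all layers can never
gain by joining a community: such vertices remain singletons.

Each pass (1) refines the current partition with single-vertex moves on the
*original* graphs, then (2) contracts all layers by the same community map —
each layer keeping its own weights, with contracted self-loops carrying twice
the internal weight so super-vertex degrees stay consistent — and optimizes
super-vertex moves level by level.  Step (1) goes beyond the classic
formulation, which only guarantees local optimality for super-vertex moves:
here the returned partition admits no profitable single-vertex move at all
(verified in tests by exhaustive neighbourhood re-evaluation).  Iteration
stops when a full pass changes nothing, or after `max_passes` (default 100,
never reached in practice).

Numerical choices: sweeps visit vertices in a random permutation re-drawn
from the seeded RNG each sweep (no order bias, fully reproducible); a move is
accepted only if its gain exceeds `min_gain` (default 1e-10, guarding against
floating-point oscillation); ties between targets keep the current community,
otherwise the lowest community label wins.  `restarts > 1` runs independent
seeds and returns the partition with the best objective.

Known limitation: greedy local search cannot always reach the global
maximizer, even at toy scale.  On the 995 connected graphs with at most 7
vertices, best-of-10 restarts attains the exhaustively-computed optimum on
979; the remaining 16 graphs have optima unreachable by any greedy
single-vertex/merge trajectory from the all-singletons start (reference C
implementations of Louvain and Leiden converge to the same suboptimal values
on them).  The corresponding test asserts the optimum and is expected to
flag those graphs; at benchmark scale the heuristic's recovery is what the
acceptance results measure.

## Baselines

Union and intersection aggregation are presence/absence operators, defined
only for unweighted layers (weighted input is rejected rather than silently
binarized); sum aggregation produces a weighted graph and accepts weighted
layers.  Consensus clustering is single-pass: standard Louvain per layer,
unweighted co-membership graph per partition, sum-aggregation, weighted
Louvain — no co-membership threshold and no iteration to convergence.  The
per-layer runs use the outer γ (the procedure itself does not specify one)
and seeds offset by the layer index, so a one-layer consensus coincides with
the plain monoplex run.

## Simulator

The generator draws independent planted-partition SBM layers sharing one
community structure: a pair inside a community is an edge with probability
`p_I`, between communities `p_E`.  The benchmark conditions are 1,000
vertices in 20 balanced communities of 50; sparse layers use
`(p_I, p_E) = (0.1, 0.01)`, dense layers `(0.5, 0.2)`, and mixed multiplexes
assign each layer one of the two uniformly at random.  Missing data
withdraws each (vertex, layer) independently with probability 0.5, deleting
that vertex's edges in that layer only — applied after edge sampling, which
is distributionally equivalent to sampling among retained pairs.  Balanced
community sizes with a non-divisible remainder give one extra vertex to each
leading community.

What the simulator does *not* emulate about real interaction data: degree
heterogeneity (no degree correction), overlapping or nested modules,
correlated noise between layers (layers are conditionally independent), and
non-random missingness (study bias concentrates real missing data on poorly
studied genes).  Recovery results on these draws therefore demonstrate the
relative behaviour of the methods under controlled density/incompleteness,
not absolute performance on biological networks.

## Evaluation and enrichment

The adjusted Rand index is the Hubert–Arabie chance-corrected form
(delegated to scikit-learn behind the package API and cross-checked against
a brute-force pair-counting oracle); identical degenerate partitions score 1.
Partitions over different universes — the real-data situation when methods
keep different vertex sets — are compared on the intersection of the two
vertex sets (`restrict=True`); this convention is a package choice.

Enrichment tests each (community, term) pair with overlap ≥ 1 using the
one-sided Fisher exact test (hypergeometric upper tail; depletion is not
tested), with Bonferroni factor = tested terms × tested communities and
q-values capped at 1.  The background universe defaults to the vertices
present in both the partition and the annotation table, and is overridable;
annotation tables are taken as given (no ontology propagation).

## Benchmark problem sizes

The recovery tests and `scripts/acceptance.py` run at 50 replicates for the
sparse 3-layer and mixed 4-layer conditions and 30 replicates for the dense
9-layer, missing-data and directional comparisons — enough that the mean
ARIs (≈0.97–0.99 for the headline conditions, against the 0.9 recovery
threshold) are
stable across seeds while keeping a full run in minutes on one CPU.  All
randomness flows from a single integer seed through `numpy` generators;
identical seeds give byte-identical outputs end to end.
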