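# multiplexcd — community detection in multiplex networks

Biological interaction data come in layers of very different nature and
quality: binary protein–protein interactions, co-expression, curated
pathways, protein complexes.  Each layer is a graph over (roughly) the same
genes/proteins, each is incomplete, and their densities differ by orders of
magnitude.  The classical workflow collapses the layers into a single graph
before clustering; `multiplexcd` instead detects communities *directly* from
the multiplex network and provides everything needed to compare the two
strategies: simulation benchmarks, partition scoring and annotation
enrichment.  It is aimed at network biologists and methods researchers who
want functional modules from heterogeneous interaction sources, or a
controlled testbed for multilayer community detection.

## The objective

For one graph `X` with total edge weight `m`, degrees `k_i` and a partition
`c`, the resolution-parametrized Newman–Girvan modularity used throughout is

    Q_γ(X, c) = (1/2m) Σ_{i≠j} ( X_ij − γ k_i k_j / 2m ) δ(c_i, c_j)

(ordered pairs, diagonal excluded; `γ > 0` scales only the null term, larger
values yield smaller communities).  A multiplex network is a collection of
layers `(X^(g))_g` on one shared vertex set; the **multiplex-modularity** of
a single partition shared by all layers is the sum of per-layer modularities,

    Q^M_γ((X^(g))_g, c) = Σ_g Q_γ(X^(g), c),

each layer keeping its own `m^g` and degrees — so a sparse curated layer and
a huge co-expression layer contribute on equal footing instead of the dense
layer drowning out the sparse one.  `Q^M_γ` is maximized with a Louvain
heuristic adapted to move vertices and contract *all* layers simultaneously.

The package also implements the baselines (union-, intersection- and
sum-aggregation followed by monoplex Louvain; consensus clustering of
per-layer partitions), a planted-partition multiplex SBM simulator with
vertex-withdrawal missing data, adjusted-Rand-index (ARI) scoring, and
one-sided Fisher exact tests with Bonferroni correction for annotation
enrichment of the detected communities.

## Worked example

Simulate a mixed-density multiplex (1,000 vertices, 20 planted communities
of 50, four layers each drawn sparse `p_I/p_E = 0.1/0.01` or dense
`0.5/0.2`), then recover the communities with each method:

```sh
multiplexcd simulate --regime mixed --layers 4 --n 1000 --communities 20 \
    --seed 3 --outdir demo
# INFO multiplexcd: layer edge counts: [107271, 7269, 7377, 7099]

multiplexcd cluster --layer demo/layer_1.txt --layer demo/layer_2.txt \
    --layer demo/layer_3.txt --layer demo/layer_4.txt \
    --method multiplex --seed 1 --output demo/multiplex.tsv
# INFO multiplexcd: 20 communities, multiplex-modularity 0.938391

multiplexcd evaluate --truth demo/planted_partition.tsv --pred demo/multiplex.tsv
# 1.000000
```

This draw has one dense and three sparse layers.  Re-running `cluster` with
`--method sum|union|intersection|consensus` on the same layers and scoring
each against the planted partition gives

| method       | ARI      |
|--------------|----------|
| multiplex    | 1.000000 |
| sum          | 0.820194 |
| union        | 0.546177 |
| intersection | 0.000621 |
| consensus    | 0.115241 |

The multiplex objective recovers the planted 20 communities exactly, while
sum-aggregation is dominated by the dense layer's noise, the union graph
saturates, the intersection graph is nearly empty, and the consensus of the
(individually uninformative) sparse-layer partitions lags far behind.  The
same comparison at scale is available as `multiplexcd benchmark --config
<yaml/json>`, which writes a tidy CSV of (regime, layers, method, replicate,
ARI) rows.

For real biological multiplexes (tens of thousands of vertices, layers of
very unequal size), raising the resolution parameter keeps communities at an
interpretable size; `--gamma 5` is a good starting point.  Communities can
then be tested for annotation enrichment:

```sh
multiplexcd enrich --partition demo/multiplex.tsv --annotations go_terms.tsv \
    --alpha 0.05 --out enrichment.tsv
```

with `go_terms.tsv` a two-column `gene<TAB>term` table; the output holds
one-sided Fisher p-values and Bonferroni q-values per (community, term) pair.

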