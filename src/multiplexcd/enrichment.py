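"""Annotation enrichment of detected communities.

Each (community, term) pair with at least one shared vertex is scored with a
one-sided Fisher exact test for over-representation: with a background of
``N`` vertices, a term covering ``K`` of them and a community of size ``n``
containing ``x`` annotated vertices, the p-value is the hypergeometric upper
tail ``P(X >= x)``.  Family-wise error is controlled with a Bonferroni
factor equal to the number of tested terms times the number of tested
communities (only terms/communities entering at least one tested pair
count).  The background universe defaults to the vertices present in both
the partition and the annotation table and can be overridden.

The same computation serves any vertex -> term table (gene-ontology terms,
disease-gene associations, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from scipy.stats import hypergeom

from .graphs import GraphError, communities

__all__ = ["AnnotationTable", "EnrichmentResult", "read_annotations", "enrich", "annotated_fraction"]


@dataclass(frozen=True)
class AnnotationTable:
    """Term -> vertex-set mapping plus the universe of annotated vertices."""

    terms: Mapping
    universe: frozenset

    @classmethod
    def from_pairs(cls, pairs) -> "AnnotationTable":
        terms: dict = {}
        for vertex, term in pairs:
            terms.setdefault(term, set()).add(vertex)
        terms = {t: frozenset(vs) for t, vs in terms.items()}
        universe = frozenset().union(*terms.values()) if terms else frozenset()
        return cls(terms=terms, universe=universe)


def read_annotations(path) -> AnnotationTable:
    """Read a two-column ``vertex<TAB>term`` TSV (flattened GAF/GMT style)."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise GraphError(f"line {lineno}: expected 'vertex<TAB>term'")
            pairs.append((parts[0], parts[1]))
    return AnnotationTable.from_pairs(pairs)


@dataclass(frozen=True)
class EnrichmentResult:
    community: object
    term: object
    overlap: int            # community ∩ term
    community_only: int     # community ∖ term
    term_only: int          # term ∖ community
    background: int         # neither, within the universe
    p: float                # one-sided Fisher (hypergeometric upper tail)
    q: float                # Bonferroni-adjusted, capped at 1
    significant: bool


def enrich(partition: Mapping, annotations: AnnotationTable, alpha: float = 0.05,
           universe=None) -> list:
    """Fisher/Bonferroni enrichment of every (community, term) pair with
    non-empty overlap, sorted by adjusted q-value.

    ``universe`` defaults to the vertices present in both the partition and
    the annotation table; communities and terms are restricted to it.
    """
    if not 0 < alpha < 1:
        raise GraphError("alpha must lie in (0, 1)")
    if universe is None:
        universe = set(partition) & set(annotations.universe)
    else:
        universe = set(universe)
    if not universe:
        raise GraphError("partition and annotation universes do not overlap")
    n_universe = len(universe)
    comm_sets = {
        lab: members & universe
        for lab, members in communities(partition).items()
    }
    comm_sets = {lab: mem for lab, mem in comm_sets.items() if mem}
    term_sets = {t: vs & universe for t, vs in annotations.terms.items()}
    term_sets = {t: vs for t, vs in term_sets.items() if vs}

    tested = []
    for lab, members in comm_sets.items():
        for term, annotated in term_sets.items():
            overlap = members & annotated
            if overlap:
                tested.append((lab, term, len(overlap), len(members), len(annotated)))
    if not tested:
        return []
    n_terms_tested = len({term for _, term, *_ in tested})
    n_comms_tested = len({lab for lab, *_ in tested})
    n_tests = n_terms_tested * n_comms_tested
    results = []
    for lab, term, x, comm_size, term_size in tested:
        p = float(hypergeom.sf(x - 1, n_universe, term_size, comm_size))
        q = min(1.0, p * n_tests)
        results.append(
            EnrichmentResult(
                community=lab,
                term=term,
                overlap=x,
                community_only=comm_size - x,
                term_only=term_size - x,
                background=n_universe - comm_size - term_size + x,
                p=p,
                q=q,
                significant=q < alpha,
            )
        )
    results.sort(key=lambda r: (r.q, r.p, str(r.community), str(r.term)))
    return results


def annotated_fraction(results, alpha: float = 0.05) -> float:
    """Fraction of tested communities with at least one result at q < alpha."""
    tested = {r.community for r in results}
    if not tested:
        return 0.0
    hit = {r.community for r in results if r.q < alpha}
    return len(hit) / len(tested)
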