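"""GO-term overrepresentation of significant regions among mutated regions.

Annotations are first propagated: every entity inherits, besides its direct
terms, all ancestors along every is_a/part_of path up to but excluding the
namespace roots.  Each term is then tested with a one-sided (right-tail)
Fisher exact test on the 2x2 table

    a = significant and annotated      b = significant, not annotated
    c = non-significant and annotated  d = non-significant, not annotated

where the background is the set of entities carrying at least one mutation.
No multiple-testing correction gates the output; a Benjamini-Hochberg column
is attached for convenience only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .io_formats import OntologyGraph

__all__ = [
    "EnrichmentResult",
    "enrich",
    "propagate_annotations",
    "right_tail_fisher",
]

DEFAULT_NAMESPACES = ("biological_process", "molecular_function")


def propagate_annotations(
    graph: OntologyGraph, annotations: Mapping[str, Iterable[str]]
) -> dict[str, frozenset[str]]:
    """Close each entity's term set under ancestors, excluding the roots.

    Terms absent from the graph are dropped (the reader already warns about
    them).  Propagation is idempotent: ancestor sets are themselves closed.
    """
    roots = graph.roots
    expanded: dict[str, frozenset[str]] = {}
    for entity, terms in annotations.items():
        closed: set[str] = set()
        for term in terms:
            if term not in graph.parents:
                continue
            closed.add(term)
            closed.update(graph.ancestors(term))
        expanded[entity] = frozenset(closed - roots)
    return expanded


def right_tail_fisher(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for X hypergeometric with population a+b+c+d, a+c annotated
    entities and a+b significant draws — the right tail of Fisher's exact test."""
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be nonnegative")
    population = a + b + c + d
    if population == 0:
        raise ValueError("empty table")
    return float(_stats.hypergeom.sf(a - 1, population, a + c, a + b))


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    name: str
    a: int
    b: int
    c: int
    d: int
    p: float
    q: float | None = None


def enrich(
    significant: Iterable[str],
    background: Iterable[str],
    annotations: Mapping[str, frozenset[str]],
    graph: OntologyGraph | None = None,
    namespaces: tuple[str, ...] = DEFAULT_NAMESPACES,
) -> list[EnrichmentResult]:
    """Right-tail Fisher enrichment of each term among significant entities.

    ``significant`` must be a subset of ``background``.  Terms annotated to no
    background entity are skipped; when a ``graph`` with namespace records is
    given, only terms in ``namespaces`` are tested (cellular_component is out
    by default).  Results are sorted by ascending p, ties by term id.
    """
    significant = frozenset(significant)
    background = frozenset(background)
    if not significant <= background:
        raise ValueError("significant set must be a subset of the background")
    if not significant:
        return []

    annotated_by_term: dict[str, set[str]] = {}
    for entity in background:
        for term in annotations.get(entity, ()):  # unannotated entities still count in b/d
            annotated_by_term.setdefault(term, set()).add(entity)

    n_significant = len(significant)
    n_background = len(background)
    results = []
    for term, entities in annotated_by_term.items():
        if graph is not None and graph.namespaces:
            if graph.namespaces.get(term) not in namespaces:
                continue
        a = len(entities & significant)
        c = len(entities) - a
        b = n_significant - a
        d = n_background - n_significant - c
        name = graph.names.get(term, "") if graph is not None else ""
        results.append(
            EnrichmentResult(term=term, name=name, a=a, b=b, c=c, d=d, p=right_tail_fisher(a, b, c, d))
        )
    results.sort(key=lambda r: (r.p, r.term))
    if results:
        q_values = multipletests([r.p for r in results], method="fdr_bh")[1]
        results = [
            EnrichmentResult(r.term, r.name, r.a, r.b, r.c, r.d, r.p, q=float(q))
            for r, q in zip(results, q_values)
        ]
    return results
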