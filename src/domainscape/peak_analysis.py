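"""How domain peaks relate to gene peaks, and landscape comparison across cohorts.

A significant domain may draw its mutations from genes that are themselves
significant (the domain peak simply mirrors gene peaks), from genes none of
which reach significance (pure aggregation — the signature finding of the
domain-centric view), or from a mixture.  A further question is persistence:
does a domain peak survive once every mutation belonging to a significant
gene is deleted (node removal) and the domain landscape re-scored from
scratch?
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .landscape_stats import LandscapeResult, domain_landscape
from .preprocess import Cohort

__all__ = [
    "LandscapeComparison",
    "PeakOrigin",
    "classify_peak_origins",
    "compare_cohorts",
    "compare_significant_sets",
    "recall_after_gene_peak_removal",
    "shared_domain_in_shared_gene",
]

ORIGIN_CLASSES = ("from_gene_peaks", "aggregated", "mixed")


@dataclass
class PeakOrigin:
    """Origin classification of one significant domain peak."""

    domain_acc: str
    origin_class: str
    contributing: dict[str, int]
    significant_genes: frozenset[str]
    retained_after_removal: bool | None = None

    def __post_init__(self) -> None:
        if self.origin_class not in ORIGIN_CLASSES:
            raise ValueError(f"unknown origin class {self.origin_class!r}")


def classify_peak_origins(
    domain_result: LandscapeResult,
    gene_result: LandscapeResult,
    breakdowns: Mapping[str, Mapping[str, int]] | None = None,
) -> list[PeakOrigin]:
    """Classify every significant domain by the significance of its gene
    contributors: all significant -> from_gene_peaks; none -> aggregated;
    otherwise mixed.  A significant domain with an empty breakdown violates
    the domain-count invariant and is an error.
    """
    if breakdowns is None:
        breakdowns = domain_result.breakdown
    significant_genes = gene_result.significant_ids
    origins = []
    for stat in domain_result.stats:
        if not stat.significant:
            continue
        contributing = dict(breakdowns.get(stat.region_id, {}))
        if not contributing:
            raise ValueError(f"significant domain {stat.region_id} has an empty gene breakdown")
        hits = {g for g in contributing if g in significant_genes}
        if hits == set(contributing):
            origin_class = "from_gene_peaks"
        elif not hits:
            origin_class = "aggregated"
        else:
            origin_class = "mixed"
        origins.append(
            PeakOrigin(
                domain_acc=stat.region_id,
                origin_class=origin_class,
                contributing=contributing,
                significant_genes=frozenset(hits),
            )
        )
    return sorted(origins, key=lambda o: o.domain_acc)


def recall_after_gene_peak_removal(
    cohort: Cohort,
    gene_result: LandscapeResult,
    *,
    domain_result: LandscapeResult | None = None,
    **landscape_options,
) -> tuple[LandscapeResult, dict[str, bool]]:
    """Delete every mutation of every significant gene and re-score domains.

    The whole gene's mutations are removed (node removal), not only the
    in-domain ones; the background p0 and the lfdr fit are recomputed on the
    reduced cohort, while the protein set and cumulative domain lengths stay
    fixed.  Returns the post-removal domain landscape and, for each domain
    significant before removal, whether it is still significant after.
    """
    if domain_result is None:
        domain_result = domain_landscape(cohort, **landscape_options)
    removed_genes = gene_result.significant_ids
    reduced_mutations = [m for m in cohort.mutations if m.gene not in removed_genes]
    reduced = Cohort(
        name=f"{cohort.name}|minus_gene_peaks",
        patients=cohort.patients,
        mutations=reduced_mutations,
        proteins=cohort.proteins,
        domains=cohort.domains,
    )
    after = domain_landscape(reduced, **landscape_options)
    retained = {
        domain_acc: (domain_acc in after.significant_ids)
        for domain_acc in sorted(domain_result.significant_ids)
    }
    return after, retained


@dataclass
class LandscapeComparison:
    """Venn summary of significant regions in two cohorts of the same kind."""

    name_a: str
    name_b: str
    kind: str
    significant_a: frozenset[str]
    significant_b: frozenset[str]

    @property
    def shared(self) -> frozenset[str]:
        return self.significant_a & self.significant_b

    @property
    def only_a(self) -> frozenset[str]:
        return self.significant_a - self.significant_b

    @property
    def only_b(self) -> frozenset[str]:
        return self.significant_b - self.significant_a

    @property
    def percent_shared_a(self) -> float:
        """Shared peaks as a percentage of cohort A's peaks, to one decimal."""
        if not self.significant_a:
            return 0.0
        return round(100.0 * len(self.shared) / len(self.significant_a), 1)

    @property
    def percent_shared_b(self) -> float:
        if not self.significant_b:
            return 0.0
        return round(100.0 * len(self.shared) / len(self.significant_b), 1)

    def venn_counts(self) -> dict[str, int]:
        return {
            "only_a": len(self.only_a),
            "only_b": len(self.only_b),
            "shared": len(self.shared),
            "union": len(self.significant_a | self.significant_b),
        }


def compare_significant_sets(
    set_a: frozenset[str] | set[str],
    set_b: frozenset[str] | set[str],
    kind: str,
    name_a: str = "A",
    name_b: str = "B",
) -> LandscapeComparison:
    return LandscapeComparison(
        name_a=name_a,
        name_b=name_b,
        kind=kind,
        significant_a=frozenset(set_a),
        significant_b=frozenset(set_b),
    )


def compare_cohorts(
    result_a: LandscapeResult,
    result_b: LandscapeResult,
    kind: str,
    name_a: str = "A",
    name_b: str = "B",
) -> LandscapeComparison:
    """Venn comparison of two called landscapes of the same kind."""
    if result_a.kind != kind or result_b.kind != kind:
        raise ValueError(
            f"kind mismatch: comparing {result_a.kind!r} vs {result_b.kind!r} as {kind!r}"
        )
    return compare_significant_sets(
        result_a.significant_ids, result_b.significant_ids, kind, name_a, name_b
    )


def shared_domain_in_shared_gene(
    gene_comparison: LandscapeComparison,
    domain_comparison: LandscapeComparison,
    domain_hosts: Mapping[str, frozenset[str]],
) -> list[str]:
    """Shared domain peaks whose host genes intersect the shared gene peaks."""
    shared_genes = gene_comparison.shared
    return sorted(
        d for d in domain_comparison.shared if domain_hosts.get(d, frozenset()) & shared_genes
    )
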