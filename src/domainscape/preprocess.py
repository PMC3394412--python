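"""Cohort assembly: filtering, representative-isoform selection, domain mapping.

The filtering policy retains a mutation only if it is somatic, passed QC, is
not listed in the supplied dbSNP-style exclusion set, and is not a synonymous
SNV.  The rules are pure conjunctive predicates, so their application order is
irrelevant; per-rule removal counts are reported.

A gene's representative protein is its longest isoform (ties broken by the
lexicographically smallest accession) and is the only protein mutations are
mapped onto — this avoids counting the same DNA event once per transcript.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import DomainInstance, MutationRecord, ProteinRecord

__all__ = [
    "FILTER_RULES",
    "Cohort",
    "CohortError",
    "CohortReport",
    "CompositionSummary",
    "DomainAssignment",
    "FilterReport",
    "assign_mutations_to_domains",
    "build_cohort",
    "classify_indel",
    "composition_from_counts",
    "cohort_composition",
    "count_recurrence",
    "filter_cohort",
    "select_representative_proteins",
]


class CohortError(ValueError):
    """A cohort invariant is violated (e.g. a mutation beyond protein length)."""


# Each rule is a removal predicate: True means the record is removed by that
# rule.  Retention is the conjunction of all rules failing, so any application
# order yields the same retained set.
FILTER_RULES: dict[str, Callable[[MutationRecord, frozenset[str]], bool]] = {
    "germline": lambda r, excl: not r.is_somatic,
    "failed_qc": lambda r, excl: not r.passed_qc,
    "in_dbsnp": lambda r, excl: r.dbsnp_id is not None and r.dbsnp_id in excl,
    "synonymous": lambda r, excl: r.variant_class == "synonymous_SNV",
}


@dataclass
class FilterReport:
    """Per-rule removal counts (a record may be counted under several rules)."""

    n_input: int
    n_retained: int
    removed_by_rule: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": rule, "removed": n} for rule, n in sorted(self.removed_by_rule.items())]
        rows.append({"rule": "total_retained", "removed": self.n_retained})
        return pd.DataFrame(rows, columns=["rule", "removed"])


def filter_cohort(
    records: Iterable[MutationRecord], exclusion_ids: Iterable[str] = ()
) -> tuple[list[MutationRecord], FilterReport]:
    """Apply the four retention rules; returns (retained records, report)."""
    exclusion = frozenset(exclusion_ids)
    records = list(records)
    removed = {rule: 0 for rule in FILTER_RULES}
    retained = []
    for record in records:
        hit = False
        for rule, predicate in FILTER_RULES.items():
            if predicate(record, exclusion):
                removed[rule] += 1
                hit = True
        if not hit:
            retained.append(record)
    return retained, FilterReport(n_input=len(records), n_retained=len(retained), removed_by_rule=removed)


def count_recurrence(records: Iterable[MutationRecord]) -> Counter:
    """Occurrences of each variant across distinct patients.

    A variant observed in m distinct patients counts m; duplicate
    (sample, variant) rows count once.
    """
    seen: set[tuple] = set()
    counts: Counter = Counter()
    for record in records:
        key = (record.sample_id, *record.variant_key)
        if key in seen:
            continue
        seen.add(key)
        counts[record.variant_key] += 1
    return counts


def select_representative_proteins(proteins: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Flag exactly one representative isoform per gene: maximal length,
    ties broken by the lexicographically smallest accession."""
    by_gene: dict[str, list[ProteinRecord]] = {}
    for protein in proteins:
        by_gene.setdefault(protein.gene, []).append(protein)
    flagged = []
    for gene, isoforms in by_gene.items():
        if not isoforms:
            raise CohortError(f"gene {gene} has no isoforms")
        best = min(isoforms, key=lambda p: (-p.length, p.protein_acc))
        for protein in isoforms:
            flagged.append(
                ProteinRecord(
                    gene=protein.gene,
                    protein_acc=protein.protein_acc,
                    length=protein.length,
                    is_representative=protein is best,
                )
            )
    return flagged


def classify_indel(nucleotide_length: int) -> str:
    """Frameshift iff the inserted/deleted nucleotide count is not a multiple of 3."""
    if nucleotide_length < 1:
        raise ValueError("indel length must be >= 1 nucleotide")
    return "nonframeshift" if nucleotide_length % 3 == 0 else "frameshift"


@dataclass
class Cohort:
    """A filtered cohort: mutations mapped onto representative proteins."""

    name: str
    patients: frozenset[str]
    mutations: list[MutationRecord]
    proteins: list[ProteinRecord]
    domains: list[DomainInstance]
    protein_by_acc: dict[str, ProteinRecord] = field(init=False, repr=False)
    representatives: dict[str, ProteinRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.protein_by_acc = {p.protein_acc: p for p in self.proteins}
        self.representatives = {p.gene: p for p in self.proteins if p.is_representative}

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def validate(self) -> None:
        rep_accs = {p.protein_acc for p in self.representatives.values()}
        for i, m in enumerate(self.mutations):
            if m.protein_acc not in rep_accs:
                raise CohortError(f"mutation {i} maps to non-representative protein {m.protein_acc}")
            if m.protein_pos > self.protein_by_acc[m.protein_acc].length:
                raise CohortError(
                    f"mutation {i} at position {m.protein_pos} exceeds length of {m.protein_acc}"
                )
        for d in self.domains:
            if d.protein_acc not in self.protein_by_acc:
                raise CohortError(f"domain instance on unknown protein {d.protein_acc}")
            if d.end > self.protein_by_acc[d.protein_acc].length:
                raise CohortError(f"domain instance {d.domain_acc} exceeds length of {d.protein_acc}")


@dataclass
class CohortReport:
    filter: FilterReport
    n_duplicate_rows: int
    n_nonrepresentative: int
    n_unknown_protein: int
    n_domain_instances_dropped: int


def build_cohort(
    name: str,
    records: Iterable[MutationRecord],
    proteins: Sequence[ProteinRecord],
    domains: Iterable[DomainInstance],
    *,
    exclusion_ids: Iterable[str] = (),
    patients: Iterable[str] | None = None,
) -> tuple[Cohort, CohortReport]:
    """Filter records, deduplicate, pick representatives and validate.

    ``patients`` fixes the cohort size (for prevalence); by default it is the
    set of sample ids observed in the *input* records, since patients without
    retained mutations still count toward prevalence denominators.
    """
    records = list(records)
    retained, filter_report = filter_cohort(records, exclusion_ids)

    deduped: list[MutationRecord] = []
    seen: set[tuple] = set()
    for record in retained:
        key = (record.sample_id, *record.variant_key)
        if key in seen:
            continue
        seen.add(key)
        deduped.append(record)
    n_duplicates = len(retained) - len(deduped)

    flagged = select_representative_proteins(proteins)
    rep_accs = {p.protein_acc for p in flagged if p.is_representative}
    known_accs = {p.protein_acc for p in flagged}

    mutations = []
    n_nonrep = 0
    n_unknown = 0
    for record in deduped:
        if record.protein_acc in rep_accs:
            mutations.append(record)
        elif record.protein_acc in known_accs:
            n_nonrep += 1
        else:
            n_unknown += 1

    kept_domains = []
    n_dom_dropped = 0
    for instance in domains:
        if instance.protein_acc in rep_accs:
            kept_domains.append(instance)
        else:
            n_dom_dropped += 1

    cohort = Cohort(
        name=name,
        patients=frozenset(patients) if patients is not None else frozenset(r.sample_id for r in records),
        mutations=mutations,
        proteins=flagged,
        domains=kept_domains,
    )
    cohort.validate()
    report = CohortReport(
        filter=filter_report,
        n_duplicate_rows=n_duplicates,
        n_nonrepresentative=n_nonrep,
        n_unknown_protein=n_unknown,
        n_domain_instances_dropped=n_dom_dropped,
    )
    return cohort, report


@dataclass(frozen=True, slots=True)
class DomainAssignment:
    """A mutation (by index into cohort.mutations) inside one domain instance."""

    mutation_index: int
    domain_acc: str
    protein_acc: str
    start: int
    end: int


def assign_mutations_to_domains(cohort: Cohort) -> tuple[list[DomainAssignment], float]:
    """Assign each mutation to every domain instance covering its position.

    Indels use their start residue.  Overlapping instances (same or different
    domains) each receive an assignment.  Returns the assignment list and the
    fraction of mutations falling inside at least one instance.
    """
    trees: dict[str, IntervalTree] = {}
    for instance in cohort.domains:
        trees.setdefault(instance.protein_acc, IntervalTree()).addi(
            instance.start, instance.end + 1, instance
        )

    assignments: list[DomainAssignment] = []
    covered = 0
    for i, mutation in enumerate(cohort.mutations):
        if mutation.protein_pos > cohort.protein_by_acc[mutation.protein_acc].length:
            raise CohortError(
                f"mutation {i} at {mutation.protein_pos} exceeds protein length"
            )
        tree = trees.get(mutation.protein_acc)
        hits = sorted(
            (iv.data for iv in tree[mutation.protein_pos]) if tree is not None else [],
            key=lambda d: (d.domain_acc, d.start, d.end),
        )
        if hits:
            covered += 1
        for instance in hits:
            assignments.append(
                DomainAssignment(
                    mutation_index=i,
                    domain_acc=instance.domain_acc,
                    protein_acc=instance.protein_acc,
                    start=instance.start,
                    end=instance.end,
                )
            )
    fraction = covered / len(cohort.mutations) if cohort.mutations else 0.0
    return assignments, fraction


# ---------------------------------------------------------------------------
# composition reporting

@dataclass(frozen=True)
class CompositionSummary:
    """Cohort-level mutation composition, mirroring the summary-table arithmetic."""

    n_total: int
    n_patients: int
    class_counts: Mapping[str, int]
    n_in_domain: int

    @property
    def class_percent(self) -> dict[str, float]:
        return {c: round(100.0 * n / self.n_total, 1) for c, n in self.class_counts.items()}

    @property
    def in_domain_percent(self) -> float:
        return round(100.0 * self.n_in_domain / self.n_total, 1)

    @property
    def mean_per_patient(self) -> float:
        return self.n_total / self.n_patients


def composition_from_counts(
    class_counts: Mapping[str, int], n_in_domain: int, n_patients: int
) -> CompositionSummary:
    """Build the composition summary from per-class tallies."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    total = sum(class_counts.values())
    if total < 1:
        raise ValueError("no mutations tallied")
    if not (0 <= n_in_domain <= total):
        raise ValueError("n_in_domain outside [0, total]")
    return CompositionSummary(
        n_total=total, n_patients=n_patients, class_counts=dict(class_counts), n_in_domain=n_in_domain
    )


def cohort_composition(cohort: Cohort, assignments: Sequence[DomainAssignment]) -> CompositionSummary:
    """Composition summary of a built cohort (in-domain = covered by >=1 instance)."""
    class_counts = Counter(m.variant_class for m in cohort.mutations)
    n_in_domain = len({a.mutation_index for a in assignments})
    return composition_from_counts(class_counts, n_in_domain, cohort.n_patients)
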