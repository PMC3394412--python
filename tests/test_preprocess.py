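"""Filtering, representative selection, recurrence and domain assignment."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from domainscape.io_formats import DomainInstance, MutationRecord, ProteinRecord
from domainscape import preprocess
from domainscape.preprocess import (
    FILTER_RULES,
    assign_mutations_to_domains,
    build_cohort,
    classify_indel,
    composition_from_counts,
    count_recurrence,
    filter_cohort,
    select_representative_proteins,
)


def _mut(sample="S1", gene="G1", acc="NP_1", pos=10, variant_class="nsSNV", **kw):
    defaults = dict(ref_res="A", alt_res="V")
    defaults.update(kw)
    return MutationRecord(sample, gene, acc, pos, variant_class=variant_class, **defaults)


class TestFilterCohort:
    @pytest.mark.parametrize(
        "record,removed",
        [
            (_mut(variant_class="synonymous_SNV"), True),  # synonymous somatic SNV
            (_mut(dbsnp_id="rs130"), True),  # listed in the exclusion set
            (_mut(is_somatic=False), True),  # germline
            (_mut(passed_qc=False), True),  # QC failure
            (_mut(variant_class="frameshift_ins"), False),  # somatic indel, QC pass
            (_mut(dbsnp_id="rs999"), False),  # dbSNP id not in the exclusion set
        ],
    )
    def test_rules(self, record, removed):
        retained, _ = filter_cohort([record], exclusion_ids={"rs130"})
        assert (len(retained) == 0) == removed

    def test_per_rule_counts(self):
        records = [
            _mut(variant_class="synonymous_SNV", is_somatic=False),  # two rules at once
            _mut(dbsnp_id="rs130"),
            _mut(),
        ]
        retained, report = filter_cohort(records, exclusion_ids={"rs130"})
        assert len(retained) == 1
        assert report.removed_by_rule == {"germline": 1, "failed_qc": 0, "in_dbsnp": 1, "synonymous": 1}
        assert report.n_input == 3 and report.n_retained == 1

    def test_order_independence(self):
        """Any permutation of the four rules removes the same set."""
        records = [
            _mut(sample=f"S{i}", pos=i + 1, variant_class=vc, is_somatic=som, passed_qc=qc, dbsnp_id=db)
            for i, (vc, som, qc, db) in enumerate(
                itertools.product(
                    ["nsSNV", "synonymous_SNV", "frameshift_del"],
                    [True, False],
                    [True, False],
                    [None, "rs130", "rs7"],
                )
            )
        ]
        exclusion = frozenset({"rs130"})
        reference, _ = filter_cohort(records, exclusion)
        for order in itertools.permutations(FILTER_RULES):
            surviving = list(records)
            for rule in order:
                surviving = [r for r in surviving if not FILTER_RULES[rule](r, exclusion)]
            assert surviving == reference


class TestRecurrence:
    def test_same_variant_three_patients_counts_three(self):
        records = [_mut(sample=s) for s in ("S1", "S2", "S3")]
        counts = count_recurrence(records)
        assert counts[records[0].variant_key] == 3

    def test_duplicate_sample_rows_count_once(self):
        records = [_mut(sample="S1"), _mut(sample="S1")]
        assert count_recurrence(records)[records[0].variant_key] == 1

    def test_disjoint_variants_each_count_one(self):
        records = [_mut(sample="S1", pos=1), _mut(sample="S2", pos=2)]
        assert set(count_recurrence(records).values()) == {1}


class TestRepresentativeSelection:
    def test_longest_isoform_wins(self):
        proteins = [ProteinRecord("APC", "NP_A", 2843), ProteinRecord("APC", "NP_B", 1200)]
        flagged = {p.protein_acc: p.is_representative for p in select_representative_proteins(proteins)}
        assert flagged == {"NP_A": True, "NP_B": False}

    def test_tie_broken_by_smallest_accession(self):
        proteins = [ProteinRecord("G", "NP_2", 400), ProteinRecord("G", "NP_1", 400)]
        flagged = {p.protein_acc: p.is_representative for p in select_representative_proteins(proteins)}
        assert flagged == {"NP_1": True, "NP_2": False}

    def test_single_isoform_is_its_own_representative(self):
        [protein] = select_representative_proteins([ProteinRecord("G", "NP_1", 100)])
        assert protein.is_representative

    def test_exactly_one_representative_per_gene(self):
        proteins = [
            ProteinRecord("G1", "NP_1", 100),
            ProteinRecord("G1", "NP_2", 300),
            ProteinRecord("G2", "NP_3", 50),
        ]
        flagged = select_representative_proteins(proteins)
        per_gene = {}
        for p in flagged:
            per_gene[p.gene] = per_gene.get(p.gene, 0) + p.is_representative
        assert per_gene == {"G1": 1, "G2": 1}


class TestClassifyIndel:
    @pytest.mark.parametrize("length,expected", [(3, "nonframeshift"), (1, "frameshift"), (9, "nonframeshift"), (4, "frameshift")])
    def test_frame_rule(self, length, expected):
        assert classify_indel(length) == expected

    def test_zero_length_is_error(self):
        with pytest.raises(ValueError):
            classify_indel(0)


def _toy_cohort():
    proteins = [ProteinRecord("G1", "NP_1", 200), ProteinRecord("G2", "NP_2", 300)]
    domains = [
        DomainInstance("PF1", "D1", "NP_1", 50, 120, 0.0),
        DomainInstance("PF2", "D2", "NP_1", 100, 160, 0.0),  # overlaps PF1 on 100..120
        DomainInstance("PF1", "D1", "NP_2", 10, 80, 0.0),
    ]
    records = [
        _mut(sample="S1", gene="G1", acc="NP_1", pos=110),  # inside both PF1 and PF2
        _mut(sample="S2", gene="G1", acc="NP_1", pos=130),  # PF2 only
        _mut(sample="S3", gene="G1", acc="NP_1", pos=180),  # linker
        _mut(sample="S4", gene="G2", acc="NP_2", pos=79, variant_class="frameshift_del"),
    ]
    return records, proteins, domains


class TestDomainAssignment:
    def test_overlap_linker_and_indel_start_rule(self):
        records, proteins, domains = _toy_cohort()
        cohort, _ = build_cohort("toy", records, proteins, domains)
        assignments, fraction = assign_mutations_to_domains(cohort)
        by_mutation = {}
        for a in assignments:
            by_mutation.setdefault(a.mutation_index, []).append(a.domain_acc)
        # position covered by two overlapping instances of different domains -> two assignments
        assert sorted(by_mutation[0]) == ["PF1", "PF2"]
        assert by_mutation[1] == ["PF2"]
        assert 2 not in by_mutation  # linker position: no assignment
        # deletion starting inside the instance is assigned even though the
        # event may extend past the instance end
        assert by_mutation[3] == ["PF1"]
        assert fraction == pytest.approx(3 / 4)

    def test_interval_invariant_and_bruteforce_oracle(self):
        """Tree-based assignment agrees with a naive scan over all instances."""
        import numpy as np

        rng = np.random.default_rng(11)
        proteins = [ProteinRecord(f"G{i}", f"NP_{i}", int(rng.integers(100, 400))) for i in range(8)]
        domains = []
        for j in range(25):
            p = proteins[int(rng.integers(0, len(proteins)))]
            start = int(rng.integers(1, p.length - 10))
            end = int(rng.integers(start, min(start + 120, p.length)))
            domains.append(DomainInstance(f"PF{j % 6}", f"D{j % 6}", p.protein_acc, start, end, 0.0))
        records = []
        for i in range(60):
            p = proteins[int(rng.integers(0, len(proteins)))]
            records.append(_mut(sample=f"S{i}", gene=p.gene, acc=p.protein_acc, pos=int(rng.integers(1, p.length + 1))))
        cohort, _ = build_cohort("rand", records, proteins, domains)
        assignments, _ = assign_mutations_to_domains(cohort)
        got = {(a.mutation_index, a.domain_acc, a.start, a.end) for a in assignments}
        expected = set()
        for i, m in enumerate(cohort.mutations):
            for d in domains:
                if d.protein_acc == m.protein_acc and d.start <= m.protein_pos <= d.end:
                    expected.add((i, d.domain_acc, d.start, d.end))
        assert got == expected
        assert all(a.start <= cohort.mutations[a.mutation_index].protein_pos <= a.end for a in assignments)

    def test_position_beyond_protein_length_is_hard_error(self):
        records = [_mut(pos=250)]
        proteins = [ProteinRecord("G1", "NP_1", 200)]
        with pytest.raises(preprocess.CohortError):
            build_cohort("bad", records, proteins, [])


class TestBuildCohort:
    def test_nonrepresentative_mutations_dropped_with_count(self):
        proteins = [ProteinRecord("G1", "NP_LONG", 300), ProteinRecord("G1", "NP_SHORT", 100)]
        records = [_mut(acc="NP_LONG", pos=10), _mut(sample="S2", acc="NP_SHORT", pos=5)]
        cohort, report = build_cohort("c", records, proteins, [])
        assert len(cohort.mutations) == 1
        assert report.n_nonrepresentative == 1

    def test_duplicate_sample_variant_rows_deduplicated(self):
        proteins = [ProteinRecord("G1", "NP_1", 100)]
        records = [_mut(), _mut()]
        cohort, report = build_cohort("c", records, proteins, [])
        assert len(cohort.mutations) == 1 and report.n_duplicate_rows == 1

    def test_class_counts_partition_retained(self):
        proteins = [ProteinRecord("G1", "NP_1", 500)]
        records = [
            _mut(sample=f"S{i}", pos=i + 1, variant_class=vc)
            for i, vc in enumerate(["nsSNV", "nsSNV", "stopgain_SNV", "frameshift_ins", "synonymous_SNV"])
        ]
        cohort, _ = build_cohort("c", records, proteins, [])
        composition = preprocess.cohort_composition(cohort, [])
        assert sum(composition.class_counts.values()) == len(cohort.mutations) == 4


class TestComposition:
    def test_percentages_and_mean(self):
        summary = composition_from_counts({"nsSNV": 796, "stopgain_SNV": 204}, n_in_domain=500, n_patients=10)
        assert summary.class_percent["nsSNV"] == 79.6
        assert summary.in_domain_percent == 50.0
        assert summary.mean_per_patient == 100.0

    @given(st.integers(1, 500), st.integers(0, 500), st.integers(1, 50))
    def test_in_domain_percent_bounded(self, a, b, patients):
        summary = composition_from_counts({"nsSNV": a}, n_in_domain=min(b, a), n_patients=patients)
        assert 0.0 <= summary.in_domain_percent <= 100.0
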