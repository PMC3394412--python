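"""Worked-example cohort: a synthetic reconstruction of a colon-cancer excerpt.

This module rebuilds, as concrete inputs, the per-gene/per-domain tallies of a
100-patient colon adenocarcinoma exome study that the package's arithmetic is
demonstrated against: domain aggregation totals (e.g. the Ras-family G-domain
"Miro" aggregating 77 mutations over a 5,861-aa cumulative length; the P53
DNA-binding domain with 28 mutations over 390 aa from TP53 and TP63; the WAP
four-disulfide core with 6 mutations from four genes; the beta-catenin-binding
APC_crr repeat occurring 7 times in APC), selected representative-protein
lengths (KRAS 189 aa, TP53 393 aa, APC 2,843 aa), and cohort-level composition
tallies.

Everything not fixed by those tallies — domain instance placements, sample
identifiers, mutation positions, and the lengths of proteins whose lengths are
not part of the reference excerpt — is SYNTHETIC: invented deterministic
filler that satisfies the interval and length invariants.  The reconstruction
is therefore suitable for exercising the aggregation arithmetic, not for any
biological statement about the listed genes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import DomainInstance, MutationRecord, ProteinRecord

__all__ = [
    "COLON_SUMMARY_TALLIES",
    "colon_domain_excerpt",
]

#: Cohort-level composition tallies of the reference colon excerpt
#: (retained mutation classes, in-domain count, cohort size).
COLON_SUMMARY_TALLIES = {
    "n_patients": 100,
    "class_counts": {
        "nsSNV": 17174,
        "frameshift_ins": 2527,
        "nonframeshift_ins": 239,
        "frameshift_del": 5,
        "nonframeshift_del": 0,
        "stoploss_SNV": 33,
        "stopgain_SNV": 1594,
    },
    "n_in_domain": 10647,
}

# (domain_acc, domain_name, [(gene, instance_length), ...]) — instance lengths
# sum to the reference cumulative domain length.
_DOMAIN_LAYOUT = [
    ("PF08477", "Miro", None),  # built programmatically below (41 hosts, 5861 aa)
    ("PF03166", "MH2", [("SMAD4", 147), ("SMAD9", 146), ("SMAD2", 146), ("SMAD3", 146), ("GARS", 146)]),
    ("PF00870", "P53", [("TP53", 193), ("TP63", 197)]),
    ("PF00095", "WAP", [("WFDC8", 75), ("SLPI", 75), ("WFDC5", 75), ("KAL1", 74)]),
    ("PF09727", "CortBP2", [("CTTNBP2NL", 182), ("CTTNBP2", 182), ("FILIP1", 182), ("FILIP1L", 180)]),
    ("PF05190", "MutS_IV", [("MSH4", 95), ("MSH6", 95), ("MSH5", 95), ("MSH2", 95)]),
    ("PF02192", "PI3K_p85B", [("PIK3CA", 231)]),
    ("PF05956", "APC_basic", [("APC", 356)]),
    # APC_crr: 7 tandem repeats on APC, cumulative 176 aa (6 x 25 + 26).
]

#: In-domain mutation counts per (domain, gene); gene-level totals below add
#: the out-of-domain remainder.
_IN_DOMAIN_COUNTS = {
    ("PF08477", "KRAS"): 28,
    ("PF08477", "NRAS"): 7,
    ("PF08477", "RAB27B"): 2,
    ("PF08477", "RAB11B"): 2,
    ("PF08477", "RABL3"): 2,
    ("PF03166", "SMAD4"): 9,
    ("PF03166", "SMAD9"): 2,
    ("PF03166", "SMAD2"): 1,
    ("PF03166", "SMAD3"): 1,
    ("PF03166", "GARS"): 1,
    ("PF00870", "TP53"): 27,
    ("PF00870", "TP63"): 1,
    ("PF00095", "WFDC8"): 3,
    ("PF00095", "SLPI"): 1,
    ("PF00095", "WFDC5"): 1,
    ("PF00095", "KAL1"): 1,
    ("PF09727", "CTTNBP2NL"): 1,
    ("PF09727", "CTTNBP2"): 2,
    ("PF09727", "FILIP1"): 5,
    ("PF09727", "FILIP1L"): 1,
    ("PF05190", "MSH4"): 2,
    ("PF05190", "MSH6"): 2,
    ("PF05190", "MSH5"): 1,
    ("PF05190", "MSH2"): 1,
    ("PF02192", "PIK3CA"): 4,
    ("PF05956", "APC"): 5,
    ("PF05923", "APC"): 8,
}

#: Gene-level totals where the reference fixes them above the in-domain sum.
_GENE_TOTALS = {"KRAS": 30, "TP53": 31, "APC": 76, "PIK3CA": 9}

#: Reference representative-protein lengths; genes absent here get synthetic
#: filler lengths derived from their instance placements.
_KNOWN_LENGTHS = {"KRAS": 189, "NRAS": 189, "TP53": 393, "APC": 2843, "PIK3CA": 1068}

_MIRO_EXTRA_HOSTS = 36  # one in-domain mutation each (total 77 with the named hosts)


def _miro_layout() -> list[tuple[str, int]]:
    hosts = [("KRAS", 143), ("NRAS", 143), ("RAB27B", 143), ("RAB11B", 143), ("RABL3", 143)]
    for i in range(1, _MIRO_EXTRA_HOSTS + 1):
        hosts.append((f"RABX{i:02d}", 143 if i < _MIRO_EXTRA_HOSTS else 141))
    return hosts  # 40 x 143 + 141 = 5861


@dataclass(frozen=True)
class _Placement:
    gene: str
    start: int
    end: int


def colon_domain_excerpt() -> tuple[
    list[MutationRecord], list[ProteinRecord], list[DomainInstance]
]:
    """Build the excerpt cohort: mutation rows, proteins and domain instances.

    Each mutation is observed in its own patient (occurrence-weighted counts
    equal row counts); every record is somatic, QC-pass and non-synonymous.
    """
    instances: list[DomainInstance] = []
    placements: dict[tuple[str, str], list[_Placement]] = {}
    max_end: dict[str, int] = {}

    def place(domain_acc: str, domain_name: str, gene: str, length: int) -> None:
        # tile instances left-to-right on the gene, leaving a 9-residue linker
        start = max_end.get(gene, 0) + 10
        end = start + length - 1
        max_end[gene] = end
        instances.append(
            DomainInstance(
                domain_acc=domain_acc,
                domain_name=domain_name,
                protein_acc=f"NP_{gene}",
                start=start,
                end=end,
                evalue=1e-10,
            )
        )
        placements.setdefault((domain_acc, gene), []).append(_Placement(gene, start, end))

    for domain_acc, domain_name, layout in _DOMAIN_LAYOUT:
        if layout is None:
            layout = _miro_layout()
        for gene, length in layout:
            place(domain_acc, domain_name, gene, length)
    # APC_crr: 7 tandem repeats on APC (6 x 25 + 26 = 176 aa cumulative)
    for copy in range(7):
        place("PF05923", "APC_crr", "APC", 25 if copy < 6 else 26)

    in_domain_counts = dict(_IN_DOMAIN_COUNTS)
    for i in range(1, _MIRO_EXTRA_HOSTS + 1):
        in_domain_counts[("PF08477", f"RABX{i:02d}")] = 1

    genes = sorted({gene for (_, gene) in in_domain_counts} | set(_GENE_TOTALS))
    proteins = []
    for gene in genes:
        length = _KNOWN_LENGTHS.get(gene, max_end.get(gene, 100) + 20)
        if length < max_end.get(gene, 0):
            raise AssertionError(f"placements exceed known length of {gene}")
        proteins.append(ProteinRecord(gene=gene, protein_acc=f"NP_{gene}", length=length))

    records: list[MutationRecord] = []
    sample_counter = 0

    def add_mutation(gene: str, pos: int) -> None:
        nonlocal sample_counter
        sample_counter += 1
        records.append(
            MutationRecord(
                sample_id=f"S{sample_counter:04d}",
                gene=gene,
                protein_acc=f"NP_{gene}",
                protein_pos=pos,
                ref_res="A",
                alt_res="V",
                variant_class="nsSNV",
            )
        )

    in_domain_total: dict[str, int] = {}
    for (domain_acc, gene), count in sorted(in_domain_counts.items()):
        spots = placements[(domain_acc, gene)]
        cumulative = sum(p.end - p.start + 1 for p in spots)
        for i in range(count):
            offset = (i * 7) % cumulative  # spread deterministically over the instances
            for p in spots:
                span = p.end - p.start + 1
                if offset < span:
                    add_mutation(gene, p.start + offset)
                    break
                offset -= span
        in_domain_total[gene] = in_domain_total.get(gene, 0) + count

    protein_length = {p.gene: p.length for p in proteins}
    for gene, total in sorted(_GENE_TOTALS.items()):
        extra = total - in_domain_total.get(gene, 0)
        if extra < 0:
            raise AssertionError(f"gene total below in-domain count for {gene}")
        # out-of-domain positions: walk back from the protein C-terminus
        pos = protein_length[gene]
        covered = {
            q
            for (d, g), spots in placements.items()
            if g == gene
            for p in spots
            for q in range(p.start, p.end + 1)
        }
        placed = 0
        while placed < extra:
            if pos not in covered:
                add_mutation(gene, pos)
                placed += 1
            pos -= 1
            if pos < 1:
                raise AssertionError(f"no room for out-of-domain mutations on {gene}")
    return records, proteins, instances
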