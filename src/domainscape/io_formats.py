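"""Readers and writers for every external format the pipeline touches.

All protein coordinates are 1-based and inclusive: residue 1 is the first
amino acid, and a domain instance spanning ``start..end`` covers
``end - start + 1`` residues.  Indels carry the start residue of the event
as their position.

Parsers never silently drop a row: malformed rows are collected into a
:class:`ParseResult` (with 1-based data-row numbers and reasons), and rows
removed by policy (E-value cutoff, unknown protein) are counted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd
from Bio import SeqIO

__all__ = [
    "VARIANT_CLASSES",
    "INDEL_CLASSES",
    "SNV_CLASSES",
    "FormatError",
    "MutationRecord",
    "ProteinRecord",
    "DomainInstance",
    "OntologyGraph",
    "RowError",
    "ParseResult",
    "read_mutation_table",
    "write_mutation_table",
    "read_protein_set",
    "write_protein_set",
    "read_domain_map",
    "write_domain_map",
    "read_obo",
    "read_term_annotations",
    "write_landscape_table",
    "read_landscape_table",
]

#: The eight protein-consequence classes a retained mutation may carry.
VARIANT_CLASSES = frozenset(
    {
        "nsSNV",
        "synonymous_SNV",
        "stopgain_SNV",
        "stoploss_SNV",
        "frameshift_ins",
        "frameshift_del",
        "nonframeshift_ins",
        "nonframeshift_del",
    }
)

INDEL_CLASSES = frozenset(
    {"frameshift_ins", "frameshift_del", "nonframeshift_ins", "nonframeshift_del"}
)
SNV_CLASSES = VARIANT_CLASSES - INDEL_CLASSES


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


@dataclass(frozen=True, slots=True)
class MutationRecord:
    """One somatic variant observation in one patient, in protein space."""

    sample_id: str
    gene: str
    protein_acc: str
    protein_pos: int
    ref_res: str
    alt_res: str
    variant_class: str
    dbsnp_id: str | None = None
    is_somatic: bool = True
    passed_qc: bool = True

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be nonempty")
        if self.protein_pos < 1:
            raise ValueError(f"protein_pos must be >= 1, got {self.protein_pos}")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")

    @property
    def variant_key(self) -> tuple[str, int, str, str]:
        """Identity of the variant independent of the patient carrying it."""
        return (self.protein_acc, self.protein_pos, self.ref_res, self.alt_res)


@dataclass(frozen=True, slots=True)
class ProteinRecord:
    """One protein isoform of a gene, identified by accession."""

    gene: str
    protein_acc: str
    length: int
    is_representative: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"protein length must be >= 1, got {self.length}")


@dataclass(frozen=True, slots=True)
class DomainInstance:
    """One placement of a domain model on one protein (1-based, inclusive)."""

    domain_acc: str
    domain_name: str
    protein_acc: str
    start: int
    end: int
    evalue: float

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval {self.start}..{self.end}")
        if self.evalue < 0:
            raise ValueError("evalue must be nonnegative")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True, slots=True)
class RowError:
    """A rejected input row: 1-based data-row number plus reason."""

    row: int
    reason: str


@dataclass
class ParseResult:
    """Parsed records together with the enumeration of rejected rows."""

    records: list
    rejected: list[RowError] = field(default_factory=list)
    dropped_evalue: int = 0
    dropped_unknown_protein: int = 0

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# mutation tables

_SIMPLE_MUTATION_COLUMNS = [
    "sample_id",
    "gene",
    "protein_acc",
    "protein_pos",
    "ref_res",
    "alt_res",
    "variant_class",
    "dbsnp_id",
    "is_somatic",
    "passed_qc",
]

#: Variant_Classification vocabulary of MAF files mapped onto our classes.
MAF_CLASS_MAP = {
    "Missense_Mutation": "nsSNV",
    "Silent": "synonymous_SNV",
    "Nonsense_Mutation": "stopgain_SNV",
    "Nonstop_Mutation": "stoploss_SNV",
    "Frame_Shift_Ins": "frameshift_ins",
    "Frame_Shift_Del": "frameshift_del",
    "In_Frame_Ins": "nonframeshift_ins",
    "In_Frame_Del": "nonframeshift_del",
}

_MAF_COLUMNS = {
    "sample_id": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "protein_acc": "RefSeq_Prot_Id",
    "protein_pos": "Protein_Position",
    "ref_res": "Reference_Residue",
    "alt_res": "Tumor_Residue",
    "variant_class": "Variant_Classification",
    "dbsnp_id": "dbSNP_RS",
    "is_somatic": "Mutation_Status",
}

_TRUE_STRINGS = {"1", "true", "yes", "y", "t"}
_FALSE_STRINGS = {"0", "false", "no", "n", "f"}


def _parse_bool(text: str) -> bool:
    low = text.strip().lower()
    if low in _TRUE_STRINGS:
        return True
    if low in _FALSE_STRINGS:
        return False
    raise ValueError(f"not a boolean: {text!r}")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_mutation_table(path: str | Path, dialect: str = "simple_tsv") -> ParseResult:
    """Read a per-patient somatic mutation table.

    ``dialect`` is ``"simple_tsv"`` (the package's native column set) or
    ``"maf_subset"`` (the subset of MAF columns named in ``_MAF_COLUMNS``;
    extra columns are ignored, ``Mutation_Status == Somatic`` marks somatic
    rows, and a ``FILTER`` column other than ``PASS`` fails QC).
    Row order is preserved; rows with unparseable coordinates or classes are
    rejected with their row numbers.
    """
    if dialect not in {"simple_tsv", "maf_subset"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    frame = _read_tsv(path)
    if dialect == "simple_tsv":
        required = _SIMPLE_MUTATION_COLUMNS
    else:
        required = [_MAF_COLUMNS[k] for k in ("sample_id", "gene", "protein_acc", "protein_pos", "variant_class")]
    for column in required:
        if column not in frame.columns:
            raise FormatError(f"missing required column {column!r} in {path}")

    result = ParseResult(records=[])
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        data = dict(zip(frame.columns, row))
        try:
            if dialect == "simple_tsv":
                record = MutationRecord(
                    sample_id=data["sample_id"],
                    gene=data["gene"],
                    protein_acc=data["protein_acc"],
                    protein_pos=int(data["protein_pos"]),
                    ref_res=data["ref_res"],
                    alt_res=data["alt_res"],
                    variant_class=data["variant_class"],
                    dbsnp_id=data["dbsnp_id"] or None,
                    is_somatic=_parse_bool(data["is_somatic"]),
                    passed_qc=_parse_bool(data["passed_qc"]),
                )
            else:
                maf_class = data[_MAF_COLUMNS["variant_class"]]
                if maf_class not in MAF_CLASS_MAP:
                    raise ValueError(f"unknown Variant_Classification {maf_class!r}")
                dbsnp = data.get(_MAF_COLUMNS["dbsnp_id"], "")
                if dbsnp.lower() in {"", "novel", "."}:
                    dbsnp = ""
                status = data.get(_MAF_COLUMNS["is_somatic"], "Somatic")
                qc = data.get("FILTER", "PASS")
                record = MutationRecord(
                    sample_id=data[_MAF_COLUMNS["sample_id"]],
                    gene=data[_MAF_COLUMNS["gene"]],
                    protein_acc=data[_MAF_COLUMNS["protein_acc"]],
                    protein_pos=int(data[_MAF_COLUMNS["protein_pos"]]),
                    ref_res=data.get(_MAF_COLUMNS["ref_res"], ""),
                    alt_res=data.get(_MAF_COLUMNS["alt_res"], ""),
                    variant_class=MAF_CLASS_MAP[maf_class],
                    dbsnp_id=dbsnp or None,
                    is_somatic=status.strip().lower() == "somatic",
                    passed_qc=qc.strip().upper() in {"PASS", ""},
                )
        except (ValueError, KeyError) as exc:
            result.rejected.append(RowError(row=i, reason=str(exc)))
            continue
        result.records.append(record)
    return result


def write_mutation_table(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write records in the ``simple_tsv`` dialect (round-trips exactly)."""
    rows = [
        {
            "sample_id": r.sample_id,
            "gene": r.gene,
            "protein_acc": r.protein_acc,
            "protein_pos": r.protein_pos,
            "ref_res": r.ref_res,
            "alt_res": r.alt_res,
            "variant_class": r.variant_class,
            "dbsnp_id": r.dbsnp_id or "",
            "is_somatic": int(r.is_somatic),
            "passed_qc": int(r.passed_qc),
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=_SIMPLE_MUTATION_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# protein sets

def read_protein_set(path: str | Path, fmt: str = "tsv") -> list[ProteinRecord]:
    """Read the protein set: ``tsv`` (gene, protein_acc, length) or ``fasta``.

    FASTA headers must carry the owning gene as a ``gene=SYMBOL`` token in the
    description; lengths are taken from the sequences.
    """
    if fmt == "tsv":
        frame = _read_tsv(path)
        for column in ("gene", "protein_acc", "length"):
            if column not in frame.columns:
                raise FormatError(f"missing required column {column!r} in {path}")
        proteins = []
        for i, row in enumerate(frame.itertuples(index=False), start=1):
            data = dict(zip(frame.columns, row))
            try:
                proteins.append(
                    ProteinRecord(gene=data["gene"], protein_acc=data["protein_acc"], length=int(data["length"]))
                )
            except ValueError as exc:
                raise FormatError(f"row {i}: {exc}") from exc
        return proteins
    if fmt == "fasta":
        proteins = []
        for seq_record in SeqIO.parse(str(path), "fasta"):
            gene = None
            for token in seq_record.description.split():
                if token.startswith("gene="):
                    gene = token[5:]
            if gene is None:
                raise FormatError(f"FASTA record {seq_record.id!r} lacks a gene= token")
            proteins.append(ProteinRecord(gene=gene, protein_acc=seq_record.id, length=len(seq_record.seq)))
        return proteins
    raise ValueError(f"unknown protein set format {fmt!r}")


def write_protein_set(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [{"gene": p.gene, "protein_acc": p.protein_acc, "length": p.length} for p in proteins],
        columns=["gene", "protein_acc", "length"],
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# domain maps

_SIMPLE_DOMAIN_COLUMNS = ["domain_acc", "domain_name", "protein_acc", "start", "end", "evalue"]


def _strip_version(accession: str) -> str:
    return accession.split(".", 1)[0]


def read_domain_map(
    path: str | Path,
    dialect: str = "simple_tsv",
    evalue_cutoff: float = 0.001,
    proteins: Sequence[ProteinRecord] | None = None,
) -> ParseResult:
    """Read domain instances, dropping placements above the E-value cutoff.

    ``dialect`` is ``"simple_tsv"`` or ``"hmmscan_domtbl"`` (the per-domain
    tabular output of ``hmmscan --domtblout``: the target is the domain model,
    the query the protein; instance coordinates are the alignment coordinates
    and the per-domain independent E-value is used).  When ``proteins`` is
    supplied, instances on unknown accessions are dropped with a warning and
    instances exceeding the protein length are rejected as row errors.
    """
    if dialect not in {"simple_tsv", "hmmscan_domtbl"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    lengths = {p.protein_acc: p.length for p in proteins} if proteins is not None else None

    raw_rows: list[tuple[int, dict]] = []
    if dialect == "simple_tsv":
        frame = _read_tsv(path)
        for column in _SIMPLE_DOMAIN_COLUMNS:
            if column not in frame.columns:
                raise FormatError(f"missing required column {column!r} in {path}")
        for i, row in enumerate(frame.itertuples(index=False), start=1):
            raw_rows.append((i, dict(zip(frame.columns, row))))
    else:
        with open(path) as handle:
            data_row = 0
            for line in handle:
                if line.startswith("#") or not line.strip():
                    continue
                data_row += 1
                parts = line.split()
                if len(parts) < 22:
                    raw_rows.append((data_row, {"_malformed": line.rstrip()}))
                    continue
                accession = parts[1]
                raw_rows.append(
                    (
                        data_row,
                        {
                            "domain_acc": _strip_version(accession) if accession != "-" else parts[0],
                            "domain_name": parts[0],
                            "protein_acc": parts[3],
                            "start": parts[17],
                            "end": parts[18],
                            "evalue": parts[12],
                        },
                    )
                )

    result = ParseResult(records=[])
    for i, data in raw_rows:
        if "_malformed" in data:
            result.rejected.append(RowError(row=i, reason="malformed domtbl line"))
            continue
        try:
            instance = DomainInstance(
                domain_acc=data["domain_acc"],
                domain_name=data["domain_name"],
                protein_acc=data["protein_acc"],
                start=int(data["start"]),
                end=int(data["end"]),
                evalue=float(data["evalue"]),
            )
        except ValueError as exc:
            result.rejected.append(RowError(row=i, reason=str(exc)))
            continue
        if instance.evalue > evalue_cutoff:
            result.dropped_evalue += 1
            continue
        if lengths is not None:
            if instance.protein_acc not in lengths:
                result.dropped_unknown_protein += 1
                warnings.warn(
                    f"domain instance on unknown protein {instance.protein_acc!r} dropped",
                    stacklevel=2,
                )
                continue
            if instance.end > lengths[instance.protein_acc]:
                result.rejected.append(
                    RowError(row=i, reason=f"instance end {instance.end} exceeds protein length")
                )
                continue
        result.records.append(instance)
    return result


def write_domain_map(instances: Iterable[DomainInstance], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "domain_acc": d.domain_acc,
                "domain_name": d.domain_name,
                "protein_acc": d.protein_acc,
                "start": d.start,
                "end": d.end,
                "evalue": d.evalue,
            }
            for d in instances
        ],
        columns=_SIMPLE_DOMAIN_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ontology

@dataclass
class OntologyGraph:
    """A GO DAG: term -> parent terms over is_a/part_of edges.

    Roots are the terms without parents (the namespace roots for full GO).
    Ancestor queries exclude the term itself but include the roots; the
    enrichment propagation step strips the roots.
    """

    parents: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)
    annotations: dict[str, frozenset[str]] = field(default_factory=dict)
    _ancestor_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.parents)

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t, ps in self.parents.items() if not ps)

    def ancestors(self, term: str) -> frozenset[str]:
        """All strict ancestors of ``term`` along every path, roots included."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        seen: set[str] = set()
        frontier = list(self.parents.get(term, ()))
        while frontier:
            parent = frontier.pop()
            if parent in seen:
                continue
            seen.add(parent)
            frontier.extend(self.parents.get(parent, ()))
        result = frozenset(seen)
        self._ancestor_cache[term] = result
        return result


def read_obo(path: str | Path) -> OntologyGraph:
    """Parse an OBO v1.2 ontology; obsolete terms excluded, cycles rejected."""
    multigraph = obonet.read_obo(path, ignore_obsolete=True)
    parent_graph = nx.DiGraph()
    parent_graph.add_nodes_from(multigraph.nodes)
    for child, parent, key in multigraph.edges(keys=True):
        if key in ("is_a", "part_of"):
            parent_graph.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(parent_graph):
        raise FormatError(f"ontology in {path} contains a cyclic is_a/part_of chain")
    parents = {term: frozenset(parent_graph.successors(term)) for term in parent_graph.nodes}
    names = {t: d["name"] for t, d in multigraph.nodes(data=True) if "name" in d}
    namespaces = {t: d["namespace"] for t, d in multigraph.nodes(data=True) if "namespace" in d}
    return OntologyGraph(parents=parents, names=names, namespaces=namespaces)


def read_term_annotations(
    path: str | Path, dialect: str = "tsv", graph: OntologyGraph | None = None
) -> dict[str, frozenset[str]]:
    """Read entity -> GO term annotations.

    ``dialect`` is ``"tsv"`` (two columns: entity id, term id; no header
    required but an ``entity\\tterm`` header line is tolerated) or
    ``"pfam2go"`` (``Pfam:PF00001 name > GO:desc ; GO:0004930``).  With a
    ``graph``, annotations to unknown terms are dropped with a warning.
    """
    pairs: list[tuple[str, str]] = []
    if dialect == "tsv":
        with open(path) as handle:
            for line in handle:
                line = line.rstrip("\n")
                if not line or line.startswith("!"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise FormatError(f"expected two tab-separated columns: {line!r}")
                if fields[0] == "entity" and fields[1] == "term":
                    continue
                pairs.append((fields[0], fields[1]))
    elif dialect == "pfam2go":
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("!"):
                    continue
                if not line.startswith("Pfam:") or " > " not in line or ";" not in line:
                    raise FormatError(f"malformed pfam2go line: {line!r}")
                left, right = line.split(" > ", 1)
                accession = left.split()[0][len("Pfam:"):]
                term = right.rsplit(";", 1)[1].strip()
                pairs.append((accession, term))
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")

    annotations: dict[str, set[str]] = {}
    dropped = 0
    for entity, term in pairs:
        if graph is not None and term not in graph.parents:
            dropped += 1
            continue
        annotations.setdefault(entity, set()).add(term)
    if dropped:
        warnings.warn(f"dropped {dropped} annotation(s) to terms absent from the ontology", stacklevel=2)
    return {entity: frozenset(terms) for entity, terms in annotations.items()}


# ---------------------------------------------------------------------------
# landscape tables

_LANDSCAPE_COLUMNS = [
    "region_id",
    "region_kind",
    "k",
    "L",
    "p_hat",
    "z",
    "lfdr",
    "significant",
    "excluded_short",
]


def write_landscape_table(stats: Sequence, path: str | Path) -> None:
    """Write per-region statistics, sorted by descending normalized frequency
    (ties broken by region id).  Undefined z/lfdr are written as empty cells.
    """
    ordered = sorted(stats, key=lambda s: (-s.p_hat, s.region_id))
    rows = [
        {
            "region_id": s.region_id,
            "region_kind": s.region_kind,
            "k": s.k,
            "L": s.L,
            "p_hat": repr(s.p_hat),
            "z": "" if s.z is None else repr(s.z),
            "lfdr": "" if s.lfdr is None else repr(s.lfdr),
            "significant": int(s.significant),
            "excluded_short": int(s.excluded_short),
        }
        for s in ordered
    ]
    frame = pd.DataFrame(rows, columns=_LANDSCAPE_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def read_landscape_table(path: str | Path) -> list:
    """Read a landscape table back into RegionStat objects (exact round trip)."""
    from .landscape_stats import RegionStat

    frame = _read_tsv(path)
    for column in _LANDSCAPE_COLUMNS:
        if column not in frame.columns:
            raise FormatError(f"missing required column {column!r} in {path}")
    stats = []
    for row in frame.itertuples(index=False):
        data = dict(zip(frame.columns, row))
        stats.append(
            RegionStat(
                region_id=data["region_id"],
                region_kind=data["region_kind"],
                k=int(data["k"]),
                L=int(data["L"]),
                z=float(data["z"]) if data["z"] != "" else None,
                lfdr=float(data["lfdr"]) if data["lfdr"] != "" else None,
                significant=bool(int(data["significant"])),
                excluded_short=bool(int(data["excluded_short"])),
            )
        )
    return stats
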