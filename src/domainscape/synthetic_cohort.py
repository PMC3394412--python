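"""Synthetic proteomes and mutation cohorts with known planted ground truth.

The generator emulates the structure of an exome-wide somatic mutation study:
a toy proteome of a few hundred genes (some with multiple isoforms, some
shorter than the landscape length cutoff), a domain library whose domains are
shared across genes (including one domain placed as seven tandem copies on a
single long protein), and per-patient mutations drawn residue-by-residue from
a uniform Bernoulli background, multiplied inside planted driver regions.

The per-residue Bernoulli model is the simplest process consistent with the
uniform-passenger assumption the statistics are built on; mutation counts are
occurrence-weighted across patients automatically.  Decoy rows (synonymous,
dbSNP-listed, germline, QC-fail) are mixed in to exercise the filters and are
recorded so tests can verify that exactly the decoys are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import DomainInstance, MutationRecord, ProteinRecord
from .landscape_stats import LandscapeResult, domain_landscape, gene_landscape
from .preprocess import Cohort, build_cohort

__all__ = [
    "CohortData",
    "DriverRegion",
    "Proteome",
    "ProteomeSpec",
    "SyntheticTruth",
    "default_truth",
    "generate_cohort",
    "generate_proteome",
    "neutral_regions",
    "null_calibration_experiment",
    "recovery_experiment",
    "run_pipeline",
    "score_recovery",
    "write_truth_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default retained-class mix: dominated by missense SNVs (~80%), then
#: frameshift insertions (~12%) and stop-gains (~7%), with rare in-frame
#: insertions, stop-losses and frameshift deletions, as in large
#: colon-adenocarcinoma exome cohorts.
DEFAULT_CLASS_PROBS: dict[str, float] = {
    "nsSNV": 17174 / 21572,
    "frameshift_ins": 2527 / 21572,
    "nonframeshift_ins": 239 / 21572,
    "frameshift_del": 5 / 21572,
    "nonframeshift_del": 0.0,
    "stoploss_SNV": 33 / 21572,
    "stopgain_SNV": 1594 / 21572,
}

_INDEL = {"frameshift_ins", "frameshift_del", "nonframeshift_ins", "nonframeshift_del"}


@dataclass(frozen=True)
class ProteomeSpec:
    """Shape of the toy proteome.

    Defaults are sized so a full simulate-and-call run finishes in seconds:
    200 genes with representative lengths mostly 180-800 aa (a small fraction
    under the 150-aa cutoff, to exercise exclusion), 40 domains of 40-200 aa
    placed on 1-6 host genes each, the first domain as 7 tandem copies on the
    first (long) gene.
    """

    n_genes: int = 200
    length_range: tuple[int, int] = (180, 800)
    short_gene_frac: float = 0.08
    short_length_range: tuple[int, int] = (60, 149)
    extra_isoform_prob: float = 0.3
    n_domains: int = 40
    domain_length_range: tuple[int, int] = (40, 200)
    hosts_range: tuple[int, int] = (1, 6)
    tandem_copies: int = 7
    nonrepresentative_instance_prob: float = 0.1


@dataclass
class Proteome:
    proteins: list[ProteinRecord]
    domains: list[DomainInstance]

    @property
    def representative_by_gene(self) -> dict[str, ProteinRecord]:
        best: dict[str, ProteinRecord] = {}
        for p in self.proteins:
            cur = best.get(p.gene)
            if (
                cur is None
                or p.length > cur.length
                or (p.length == cur.length and p.protein_acc < cur.protein_acc)
            ):
                best[p.gene] = p
        return best


def generate_proteome(spec: ProteomeSpec, seed: int) -> Proteome:
    """Deterministically generate proteins and domain instances from a spec."""
    rng = np.random.default_rng(seed)
    proteins: list[ProteinRecord] = []
    rep_length: dict[str, int] = {}
    rep_acc: dict[str, str] = {}

    n_short = int(round(spec.short_gene_frac * spec.n_genes))
    short_idx = set(rng.choice(np.arange(1, spec.n_genes), size=min(n_short, spec.n_genes - 1), replace=False))
    for i in range(spec.n_genes):
        gene = f"G{i:04d}"
        acc = f"NP_{i:05d}"
        if i == 0:
            length = spec.length_range[1]  # long host for the tandem-copy domain
        elif i in short_idx:
            length = int(rng.integers(spec.short_length_range[0], spec.short_length_range[1] + 1))
        else:
            length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        proteins.append(ProteinRecord(gene=gene, protein_acc=acc, length=length))
        rep_length[gene] = length
        rep_acc[gene] = acc
        if rng.random() < spec.extra_isoform_prob and length > 40:
            iso_length = int(rng.integers(30, length))
            proteins.append(ProteinRecord(gene=gene, protein_acc=f"{acc}_b", length=iso_length))

    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    instances: list[DomainInstance] = []
    for j in range(spec.n_domains):
        domain_acc = f"PF9{j:04d}"
        domain_name = f"DOM{j:03d}"
        if j == 0 and spec.tandem_copies > 1:
            host = genes[0]
            length = rep_length[host]
            copy_len = min(
                int(rng.integers(*spec.domain_length_range)), max((length - 10) // spec.tandem_copies, 10)
            )
            start = int(rng.integers(1, length - spec.tandem_copies * copy_len + 2))
            for c in range(spec.tandem_copies):
                s = start + c * copy_len
                instances.append(
                    DomainInstance(
                        domain_acc=domain_acc,
                        domain_name=domain_name,
                        protein_acc=rep_acc[host],
                        start=s,
                        end=s + copy_len - 1,
                        evalue=float(10.0 ** rng.uniform(-30, -4)),
                    )
                )
            continue
        dlen = int(rng.integers(*spec.domain_length_range))
        eligible = [g for g in genes if rep_length[g] >= dlen + 2]
        n_hosts = int(rng.integers(spec.hosts_range[0], spec.hosts_range[1] + 1))
        hosts = rng.choice(eligible, size=min(n_hosts, len(eligible)), replace=False)
        for host in hosts:
            length = rep_length[host]
            start = int(rng.integers(1, length - dlen + 2))
            if start + dlen - 1 > length:
                raise ValueError(f"domain placement exceeds protein length on {host}")
            instances.append(
                DomainInstance(
                    domain_acc=domain_acc,
                    domain_name=domain_name,
                    protein_acc=rep_acc[host],
                    start=start,
                    end=start + dlen - 1,
                    evalue=float(10.0 ** rng.uniform(-30, -4)),
                )
            )
            if rng.random() < spec.nonrepresentative_instance_prob:
                iso_acc = f"{rep_acc[host]}_b"
                iso = next((p for p in proteins if p.protein_acc == iso_acc), None)
                if iso is not None and iso.length >= dlen:
                    instances.append(
                        DomainInstance(
                            domain_acc=domain_acc,
                            domain_name=domain_name,
                            protein_acc=iso_acc,
                            start=1,
                            end=dlen,
                            evalue=float(10.0 ** rng.uniform(-30, -4)),
                        )
                    )
    return Proteome(proteins=proteins, domains=instances)


@dataclass(frozen=True)
class DriverRegion:
    """A planted elevated-rate region: a whole gene or every instance of a domain."""

    kind: str  # "gene" | "domain"
    target: str
    multiplier: float

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "domain"):
            raise ValueError("driver kind must be gene or domain")
        if self.multiplier < 1:
            raise ValueError("driver multiplier must be >= 1")


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate a cohort and score recovery."""

    proteome: Proteome
    seed: int
    background_rate: float = 5e-5
    n_patients: int = 100
    drivers: tuple[DriverRegion, ...] = ()
    class_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    decoy_synonymous_frac: float = 0.05
    decoy_dbsnp_frac: float = 0.05
    decoy_germline_frac: float = 0.03
    decoy_qcfail_frac: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 < self.background_rate < 1.0) and self.background_rate != 0.0:
            raise ValueError("background rate must lie in [0, 1)")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class probabilities must sum to 1, got {total}")

    # -- rate model -----------------------------------------------------

    def rate_profiles(self) -> dict[str, np.ndarray]:
        """Per-residue per-patient mutation probability on each representative protein."""
        reps = self.proteome.representative_by_gene
        profiles = {
            p.protein_acc: np.full(p.length, self.background_rate, dtype=float)
            for p in reps.values()
        }
        acc_by_gene = {g: p.protein_acc for g, p in reps.items()}
        for driver in self.drivers:
            boosted = self.background_rate * driver.multiplier
            if boosted >= 1.0:
                raise ValueError("driver rate multiplier pushes probability to >= 1")
            if driver.kind == "gene":
                acc = acc_by_gene.get(driver.target)
                if acc is None:
                    raise ValueError(f"driver gene {driver.target} not in proteome")
                profiles[acc] = np.maximum(profiles[acc], boosted)
            else:
                hit = False
                for inst in self.proteome.domains:
                    if inst.domain_acc == driver.target and inst.protein_acc in profiles:
                        segment = profiles[inst.protein_acc][inst.start - 1 : inst.end]
                        np.maximum(segment, boosted, out=segment)
                        hit = True
                if not hit:
                    raise ValueError(f"driver domain {driver.target} has no representative instance")
        return profiles

    def expected_gene_counts(self) -> dict[str, float]:
        reps = self.proteome.representative_by_gene
        profiles = self.rate_profiles()
        return {g: float(profiles[p.protein_acc].sum() * self.n_patients) for g, p in reps.items()}

    def expected_domain_counts(self) -> dict[str, float]:
        """Expected occurrence-weighted count per domain (instances of one
        domain assumed non-overlapping with each other)."""
        profiles = self.rate_profiles()
        expected: dict[str, float] = {}
        for inst in self.proteome.domains:
            if inst.protein_acc not in profiles:
                continue
            expected[inst.domain_acc] = expected.get(inst.domain_acc, 0.0) + float(
                profiles[inst.protein_acc][inst.start - 1 : inst.end].sum() * self.n_patients
            )
        return expected


@dataclass
class CohortData:
    """A generated mutation table plus the bookkeeping tests rely on."""

    records: list[MutationRecord]
    somatic_records: list[MutationRecord]
    decoy_records: list[MutationRecord]
    exclusion_ids: frozenset[str]
    truth: SyntheticTruth

    @property
    def patient_ids(self) -> list[str]:
        return [f"P{i:04d}" for i in range(self.truth.n_patients)]


def default_truth(
    seed: int,
    drivers: Sequence[DriverRegion] = (),
    spec: ProteomeSpec | None = None,
    **overrides,
) -> SyntheticTruth:
    """Proteome + truth at the package's default study conditions."""
    spec = spec or ProteomeSpec()
    proteome = generate_proteome(spec, seed)
    return SyntheticTruth(proteome=proteome, seed=seed, drivers=tuple(drivers), **overrides)


def generate_cohort(truth: SyntheticTruth) -> CohortData:
    """Draw the per-patient mutation table defined by ``truth``.

    Deterministic under ``truth.seed``; same truth twice gives identical rows.
    """
    rng = np.random.default_rng(truth.seed)
    classes = sorted(truth.class_probs)
    probs = np.array([truth.class_probs[c] for c in classes])
    reps = sorted(truth.proteome.representative_by_gene.values(), key=lambda p: p.protein_acc)
    profiles = truth.rate_profiles()

    somatic: list[MutationRecord] = []
    for protein in reps:
        profile = profiles[protein.protein_acc]
        if profile.max() == 0.0:
            continue
        hits = rng.random((truth.n_patients, protein.length)) < profile[None, :]
        patients_idx, positions_idx = np.nonzero(hits)
        if patients_idx.size == 0:
            continue
        class_idx = rng.choice(len(classes), size=patients_idx.size, p=probs)
        ref_idx = rng.integers(0, len(AMINO_ACIDS), size=patients_idx.size)
        alt_idx = rng.integers(0, len(AMINO_ACIDS), size=patients_idx.size)
        for pat, pos0, ci, ri, ai in zip(patients_idx, positions_idx, class_idx, ref_idx, alt_idx):
            variant_class = classes[ci]
            is_indel = variant_class in _INDEL
            somatic.append(
                MutationRecord(
                    sample_id=f"P{pat:04d}",
                    gene=protein.gene,
                    protein_acc=protein.protein_acc,
                    protein_pos=int(pos0) + 1,
                    ref_res="" if is_indel else AMINO_ACIDS[ri],
                    alt_res="" if is_indel else AMINO_ACIDS[(ai + 1) % len(AMINO_ACIDS) if ai == ri else ai],
                    variant_class=variant_class,
                )
            )

    decoys: list[MutationRecord] = []
    exclusion: set[str] = set()

    def random_site() -> tuple[ProteinRecord, int, str]:
        protein = reps[int(rng.integers(0, len(reps)))]
        pos = int(rng.integers(1, protein.length + 1))
        sample = f"P{int(rng.integers(0, truth.n_patients)):04d}"
        return protein, pos, sample

    def random_residues() -> tuple[str, str]:
        i, j = rng.integers(0, len(AMINO_ACIDS), size=2)
        return AMINO_ACIDS[int(i)], AMINO_ACIDS[int(j)]

    n_somatic = len(somatic)
    for _ in range(int(round(truth.decoy_synonymous_frac * n_somatic))):
        protein, pos, sample = random_site()
        ref, _ = random_residues()
        decoys.append(
            MutationRecord(sample, protein.gene, protein.protein_acc, pos, ref, ref, "synonymous_SNV")
        )
    for i in range(int(round(truth.decoy_dbsnp_frac * n_somatic))):
        protein, pos, sample = random_site()
        ref, alt = random_residues()
        rsid = f"rs{9000000 + i}"
        exclusion.add(rsid)
        decoys.append(
            MutationRecord(sample, protein.gene, protein.protein_acc, pos, ref, alt, "nsSNV", dbsnp_id=rsid)
        )
    for _ in range(int(round(truth.decoy_germline_frac * n_somatic))):
        protein, pos, sample = random_site()
        ref, alt = random_residues()
        decoys.append(
            MutationRecord(sample, protein.gene, protein.protein_acc, pos, ref, alt, "nsSNV", is_somatic=False)
        )
    for _ in range(int(round(truth.decoy_qcfail_frac * n_somatic))):
        protein, pos, sample = random_site()
        ref, alt = random_residues()
        decoys.append(
            MutationRecord(sample, protein.gene, protein.protein_acc, pos, ref, alt, "nsSNV", passed_qc=False)
        )

    records = somatic + decoys
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return CohortData(
        records=records,
        somatic_records=somatic,
        decoy_records=decoys,
        exclusion_ids=frozenset(exclusion),
        truth=truth,
    )


def run_pipeline(
    data: CohortData, **landscape_options
) -> tuple[Cohort, LandscapeResult, LandscapeResult]:
    """Build the cohort from generated rows and call both landscapes."""
    cohort, _report = build_cohort(
        f"synthetic:{data.truth.seed}",
        data.records,
        data.truth.proteome.proteins,
        data.truth.proteome.domains,
        exclusion_ids=data.exclusion_ids,
        patients=data.patient_ids,
    )
    genes = gene_landscape(cohort, **landscape_options)
    domains = domain_landscape(cohort, **landscape_options)
    return cohort, genes, domains


def score_recovery(
    truth: SyntheticTruth, gene_result: LandscapeResult, domain_result: LandscapeResult
) -> dict[tuple[str, str], bool]:
    """For each planted driver, was its region flagged significant?"""
    recovered = {}
    for driver in truth.drivers:
        result = gene_result if driver.kind == "gene" else domain_result
        recovered[(driver.kind, driver.target)] = driver.target in result.significant_ids
    return recovered


def neutral_regions(truth: SyntheticTruth) -> tuple[set[str], set[str]]:
    """Region ids untouched by any planted driver (directly or via overlap).

    A gene hosting an instance of a driver domain is contaminated; so is a
    domain with an instance on a driver gene's representative protein.
    """
    reps = truth.proteome.representative_by_gene
    acc_to_gene = {p.protein_acc: p.gene for p in reps.values()}
    driver_genes = {d.target for d in truth.drivers if d.kind == "gene"}
    driver_domains = {d.target for d in truth.drivers if d.kind == "domain"}
    contaminated_genes = set(driver_genes)
    contaminated_domains = set(driver_domains)
    for inst in truth.proteome.domains:
        gene = acc_to_gene.get(inst.protein_acc)
        if gene is None:
            continue
        if inst.domain_acc in driver_domains:
            contaminated_genes.add(gene)
        if gene in driver_genes:
            contaminated_domains.add(inst.domain_acc)
    genes = set(reps) - contaminated_genes
    domains = {i.domain_acc for i in truth.proteome.domains} - contaminated_domains
    return genes, domains


def null_calibration_experiment(
    n_replicates: int = 20, base_seed: int = 0, **landscape_options
) -> dict[str, float]:
    """Pure-null cohorts (no drivers): fraction of regions called significant.

    Returns per-kind false-peak fractions over all replicates.
    """
    rng = np.random.default_rng(base_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    false_calls = {"gene": 0, "domain": 0}
    totals = {"gene": 0, "domain": 0}
    for seed in seeds:
        truth = default_truth(int(seed))
        data = generate_cohort(truth)
        _, genes, domains = run_pipeline(data, **landscape_options)
        for kind, result in (("gene", genes), ("domain", domains)):
            tested = [s for s in result.stats if not s.excluded_short]
            totals[kind] += len(tested)
            false_calls[kind] += sum(s.significant for s in tested)
    return {
        "gene_false_peak_fraction": false_calls["gene"] / max(totals["gene"], 1),
        "domain_false_peak_fraction": false_calls["domain"] / max(totals["domain"], 1),
        "n_gene_regions": totals["gene"],
        "n_domain_regions": totals["domain"],
    }


def _default_drivers(truth_seed: int, multiplier: float) -> tuple[DriverRegion, ...]:
    """Pick reproducible driver targets with testable regions (L >= 150)."""
    spec = ProteomeSpec()
    proteome = generate_proteome(spec, truth_seed)
    reps = proteome.representative_by_gene
    from .landscape_stats import cumulative_domain_lengths

    lengths = cumulative_domain_lengths(
        proteome.domains, representative_accs={p.protein_acc for p in reps.values()}
    )
    eligible_domains = sorted(d for d, L in lengths.items() if L >= 150)
    eligible_genes = sorted(g for g, p in reps.items() if p.length >= 150)
    drivers = [DriverRegion("domain", d, multiplier) for d in eligible_domains[:3]]
    drivers += [DriverRegion("gene", g, multiplier) for g in eligible_genes[:2]]
    return tuple(drivers)


def recovery_experiment(
    n_replicates: int = 20, base_seed: int = 0, multiplier: float = 10.0, **landscape_options
) -> dict[str, float]:
    """Planted-driver cohorts: fraction of planted regions recovered, and the
    false-peak fraction among uncontaminated neutral regions."""
    rng = np.random.default_rng(base_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    n_recovered = 0
    n_planted = 0
    n_false = 0
    n_neutral = 0
    for seed in seeds:
        seed = int(seed)
        drivers = _default_drivers(seed, multiplier)
        truth = default_truth(seed, drivers=drivers)
        data = generate_cohort(truth)
        _, genes, domains = run_pipeline(data, **landscape_options)
        recovered = score_recovery(truth, genes, domains)
        n_planted += len(recovered)
        n_recovered += sum(recovered.values())
        neutral_genes, neutral_domains = neutral_regions(truth)
        for result, neutral in ((genes, neutral_genes), (domains, neutral_domains)):
            tested = [s for s in result.stats if not s.excluded_short and s.region_id in neutral]
            n_neutral += len(tested)
            n_false += sum(s.significant for s in tested)
    return {
        "recovery_fraction": n_recovered / max(n_planted, 1),
        "neutral_false_peak_fraction": n_false / max(n_neutral, 1),
        "n_planted": n_planted,
        "n_neutral_regions": n_neutral,
    }


def write_truth_table(truth: SyntheticTruth, path: str | Path) -> None:
    """Planted drivers and expectations as TSV, for recovery scoring."""
    expected_genes = truth.expected_gene_counts()
    expected_domains = truth.expected_domain_counts()
    rows = []
    for driver in truth.drivers:
        expected = (
            expected_genes.get(driver.target)
            if driver.kind == "gene"
            else expected_domains.get(driver.target)
        )
        rows.append(
            {
                "kind": driver.kind,
                "target": driver.target,
                "multiplier": driver.multiplier,
                "expected_count": expected,
            }
        )
    pd.DataFrame(rows, columns=["kind", "target", "multiplier", "expected_count"]).to_csv(
        path, sep="\t", index=False
    )
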