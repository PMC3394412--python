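"""Run configuration, end-to-end orchestration and landscape-map layout.

``run_landscape`` composes the whole pipeline deterministically: read the
mutation table, protein set and domain map, filter and build the cohort, call
the gene and domain landscapes, classify domain-peak origins (including the
re-test after deleting significant genes' mutations), and export everything
as TSV — identical inputs and configuration give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io_formats, landscape_stats, peak_analysis, preprocess

logger = logging.getLogger("domainscape")

__all__ = ["RunConfig", "layout_landscape", "run_landscape"]


@dataclass
class RunConfig:
    """All knobs of a landscape run; round-trips through a key=value file."""

    mutations: str = ""
    proteins: str = ""
    domains: str = ""
    exclusion: str = ""  # optional: one dbSNP-style id per line
    mutation_dialect: str = "simple_tsv"
    domain_dialect: str = "simple_tsv"
    protein_format: str = "tsv"
    evalue_cutoff: float = 0.001
    lfdr_threshold: float = 0.1
    min_length: int = 150
    prevalence_threshold: float = 0.04
    z_form: str = "standardized"
    min_regions: int = 200
    seed: int = 0
    outdir: str = "out"

    def __post_init__(self) -> None:
        if self.evalue_cutoff < 0 or self.lfdr_threshold < 0:
            raise ValueError("cutoffs must be nonnegative")
        if self.min_length < 1 or self.prevalence_threshold <= 0:
            raise ValueError("thresholds must be positive")

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name}={getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        values: dict[str, object] = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise io_formats.FormatError(f"expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in types:
                raise io_formats.FormatError(f"unknown configuration key {key!r}")
            kind = types[key]
            if kind == "int":
                values[key] = int(value.strip())
            elif kind == "float":
                values[key] = float(value.strip())
            else:
                values[key] = value.strip()
        return cls(**values)


def layout_landscape(
    stats: Sequence[landscape_stats.RegionStat],
    grid_seed: int = 0,
    height_cap: float | None = None,
) -> pd.DataFrame:
    """Place each region on a ceil(sqrt(N)) x ceil(sqrt(N)) grid.

    Regions are ordered deterministically (descending normalized frequency,
    ties by id) and shuffled onto grid cells with a seeded permutation; the
    height of each point is its normalized frequency p_hat, optionally capped
    so one towering peak does not flatten the rest of the map.
    """
    ordered = sorted(stats, key=lambda s: (-s.p_hat, s.region_id))
    n = len(ordered)
    side = max(1, math.isqrt(n - 1) + 1) if n else 1
    rng = np.random.default_rng(grid_seed)
    cells = rng.permutation(side * side)[:n]
    rows = []
    for s, cell in zip(ordered, cells):
        height = s.p_hat
        if height_cap is not None:
            height = min(height, height_cap)
        rows.append(
            {
                "region_id": s.region_id,
                "x": int(cell % side),
                "y": int(cell // side),
                "height": repr(height),
            }
        )
    return pd.DataFrame(rows, columns=["region_id", "x", "y", "height"])


def _landscape_options(config: RunConfig) -> dict:
    return {
        "lfdr_threshold": config.lfdr_threshold,
        "min_length": config.min_length,
        "z_form": config.z_form,
        "min_regions": config.min_regions,
    }


def _origins_frame(
    origins: Sequence[peak_analysis.PeakOrigin], retained: dict[str, bool]
) -> pd.DataFrame:
    rows = [
        {
            "domain_acc": o.domain_acc,
            "origin_class": o.origin_class,
            "retained_after_removal": int(retained.get(o.domain_acc, False)),
            "contributing_genes": ";".join(
                f"{g}:{n}" for g, n in sorted(o.contributing.items(), key=lambda kv: (-kv[1], kv[0]))
            ),
            "significant_contributors": ";".join(sorted(o.significant_genes)),
        }
        for o in origins
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "domain_acc",
            "origin_class",
            "retained_after_removal",
            "contributing_genes",
            "significant_contributors",
        ],
    )


def run_landscape(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline per ``config``; returns the written file paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    parsed = io_formats.read_mutation_table(config.mutations, dialect=config.mutation_dialect)
    if parsed.rejected:
        logger.warning("mutation table: %d row(s) rejected", len(parsed.rejected))
    proteins = io_formats.read_protein_set(config.proteins, fmt=config.protein_format)
    domain_parse = io_formats.read_domain_map(
        config.domains,
        dialect=config.domain_dialect,
        evalue_cutoff=config.evalue_cutoff,
        proteins=proteins,
    )
    exclusion_ids: frozenset[str] = frozenset()
    if config.exclusion:
        exclusion_ids = frozenset(
            line.strip() for line in Path(config.exclusion).read_text().splitlines() if line.strip()
        )

    cohort, report = preprocess.build_cohort(
        name=str(config.mutations),
        records=parsed.records,
        proteins=proteins,
        domains=domain_parse.records,
        exclusion_ids=exclusion_ids,
    )
    logger.info(
        "cohort: %d/%d mutations retained over %d patients",
        len(cohort.mutations),
        report.filter.n_input,
        cohort.n_patients,
    )
    assignments, fraction_in_domain = preprocess.assign_mutations_to_domains(cohort)
    logger.info("fraction of mutations inside domain instances: %.3f", fraction_in_domain)

    options = _landscape_options(config)
    genes = landscape_stats.gene_landscape(cohort, **options)
    domains = landscape_stats.domain_landscape(cohort, assignments=assignments, **options)
    logger.info(
        "significant peaks: %d genes, %d domains",
        len(genes.significant_ids),
        len(domains.significant_ids),
    )

    origins = peak_analysis.classify_peak_origins(domains, genes)
    _, retained = peak_analysis.recall_after_gene_peak_removal(
        cohort, genes, domain_result=domains, **options
    )

    outputs: dict[str, Path] = {}

    def _write(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        outputs[name] = path

    _write("gene_landscape.tsv", lambda p: io_formats.write_landscape_table(genes.stats, p))
    _write("domain_landscape.tsv", lambda p: io_formats.write_landscape_table(domains.stats, p))

    filter_frame = report.filter.to_frame()
    extra = pd.DataFrame(
        [
            {"rule": "duplicate_rows", "removed": report.n_duplicate_rows},
            {"rule": "nonrepresentative_isoform", "removed": report.n_nonrepresentative},
            {"rule": "unknown_protein", "removed": report.n_unknown_protein},
            {"rule": "rejected_rows", "removed": len(parsed.rejected)},
        ]
    )
    _write(
        "filter_report.tsv",
        lambda p: pd.concat([filter_frame, extra], ignore_index=True).to_csv(p, sep="\t", index=False),
    )
    _write("peak_origins.tsv", lambda p: _origins_frame(origins, retained).to_csv(p, sep="\t", index=False))
    _write(
        "gene_layout.tsv",
        lambda p: layout_landscape(genes.stats, grid_seed=config.seed).to_csv(p, sep="\t", index=False),
    )
    _write(
        "domain_layout.tsv",
        lambda p: layout_landscape(domains.stats, grid_seed=config.seed).to_csv(p, sep="\t", index=False),
    )
    return outputs
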