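# Methods

## Model and procedure

`domainscape` tests whether genes or protein domains accumulate somatic
mutations beyond what a uniform passenger process explains.

**Inputs and mapping.** The pipeline begins at protein-space mutation
annotations (sample id, gene, protein accession, 1-based residue position,
consequence class); it does not re-derive consequences from DNA. Retention
requires a mutation to be somatic, QC-passing, absent from a user-supplied
dbSNP-style exclusion list, and non-synonymous. The four rules are
conjunctive predicates, so their order is irrelevant; per-rule removal
counts are reported. Duplicate (sample, variant) rows count once — counts
are per-patient occurrences, not file rows. Each gene's *representative
protein* is its longest isoform (ties broken by smallest accession);
mutations on other isoforms are dropped with a count, so one DNA event is
never replicated across transcripts. Indels are located by their start
residue. A mutation is assigned to *every* domain instance covering its
position (overlapping instances of different domains each count; multiple
instances of the same domain count once per mutation).

**Statistic.** For a region with count *k* and length *L* (representative
protein length for genes; cumulative length of all instances of a domain
over representative proteins for domains), p̂ = k/L and

    z = (p̂ − p₀) / sqrt(p₀ (1 − p₀) / L),    p₀ = Σk / ΣL .

Pooling Σk over patients makes p₀ absorb both the per-patient rate and the
cohort size; under the uniform-passenger null, k ~ Binomial against p₀ and z
is approximately standard normal. The alternative `bernoulli_snr` form
z = sqrt(p̂/(1−p̂)) — the literal signal-to-noise ratio of a Bernoulli(p̂)
variable — is monotone in p̂ but not centered; it is provided behind a flag
because the normalization's exact algebra is a genuinely open design point,
and the standardized form is the default because the lfdr machinery expects
approximately N(0,1) null scores.

**Local false discovery rate.** The z ensemble of one landscape (genes and
domains are fitted separately, with separate p₀) enters a two-groups fit:

* marginal density f — Poisson regression of 120 equal-width bin counts on a
  degree-7 polynomial of the standardized bin centers (the classical
  Lindsey-method density estimate);
* empirical null f₀ — a normal with mean/sd estimated by truncated maximum
  likelihood on the central 50% of z, and
  π₀ = (count in central window) / (N · null mass of the window), capped at 1;
* lfdr(z) = min(1, π₀ f₀(z)/f(z)), evaluated in log space.

Regions shorter than **150 aa** are excluded from the fit (flagged
`excluded_short`, lfdr undefined); a region is significant iff
**lfdr < 0.1** strictly, it passes the length cutoff, and k > 0. Zero-count
regions stay in the domain ensemble — they inform the null — but can never
be peaks.

**Small landscapes.** The binned polynomial fit and the empirical null are
unstable below ~200 regions. Under that size the null is the theoretical
N(0,1) with π₀ = 1, and the marginal f is a Gaussian kernel density estimate
(Scott bandwidth, deterministic). The same fallback applies when the
truncated-normal MLE degenerates. The KDE route is conservative in the
bulk (its own-kernel mass at an isolated point bounds the lfdr from below at
roughly φ(z)·n·h·√(2π)), and the measured false-peak rate on pure-null
synthetic cohorts stays well under 2%.

**Peak origins and removal re-test.** Each significant domain is classified
by its contributors: `from_gene_peaks` (every contributing gene is itself
significant), `aggregated` (none is), or `mixed`. The `mixed` class is an
addition over the two poles usually discussed, because real breakdowns mix
both kinds of contributor. The removal re-test deletes *all* mutations of
every significant gene (node removal, not just in-domain mutations),
recomputes domain counts, p₀ and a fresh lfdr fit on the reduced cohort —
the null is refit rather than reused, since removing the largest peaks
changes both the background rate and the z ensemble — and reports which
domains remain significant. Cumulative domain lengths are kept fixed at the
original protein set.

**Comparison and enrichment.** Cross-cohort comparison is a Venn summary of
significant-region sets with shared percentages reported to one decimal; no
overlap p-value is computed. GO enrichment first propagates annotations to
all ancestors along every is_a/part_of path, excluding the namespace roots
(propagation is idempotent), then tests each term with the right tail of
Fisher's exact test on the 2×2 table of (significant vs not) × (annotated vs
not), over the background of regions with ≥1 mutation. Biological-process
and molecular-function terms are tested; cellular-component is excluded by
default. Results are ranked by raw p (ties by term id); a Benjamini–Hochberg
column is attached for convenience but gates nothing.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `evalue_cutoff` | 0.001 | max per-instance (independent) E-value for a domain placement |
| `lfdr_threshold` | 0.1 | strict significance cutoff on the local FDR |
| `min_length` | 150 aa | minimum region length entering the lfdr fit |
| `prevalence_threshold` | 0.04 | "high mutation prevalence" = k / n_patients at or above this |
| `z_form` | `standardized` | `standardized` or `bernoulli_snr` (see above) |
| `min_regions` | 200 | minimum ensemble size for the empirical-null route |
| `seed` | 0 | grid-layout shuffling (and simulation, where applicable) |

## Synthetic-data generator

`synthetic_cohort` generates the study conditions every statistical property
is asserted under: 200 genes (representative lengths uniform on 180–800 aa,
8% deliberately under the 150-aa cutoff; 30% of genes carry a shorter second
isoform), 40 domains of 40–200 aa placed on 1–6 host genes each (domain 0 as
7 tandem copies on the first, long, gene; occasional instances on
non-representative isoforms exercise the restriction logic), 100 patients,
and a background rate of r = 5·10⁻⁵ mutations per residue per patient —
giving ≈2 mutations per average gene and ≈500 per cohort, comparable in
per-gene sparsity to real exome cohorts while keeping full runs in seconds.
Mutations are drawn per patient per residue (Bernoulli r, times the
multiplier m inside planted driver regions — a whole gene, or every instance
of a domain); classes follow the retained-class mix of large colon-cancer
exome studies (~80% missense, ~12% frameshift insertion, ~7% stop-gain);
decoy rows (5% synonymous, 5% dbSNP-listed, 3% germline, 2% QC-fail, as
fractions of the somatic count) exercise the filters. Everything is
deterministic under the truth seed.

What the generator does **not** emulate: trinucleotide mutational
signatures, patient-level mutation-burden heterogeneity (hypermutators),
covariate structure in the background rate (expression, replication timing),
DNA-space coordinates, or realistic gene symbols. Passing tests therefore
demonstrate the statistics' behavior under their own model assumptions
(uniform passengers, independent patients), not robustness to the
covariate-driven rate variation of real tumors.

## Worked-example excerpt

`examples.colon_domain_excerpt()` rebuilds a small colon-cancer excerpt from
per-gene/per-domain tallies (domain totals, cumulative lengths, selected
protein lengths, cohort composition counts) so the aggregation arithmetic is
exercised on concrete published-scale numbers. Instance placements, sample
ids, mutation positions and unlisted protein lengths are synthetic filler;
the module is suitable for arithmetic checks only. One reference row (the
bitter-taste-receptor domain TAS2R) is internally inconsistent between its
total and its per-gene breakdown and is omitted. The Ras-domain row's "46
further host genes with 36 additional mutations" cannot hold with every gene
contributing; the excerpt uses 36 extra hosts with one mutation each, which
preserves the assertable total (77).

## Numerical choices

* p₀ pools **all** regions of a landscape, including length-excluded short
  ones — short regions still carry passenger information; only the lfdr fit
  is restricted to regions ≥ 150 aa.
* lfdr is computed in log space (polynomial log-density minus log-normalizer
  vs normal log-pdf) to avoid underflow at extreme z, then clipped to [0,1].
* Ties: representative isoform by smallest accession; landscape tables
  sorted by descending p̂ then id; enrichment by (p, term id); assignment
  hits by (domain, start, end). All outputs are byte-stable under fixed
  inputs and configuration.
* Degenerate inputs: an all-identical z ensemble, a zero total length, a
  background rate outside (0,1), or a mutation beyond its protein length are
  hard errors; an empty cohort after filtering is legal.
* The truncated-normal MLE uses Nelder–Mead from the central-window moments;
  on non-convergence the theoretical null is used with a warning.

## Known limitations

* The binomial/normal approximation discretizes z at low counts (k is a
  small integer); the empirical null absorbs the resulting over-dispersion
  but individual lfdr values at the extreme tail of tiny landscapes are
  coarse.
* With fewer than ~200 testable regions the theoretical-null fallback
  assumes the standardized z is exactly N(0,1); if the background is
  contaminated by strong drivers, p₀ is inflated and neutral z shifts
  slightly negative, which is conservative for peak calling but biases
  lfdr values away from calibration.
* Domain instances of the same domain are assumed non-overlapping when
  expected counts are computed for truth tables (placements generated by the
  package satisfy this).
* Enrichment treats regions as exchangeable units; no term-size pruning or
  semantic-similarity collapsing is applied.
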