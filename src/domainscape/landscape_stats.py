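"""Length-normalized mutation frequencies, z-scores and local false discovery rates.

The model: under a uniform passenger process, the occurrence-weighted mutation
count k of a region of length L amino acids behaves like a binomial draw with
per-residue success probability p0 pooled over the landscape (p0 = sum k /
sum L, absorbing both the per-patient rate and the cohort size).  Each region's
relative frequency p_hat = k / L is standardized,

    z = (p_hat - p0) / sqrt(p0 * (1 - p0) / L),

which is approximately N(0,1) for passenger-only regions, and the ensemble of
z scores is fed to a local-false-discovery-rate fit in the two-groups style:
the marginal density f is estimated by Poisson regression of binned counts on
a polynomial basis, the null component f0 is a normal density whose mean and
spread are estimated from the central portion of the z ensemble, and

    lfdr(z) = min(1, pi0 * f0(z) / f(z)).

Regions shorter than a heuristic minimum length (150 aa) are excluded from
the fit; a region is a "peak" when its lfdr falls strictly below the
threshold (0.1 by default).

An alternative score, the literal signal-to-noise ratio of a Bernoulli(p_hat)
variable, z = sqrt(p_hat / (1 - p_hat)), is available as
``z_form="bernoulli_snr"``; it is monotone in p_hat but not centered, so the
empirical-null machinery has to absorb its location, and the standardized form
is the default.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from numpy.polynomial import polynomial as npoly
from scipy import optimize, stats

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .preprocess import Cohort, DomainAssignment

__all__ = [
    "LandscapeResult",
    "LfdrFit",
    "RegionStat",
    "background_rate",
    "call_peaks",
    "cumulative_domain_lengths",
    "domain_counts",
    "domain_host_genes",
    "domain_landscape",
    "fit_local_fdr",
    "gene_landscape",
    "gene_counts",
    "make_region_stats",
    "mutation_prevalence",
    "normalized_frequency",
    "zscore",
]


@dataclass
class RegionStat:
    """Per-region (gene or domain) mutation statistics."""

    region_id: str
    region_kind: str  # "gene" | "domain"
    k: int
    L: int
    z: float | None = None
    lfdr: float | None = None
    significant: bool = False
    excluded_short: bool = False

    def __post_init__(self) -> None:
        if self.region_kind not in ("gene", "domain"):
            raise ValueError(f"region_kind must be gene or domain, got {self.region_kind!r}")
        if self.k < 0 or self.L < 1:
            raise ValueError("require k >= 0 and L >= 1")

    @property
    def p_hat(self) -> float:
        return self.k / self.L


def gene_counts(cohort: "Cohort") -> dict[str, int]:
    """Occurrence-weighted mutation count per gene (sums to total retained)."""
    counts = Counter(m.gene for m in cohort.mutations)
    return dict(counts)


def cumulative_domain_lengths(
    instances: Iterable, representative_accs: Iterable[str] | None = None
) -> dict[str, int]:
    """Summed residue length of all placements of each domain.

    When ``representative_accs`` is given, only instances on those proteins
    contribute (the cancer protein set restriction).
    """
    allowed = set(representative_accs) if representative_accs is not None else None
    lengths: dict[str, int] = {}
    for instance in instances:
        if allowed is not None and instance.protein_acc not in allowed:
            continue
        lengths[instance.domain_acc] = lengths.get(instance.domain_acc, 0) + instance.length
    return lengths


def domain_counts(
    assignments: Sequence["DomainAssignment"], cohort: "Cohort"
) -> tuple[dict[str, int], dict[str, Counter]]:
    """Mutation count per domain, with the per-gene breakdown.

    A mutation covered by several instances of the *same* domain counts once
    toward that domain; instances of different domains each count.
    """
    unique: set[tuple[int, str]] = set()
    for a in assignments:
        unique.add((a.mutation_index, a.domain_acc))
    counts: dict[str, int] = {}
    breakdown: dict[str, Counter] = {}
    for mutation_index, domain_acc in sorted(unique):
        gene = cohort.mutations[mutation_index].gene
        counts[domain_acc] = counts.get(domain_acc, 0) + 1
        breakdown.setdefault(domain_acc, Counter())[gene] += 1
    return counts, breakdown


def domain_host_genes(cohort: "Cohort") -> dict[str, frozenset[str]]:
    """Genes hosting at least one instance of each domain (representative set)."""
    acc_to_gene = {p.protein_acc: p.gene for p in cohort.proteins}
    hosts: dict[str, set[str]] = {}
    for instance in cohort.domains:
        hosts.setdefault(instance.domain_acc, set()).add(acc_to_gene[instance.protein_acc])
    return {d: frozenset(g) for d, g in hosts.items()}


def normalized_frequency(k: int, L: int) -> float:
    """Length-normalized mutation frequency p_hat = k / L."""
    if L < 1:
        raise ValueError("normalizing length must be >= 1")
    if k < 0:
        raise ValueError("count must be >= 0")
    return k / L


def background_rate(stats_list: Sequence[RegionStat]) -> float:
    """Pooled passenger rate p0 = sum(k) / sum(L) over the given regions."""
    if not stats_list:
        raise ValueError("need at least one region")
    total_l = sum(s.L for s in stats_list)
    if total_l == 0:
        raise ValueError("total length is zero")
    return sum(s.k for s in stats_list) / total_l


def zscore(k: int, L: int, p0: float, form: str = "standardized") -> float:
    """Normalized score of a region against the pooled background.

    ``standardized`` (default): (k/L - p0) / sqrt(p0 (1-p0) / L).
    ``bernoulli_snr``: sqrt(p_hat / (1 - p_hat)), the literal Bernoulli
    signal-to-noise ratio of the region's own relative frequency.
    """
    p_hat = normalized_frequency(k, L)
    if form == "standardized":
        if not (0.0 < p0 < 1.0):
            raise ValueError(f"p0 must lie in (0, 1), got {p0}")
        return (p_hat - p0) / math.sqrt(p0 * (1.0 - p0) / L)
    if form == "bernoulli_snr":
        if p_hat >= 1.0:
            raise ValueError("bernoulli_snr undefined for p_hat >= 1")
        return math.sqrt(p_hat / (1.0 - p_hat))
    raise ValueError(f"unknown z form {form!r}")


@dataclass
class LfdrFit:
    """A fitted local-false-discovery-rate curve.

    ``method`` records which route produced the fit: ``"empirical"`` (Poisson
    regression marginal + MLE empirical null on the central z) or
    ``"theoretical"`` (N(0,1) null with a kernel-density marginal, used for
    small ensembles where the empirical null is unstable).
    """

    method: str
    null_mean: float
    null_sd: float
    pi0: float
    lfdr: np.ndarray
    bin_edges: np.ndarray | None = None
    bin_counts: np.ndarray | None = None
    coefficients: np.ndarray | None = None
    _log_f: object = field(default=None, repr=False)

    def evaluate(self, z: np.ndarray) -> np.ndarray:
        """lfdr at arbitrary z, clipped to [0, 1]."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        log_f0 = stats.norm.logpdf(z, loc=self.null_mean, scale=self.null_sd)
        log_f = np.atleast_1d(self._log_f(z))
        log_lfdr = math.log(self.pi0) + log_f0 - log_f
        return np.exp(np.minimum(log_lfdr, 0.0))

    def diagnostics_frame(self):
        import pandas as pd

        if self.bin_edges is None:
            return pd.DataFrame(columns=["bin_center", "count", "fitted_density"])
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        fitted = np.exp(np.atleast_1d(self._log_f(centers)))
        return pd.DataFrame(
            {"bin_center": centers, "count": self.bin_counts, "fitted_density": fitted}
        )


def _fit_empirical_null(z: np.ndarray) -> tuple[float, float, float] | None:
    """MLE normal null on the central 50% of z; returns (mean, sd, pi0) or
    None when the optimization degenerates."""
    a, b = np.quantile(z, [0.25, 0.75])
    central = z[(z >= a) & (z <= b)]
    if central.size < 10 or b <= a:
        return None

    def negative_loglik(theta: np.ndarray) -> float:
        delta, log_sigma = theta
        sigma = math.exp(log_sigma)
        mass = stats.norm.cdf((b - delta) / sigma) - stats.norm.cdf((a - delta) / sigma)
        if mass <= 1e-12:
            return 1e12
        return -(stats.norm.logpdf(central, delta, sigma).sum() - central.size * math.log(mass))

    start = np.array([central.mean(), math.log(max(central.std(), 1e-3))])
    result = optimize.minimize(negative_loglik, start, method="Nelder-Mead")
    if not result.success:
        return None
    delta, log_sigma = result.x
    sigma = math.exp(log_sigma)
    if not (math.isfinite(delta) and 1e-6 < sigma < 1e6):
        return None
    mass = stats.norm.cdf((b - delta) / sigma) - stats.norm.cdf((a - delta) / sigma)
    pi0 = min(1.0, central.size / (z.size * mass))
    pi0 = max(pi0, 1e-6)
    return float(delta), float(sigma), float(pi0)


def fit_local_fdr(
    z_values: Sequence[float],
    *,
    n_bins: int = 120,
    degree: int = 7,
    min_regions: int = 200,
) -> LfdrFit:
    """Fit the local false discovery rate of a z ensemble.

    With at least ``min_regions`` values: the marginal log-density is fitted
    by Poisson regression of ``n_bins`` equal-width bin counts on a
    ``degree``-order polynomial of the (standardized) bin centers, and the
    null is an empirical normal fitted by maximum likelihood to the central
    50% of z with pi0 capped at 1.  Below ``min_regions`` (or when the null
    MLE degenerates) the theoretical N(0,1) null is used with a Gaussian
    kernel estimate of the marginal.
    """
    z = np.asarray(list(z_values), dtype=float)
    if z.size < 4:
        raise ValueError(f"need at least 4 z values, got {z.size}")
    if np.ptp(z) == 0:
        raise ValueError("degenerate z ensemble: all values identical")

    empirical_ok = z.size >= min_regions
    fit: LfdrFit
    if empirical_ok:
        edges = np.linspace(z.min(), z.max() + 1e-9, n_bins + 1)
        counts, _ = np.histogram(z, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        width = edges[1] - edges[0]
        loc, scale = z.mean(), z.std()
        design = np.vander((centers - loc) / scale, degree + 1, increasing=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(counts, design, family=sm.families.Poisson()).fit()
        beta = np.asarray(glm.params)
        log_norm = math.log(z.size * width)

        def log_f(t: np.ndarray, _beta=beta, _loc=loc, _scale=scale, _ln=log_norm) -> np.ndarray:
            t = np.asarray(t, dtype=float)
            return npoly.polyval((t - _loc) / _scale, _beta) - _ln

        null = _fit_empirical_null(z)
        if null is None:
            warnings.warn("empirical null fit degenerated; falling back to N(0,1)", stacklevel=2)
            null_mean, null_sd, pi0 = 0.0, 1.0, 1.0
        else:
            null_mean, null_sd, pi0 = null
        fit = LfdrFit(
            method="empirical" if null is not None else "theoretical",
            null_mean=null_mean,
            null_sd=null_sd,
            pi0=pi0,
            lfdr=np.empty(0),
            bin_edges=edges,
            bin_counts=counts,
            coefficients=beta,
            _log_f=log_f,
        )
    else:
        kde = stats.gaussian_kde(z)

        def log_f(t: np.ndarray, _kde=kde) -> np.ndarray:
            return _kde.logpdf(np.asarray(t, dtype=float))

        fit = LfdrFit(
            method="theoretical",
            null_mean=0.0,
            null_sd=1.0,
            pi0=1.0,
            lfdr=np.empty(0),
            _log_f=log_f,
        )
    fit.lfdr = fit.evaluate(z)
    return fit


@dataclass
class LandscapeResult:
    """A called landscape: stats with z/lfdr/significance, plus the fit."""

    kind: str
    stats: list[RegionStat]
    p0: float
    fit: LfdrFit | None
    lfdr_threshold: float
    min_length: int
    breakdown: dict[str, Counter] = field(default_factory=dict)

    @property
    def significant_ids(self) -> frozenset[str]:
        return frozenset(s.region_id for s in self.stats if s.significant)

    def stat(self, region_id: str) -> RegionStat:
        for s in self.stats:
            if s.region_id == region_id:
                return s
        raise KeyError(region_id)


def make_region_stats(
    counts: Mapping[str, int], lengths: Mapping[str, int], kind: str
) -> list[RegionStat]:
    """One RegionStat per region with a known length; missing counts are 0.

    Regions with counts but no length are rejected — a mutation cannot be
    normalized without its region length.
    """
    missing = set(counts) - set(lengths)
    if missing:
        raise ValueError(f"regions with counts but no length: {sorted(missing)[:5]}")
    return [
        RegionStat(region_id=rid, region_kind=kind, k=int(counts.get(rid, 0)), L=int(L))
        for rid, L in sorted(lengths.items())
    ]


def call_peaks(
    stats_list: Sequence[RegionStat],
    *,
    lfdr_threshold: float = 0.1,
    min_length: int = 150,
    z_form: str = "standardized",
    min_regions: int = 200,
    kind: str | None = None,
) -> LandscapeResult:
    """Score a landscape and flag its significant peaks.

    The background p0 pools every region (short ones carry passenger
    information); regions under ``min_length`` are flagged ``excluded_short``
    and left out of the lfdr fit.  A region is significant iff its lfdr is
    strictly below the threshold, it passes the length cutoff and it has at
    least one mutation.
    """
    stats_list = list(stats_list)
    if kind is None:
        kind = stats_list[0].region_kind if stats_list else "gene"
    p0 = background_rate(stats_list)
    for s in stats_list:
        s.excluded_short = s.L < min_length
        s.z = zscore(s.k, s.L, p0, form=z_form)
        s.lfdr = None
        s.significant = False
    included = [s for s in stats_list if not s.excluded_short]
    fit = None
    if len(included) >= 4 and np.ptp([s.z for s in included]) > 0:
        fit = fit_local_fdr([s.z for s in included], min_regions=min_regions)
        for s, value in zip(included, fit.lfdr):
            s.lfdr = float(value)
            s.significant = s.lfdr < lfdr_threshold and s.k > 0
    return LandscapeResult(
        kind=kind,
        stats=stats_list,
        p0=p0,
        fit=fit,
        lfdr_threshold=lfdr_threshold,
        min_length=min_length,
    )


def gene_landscape(cohort: "Cohort", **options) -> LandscapeResult:
    """Gene-level landscape over the cancer gene set (genes with >=1 mutation)."""
    counts = gene_counts(cohort)
    lengths = {g: p.length for g, p in cohort.representatives.items() if g in counts}
    stats_list = make_region_stats(counts, lengths, "gene")
    return call_peaks(stats_list, kind="gene", **options)


def domain_landscape(
    cohort: "Cohort", assignments: Sequence["DomainAssignment"] | None = None, **options
) -> LandscapeResult:
    """Domain-level landscape over every domain placed on the cancer protein set.

    Counts aggregate mutations across all host genes; lengths are cumulative
    over all instances.  Domains without mutations stay in the ensemble with
    k = 0 (they inform the null) but can never be significant.
    """
    from .preprocess import assign_mutations_to_domains

    if assignments is None:
        assignments, _ = assign_mutations_to_domains(cohort)
    counts, breakdown = domain_counts(assignments, cohort)
    lengths = cumulative_domain_lengths(
        cohort.domains, representative_accs={p.protein_acc for p in cohort.representatives.values()}
    )
    stats_list = make_region_stats(counts, lengths, "domain")
    result = call_peaks(stats_list, kind="domain", **options)
    result.breakdown = breakdown
    return result


def mutation_prevalence(
    k: int, n_patients: int, high_threshold: float = 0.04
) -> tuple[float, bool]:
    """Domain mutation count over cohort size; "high" at or above the threshold."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if k < 0:
        raise ValueError("count must be >= 0")
    prevalence = k / n_patients
    return prevalence, prevalence >= high_threshold
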