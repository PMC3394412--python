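"""Normalized frequencies, z-scores, lfdr fitting and peak calling."""

from __future__ import annotations

import math
from decimal import Decimal, getcontext

import numpy as np
import pytest

from domainscape.landscape_stats import (
    LandscapeResult,
    RegionStat,
    background_rate,
    call_peaks,
    cumulative_domain_lengths,
    domain_counts,
    fit_local_fdr,
    gene_counts,
    make_region_stats,
    mutation_prevalence,
    normalized_frequency,
    zscore,
)
from domainscape.io_formats import DomainInstance


class TestCountsAndLengths:
    def test_gene_counts_partition_total(self, excerpt_cohort, excerpt_domain_stats):
        counts = excerpt_domain_stats["gene_counts"]
        assert sum(counts.values()) == len(excerpt_cohort.mutations)
        assert counts["KRAS"] == 30 and counts["TP53"] == 31 and counts["APC"] == 76

    def test_cumulative_length_simple(self):
        instances = [
            DomainInstance("PF1", "D", "NP_1", 1, 50, 0.0),
            DomainInstance("PF1", "D", "NP_2", 11, 70, 0.0),
        ]
        assert cumulative_domain_lengths(instances) == {"PF1": 110}

    def test_cumulative_length_reference_rows(self, excerpt_domain_stats):
        lengths = excerpt_domain_stats["lengths"]
        assert lengths["PF00870"] == 390  # P53 DNA-binding domain over TP53+TP63
        assert lengths["PF05923"] == 176  # 7 APC_crr tandem repeats in APC

    def test_restriction_to_representative_proteins(self):
        instances = [
            DomainInstance("PF1", "D", "NP_REP", 1, 50, 0.0),
            DomainInstance("PF1", "D", "NP_ISO", 1, 99, 0.0),
        ]
        assert cumulative_domain_lengths(instances, representative_accs={"NP_REP"}) == {"PF1": 50}

    def test_domain_breakdowns_sum_to_totals(self, excerpt_domain_stats):
        counts, breakdown = excerpt_domain_stats["counts"], excerpt_domain_stats["breakdown"]
        for domain_acc, k in counts.items():
            assert sum(breakdown[domain_acc].values()) == k
        assert dict(breakdown["PF03166"]) == {"SMAD4": 9, "SMAD9": 2, "SMAD2": 1, "SMAD3": 1, "GARS": 1}
        assert dict(breakdown["PF00095"]) == {"WFDC8": 3, "SLPI": 1, "WFDC5": 1, "KAL1": 1}


class TestFrequencyAndZ:
    @pytest.mark.parametrize(
        "k,L,expected",
        [(30, 189, 30 / 189), (0, 555, 0.0), (28, 390, 28 / 390)],
    )
    def test_normalized_frequency(self, k, L, expected):
        assert normalized_frequency(k, L) == pytest.approx(expected, rel=1e-15)

    def test_scale_invariance(self):
        for k, L in [(3, 200), (7, 151)]:
            assert normalized_frequency(k * 5, L * 5) == pytest.approx(normalized_frequency(k, L), rel=1e-15)

    def test_background_rate_pools_counts_over_lengths(self):
        stats = [RegionStat("A", "gene", 2, 100), RegionStat("B", "gene", 1, 200)]
        assert background_rate(stats) == pytest.approx(0.01, rel=1e-15)

    def test_all_zero_counts_make_z_undefined(self):
        stats = [RegionStat("A", "gene", 0, 100)]
        assert background_rate(stats) == 0.0
        with pytest.raises(ValueError):
            zscore(0, 100, 0.0)

    def test_zero_at_background_and_monotone(self):
        p0 = 0.01
        assert zscore(2, 200, p0) == pytest.approx(0.0, abs=1e-15)
        assert zscore(0, 200, p0) < 0
        z_values = [zscore(k, 200, p0) for k in range(0, 30)]
        assert z_values == sorted(z_values)

    def test_standardized_matches_decimal_arithmetic_oracle(self):
        """Independent high-precision re-derivation of the same formula."""
        getcontext().prec = 60
        k, L, p0 = 30, 189, Decimal("0.002")
        p_hat = Decimal(k) / Decimal(L)
        expected = (p_hat - p0) / ((p0 * (1 - p0) / Decimal(L)).sqrt())
        assert zscore(30, 189, 0.002) == pytest.approx(float(expected), rel=1e-12)

    def test_bernoulli_snr_form(self):
        assert zscore(30, 189, 0.002, form="bernoulli_snr") == pytest.approx(
            math.sqrt((30 / 189) / (1 - 30 / 189)), rel=1e-12
        )

    def test_invalid_background_rejected(self):
        with pytest.raises(ValueError):
            zscore(1, 10, 1.0)


class TestLfdrFit:
    def test_null_calibration_large_ensemble(self):
        """On pure N(0,1) draws almost nothing falls under lfdr 0.1."""
        rng = np.random.default_rng(7)
        fit = fit_local_fdr(rng.standard_normal(10000))
        assert fit.method == "empirical"
        assert (fit.lfdr < 0.1).mean() <= 0.02

    def test_mixture_detection_matches_true_density_oracle(self):
        """Detection of a shifted component tracks the closed-form lfdr
        computed from the true mixture densities (independent oracle)."""
        from scipy.stats import norm

        rng = np.random.default_rng(13)
        null = rng.standard_normal(9500)
        shifted = rng.normal(4.0, 1.0, 500)
        z = np.concatenate([null, shifted])
        fit = fit_local_fdr(z)

        true_f = 0.95 * norm.pdf(shifted) + 0.05 * norm.pdf(shifted, 4.0, 1.0)
        oracle_lfdr = np.minimum(1.0, 0.95 * norm.pdf(shifted) / true_f)
        oracle_detected = (oracle_lfdr < 0.1).mean()
        fitted_detected = (fit.evaluate(shifted) < 0.1).mean()
        assert fitted_detected == pytest.approx(oracle_detected, abs=0.10)
        assert fitted_detected >= 0.5
        assert (fit.evaluate(null) < 0.1).mean() <= 0.02

    def test_lfdr_clipped_to_unit_interval(self):
        rng = np.random.default_rng(3)
        for n in (50, 5000):  # exercises both the KDE and the Poisson-regression route
            fit = fit_local_fdr(rng.standard_normal(n))
            assert np.all(fit.lfdr >= 0.0) and np.all(fit.lfdr <= 1.0)

    def test_small_ensemble_uses_theoretical_null(self):
        rng = np.random.default_rng(5)
        fit = fit_local_fdr(rng.standard_normal(60))
        assert fit.method == "theoretical"
        assert fit.null_mean == 0.0 and fit.null_sd == 1.0 and fit.pi0 == 1.0

    def test_degenerate_ensemble_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_local_fdr([1.0] * 500)


class TestCallPeaks:
    def _stats(self, rng, n=300, short=3, outliers=2):
        stats = [RegionStat(f"R{i:03d}", "gene", int(rng.poisson(2)), 200) for i in range(n)]
        for i in range(short):
            stats[i] = RegionStat(f"R{i:03d}", "gene", 1, 100)  # below the length cutoff
        for i in range(outliers):
            stats[n - 1 - i] = RegionStat(f"R{n - 1 - i:03d}", "gene", 60, 200)
        return stats

    def test_short_regions_excluded_and_never_significant(self):
        rng = np.random.default_rng(21)
        result = call_peaks(self._stats(rng))
        short = [s for s in result.stats if s.L < 150]
        assert short and all(s.excluded_short and not s.significant and s.lfdr is None for s in short)

    def test_outliers_called_significant(self):
        rng = np.random.default_rng(21)
        result = call_peaks(self._stats(rng))
        assert {"R299", "R298"} <= result.significant_ids

    def test_threshold_is_strict(self):
        rng = np.random.default_rng(21)
        stats = self._stats(rng)
        result = call_peaks(stats, lfdr_threshold=0.0)
        assert not result.significant_ids  # lfdr < 0 is impossible

    def test_zero_count_regions_never_significant(self):
        rng = np.random.default_rng(2)
        stats = [RegionStat(f"R{i}", "gene", int(rng.poisson(2)), 200) for i in range(250)]
        stats[0] = RegionStat("R0", "gene", 0, 200)
        result = call_peaks(stats)
        assert not result.stat("R0").significant

    def test_counts_but_no_length_rejected(self):
        with pytest.raises(ValueError, match="no length"):
            make_region_stats({"A": 3}, {}, "gene")


class TestPrevalence:
    @pytest.mark.parametrize(
        "k,n,expected,high",
        [(4, 100, 0.04, True), (0, 100, 0.0, False), (132, 100, 1.32, True)],
    )
    def test_prevalence_values(self, k, n, expected, high):
        value, is_high = mutation_prevalence(k, n)
        assert value == pytest.approx(expected, rel=1e-15) and is_high == high

    def test_zero_patients_is_error(self):
        with pytest.raises(ValueError):
            mutation_prevalence(1, 0)
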