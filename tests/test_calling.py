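"""Chromosome ratios, euploid reference, z-scores and the decision rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ffenrich import (ReferenceStats, Thresholds, bin_counts, build_reference,
                      chromosome_ratio, decide, gc_correct_run, z_score)

from conftest import make_sample


def uniform_table(n_chroms=10, bins_per_chrom=10, target=0):
    """Corrected bin table with equal counts; chrom 0 holds 10% of bins."""
    chroms = [f"chr{i+1}" for i in range(n_chroms)]
    rows = []
    for c in chroms:
        for b in range(bins_per_chrom):
            rows.append((c, b * 20_000))
    table = pd.DataFrame(rows, columns=["chrom", "bin_start"])
    table["chrom"] = pd.Categorical(table["chrom"], categories=chroms)
    table["gc"] = 0.5
    table["raw_count"] = 100
    table["corrected"] = 100.0
    table["masked"] = False
    table.attrs["autosomal"] = np.ones(len(table), dtype=bool)
    table.attrs["n_reads"] = int(table["raw_count"].sum())
    return table


class TestChromosomeRatio:
    def test_uniform_counts_give_bin_share(self):
        table = uniform_table()
        assert chromosome_ratio(table, "chr1") == pytest.approx(0.10)

    def test_single_chromosome_ratio_is_one(self):
        table = uniform_table(n_chroms=1)
        assert chromosome_ratio(table, "chr1") == pytest.approx(1.0)

    def test_zero_denominator_rejected(self):
        table = uniform_table()
        table["corrected"] = 0.0
        with pytest.raises(ValueError):
            chromosome_ratio(table, "chr1")

    def test_trisomic_ratio_elevated_by_half_ff(self, genome):
        """chr21 ratio of trisomic samples ~ euploid ratio * (1 + ff/2)."""
        ff = 0.10
        eu, tr = [], []
        for i in range(6):
            r_eu, _ = make_sample(genome, ff, n=400_000, seed=30 + i)
            r_tr, _ = make_sample(genome, ff, trisomy="chr21", n=400_000,
                                  seed=60 + i)
            eu.append(bin_counts(r_eu, genome))
            tr.append(bin_counts(r_tr, genome))
        corrected = gc_correct_run(eu + tr)
        r_eu = [chromosome_ratio(t, "chr21") for t in corrected[:6]]
        r_tr = [chromosome_ratio(t, "chr21") for t in corrected[6:]]
        boost = np.mean(r_tr) / np.mean(r_eu)
        se = np.sqrt(np.var(r_tr, ddof=1) / 6) / np.mean(r_eu)
        assert abs(boost - (1 + ff / 2)) < 3 * se + 0.005


class TestReference:
    def test_hand_arithmetic_two_samples(self):
        stats = ReferenceStats.from_ratios({"chr21": [0.009, 0.011]},
                                           min_samples=2)
        assert stats.mu["chr21"] == pytest.approx(0.010)
        assert stats.sd["chr21"] == pytest.approx(0.0014142, rel=1e-4)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError):
            ReferenceStats.from_ratios({"chr21": [0.01, 0.01]}, min_samples=2)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ReferenceStats.from_ratios({"chr21": [0.009, 0.011]},
                                       min_samples=20)


class TestZScore:
    def test_mean_ratio_scores_zero(self):
        stats = ReferenceStats(mu={"chr21": 0.01}, sd={"chr21": 0.001},
                               n_samples=30)
        assert z_score(0.01, stats, "chr21") == 0.0

    def test_exactly_three_sd_is_not_positive(self):
        stats = ReferenceStats(mu={"chr21": 0.01}, sd={"chr21": 0.001},
                               n_samples=30)
        z = z_score(0.013, stats, "chr21")
        call = decide({"chr21": z}, fetal_fraction=0.1, n_unique=10**9)
        assert z == pytest.approx(3.0)
        assert call.decision == "negative"

    def test_missing_chromosome_rejected(self):
        stats = ReferenceStats(mu={"chr21": 0.01}, sd={"chr21": 0.001},
                               n_samples=30)
        with pytest.raises(KeyError):
            z_score(0.01, stats, "chr13")

    @given(st.floats(-0.01, 0.05), st.floats(-0.01, 0.05))
    def test_strictly_increasing_in_ratio(self, a, b):
        stats = ReferenceStats(mu={"chr21": 0.013}, sd={"chr21": 0.0005},
                               n_samples=30)
        if a < b:
            assert z_score(a, stats, "chr21") < z_score(b, stats, "chr21")


class TestDecision:
    thresholds = Thresholds(min_reads=3_500)

    def test_ff_just_below_floor_is_no_call(self):
        call = decide({"chr21": 10.0}, fetal_fraction=0.039, n_unique=10**6,
                      thresholds=self.thresholds)
        assert call.decision == "no_call" and call.no_call_reason == "low_ff"

    def test_low_reads_is_no_call(self):
        call = decide({"chr21": 10.0}, fetal_fraction=0.2, n_unique=100,
                      thresholds=self.thresholds)
        assert call.no_call_reason == "low_reads"

    def test_unpredictable_ff_is_no_call(self):
        call = decide({"chr21": 0.0}, fetal_fraction=None, n_unique=10**6,
                      thresholds=self.thresholds, ff_predictable=False)
        assert call.no_call_reason == "ff_unpredictable"

    def test_published_enriched_zscores_yield_five_positives(self):
        """Eleven false-negative samples re-screened after enrichment: the
        strict z > 3 rule flags exactly five of the printed z-scores."""
        z_values = [11.92, -1.05, 5.076, 2.16, 1.687, 4.01, -1.86, 1.096,
                    1.634, 10.14, 6.972]
        ffs = [15.6, 18.6, 11.4, 26.4, 15.2, 11.8, 18.8, 19, 14.7, 14.6, 7.9]
        calls = [decide({"chr21": z}, fetal_fraction=ff / 100,
                        n_unique=10**7, thresholds=Thresholds())
                 for z, ff in zip(z_values, ffs)]
        positives = [c for c in calls if c.decision == "positive"]
        assert len(positives) == 5

    def test_moderate_z_with_adequate_ff_is_negative(self):
        call = decide({"chr21": 2.41}, fetal_fraction=0.056, n_unique=10**7,
                      thresholds=Thresholds())
        assert call.decision == "negative"


class TestEuploidCalibration:
    def test_euploid_z_scores_mostly_within_three_sd(self, genome):
        """~99.7% of euploid z values should fall in (-3, 3); assert >= 98%
        on 120 samples scored against an independent 25-sample reference."""
        n = 150_000
        ref_tables = [bin_counts(make_sample(genome, 0.12, n=n, seed=2000 + i,
                                             gc_amp=4.0)[0], genome)
                      for i in range(25)]
        test_tables = [bin_counts(make_sample(genome, 0.12, n=n, seed=3000 + i,
                                              gc_amp=4.0)[0], genome)
                       for i in range(120)]
        corrected = gc_correct_run(ref_tables + test_tables)
        stats = build_reference(corrected[:25], min_samples=20)
        zs = []
        for t in corrected[25:]:
            for c in ("chr13", "chr18", "chr21"):
                zs.append(z_score(chromosome_ratio(t, c), stats, c))
        zs = np.array(zs)
        assert (np.abs(zs) < 3).mean() >= 0.98
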