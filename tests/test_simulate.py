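"""Generator statistics: origin sampling, trisomy dosage, bead enrichment."""

import numpy as np
import pandas as pd
import pytest

from ffenrich import (BeadRetention, CohortSpec, SampleTruth, chry_fraction,
                      generate_cohort, in_silico_size_select,
                      simulate_bead_enrichment)
from ffenrich.simulate import fetal_copy_weights

from conftest import make_sample


class TestSampleTruth:
    @pytest.mark.parametrize("kw", [
        {"fetal_fraction": 0.6},
        {"fetal_fraction": -0.01},
        {"fetal_sex": "unknown"},
        {"trisomy": "chr12"},
        {"n_fragments": 0},
    ])
    def test_invalid_truth_rejected(self, kw):
        base = dict(fetal_fraction=0.1, fetal_sex="male", trisomy=None,
                    n_fragments=10, seed=0)
        base.update(kw)
        with pytest.raises(ValueError):
            SampleTruth(**base)


class TestGenerateSample:
    def test_zero_fetal_fraction_yields_no_fetal_fragments(self, toy_genome):
        rec, _ = make_sample(toy_genome, 0.0, n=20_000)
        assert (rec["origin"] == "fetal").sum() == 0

    def test_fetal_share_within_binomial_error(self, toy_genome):
        n = 200_000
        rec, _ = make_sample(toy_genome, 0.10, n=n, seed=1)
        frac = (rec["origin"] == "fetal").mean()
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(frac - 0.10) < 3 * se

    def test_trisomy_dosage_is_1_5x_disomic_share(self, genome):
        """Among fetal-origin fragments the trisomic chromosome's share must
        match the 1.5x-reweighted multinomial expectation."""
        rec, _ = make_sample(genome, 0.2, trisomy="chr21", n=400_000, seed=2,
                             dup_rate=0.0, multimap_rate=0.0)
        fetal = rec.loc[rec["origin"] == "fetal"]
        share = (fetal["chrom"] == "chr21").mean()
        w = fetal_copy_weights(genome, "male", "chr21")
        expected = (1.5 * genome.lengths[genome.chrom_index("chr21")]
                    / (w * genome.lengths).sum())
        se = np.sqrt(expected * (1 - expected) / len(fetal))
        assert abs(share - expected) < 4 * se
        # and ~1.5x the disomic expectation
        disomic = (genome.lengths[genome.chrom_index("chr21")]
                   / (fetal_copy_weights(genome, "male", None)
                      * genome.lengths).sum())
        assert share / disomic == pytest.approx(1.5, rel=0.05)

    def test_female_fetus_emits_no_fetal_chry(self, genome):
        rec, _ = make_sample(genome, 0.3, sex="female", n=100_000, seed=3)
        fetal = rec.loc[rec["origin"] == "fetal"]
        assert (fetal["chrom"] == "chrY").sum() == 0

    def test_fragments_stay_within_chromosomes(self, toy_genome):
        rec, _ = make_sample(toy_genome, 0.1, n=50_000, seed=4)
        lens = toy_genome.lengths[rec["chrom"].cat.codes.to_numpy()]
        assert (rec["start"] >= 0).all()
        assert (rec["start"].to_numpy() + rec["length"].to_numpy() <= lens).all()
        assert rec["length"].between(50, 250).all()


class TestGenerateCohort:
    def test_reproducible_under_seed(self, toy_genome):
        spec = CohortSpec(n_samples=3, n_fragments=5_000)
        a = [r for r, _ in generate_cohort(toy_genome, spec, seed=7)]
        b = [r for r, _ in generate_cohort(toy_genome, spec, seed=7)]
        for ra, rb in zip(a, b):
            pd.testing.assert_frame_equal(ra, rb)

    def test_different_seeds_differ(self, toy_genome):
        spec = CohortSpec(n_samples=1, n_fragments=5_000)
        (ra, _), = generate_cohort(toy_genome, spec, seed=1)
        (rb, _), = generate_cohort(toy_genome, spec, seed=2)
        assert not ra["start"].equals(rb["start"])

    def test_empty_cohort(self, toy_genome):
        spec = CohortSpec(n_samples=0, n_fragments=5_000)
        assert list(generate_cohort(toy_genome, spec, seed=1)) == []

    def test_trisomy_prevalence_within_binomial_interval(self, toy_genome):
        from ffenrich import draw_truths
        spec = CohortSpec(n_samples=200, n_fragments=1, trisomy_prevalence=0.5)
        truths = draw_truths(spec, seed=11)
        k = sum(t.trisomy is not None for t in truths)
        # central 99% interval of Binomial(200, 0.5)
        assert 82 <= k <= 118

    def test_ff_range_respected(self, toy_genome):
        from ffenrich import draw_truths
        spec = CohortSpec(n_samples=100, n_fragments=1)
        truths = draw_truths(spec, seed=5)
        ffs = [t.fetal_fraction for t in truths]
        assert min(ffs) >= 0.03 and max(ffs) <= 0.30


class TestBeadEnrichment:
    def test_identity_retention_keeps_everything(self, toy_genome):
        rec, _ = make_sample(toy_genome, 0.1, n=20_000, seed=6)
        kept = simulate_bead_enrichment(rec, retention=lambda l: np.ones(len(l)),
                                        seed=0)
        pd.testing.assert_frame_equal(kept, rec)

    def test_step_retention_equals_hard_cutoff(self, toy_genome):
        rec, _ = make_sample(toy_genome, 0.1, n=20_000, seed=6)
        step = lambda l: (np.asarray(l) < 160).astype(float)
        kept = simulate_bead_enrichment(rec, retention=step, seed=0)
        pd.testing.assert_frame_equal(kept, in_silico_size_select(rec, 160))

    def test_output_is_subset_of_input(self, toy_genome):
        rec, _ = make_sample(toy_genome, 0.1, n=20_000, seed=8)
        kept = simulate_bead_enrichment(rec, BeadRetention.preset("1.3x"), seed=1)
        assert kept.index.isin(rec.index).all() and len(kept) < len(rec)

    def test_invalid_retention_rejected(self, toy_genome):
        rec, _ = make_sample(toy_genome, 0.1, n=1_000, seed=9)
        with pytest.raises(ValueError):
            simulate_bead_enrichment(rec, retention=lambda l: np.full(len(l), 1.5),
                                     seed=0)

    def test_presets_ordered_by_steepness(self):
        lengths = np.array([150, 170])
        r12 = BeadRetention.preset("1.2x")(lengths)
        r15 = BeadRetention.preset("1.5x")(lengths)
        assert r15[0] > r12[0] and r15[1] < r12[1]

    def test_strongest_preset_raises_chry_fraction_1p5_to_4x(self, genome):
        """The 1.5x bead preset must raise the chrY read fraction of an
        ff=0.10 male sample by a factor in [1.5, 4]."""
        rec, _ = make_sample(genome, 0.10, n=1_200_000, seed=10)
        kept = simulate_bead_enrichment(rec, BeadRetention.preset("1.5x"),
                                        seed=2)
        factor = chry_fraction(kept) / chry_fraction(rec)
        assert 1.5 <= factor <= 4.0

    def test_enrichment_raises_fetal_fraction_in_expectation(self, genome):
        """Monotone enrichment: decreasing retention on a stochastically
        shorter fetal distribution raises the origin-channel fetal share."""
        pre_frac, post_frac = [], []
        for seed in range(5):
            rec, _ = make_sample(genome, 0.10, n=200_000, seed=20 + seed)
            kept = simulate_bead_enrichment(rec, BeadRetention.preset("1.3x"),
                                            seed=seed)
            pre_frac.append((rec["origin"] == "fetal").mean())
            post_frac.append((kept["origin"] == "fetal").mean())
        assert np.mean(post_frac) > np.mean(pre_frac) + 3 * np.std(pre_frac)
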