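"""Shared fixtures.

Heavier simulated objects (calibration cohorts, references) are
session-scoped so the statistical tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ffenrich import (ChrYCalibration, GenomeModel, SampleTruth,
                      apply_read_filters, calibrate_chry, generate_sample)
from ffenrich.simulate import GCBias

settings.register_profile("suite", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def genome() -> GenomeModel:
    return GenomeModel.scaled_hg19()


@pytest.fixture(scope="session")
def toy_genome() -> GenomeModel:
    """Two autosomes + sex chromosomes, 10 full bins each, flat-ish GC."""
    lengths = {"chr1": 200_000, "chr2": 200_000, "chrX": 100_000,
               "chrY": 40_000}
    return GenomeModel.from_lengths(lengths, bin_size=20_000, gc_seed=11)


def make_sample(genome, ff, sex="male", trisomy=None, n=150_000, seed=0,
                gc_amp=0.0, **kw):
    truth = SampleTruth(fetal_fraction=ff, fetal_sex=sex, trisomy=trisomy,
                        n_fragments=n, seed=seed)
    bias = GCBias(gc_amp) if gc_amp else None
    return generate_sample(genome, truth, gc_bias=bias, **kw), truth


@pytest.fixture(scope="session")
def chry_calibration(genome) -> ChrYCalibration:
    """Calibration from a 30-male + 8-female synthetic cohort."""
    rng = np.random.default_rng(42)
    males = []
    for i, ff in enumerate(np.linspace(0.04, 0.30, 30)):
        rec, _ = make_sample(genome, float(ff), "male", n=150_000, seed=500 + i)
        males.append((apply_read_filters(rec)[0], float(ff)))
    females = []
    for i in range(8):
        ff = float(rng.uniform(0.06, 0.2))
        rec, _ = make_sample(genome, ff, "female", n=150_000, seed=700 + i)
        females.append(apply_read_filters(rec)[0])
    return calibrate_chry(males, females)
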