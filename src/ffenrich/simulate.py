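"""Synthetic maternal-plasma cfDNA cohorts and a bead size-selection model.

Each simulated sample is a table of aligned single-end fragments
(chrom, start, length, duplicate/unique-mapping flags) plus a hidden
``origin`` column (maternal/fetal) that only tests and truth bookkeeping may
read — none of the analysis stages touches it.

Fragments are drawn independently: origin ~ Bernoulli(fetal fraction),
length from the origin's size distribution, genomic bin proportional to
(bin span x chromosome copy weight x GC-bias curve), position uniform within
the bin.  A male fetus contributes chrY fragments in proportion to chrY's
share of a 46,XY genome (half-weight sex chromosomes); a trisomic chromosome
carries 1.5x fetal weight.  Maternal fragments hit chrY only through a small
configurable mismapping weight, emulating the nonzero chrY read fraction
observed in pregnancies with female fetuses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import SizeDistribution
from .genome import GenomeModel

FRAGMENT_COLUMNS = ["chrom", "start", "length", "is_duplicate", "is_unique"]

TRISOMY_CHROMS = ("chr13", "chr18", "chr21")

#: Logistic bead-retention steepness per bead-ratio preset (1/bp); the
#: 1.5x preset is the steepest, approaching the hard <160 bp cutoff.
BEAD_PRESETS = {"1.2x": 0.15, "1.3x": 0.30, "1.5x": 0.60}

#: Default maternal chrY mismapping weight (fraction of chrY length used as
#: placement weight); yields a female-pregnancy chrY read fraction ~2e-4.
DEFAULT_CHRY_MISMAP_WEIGHT = 0.01


@dataclass(frozen=True)
class SampleTruth:
    """Ground truth for one simulated sample."""

    fetal_fraction: float
    fetal_sex: str                  # "male" | "female"
    trisomy: str | None = None      # chr13 / chr18 / chr21 / None
    n_fragments: int = 3_500_000
    seed: int = 0
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fetal_fraction <= 0.5:
            raise ValueError("fetal_fraction must lie in [0, 0.5]")
        if self.fetal_sex not in ("male", "female"):
            raise ValueError("fetal_sex must be 'male' or 'female'")
        if self.trisomy is not None and self.trisomy not in TRISOMY_CHROMS:
            raise ValueError(f"trisomy must be one of {TRISOMY_CHROMS} or None")
        if self.n_fragments <= 0:
            raise ValueError("n_fragments must be positive")


@dataclass(frozen=True)
class GCBias:
    """Unimodal quadratic sampling bias in bin GC: 1 - amplitude*(gc-peak)^2."""

    amplitude: float = 4.0
    peak: float = 0.40
    floor: float = 0.05

    def __call__(self, gc: np.ndarray) -> np.ndarray:
        val = 1.0 - self.amplitude * (np.asarray(gc, dtype=float) - self.peak) ** 2
        return np.clip(val, self.floor, None)


@dataclass(frozen=True)
class BeadRetention:
    """Length-dependent bead retention: logistic, decreasing in length.

    ``retention(L) = 1 / (1 + exp(steepness * (L - midpoint)))`` so that a
    fragment at the midpoint (default 160 bp) is kept with probability 0.5.
    """

    steepness: float = 0.60
    midpoint: float = 160.0

    @classmethod
    def preset(cls, name: str) -> "BeadRetention":
        try:
            return cls(steepness=BEAD_PRESETS[name])
        except KeyError:
            raise ValueError(
                f"unknown bead preset {name!r}; choose from {sorted(BEAD_PRESETS)}"
            ) from None

    def __call__(self, length: np.ndarray) -> np.ndarray:
        z = self.steepness * (np.asarray(length, dtype=float) - self.midpoint)
        return 1.0 / (1.0 + np.exp(z))


# ----------------------------------------------------------------------
# chromosome copy weights


def maternal_copy_weights(
    genome: GenomeModel, chry_mismap_weight: float = DEFAULT_CHRY_MISMAP_WEIGHT
) -> np.ndarray:
    """Relative placement weight per chromosome for maternal (46,XX) DNA."""
    w = np.ones(len(genome.chroms))
    if "chrY" in genome.chroms:
        w[genome.chrom_index("chrY")] = chry_mismap_weight
    return w


def fetal_copy_weights(
    genome: GenomeModel, fetal_sex: str, trisomy: str | None
) -> np.ndarray:
    """Relative placement weight per chromosome for fetal DNA.

    Sex chromosomes carry half weight in a male fetus (one X, one Y per
    diploid autosome pair); a female fetus emits no chrY fragments.  The
    trisomic chromosome carries 1.5x weight (three copies vs two).
    """
    w = np.ones(len(genome.chroms))
    if "chrX" in genome.chroms:
        w[genome.chrom_index("chrX")] = 0.5 if fetal_sex == "male" else 1.0
    if "chrY" in genome.chroms:
        w[genome.chrom_index("chrY")] = 0.5 if fetal_sex == "male" else 0.0
    if trisomy is not None:
        w[genome.chrom_index(trisomy)] = 1.5
    return w


def _bin_sampling_cdf(genome: GenomeModel, copy_weights: np.ndarray,
                      bias: GCBias | None) -> np.ndarray:
    w = genome.bin_span.astype(float) * copy_weights[genome.bin_chrom]
    if bias is not None:
        w = w * bias(genome.bin_gc)
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate placement weights (no positive mass)")
    return np.cumsum(w / total)


# ----------------------------------------------------------------------
# sample / cohort generation


def generate_sample(
    genome: GenomeModel,
    truth: SampleTruth,
    *,
    maternal_dist: SizeDistribution | None = None,
    fetal_dist: SizeDistribution | None = None,
    gc_bias: GCBias | None = None,
    dup_rate: float = 0.02,
    multimap_rate: float = 0.01,
    chry_mismap_weight: float = DEFAULT_CHRY_MISMAP_WEIGHT,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one plasma cfDNA sample as a fragment table.

    Returns a DataFrame with columns chrom (categorical), start, length,
    is_duplicate, is_unique and the truth-only column origin.  Duplicates are
    created by re-emitting already-drawn records (so the output holds
    ``n_fragments * (1 + dup_rate)`` rows on average); a ``multimap_rate``
    fraction of records is flagged as non-uniquely mapping.
    """
    maternal_dist = maternal_dist or SizeDistribution.maternal_default()
    fetal_dist = fetal_dist or SizeDistribution.fetal_default()
    if fetal_dist.mass_below(150) <= maternal_dist.mass_below(150):
        raise ValueError(
            "fetal length distribution must place more mass below 150 bp "
            "than the maternal distribution"
        )
    if rng is None:
        rng = np.random.default_rng(truth.seed)

    n = truth.n_fragments
    is_fetal = rng.random(n) < truth.fetal_fraction

    lengths = np.empty(n, dtype=np.int16)
    n_fet = int(is_fetal.sum())
    lengths[is_fetal] = fetal_dist.sample(rng, n_fet)
    lengths[~is_fetal] = maternal_dist.sample(rng, n - n_fet)

    mat_cdf = _bin_sampling_cdf(
        genome, maternal_copy_weights(genome, chry_mismap_weight), gc_bias
    )
    fet_w = fetal_copy_weights(genome, truth.fetal_sex, truth.trisomy)
    if truth.fetal_sex == "female" and "chrY" in genome.chroms:
        assert fet_w[genome.chrom_index("chrY")] == 0.0
    fet_cdf = _bin_sampling_cdf(genome, fet_w, gc_bias)

    u = rng.random(n)
    bins = np.empty(n, dtype=np.int64)
    bins[is_fetal] = np.searchsorted(fet_cdf, u[is_fetal], side="right")
    bins[~is_fetal] = np.searchsorted(mat_cdf, u[~is_fetal], side="right")
    bins = np.minimum(bins, genome.n_bins - 1)

    span = genome.bin_span[bins]
    starts = genome.bin_start[bins] + (rng.random(n) * span).astype(np.int64)
    chrom_codes = genome.bin_chrom[bins]
    # keep start + length within the chromosome
    chrom_len = genome.lengths[chrom_codes]
    starts = np.minimum(starts, np.maximum(chrom_len - lengths, 0))

    is_unique = rng.random(n) >= multimap_rate
    is_dup = np.zeros(n, dtype=bool)
    origin_codes = is_fetal.astype(np.int8)  # 0 maternal, 1 fetal

    if dup_rate > 0:
        n_dup = rng.binomial(n, dup_rate)
        if n_dup:
            idx = rng.integers(0, n, n_dup)
            chrom_codes = np.concatenate([chrom_codes, chrom_codes[idx]])
            starts = np.concatenate([starts, starts[idx]])
            lengths = np.concatenate([lengths, lengths[idx]])
            is_unique = np.concatenate([is_unique, is_unique[idx]])
            is_dup = np.concatenate([is_dup, np.ones(n_dup, dtype=bool)])
            origin_codes = np.concatenate([origin_codes, origin_codes[idx]])
    perm = rng.permutation(len(starts))

    return pd.DataFrame({
        "chrom": pd.Categorical.from_codes(
            chrom_codes[perm].astype(np.int16), categories=list(genome.chroms)
        ),
        "start": starts[perm],
        "length": lengths[perm],
        "is_duplicate": is_dup[perm],
        "is_unique": is_unique[perm],
        "origin": pd.Categorical.from_codes(
            origin_codes[perm], categories=["maternal", "fetal"]
        ),
    })


@dataclass(frozen=True)
class CohortSpec:
    """Population parameters for a simulated cohort.

    Defaults mirror the screening setting the pipeline targets: fetal
    fraction ~ Normal(0.13, 0.045) truncated to [0.03, 0.30] (the 3-30%
    clinical range, mean ~13%), even fetal sex ratio, and single-end
    libraries of 3.5 million fragments.
    """

    n_samples: int
    n_fragments: int = 3_500_000
    ff_mean: float = 0.13
    ff_sd: float = 0.045
    ff_range: tuple[float, float] = (0.03, 0.30)
    male_fraction: float = 0.5
    trisomy_prevalence: float = 0.0
    trisomy_chroms: tuple[str, ...] = TRISOMY_CHROMS
    gc_bias_amplitude: float = 4.0
    gc_bias_amplitude_sd: float = 0.8
    dup_rate: float = 0.02
    multimap_rate: float = 0.01


def draw_truths(spec: CohortSpec, seed: int) -> list[SampleTruth]:
    """Draw per-sample ground truths (reproducible under the seed)."""
    rng = np.random.default_rng(seed)
    child_seeds = np.random.SeedSequence(seed).spawn(spec.n_samples)
    truths = []
    for i, child in enumerate(child_seeds):
        ff = float(np.clip(rng.normal(spec.ff_mean, spec.ff_sd), *spec.ff_range))
        sex = "male" if rng.random() < spec.male_fraction else "female"
        trisomy = None
        if rng.random() < spec.trisomy_prevalence:
            trisomy = str(rng.choice(spec.trisomy_chroms))
        truths.append(SampleTruth(
            fetal_fraction=ff, fetal_sex=sex, trisomy=trisomy,
            n_fragments=spec.n_fragments,
            seed=int(child.generate_state(1)[0] % (2**31)),
            sample_id=f"S{i:04d}",
        ))
    return truths


def generate_cohort(
    genome: GenomeModel, spec: CohortSpec, seed: int,
    maternal_dist: SizeDistribution | None = None,
    fetal_dist: SizeDistribution | None = None,
):
    """Yield ``(fragments, truth)`` pairs for a seeded cohort.

    The per-sample GC-bias amplitude is jittered around the cohort mean,
    emulating run-to-run bias variation that the correction stage must
    absorb.  Identical ``(spec, seed)`` inputs reproduce the cohort exactly.
    """
    truths = draw_truths(spec, seed)
    amp_rng = np.random.default_rng(np.random.SeedSequence((seed, 1)).generate_state(1)[0])
    for truth in truths:
        amp = max(0.0, amp_rng.normal(spec.gc_bias_amplitude,
                                      spec.gc_bias_amplitude_sd))
        records = generate_sample(
            genome, truth,
            maternal_dist=maternal_dist, fetal_dist=fetal_dist,
            gc_bias=GCBias(amplitude=amp),
            dup_rate=spec.dup_rate, multimap_rate=spec.multimap_rate,
        )
        yield records, truth


def simulate_bead_enrichment(
    records: pd.DataFrame,
    retention: BeadRetention | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Stochastic analogue of bead size selection.

    Each record is kept independently with probability ``retention(length)``.
    Never creates records: the output is a subset of the input.
    """
    retention = retention or BeadRetention()
    if rng is None:
        rng = np.random.default_rng(seed)
    prob = retention(records["length"].to_numpy())
    if np.any(prob < 0) or np.any(prob > 1):
        raise ValueError("retention probabilities must lie in [0, 1]")
    keep = rng.random(len(records)) < prob
    return records.loc[keep]
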