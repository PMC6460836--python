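"""Chromosome-ratio z-scores against a euploid reference and trisomy calls.

The chromosome ratio of a test sample is the GC-corrected read share of one
chromosome among all unmasked autosomal bins.  The z-score standardizes that
ratio against the mean and SD of a reference set of euploid pregnancies
processed with the same protocol (enriched libraries are scored against an
enriched reference).  A trisomy is reported for any tested chromosome with
z strictly greater than 3; a sample is a no-call when its unique read count
or its fetal-fraction estimate falls below the QC floors, or when the fetal
fraction is unpredictable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_TEST_CHROMS = ("chr13", "chr18", "chr21")


@dataclass(frozen=True)
class ReferenceStats:
    """Per-chromosome mean and SD of euploid reference chromosome ratios."""

    mu: dict[str, float]
    sd: dict[str, float]
    n_samples: int

    def __post_init__(self) -> None:
        for c, s in self.sd.items():
            if not s > 0:
                raise ValueError(f"degenerate reference: sd({c}) is not positive")

    @classmethod
    def from_ratios(cls, ratios: dict[str, list[float]],
                    min_samples: int = 20) -> "ReferenceStats":
        ns = {len(v) for v in ratios.values()}
        if len(ns) != 1:
            raise ValueError("ragged ratio lists")
        n = ns.pop()
        if n < min_samples:
            raise ValueError(f"reference needs >= {min_samples} samples, got {n}")
        mu = {c: float(np.mean(v)) for c, v in ratios.items()}
        sd = {c: float(np.std(v, ddof=1)) for c, v in ratios.items()}
        return cls(mu=mu, sd=sd, n_samples=n)


@dataclass(frozen=True)
class Thresholds:
    """QC and decision thresholds for calling."""

    z_cutoff: float = 3.0
    min_ff: float = 0.04
    min_reads: float = 3_500_000.0


@dataclass(frozen=True)
class CallResult:
    sample_id: str | None
    z: dict[str, float]
    fetal_fraction: float | None
    n_unique: int
    decision: str                      # "positive" | "negative" | "no_call"
    positive_chroms: tuple[str, ...] = ()
    no_call_reason: str | None = None  # "low_reads" | "low_ff" | "ff_unpredictable"

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "z": self.z,
            "fetal_fraction": self.fetal_fraction,
            "n_unique": self.n_unique,
            "decision": self.decision,
            "positive_chroms": list(self.positive_chroms),
            "no_call_reason": self.no_call_reason,
        }


def chromosome_ratio(table: pd.DataFrame, chrom: str) -> float:
    """Corrected-count share of ``chrom`` among unmasked autosomal bins."""
    ok = ~table["masked"].to_numpy()
    autosomal = table.attrs.get("autosomal")
    if autosomal is None:
        autosomal = np.array([str(c).replace("chr", "").isdigit()
                              for c in table["chrom"]])
    counts = table["corrected"].to_numpy()
    denom = counts[ok & autosomal].sum()
    if denom <= 0:
        raise ValueError("zero denominator: no corrected counts on unmasked "
                         "autosomal bins")
    on_chrom = (table["chrom"] == chrom).to_numpy()
    if not (ok & on_chrom).any():
        raise ValueError(f"no unmasked bins on {chrom}")
    return float(counts[ok & on_chrom].sum() / denom)


def build_reference(
    tables: list[pd.DataFrame],
    chroms: tuple[str, ...] = DEFAULT_TEST_CHROMS,
    min_samples: int = 20,
) -> ReferenceStats:
    """Reference mean/SD of chromosome ratios from euploid, corrected tables."""
    ratios = {c: [chromosome_ratio(t, c) for t in tables] for c in chroms}
    return ReferenceStats.from_ratios(ratios, min_samples=min_samples)


def z_score(ratio: float, stats: ReferenceStats, chrom: str) -> float:
    """(ratio - reference mean) / reference SD for one chromosome."""
    if chrom not in stats.mu:
        raise KeyError(f"{chrom} not present in reference")
    return (ratio - stats.mu[chrom]) / stats.sd[chrom]


def decide(
    z: dict[str, float],
    fetal_fraction: float | None,
    n_unique: int,
    thresholds: Thresholds = Thresholds(),
    ff_predictable: bool = True,
    sample_id: str | None = None,
) -> CallResult:
    """Apply the QC floors and the strict z > cutoff rule.

    QC precedence: read count, then fetal-fraction predictability, then the
    fetal-fraction floor.  ``z == cutoff`` is *not* positive (strict rule).
    """
    base = dict(z=z, fetal_fraction=fetal_fraction, n_unique=n_unique,
                sample_id=sample_id)
    if n_unique < thresholds.min_reads:
        return CallResult(decision="no_call", no_call_reason="low_reads", **base)
    if not ff_predictable or fetal_fraction is None:
        return CallResult(decision="no_call", no_call_reason="ff_unpredictable",
                          **base)
    if fetal_fraction < thresholds.min_ff:
        return CallResult(decision="no_call", no_call_reason="low_ff", **base)
    positive = tuple(c for c, v in z.items() if v > thresholds.z_cutoff)
    if positive:
        return CallResult(decision="positive", positive_chroms=positive, **base)
    return CallResult(decision="negative", **base)


def call_sample(
    table: pd.DataFrame,
    stats: ReferenceStats,
    fetal_fraction,
    thresholds: Thresholds = Thresholds(),
    sample_id: str | None = None,
) -> CallResult:
    """Score a corrected bin table against a reference and call it.

    ``fetal_fraction`` may be a plain proportion or an
    :class:`~ffenrich.fetal_fraction.FFEstimate` (whose predictability flag
    feeds the no-call rule).
    """
    ff_predictable = True
    ff = fetal_fraction
    if hasattr(fetal_fraction, "predictable"):
        ff_predictable = fetal_fraction.predictable
        ff = fetal_fraction.p
    z = {c: z_score(chromosome_ratio(table, c), stats, c) for c in stats.mu}
    n_unique = int(table.attrs.get("n_reads", table["raw_count"].sum()))
    if sample_id is None:
        sample_id = table.attrs.get("sample_id")
    return decide(z, ff, n_unique, thresholds,
                  ff_predictable=ff_predictable, sample_id=sample_id)
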