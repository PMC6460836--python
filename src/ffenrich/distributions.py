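"""Fragment-length distributions for maternal- and fetal-origin cfDNA.

Plasma cfDNA is nucleosomally patterned: the bulk (maternal-origin) fragments
peak at the chromatosome length (~166 bp) with a minor mono-nucleosome
component (~143 bp).  Placental (fetal-origin) fragments are systematically
shorter: the chromatosome peak is depleted and shifted down a few bases, the
nucleosome component is stronger, and there is a broad sub-150 bp shoulder.
The defaults below are discrete mixtures over 50-250 bp chosen so that the
fetal/maternal density ratio rises from ~100 bp to a peak around 120-140 bp
and falls below 1 above 160 bp, the shape that makes length-based fetal
enrichment work; the exact parametric forms are free modelling choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

SUPPORT_MIN = 50
SUPPORT_MAX = 250

#: Frozen default mixture weights/components (weight, kind, params).
MATERNAL_COMPONENTS = (
    (0.80, "gaussian", (166.0, 9.0)),
    (0.16, "gaussian", (143.0, 9.0)),
    (0.04, "uniform", (100, 200)),
)
FETAL_COMPONENTS = (
    (0.42, "gaussian", (160.0, 9.0)),
    (0.29, "gaussian", (143.0, 9.0)),
    (0.24, "gaussian", (137.0, 11.0)),
    (0.05, "uniform", (100, 200)),
)


@dataclass(frozen=True)
class SizeDistribution:
    """Discrete fragment-length pmf on integer lengths 50-250 bp."""

    support: np.ndarray
    pmf: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.pmf < 0):
            raise ValueError("pmf entries must be non-negative")
        if abs(float(self.pmf.sum()) - 1.0) > 1e-9:
            raise ValueError("pmf must sum to 1 (tolerance 1e-9)")
        if len(self.support) != len(self.pmf):
            raise ValueError("support and pmf lengths differ")

    # ------------------------------------------------------------------
    @classmethod
    def from_components(
        cls,
        components,
        support: np.ndarray | None = None,
    ) -> "SizeDistribution":
        """Mixture of gaussian / uniform components, discretized on support.

        ``components`` is an iterable of ``(weight, kind, params)`` with kind
        ``"gaussian"`` (mu, sigma) or ``"uniform"`` (lo, hi) — uniform over
        integer lengths in half-open ``[lo, hi)``.
        """
        if support is None:
            support = np.arange(SUPPORT_MIN, SUPPORT_MAX + 1)
        support = np.asarray(support)
        pmf = np.zeros(len(support), dtype=np.float64)
        total_w = 0.0
        for weight, kind, params in components:
            if kind == "gaussian":
                mu, sigma = params
                comp = stats.norm.pdf(support, mu, sigma)
            elif kind == "uniform":
                lo, hi = params
                comp = ((support >= lo) & (support < hi)).astype(float)
            else:
                raise ValueError(f"unknown component kind {kind!r}")
            s = comp.sum()
            if s <= 0:
                raise ValueError(f"component {kind}{params} has no mass on support")
            pmf += weight * comp / s
            total_w += weight
        pmf /= total_w
        return cls(support=support, pmf=pmf)

    @classmethod
    def maternal_default(cls) -> "SizeDistribution":
        return cls.from_components(MATERNAL_COMPONENTS)

    @classmethod
    def fetal_default(cls) -> "SizeDistribution":
        return cls.from_components(FETAL_COMPONENTS)

    # ------------------------------------------------------------------
    @property
    def cdf(self) -> np.ndarray:
        return np.cumsum(self.pmf)

    def mass_below(self, cutoff: float) -> float:
        """Total probability of lengths strictly below ``cutoff``."""
        return float(self.pmf[self.support < cutoff].sum())

    def mass_in(self, lo: float, hi: float) -> float:
        """Probability of lengths in half-open ``[lo, hi)``."""
        mask = (self.support >= lo) & (self.support < hi)
        return float(self.pmf[mask].sum())

    def mean(self) -> float:
        return float((self.support * self.pmf).sum())

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` lengths (int16)."""
        idx = np.searchsorted(self.cdf, rng.random(n), side="right")
        idx = np.minimum(idx, len(self.support) - 1)
        return self.support[idx].astype(np.int16)
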