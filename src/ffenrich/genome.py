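"""Genome model: chromosome sizes and fixed-width bins with per-bin GC.

Counting and GC correction work on fixed-width bins (default 20 kb).  The
default genome is a desk-scale model with hg19 chromosome lengths divided by
a configurable factor, which preserves the relative chromosome ratios that
the z-score statistic depends on while keeping simulated cohorts cheap.
Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: hg19 chromosome lengths (chr1..chr22, chrX, chrY), in bases.
HG19_LENGTHS: dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430,
    "chr4": 191154276, "chr5": 180915260, "chr6": 171115067,
    "chr7": 159138663, "chr8": 146364022, "chr9": 141213431,
    "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392,
    "chr16": 90354753, "chr17": 81195210, "chr18": 78077248,
    "chr19": 59128983, "chr20": 63025520, "chr21": 48129895,
    "chr22": 51304566, "chrX": 155270560, "chrY": 59373566,
}

HG19_TOTAL: int = sum(HG19_LENGTHS.values())

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome sizes plus a genome-wide binning with per-bin GC content.

    Bins are half-open ``[bin_start, bin_end)`` intervals of at most
    ``bin_size`` bases; the last bin of each chromosome may be a shorter,
    partial bin.
    """

    chroms: tuple[str, ...]
    lengths: np.ndarray          # int64, one entry per chromosome
    bin_size: int
    bin_chrom: np.ndarray        # int16 chromosome index per bin
    bin_start: np.ndarray        # int64
    bin_end: np.ndarray          # int64
    bin_gc: np.ndarray           # float64 in [0, 1]
    _chrom_index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if np.any(self.lengths <= 0):
            raise ValueError("all chromosome lengths must be positive")
        if np.any(self.bin_gc < 0) or np.any(self.bin_gc > 1):
            raise ValueError("bin GC fractions must lie in [0, 1]")
        expected = int(np.ceil(self.lengths / self.bin_size).sum())
        if len(self.bin_gc) != expected:
            raise ValueError(
                f"bin count {len(self.bin_gc)} does not match "
                f"sum(ceil(length/bin_size)) = {expected}"
            )
        object.__setattr__(
            self, "_chrom_index", {c: i for i, c in enumerate(self.chroms)}
        )

    # ------------------------------------------------------------------
    @classmethod
    def from_lengths(
        cls,
        lengths: dict[str, int],
        bin_size: int = 20_000,
        bin_gc: np.ndarray | None = None,
        gc_seed: int = 7,
    ) -> "GenomeModel":
        """Build a genome model from a chromosome-length mapping.

        When ``bin_gc`` is not supplied, a smooth synthetic GC landscape is
        drawn deterministically from ``gc_seed`` (moving-average filtered
        noise around 0.50, clipped to [0.36, 0.64] — bins sit mostly above
        the sampling-bias optimum, as 20-kb human bins mostly do).
        """
        chroms = tuple(lengths)
        lens = np.asarray([lengths[c] for c in chroms], dtype=np.int64)
        nbins = np.ceil(lens / bin_size).astype(np.int64)
        bin_chrom = np.repeat(np.arange(len(chroms), dtype=np.int16), nbins)
        bin_start = np.concatenate(
            [np.arange(n, dtype=np.int64) * bin_size for n in nbins]
        )
        bin_end = np.minimum(bin_start + bin_size, lens[bin_chrom])
        if bin_gc is None:
            bin_gc = _smooth_gc_field(len(bin_chrom), seed=gc_seed)
        bin_gc = np.asarray(bin_gc, dtype=np.float64)
        return cls(
            chroms=chroms, lengths=lens, bin_size=bin_size,
            bin_chrom=bin_chrom, bin_start=bin_start, bin_end=bin_end,
            bin_gc=bin_gc,
        )

    @classmethod
    def scaled_hg19(
        cls, scale: int = 1000, bin_size: int = 20_000, gc_seed: int = 7
    ) -> "GenomeModel":
        """hg19 chromosome lengths divided by ``scale`` (default 1/1000)."""
        lengths = {c: max(1, round(l / scale)) for c, l in HG19_LENGTHS.items()}
        return cls.from_lengths(lengths, bin_size=bin_size, gc_seed=gc_seed)

    # ------------------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return len(self.bin_gc)

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())

    @property
    def bin_span(self) -> np.ndarray:
        """Number of bases covered by each bin (partial bins are shorter)."""
        return self.bin_end - self.bin_start

    @property
    def bin_is_partial(self) -> np.ndarray:
        return self.bin_span < self.bin_size

    @property
    def bin_is_autosomal(self) -> np.ndarray:
        auto = np.array([c in AUTOSOMES for c in self.chroms])
        return auto[self.bin_chrom]

    @property
    def chrom_bin_offsets(self) -> np.ndarray:
        """Index of the first bin of each chromosome in the global arrays."""
        nbins = np.ceil(self.lengths / self.bin_size).astype(np.int64)
        return np.concatenate([[0], np.cumsum(nbins)[:-1]])

    def chrom_index(self, chrom: str) -> int:
        try:
            return self._chrom_index[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def bin_index(self, chrom_codes: np.ndarray, starts: np.ndarray) -> np.ndarray:
        """Global bin index for fragments, assigned by start coordinate."""
        return self.chrom_bin_offsets[chrom_codes] + starts // self.bin_size

    # ------------------------------------------------------------------
    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(chromosome sizes, per-bin GC) as DataFrames for TSV export."""
        sizes = pd.DataFrame({"chrom": self.chroms, "length": self.lengths})
        bins = pd.DataFrame({
            "chrom": np.asarray(self.chroms)[self.bin_chrom],
            "bin_start": self.bin_start,
            "gc": self.bin_gc,
        })
        return sizes, bins

    def save(self, sizes_path, bins_path) -> None:
        sizes, bins = self.to_frames()
        sizes.to_csv(sizes_path, sep="\t", index=False)
        bins.to_csv(bins_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, sizes_path, bins_path, bin_size: int = 20_000) -> "GenomeModel":
        sizes = pd.read_csv(sizes_path, sep="\t")
        bins = pd.read_csv(bins_path, sep="\t")
        lengths = dict(zip(sizes["chrom"], sizes["length"].astype(int)))
        chroms = tuple(lengths)
        order = {c: i for i, c in enumerate(chroms)}
        bins = bins.sort_values(
            ["chrom", "bin_start"],
            key=lambda s: s.map(order) if s.name == "chrom" else s,
            kind="stable",
        )
        return cls.from_lengths(lengths, bin_size=bin_size,
                                bin_gc=bins["gc"].to_numpy())


def _smooth_gc_field(n: int, seed: int, mean: float = 0.50,
                     sd: float = 0.06, window: int = 5) -> np.ndarray:
    """Moving-average filtered Gaussian noise, clipped to [0.36, 0.64]."""
    rng = np.random.default_rng(seed)
    raw = rng.normal(0.0, 1.0, n + window - 1)
    kernel = np.ones(window) / window
    smooth = np.convolve(raw, kernel, mode="valid")
    smooth = smooth / smooth.std() * sd if smooth.std() > 0 else smooth
    return np.clip(mean + smooth, 0.36, 0.64)
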