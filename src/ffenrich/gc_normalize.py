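"""Binned read counting and three-step GC-bias correction.

Unique reads are counted per genome bin (a fragment belongs to the bin
containing its start coordinate).  GC correction then proceeds in three
steps:

1. **Loess regression** — per sample, a loess fit (span 0.75, degree 2) of
   raw bin count against bin GC; each count is rescaled by
   ``median(raw) / fitted``.
2. **Intra-run normalization** — each bin is divided by the median, across
   the samples of the same sequencing run, of that bin's depth-normalized
   step-1 value.  Requires at least ``min_run`` run samples; otherwise the
   step is skipped and flagged.
3. **Linear-model regression** — the step-2 counts are regressed on GC and
   GC^2 across bins and the fitted GC component is subtracted, flooring at
   zero.

Totals are renormalized to the input total after each step.  Bins are masked
(excluded from all fits and downstream ratios) when their GC lies outside
[0.2, 0.8], when the loess fit is non-positive, when the run median is zero,
or when the bin is a partial end-of-chromosome bin (whose smaller span would
otherwise masquerade as depth signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .loess import loess_smooth

GC_BOUNDS = (0.2, 0.8)


def bin_counts(
    records: pd.DataFrame, genome: GenomeModel, sample_id: str | None = None
) -> pd.DataFrame:
    """Count fragments per genome bin (assignment by start coordinate).

    Returns a bin table with columns chrom, bin_start, gc, raw_count and a
    ``masked`` column pre-marking partial and GC-extreme bins.  The table
    carries ``attrs``: sample_id, n_reads and the autosomal bin mask.
    """
    chrom_codes = records["chrom"].cat.codes.to_numpy()
    if (chrom_codes < 0).any():
        raise ValueError("malformed fragment file: unknown chromosome")
    starts = records["start"].to_numpy()
    lengths = records["length"].to_numpy()
    chrom_len = genome.lengths[chrom_codes]
    bad = (starts < 0) | (starts + lengths > chrom_len)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"malformed fragment file: record {row} extends beyond its "
            "chromosome end"
        )
    bins = genome.bin_index(chrom_codes, starts)
    counts = np.bincount(bins, minlength=genome.n_bins)

    table = pd.DataFrame({
        "chrom": pd.Categorical.from_codes(
            genome.bin_chrom.astype(np.int16), categories=list(genome.chroms)
        ),
        "bin_start": genome.bin_start,
        "gc": genome.bin_gc,
        "raw_count": counts,
        "masked": genome.bin_is_partial
        | (genome.bin_gc < GC_BOUNDS[0])
        | (genome.bin_gc > GC_BOUNDS[1]),
    })
    table.attrs["sample_id"] = sample_id
    table.attrs["n_reads"] = int(len(records))
    table.attrs["autosomal"] = genome.bin_is_autosomal
    return table


@dataclass(frozen=True)
class RunMedians:
    """Per-bin intra-run medians of depth-normalized step-1 counts."""

    median: np.ndarray | None    # None when the run was too small
    mask: np.ndarray             # bins unusable anywhere in the run
    n_run: int

    @property
    def applied(self) -> bool:
        return self.median is not None


def _rescale(values: np.ndarray, ok: np.ndarray, target_total: float) -> np.ndarray:
    total = values[ok].sum()
    if total > 0:
        values = values * (target_total / total)
    return values


def _autosomal(table: pd.DataFrame) -> np.ndarray:
    auto = table.attrs.get("autosomal")
    if auto is None:
        auto = np.array([str(c).removeprefix("chr").isdigit()
                         for c in table["chrom"]])
    return auto


def _step1_loess(table: pd.DataFrame, span: float) -> tuple[np.ndarray, np.ndarray]:
    """Loess depth correction; returns (corrected counts, updated mask).

    The GC curve is fit on unmasked autosomal bins only — sex-chromosome
    bins carry copy-number depth signal unrelated to GC — and then
    evaluated at every unmasked bin's GC.
    """
    mask = table["masked"].to_numpy().copy()
    ok = ~mask
    auto = _autosomal(table)
    gc = table["gc"].to_numpy()
    raw = table["raw_count"].to_numpy().astype(float)
    fit_dom = ok & auto
    fitted = np.full(len(raw), np.nan)
    fitted[ok] = loess_smooth(gc[fit_dom], raw[fit_dom], x_eval=gc[ok],
                              span=span, degree=2)
    mask |= ok & ~(fitted > 0)
    ok = ~mask
    med = np.median(raw[ok & auto])
    c1 = raw.copy()
    c1[ok] = raw[ok] * (med / fitted[ok])
    c1 = _rescale(c1, ok, raw[~table["masked"].to_numpy()].sum())
    return c1, mask


def compute_run_medians(
    tables: list[pd.DataFrame], span: float = 0.75, min_run: int = 8
) -> tuple[list[tuple[np.ndarray, np.ndarray]], RunMedians]:
    """Step-1 correct every run sample and form per-bin run medians.

    Returns the per-sample ``(step1 counts, mask)`` pairs and the
    :class:`RunMedians` (with ``median=None`` when the run is smaller than
    ``min_run``).
    """
    if not tables:
        raise ValueError("empty run")
    step1 = [_step1_loess(t, span) for t in tables]
    mask = np.logical_or.reduce([m for _, m in step1])
    if len(tables) < min_run:
        return step1, RunMedians(median=None, mask=mask, n_run=len(tables))
    ok = ~mask
    norm = np.array([c1 / max(c1[ok].mean(), np.finfo(float).tiny)
                     for c1, _ in step1])
    med = np.median(norm, axis=0)
    mask = mask | (ok & (med <= 0))
    return step1, RunMedians(median=med, mask=mask, n_run=len(tables))


def _apply_steps_2_3(
    table: pd.DataFrame, c1: np.ndarray, mask: np.ndarray, medians: RunMedians
) -> pd.DataFrame:
    mask = mask | medians.mask
    ok = ~mask
    total = c1[ok].sum()
    if medians.applied:
        c2 = c1.copy()
        c2[ok] = c1[ok] / medians.median[ok]
        c2 = _rescale(c2, ok, total)
    else:
        c2 = c1
    gc = table["gc"].to_numpy()
    auto = _autosomal(table)
    coef = np.polyfit(gc[ok & auto], c2[ok & auto], 2)
    fitted = np.polyval(coef, gc)
    c3 = c2.copy()
    c3[ok] = np.clip(c2[ok] - (fitted[ok] - c2[ok & auto].mean()), 0.0, None)
    c3 = _rescale(c3, ok, total)
    out = table.copy()
    out["corrected"] = c3
    out["masked"] = mask
    out.attrs.update(table.attrs)
    out.attrs["intrarun_applied"] = medians.applied
    return out


def gc_correct_run(
    tables: list[pd.DataFrame], span: float = 0.75, min_run: int = 8
) -> list[pd.DataFrame]:
    """GC-correct all samples of one sequencing run together."""
    step1, medians = compute_run_medians(tables, span=span, min_run=min_run)
    return [
        _apply_steps_2_3(t, c1, m, medians)
        for t, (c1, m) in zip(tables, step1)
    ]


def gc_correct_against(
    table: pd.DataFrame, medians: RunMedians, span: float = 0.75
) -> pd.DataFrame:
    """GC-correct a sample against precomputed run medians."""
    c1, mask = _step1_loess(table, span)
    return _apply_steps_2_3(table, c1, mask, medians)


def gc_count_correlation(table: pd.DataFrame, column: str = "raw_count") -> float:
    """Pearson correlation of bin counts with GC over unmasked autosomal bins."""
    ok = ~table["masked"].to_numpy() & _autosomal(table)
    return float(np.corrcoef(table[column].to_numpy()[ok],
                             table["gc"].to_numpy()[ok])[0, 1])


def gc_correct(
    table: pd.DataFrame,
    run_tables: list[pd.DataFrame] | None = None,
    span: float = 0.75,
    min_run: int = 8,
) -> pd.DataFrame:
    """GC-correct one sample, optionally against a run of sibling samples.

    ``run_tables`` are the other raw bin tables of the same sequencing run;
    when the run (including this sample) holds fewer than ``min_run`` samples
    the intra-run step is skipped and the output flags that.
    """
    run = [table] + list(run_tables or [])
    return gc_correct_run(run, span=span, min_run=min_run)[0]
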