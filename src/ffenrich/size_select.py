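"""In-silico size selection and the per-length-bin fetal-fraction analysis.

Short-fragment selection (< 160 bp by default) enriches the fetal component
because fetal-origin cfDNA is systematically shorter.  The bin analysis
quantifies that: reads are split into ten 10-bp length bins spanning
[100, 200) bp, the chrY read fraction (a raw proxy for fetal fraction in
male-fetus pregnancies) is computed per bin, and each bin's fraction is
expressed as a fold change against the pooled chrY fraction of all reads.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: The ten half-open length bins of the fold-change analysis.
LENGTH_BINS: tuple[tuple[int, int], ...] = tuple(
    (lo, lo + 10) for lo in range(100, 200, 10)
)


def in_silico_size_select(records: pd.DataFrame, cutoff: int = 160) -> pd.DataFrame:
    """Retain exactly the records with length strictly below ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return records.loc[records["length"].to_numpy() < cutoff]


def _bin_counts_one(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Per-length-bin (total, chrY) counts plus overall (total, chrY)."""
    lengths = records["length"].to_numpy()
    is_y = (records["chrom"] == "chrY").to_numpy()
    edges = np.arange(100, 201, 10)
    idx = np.searchsorted(edges, lengths, side="right") - 1
    in_range = (idx >= 0) & (idx < len(LENGTH_BINS))
    total = np.bincount(idx[in_range], minlength=len(LENGTH_BINS))
    chry = np.bincount(idx[in_range & is_y], minlength=len(LENGTH_BINS)) \
        if (in_range & is_y).any() else np.zeros(len(LENGTH_BINS), dtype=int)
    return total, chry, len(records), int(is_y.sum())


def binwise_ff_foldchange(
    samples,
    group_size: int = 100,
    mode: str = "mixed",
) -> pd.DataFrame:
    """Per-length-bin chrY fraction and fold change versus the pooled fraction.

    ``samples`` is a sequence of fragment tables from male-fetus pregnancies.
    In ``mixed`` mode (the default) consecutive samples are pooled into mixed
    sets of up to ``group_size`` samples, the per-bin chrY fraction is
    computed per mixed set, and fractions are averaged across sets.  In
    ``pooled`` mode counts are summed over the whole cohort first;
    ``per_sample`` is mixed mode with groups of one.

    Reads outside [100, 200) are excluded from the bin table but kept in the
    pooled denominator the fold changes are measured against.  Bins without
    reads get a missing (NaN) fold change, never zero.
    """
    if mode not in ("mixed", "pooled", "per_sample"):
        raise ValueError("mode must be 'mixed', 'pooled' or 'per_sample'")
    if mode == "per_sample":
        group_size, mode = 1, "mixed"
    samples = list(samples)
    if not samples:
        raise ValueError("at least one sample is required")

    per_sample = [_bin_counts_one(s) for s in samples]
    totals = np.array([t for t, _, _, _ in per_sample])
    chrys = np.array([c for _, c, _, _ in per_sample])
    n_all = sum(n for _, _, n, _ in per_sample)
    y_all = sum(y for _, _, _, y in per_sample)
    if y_all == 0:
        raise ValueError("pooled chrY fraction is zero; cannot form fold changes")
    pooled_frac_all = y_all / n_all

    if mode == "pooled":
        tot = totals.sum(axis=0)
        yy = chrys.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, yy / np.where(tot > 0, tot, 1), np.nan)
    else:
        groups = [slice(i, i + group_size) for i in range(0, len(samples), group_size)]
        fracs = []
        for g in groups:
            t = totals[g].sum(axis=0)
            c = chrys[g].sum(axis=0)
            fracs.append(np.where(t > 0, c / np.where(t > 0, t, 1), np.nan))
        fr = np.array(fracs)
        valid = ~np.isnan(fr)
        nvalid = valid.sum(axis=0)
        frac = np.where(
            nvalid > 0,
            np.where(valid, fr, 0.0).sum(axis=0) / np.maximum(nvalid, 1),
            np.nan,
        )
        tot = totals.sum(axis=0)
        yy = chrys.sum(axis=0)

    table = pd.DataFrame({
        "bin_lo": [lo for lo, _ in LENGTH_BINS],
        "bin_hi": [hi for _, hi in LENGTH_BINS],
        "n_reads": tot,
        "n_chry": yy,
        "chry_frac": frac,
        "fold_change": frac / pooled_frac_all,
    })
    table.attrs["pooled_chry_frac"] = pooled_frac_all
    table.attrs["n_total_reads"] = n_all
    return table
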