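"""Post-alignment read filtering to "unique reads".

Removal order is fixed: (1) fragments shorter than ``min_length`` (default
50 bp), (2) non-uniquely mapping fragments, (3) duplicates.  A duplicate is
any record pre-flagged as duplicate, or any repeat of an already-seen
(chrom, start, length) key — single-end data, so strand is not part of the
key.  The counts in the report reconcile exactly with the input size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_short_removed: int
    n_multimap_removed: int
    n_dup_removed: int
    n_unique: int

    def __post_init__(self) -> None:
        removed = self.n_short_removed + self.n_multimap_removed + self.n_dup_removed
        if self.n_unique != self.n_input - removed or min(
            self.n_input, self.n_short_removed, self.n_multimap_removed,
            self.n_dup_removed, self.n_unique,
        ) < 0:
            raise ValueError("inconsistent filter report counts")


def _dedup_keep_first(chrom_codes: np.ndarray, starts: np.ndarray,
                      lengths: np.ndarray) -> np.ndarray:
    """Boolean mask marking the first occurrence of each (chrom,start,length)."""
    # pack into a single int64 key: chrom (8 bits) | start | length (9 bits)
    key = (chrom_codes.astype(np.int64) << 50) | \
          (starts.astype(np.int64) << 9) | lengths.astype(np.int64)
    order = np.argsort(key, kind="stable")
    sorted_key = key[order]
    first_sorted = np.ones(len(key), dtype=bool)
    first_sorted[1:] = sorted_key[1:] != sorted_key[:-1]
    first = np.empty(len(key), dtype=bool)
    first[order] = first_sorted
    return first


def apply_read_filters(
    records: pd.DataFrame, min_length: int = 50
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply length / mapping / duplicate filters; return (records, report)."""
    lengths = records["length"].to_numpy()
    if np.any(lengths < 0):
        raise ValueError("malformed fragment file: negative fragment length")
    n_input = len(records)

    keep_len = lengths >= min_length
    n_short = n_input - int(keep_len.sum())

    is_unique = records["is_unique"].to_numpy()
    keep_map = keep_len & is_unique
    n_multi = int(keep_len.sum()) - int(keep_map.sum())

    sub = records.loc[keep_map]
    not_flagged = ~sub["is_duplicate"].to_numpy()
    # drop pre-flagged records first, then first-occurrence dedup among the
    # rest: the retained count is the number of distinct unflagged keys and
    # is therefore invariant under input permutation
    keep_dup = not_flagged.copy()
    unflagged = sub.loc[not_flagged]
    first = _dedup_keep_first(
        unflagged["chrom"].cat.codes.to_numpy(),
        unflagged["start"].to_numpy(),
        unflagged["length"].to_numpy(),
    )
    keep_dup[not_flagged] = first
    n_dup = len(sub) - int(keep_dup.sum())

    out = sub.loc[keep_dup]
    report = FilterReport(
        n_input=n_input,
        n_short_removed=n_short,
        n_multimap_removed=n_multi,
        n_dup_removed=n_dup,
        n_unique=len(out),
    )
    return out, report
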