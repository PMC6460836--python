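"""Reading and writing the pipeline's on-disk formats.

Fragment tables travel as TSV (gzip-transparent) with columns
``chrom  start  length  dup  uniq`` and, in truth mode, ``origin``.
Aligned reads can also be ingested from SAM/BAM via pysam (duplicate =
FLAG 0x400, unique = MAPQ > 0).  Truth tables are TSV; call results and
fetal-fraction estimates are JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .simulate import SampleTruth

FRAGMENT_DTYPES = {"start": np.int64, "length": np.int64, "dup": np.int8,
                   "uniq": np.int8}


def write_fragments_tsv(records: pd.DataFrame, path, truth_mode: bool = True) -> None:
    out = pd.DataFrame({
        "chrom": records["chrom"].astype(str),
        "start": records["start"],
        "length": records["length"],
        "dup": records["is_duplicate"].astype(np.int8),
        "uniq": records["is_unique"].astype(np.int8),
    })
    if truth_mode and "origin" in records:
        out["origin"] = records["origin"].astype(str)
    out.to_csv(path, sep="\t", index=False)


def read_fragments_tsv(path, genome: GenomeModel | None = None) -> pd.DataFrame:
    """Read a fragment TSV, validating records against the genome if given.

    Malformed rows (negative coordinates/lengths, unknown chromosome,
    fragment beyond the chromosome end) raise ``ValueError`` naming the
    offending line (1-based, excluding the header).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "length", "dup", "uniq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fragment file missing columns: {sorted(missing)}")
    chroms = list(genome.chroms) if genome is not None else \
        list(pd.unique(df["chrom"]))
    chrom = pd.Categorical(df["chrom"], categories=chroms)
    bad = np.flatnonzero(chrom.codes < 0)
    if len(bad):
        raise ValueError(
            f"malformed fragment file {path}: unknown chromosome "
            f"{df['chrom'].iloc[bad[0]]!r} at line {bad[0] + 1}"
        )
    starts = df["start"].to_numpy()
    lengths = df["length"].to_numpy()
    bad = np.flatnonzero((starts < 0) | (lengths < 0))
    if len(bad):
        raise ValueError(
            f"malformed fragment file {path}: negative coordinate at "
            f"line {bad[0] + 1}"
        )
    if genome is not None:
        chrom_len = genome.lengths[chrom.codes]
        bad = np.flatnonzero(starts + lengths > chrom_len)
        if len(bad):
            raise ValueError(
                f"malformed fragment file {path}: fragment beyond chromosome "
                f"end at line {bad[0] + 1}"
            )
    out = pd.DataFrame({
        "chrom": chrom,
        "start": starts.astype(np.int64),
        "length": lengths.astype(np.int64),
        "is_duplicate": df["dup"].astype(bool),
        "is_unique": df["uniq"].astype(bool),
    })
    if "origin" in df.columns:
        out["origin"] = pd.Categorical(df["origin"],
                                       categories=["maternal", "fetal"])
    return out


def read_alignments(path, genome: GenomeModel | None = None) -> pd.DataFrame:
    """Ingest aligned single-end reads from SAM/BAM into a fragment table.

    Maps reference name -> chrom, 0-based start, query/template length,
    FLAG 0x400 -> duplicate, MAPQ > 0 -> unique.  Unmapped reads are skipped.
    """
    import pysam

    chroms, starts, lengths, dups, uniqs = [], [], [], [], []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            chroms.append(read.reference_name)
            starts.append(read.reference_start)
            tlen = abs(read.template_length) or read.query_length \
                or (read.reference_length or 0)
            lengths.append(tlen)
            dups.append(read.is_duplicate)
            uniqs.append(read.mapping_quality > 0)
    categories = list(genome.chroms) if genome is not None else \
        sorted(set(chroms))
    return pd.DataFrame({
        "chrom": pd.Categorical(chroms, categories=categories),
        "start": np.asarray(starts, dtype=np.int64),
        "length": np.asarray(lengths, dtype=np.int64),
        "is_duplicate": np.asarray(dups, dtype=bool),
        "is_unique": np.asarray(uniqs, dtype=bool),
    })


def write_truths_tsv(truths: list[SampleTruth], path) -> None:
    pd.DataFrame([asdict(t) for t in truths]).to_csv(path, sep="\t", index=False)


def read_truths_tsv(path) -> list[SampleTruth]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        trisomy = row.trisomy if isinstance(row.trisomy, str) else None
        sample_id = row.sample_id if isinstance(row.sample_id, str) else None
        out.append(SampleTruth(
            fetal_fraction=float(row.fetal_fraction), fetal_sex=row.fetal_sex,
            trisomy=trisomy, n_fragments=int(row.n_fragments),
            seed=int(row.seed), sample_id=sample_id,
        ))
    return out


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        return asdict(o)

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=default)


def write_bin_table_tsv(table: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "bin_start", "gc", "raw_count", "corrected",
                        "masked") if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False)
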