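"""Readers and writers for the plain-text formats the pipeline consumes.

Pairs tables are tab-delimited with one aligned pair per row; BED intervals
and chrom.sizes follow their usual conventions (0-based, half-open).
SAM/BAM input goes through pysam.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

PAIR_COLUMNS = [
    "read_id",
    "chrom1",
    "pos1",
    "strand1",
    "mapq1",
    "nm1",
    "chrom2",
    "pos2",
    "strand2",
    "mapq2",
    "nm2",
]


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table, preserving order."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed chrom.sizes line: {line!r}")
            sizes[fields[0]] = int(fields[1])
    if not sizes:
        raise ValueError(f"empty chrom.sizes file: {path}")
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3+ into a DataFrame with chrom/start/end (+name/score if present)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed BED line {ln}: {line!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: non-integer coordinates at line {ln}") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}: invalid interval at line {ln}: {start}-{end}")
            row = {"chrom": fields[0], "start": start, "end": end}
            if len(fields) > 3:
                row["name"] = fields[3]
            if len(fields) > 4:
                try:
                    row["score"] = float(fields[4])
                except ValueError:
                    row["score"] = np.nan
            rows.append(row)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
    return df.dropna(axis=1, how="all")


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score") if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_pairs_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited pairs table (header required, superset of PAIR_COLUMNS)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PAIR_COLUMNS if c not in df.columns and c != "read_id"]
    if missing:
        raise ValueError(f"pairs table missing columns: {missing}")
    if "read_id" not in df.columns:
        df.insert(0, "read_id", [f"pair{i}" for i in range(len(df))])
    return df


def write_pairs_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in PAIR_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, sep="\t", index=False)


def read_pairs_sam(path: str | Path) -> pd.DataFrame:
    """Pair primary alignments from a (name-grouped or unsorted) SAM/BAM file.

    The 5' mapped coordinate of each end is reference_start for forward
    alignments and reference_end - 1 for reverse alignments. Reads without a
    mate in the file raise an error.
    """
    import pysam

    pending: dict[str, object] = {}
    rows = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if not aln.is_paired:
                raise ValueError(f"unpaired read in input: {aln.query_name}")
            mate = pending.pop(aln.query_name, None)
            if mate is None:
                pending[aln.query_name] = aln
                continue
            first, second = (mate, aln) if mate.is_read1 else (aln, mate)
            row = {"read_id": aln.query_name}
            for i, a in ((1, first), (2, second)):
                pos5 = a.reference_end - 1 if a.is_reverse else a.reference_start
                row[f"chrom{i}"] = a.reference_name
                row[f"pos{i}"] = int(pos5)
                row[f"strand{i}"] = "-" if a.is_reverse else "+"
                row[f"mapq{i}"] = int(a.mapping_quality)
                try:
                    row[f"nm{i}"] = int(a.get_tag("NM"))
                except KeyError:
                    row[f"nm{i}"] = 0
            rows.append(row)
    if pending:
        name = next(iter(pending))
        raise ValueError(f"read without mate in input: {name}")
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
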