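"""Classification of paired-end alignments into valid / informative classes.

A pair survives filtering when both ends map with high confidence
(mapq >= 30, mismatches <= 2 by default) to a known chromosome outside
blacklisted regions. Surviving ("valid") pairs split into trans-informative
(ends on different chromosomes), cis-informative (same chromosome, more than
600 bp apart — taken to represent captured ligation events) and
valid-noninformative (same chromosome, close together; dominated by
unligated fragments). The 600-bp threshold is diagnosed from the four
end-orientation proportions as a function of mapping distance: unligated
fragments are almost exclusively forward-reverse, whereas true ligation
products show ~25% of each configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .util import merge_intervals, points_in_intervals

LABELS = (
    "discarded",
    "duplicate",
    "valid_noninformative",
    "cis_informative",
    "trans_informative",
)

ORIENTATIONS = ("FF", "FR", "RF", "RR")


@dataclass
class PairStats:
    """Per-label pair counts plus an optional orientation-by-distance table."""

    counts: dict[str, int]
    n_input: int
    orientation: pd.DataFrame | None = field(default=None, repr=False)

    def fraction(self, label: str) -> float:
        return self.counts.get(label, 0) / self.n_input if self.n_input else float("nan")


def _require_columns(pairs: pd.DataFrame) -> None:
    needed = [
        "chrom1", "pos1", "strand1", "mapq1", "nm1",
        "chrom2", "pos2", "strand2", "mapq2", "nm2",
    ]
    missing = [c for c in needed if c not in pairs.columns]
    if missing:
        raise ValueError(f"pairs table missing columns: {missing}")


def _blacklist_lookup(blacklist: pd.DataFrame | None) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    lookup: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if blacklist is None or len(blacklist) == 0:
        return lookup
    for chrom, sub in blacklist.sort_values(["chrom", "start"]).groupby("chrom", sort=False):
        s, e = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        lookup[str(chrom)] = (s, e)
    return lookup


def classify_pairs(
    pairs: pd.DataFrame,
    chrom_sizes: dict[str, int],
    blacklist: pd.DataFrame | None = None,
    min_mapq: int = 30,
    max_mismatch: int = 2,
    informative_distance: int = 600,
) -> tuple[pd.DataFrame, PairStats]:
    """Label each pair as discarded / valid_noninformative / cis_informative / trans_informative.

    Coordinates are 0-based 5' mapped positions; pair distance is
    ``|pos1 - pos2|`` and the informative threshold is strict (a distance of
    exactly ``informative_distance`` is noninformative). Blacklist overlap is
    tested on the single 5' base of each end.

    Returns a copy of the table with a ``label`` column plus summary counts.
    """
    _require_columns(pairs)
    df = pairs.copy()
    for col in ("chrom1", "chrom2"):
        unknown = set(df[col].astype(str)) - set(chrom_sizes)
        if unknown:
            raise ValueError(f"unknown chromosome in pairs: {sorted(unknown)[0]!r}")
    for pcol, ccol in (("pos1", "chrom1"), ("pos2", "chrom2")):
        pos = df[pcol].to_numpy()
        if np.any(pos < 0):
            raise ValueError(f"negative coordinate in column {pcol}")
        lengths = df[ccol].map(chrom_sizes).to_numpy()
        if np.any(pos >= lengths):
            bad = df.loc[pos >= lengths, ccol].iloc[0]
            raise ValueError(f"coordinate beyond chromosome end on {bad!r}")

    keep = (
        (df["mapq1"].to_numpy() >= min_mapq)
        & (df["mapq2"].to_numpy() >= min_mapq)
        & (df["nm1"].to_numpy() <= max_mismatch)
        & (df["nm2"].to_numpy() <= max_mismatch)
    )
    bl = _blacklist_lookup(blacklist)
    if bl:
        hit = np.zeros(len(df), dtype=bool)
        for end in ("1", "2"):
            chroms = df[f"chrom{end}"].to_numpy()
            positions = df[f"pos{end}"].to_numpy()
            for chrom, (s, e) in bl.items():
                sel = chroms == chrom
                if sel.any():
                    hit[sel] |= points_in_intervals(positions[sel], s, e)
        keep &= ~hit

    same_chrom = df["chrom1"].to_numpy() == df["chrom2"].to_numpy()
    distance = np.abs(df["pos1"].to_numpy() - df["pos2"].to_numpy())
    label = np.where(
        ~keep,
        "discarded",
        np.where(
            ~same_chrom,
            "trans_informative",
            np.where(distance > informative_distance, "cis_informative", "valid_noninformative"),
        ),
    )
    df["label"] = label
    return df, pair_stats(df)


def pair_stats(labeled: pd.DataFrame) -> PairStats:
    counts = {lab: 0 for lab in LABELS}
    counts.update(labeled["label"].value_counts().to_dict())
    return PairStats(counts=counts, n_input=len(labeled))


def deduplicate(labeled: pd.DataFrame) -> tuple[pd.DataFrame, PairStats]:
    """Mark PCR duplicates among non-discarded pairs.

    Pairs sharing identical (chrom, pos, strand) on both ends — after sorting
    the two ends by (chrom, pos) — are duplicates; the first occurrence in
    input order is retained and the rest are relabeled ``duplicate``.
    """
    if "label" not in labeled.columns:
        raise ValueError("deduplicate expects a labeled pair table (run classify_pairs first)")
    df = labeled.copy()
    if len(df) == 0:
        return df, pair_stats(df)
    c1 = df["chrom1"].astype(str).to_numpy()
    c2 = df["chrom2"].astype(str).to_numpy()
    p1 = df["pos1"].to_numpy()
    p2 = df["pos2"].to_numpy()
    s1 = df["strand1"].astype(str).to_numpy()
    s2 = df["strand2"].astype(str).to_numpy()
    swap = (c2 < c1) | ((c1 == c2) & (p2 < p1))
    key = pd.DataFrame(
        {
            "a": np.where(swap, c2, c1),
            "b": np.where(swap, p2, p1),
            "c": np.where(swap, s2, s1),
            "d": np.where(swap, c1, c2),
            "e": np.where(swap, p1, p2),
            "f": np.where(swap, s1, s2),
        },
        index=df.index,
    )
    eligible = df["label"].to_numpy() != "discarded"
    dup = key.duplicated(keep="first").to_numpy() & eligible
    df.loc[dup, "label"] = "duplicate"
    return df, pair_stats(df)


def orientation_profile(
    pairs: pd.DataFrame,
    distance_edges,
) -> pd.DataFrame:
    """Fractions of FF/FR/RF/RR end orientations per mapping-distance stratum.

    Ends are ordered by coordinate before reading off strands, so "FR" means
    the lower-coordinate end maps forward and the higher-coordinate end maps
    reverse (the configuration of an unligated fragment). Strata are the
    half-open intervals between consecutive ``distance_edges``. Empty strata
    report NaN fractions, not zero.
    """
    _require_columns(pairs)
    if len(pairs) and (pairs["chrom1"].to_numpy() != pairs["chrom2"].to_numpy()).any():
        raise ValueError("orientation_profile expects same-chromosome pairs only")
    edges = np.asarray(list(distance_edges), dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("distance_edges must be increasing with at least two values")
    p1 = pairs["pos1"].to_numpy()
    p2 = pairs["pos2"].to_numpy()
    s1 = pairs["strand1"].astype(str).to_numpy()
    s2 = pairs["strand2"].astype(str).to_numpy()
    swap = p2 < p1
    left = np.where(swap, s2, s1)
    right = np.where(swap, s1, s2)
    code = {"+": "F", "-": "R"}
    orient = np.array([code[a] + code[b] for a, b in zip(left, right)]) if len(pairs) else np.array([])
    distance = np.abs(p1 - p2)
    stratum = np.digitize(distance, edges) - 1
    inside = (stratum >= 0) & (stratum < edges.size - 1)

    table = []
    for k in range(edges.size - 1):
        sel = inside & (stratum == k)
        n = int(sel.sum())
        row = {"lo": edges[k], "hi": edges[k + 1], "n": n}
        for o in ORIENTATIONS:
            row[o] = (orient[sel] == o).sum() / n if n else np.nan
        table.append(row)
    return pd.DataFrame(table)
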