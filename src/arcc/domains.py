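"""TAD and compartment strength by scaled aggregation of chromatin domains.

Chromatin domains (typed "active" or "H3K27me3") differ in size, so their
on-diagonal squares (TAD signal) and off-diagonal rectangles (compartment
signal) are rescaled to a fixed 19x19 layout before averaging: the domain
itself maps to the central 9x9 square and up to 25 kb of each flanking
region maps to 5 bins per side. Rescaling uses area-weighted averaging,
which conserves the mean of the source signal. TAD strength is the log2
ratio (and percent difference) of the central square over the four flanking
5x10 side rectangles; compartment strength compares the central signal of
same-type versus different-type domain pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .aggregation import DenseMaps
from .matrix import ContactMatrix

DOMAIN_TYPES = ("active", "H3K27me3")

GRID_DOMAIN = 9
GRID_FLANK = 5
GRID_SIDE = GRID_DOMAIN + 2 * GRID_FLANK  # 19


@dataclass
class DomainAggregate:
    """Aggregated scaled grid with center/side statistics.

    ``percent_difference`` is 100*(center - side)/side; ``t_p`` is the
    two-sided one-sample t-test p across per-region log2(center/side) ratios.
    """

    grid: np.ndarray
    n: int
    center_mean: float
    side_mean: float
    per_region: np.ndarray = field(repr=False, default=None)
    t_p: float = np.nan

    @property
    def percent_difference(self) -> float:
        return 100.0 * (self.center_mean - self.side_mean) / self.side_mean

    @property
    def log2_fold_change(self) -> float:
        return float(np.log2(self.center_mean / self.side_mean))


def validate_domains(domains: pd.DataFrame) -> pd.DataFrame:
    for col in ("chrom", "start", "end", "type"):
        if col not in domains.columns:
            raise ValueError("domains need chrom/start/end/type columns")
    bad = set(domains["type"]) - set(DOMAIN_TYPES)
    if bad:
        raise ValueError(f"unknown domain type(s): {sorted(bad)}")
    d = domains.sort_values(["chrom", "start"]).reset_index(drop=True)
    for chrom, sub in d.groupby("chrom", sort=False):
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping domains on {chrom!r}")
    return d


def _resample_operator(src_edges: np.ndarray, dst_edges: np.ndarray) -> np.ndarray:
    """Area-weighted 1D resampling matrix W (n_dst x n_src): each target cell
    averages source cells proportionally to bp overlap. Conserves means of
    constant signals exactly."""
    n_dst = len(dst_edges) - 1
    n_src = len(src_edges) - 1
    W = np.zeros((n_dst, n_src))
    for t in range(n_dst):
        lo, hi = dst_edges[t], dst_edges[t + 1]
        ov = np.minimum(hi, src_edges[1:]) - np.maximum(lo, src_edges[:-1])
        ov = np.clip(ov, 0, None)
        total = ov.sum()
        if total > 0:
            W[t] = ov / total
    return W


def _axis_edges_and_operator(
    cm: ContactMatrix, chrom: str, start: int, end: int, flank_l: int, flank_r: int
):
    """Resampling operator from matrix bins onto the 19-cell scaled axis of a
    region [start-flank_l, end+flank_r); missing flanks give NaN rows."""
    starts = cm.binning.starts(chrom)
    ends = cm.binning.ends(chrom)
    lo_bp = start - flank_l
    hi_bp = end + flank_r
    b0 = int(np.searchsorted(ends, lo_bp, side="right"))
    b1 = int(np.searchsorted(starts, hi_bp, side="left"))
    src_edges = np.concatenate(([starts[b0]], ends[b0:b1]))
    dst_edges = np.concatenate(
        [
            np.linspace(lo_bp, start, GRID_FLANK + 1)[:-1] if flank_l > 0 else [np.nan] * GRID_FLANK,
            np.linspace(start, end, GRID_DOMAIN + 1)[:-1],
            np.linspace(end, hi_bp, GRID_FLANK + 1) if flank_r > 0 else [np.nan] * (GRID_FLANK + 1),
        ]
    )
    if flank_l <= 0:
        dst_edges[:GRID_FLANK] = np.nan
    if flank_r <= 0:
        dst_edges[-GRID_FLANK:] = np.nan
        dst_edges[-(GRID_FLANK + 1)] = end
    W = np.zeros((GRID_SIDE, len(src_edges) - 1))
    valid = np.ones(GRID_SIDE, dtype=bool)
    for t in range(GRID_SIDE):
        lo, hi = dst_edges[t], dst_edges[t + 1]
        if not (np.isfinite(lo) and np.isfinite(hi)):
            valid[t] = False
            continue
        ov = np.clip(np.minimum(hi, src_edges[1:]) - np.maximum(lo, src_edges[:-1]), 0, None)
        tot = ov.sum()
        if tot <= 0:
            valid[t] = False
            continue
        W[t] = ov / tot
    return W, valid, b0, b1


def _block_validity(cm: ContactMatrix, chrom: str, a0: int, a1: int, b0: int, b1: int):
    """Validity mask of a dense block: cells whose distance fell outside the
    decay-normalization range were masked to zero and must not be averaged
    into the scaled grid (notably the diagonal)."""
    if cm.decay_range is None:
        return np.ones((a1 - a0, b1 - b0), dtype=bool)
    m = cm.binning.midpoints(chrom)
    d = np.abs(m[a0:a1, None] - m[None, b0:b1])
    lo, hi = cm.decay_range
    return (d >= lo) & (d <= hi)


def _masked_rescale(Wi: np.ndarray, Wj: np.ndarray, block: np.ndarray, valid: np.ndarray):
    num = Wi @ np.where(valid, block, 0.0) @ Wj.T
    den = Wi @ valid.astype(float) @ Wj.T
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 1e-12, num / den, np.nan)


def _side_blocks(grid: np.ndarray):
    """The four flanking 5x10 rectangles (top/bottom/left/right).

    Each block spans the 9 domain rows/columns plus the one adjacent cell on
    its near-diagonal side, giving the printed 5x10 shape. Extending toward
    the diagonal (rather than across the domain to the opposite flank) keeps
    the blocks free of flank-to-flank cells, whose compartment signal would
    contaminate the side estimate. The layout is symmetric under
    transposition and 180-degree rotation.
    """
    f, d = GRID_FLANK, GRID_DOMAIN
    top = grid[0:f, f - 1 : f + d]
    bottom = grid[f + d : 2 * f + d, f : f + d + 1]
    left = grid[f - 1 : f + d, 0:f]
    right = grid[f : f + d + 1, f + d : 2 * f + d]
    return top, bottom, left, right


def _center_side(grid: np.ndarray) -> tuple[float, float]:
    f, d = GRID_FLANK, GRID_DOMAIN
    center = np.nanmean(grid[f : f + d, f : f + d])
    blocks = [b for b in _side_blocks(grid) if np.isfinite(b).any()]
    if not blocks:
        return float(center), np.nan
    side = np.nanmean([np.nanmean(b) for b in blocks])
    return float(center), float(side)


def _flank_extents(sub: pd.DataFrame, idx: int, dom_type: str, flank: int, chrom_len: int):
    """Flank sizes truncated to the adjacent opposite-type neighbor's extent
    and to chromosome edges; 0 when no opposite-type neighbor is adjacent."""
    row = sub.iloc[idx]
    fl = fr = 0
    if idx > 0:
        prev = sub.iloc[idx - 1]
        if prev["type"] != dom_type and prev["end"] >= row["start"]:
            fl = min(flank, int(prev["end"] - prev["start"]))
    if idx < len(sub) - 1:
        nxt = sub.iloc[idx + 1]
        if nxt["type"] != dom_type and nxt["start"] <= row["end"]:
            fr = min(flank, int(nxt["end"] - nxt["start"]))
    fl = min(fl, int(row["start"]))
    fr = min(fr, chrom_len - int(row["end"]))
    return fl, fr


def aggregate_intra_domain(
    cm: ContactMatrix,
    domains: pd.DataFrame,
    dom_type: str,
    min_size: int = 5_000,
    flank: int = 25_000,
    exclude_chroms: tuple = ("chrX", "X"),
    maps: DenseMaps | None = None,
) -> DomainAggregate:
    """Aggregate on-diagonal domain squares (TAD strength) for one domain type.

    Each domain of at least ``min_size`` bp is extracted with up to ``flank``
    bp of the adjacent opposite-type domains (truncated to the neighbor's
    actual extent), rescaled to the 19x19 layout and averaged. The X
    chromosome is excluded by default (domains are not defined there).
    """
    if not (cm.balanced and cm.decay_normalized):
        raise ValueError("domain aggregation expects a balanced, decay-normalized matrix")
    d = validate_domains(domains)
    maps = maps or DenseMaps(cm)
    grids = []
    per_region = []
    for chrom, sub in d.groupby("chrom", sort=False):
        if str(chrom) in exclude_chroms or str(chrom) not in cm.counts:
            continue
        chrom_len = cm.binning.chrom_sizes[str(chrom)]
        dense = maps.dense(str(chrom))
        sub = sub.reset_index(drop=True)
        for idx in range(len(sub)):
            row = sub.iloc[idx]
            if row["type"] != dom_type or row["end"] - row["start"] < min_size:
                continue
            fl, fr = _flank_extents(sub, idx, dom_type, flank, chrom_len)
            W, valid, b0, b1 = _axis_edges_and_operator(
                cm, str(chrom), int(row["start"]), int(row["end"]), fl, fr
            )
            block = dense[b0:b1, b0:b1]
            cell_ok = _block_validity(cm, str(chrom), b0, b1, b0, b1)
            g = _masked_rescale(W, W, block, cell_ok)
            g[~valid, :] = np.nan
            g[:, ~valid] = np.nan
            grids.append(g)
            c, s = _center_side(g)
            if np.isfinite(c) and np.isfinite(s) and s > 0 and c > 0:
                per_region.append(np.log2(c / s))
    if not grids:
        raise ValueError(f"no qualifying domain of type {dom_type!r}")
    with warnings.catch_warnings():
        # chromosome-edge flanks are legitimately all-NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        grid = np.nanmean(np.stack(grids), axis=0)
    center, side = _center_side(grid)
    per_region = np.asarray(per_region)
    t_p = float(stats.ttest_1samp(per_region, 0.0).pvalue) if len(per_region) > 2 else np.nan
    return DomainAggregate(
        grid=grid, n=len(grids), center_mean=center, side_mean=side,
        per_region=per_region, t_p=t_p,
    )


def aggregate_inter_domain(
    cm: ContactMatrix,
    domains: pd.DataFrame,
    pair_kind: str,
    d_min: float = 50_000.0,
    d_max: float = 2_000_000.0,
    min_size: int = 5_000,
    flank: int = 25_000,
    exclude_chroms: tuple = ("chrX", "X"),
    maps: DenseMaps | None = None,
) -> DomainAggregate:
    """Aggregate off-diagonal rectangles over domain pairs (compartment signal).

    ``pair_kind`` is "same_type" or "cross_type"; qualifying pairs are
    same-chromosome domains with midpoint distance in [d_min, d_max]. The
    compartment strength of a map is the percent difference between the
    central signal of the same-type and cross-type aggregates
    (see ``compartment_strength``).
    """
    if pair_kind not in ("same_type", "cross_type"):
        raise ValueError("pair_kind must be 'same_type' or 'cross_type'")
    if not (cm.balanced and cm.decay_normalized):
        raise ValueError("domain aggregation expects a balanced, decay-normalized matrix")
    d = validate_domains(domains)
    maps = maps or DenseMaps(cm)
    grids = []
    per_region = []
    for chrom, sub in d.groupby("chrom", sort=False):
        if str(chrom) in exclude_chroms or str(chrom) not in cm.counts:
            continue
        chrom_len = cm.binning.chrom_sizes[str(chrom)]
        sub = sub.reset_index(drop=True)
        mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) / 2
        sizes = sub["end"].to_numpy() - sub["start"].to_numpy()
        axes = {}
        dense = None
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                dist = mids[j] - mids[i]
                if dist < d_min or dist > d_max:
                    continue
                same = sub.iloc[i]["type"] == sub.iloc[j]["type"]
                if (pair_kind == "same_type") != same:
                    continue
                if sizes[i] < min_size or sizes[j] < min_size:
                    continue
                if dense is None:
                    dense = maps.dense(str(chrom))
                for k in (i, j):
                    if k not in axes:
                        fl, fr = _flank_extents(sub, k, sub.iloc[k]["type"], flank, chrom_len)
                        axes[k] = _axis_edges_and_operator(
                            cm, str(chrom), int(sub.iloc[k]["start"]), int(sub.iloc[k]["end"]), fl, fr
                        )
                    if axes[k] is None:
                        break
                Wi, vi, a0, a1 = axes[i]
                Wj, vj, b0, b1 = axes[j]
                block = dense[a0:a1, b0:b1]
                cell_ok = _block_validity(cm, str(chrom), a0, a1, b0, b1)
                g = _masked_rescale(Wi, Wj, block, cell_ok)
                g[~vi, :] = np.nan
                g[:, ~vj] = np.nan
                grids.append(g)
                c, s = _center_side(g)
                if np.isfinite(c) and np.isfinite(s) and s > 0 and c > 0:
                    per_region.append(np.log2(c / s))
    if not grids:
        raise ValueError(f"no qualifying {pair_kind} domain pairs in range")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        grid = np.nanmean(np.stack(grids), axis=0)
    center, side = _center_side(grid)
    per_region = np.asarray(per_region)
    t_p = float(stats.ttest_1samp(per_region, 0.0).pvalue) if len(per_region) > 2 else np.nan
    return DomainAggregate(
        grid=grid, n=len(grids), center_mean=center, side_mean=side,
        per_region=per_region, t_p=t_p,
    )


def compartment_strength(same: DomainAggregate, cross: DomainAggregate) -> float:
    """Percent difference of central contact signal, same-type vs cross-type
    domain pairs: 100*(center_same - center_cross)/center_cross."""
    return 100.0 * (same.center_mean - cross.center_mean) / cross.center_mean


@dataclass
class StrainFoldChange:
    fold_change: float
    reciprocal: float
    defined: bool
    note: str = ""


def strain_fold_change(wt_percent_diff: float, mut_percent_diff: float) -> StrainFoldChange:
    """Fold change of domain/compartment strength (percent difference)
    between strains. A mutant strength <= 0 means the structure is lost
    outright; the ratio is then undefined and reported qualitatively."""
    if mut_percent_diff <= 0:
        return StrainFoldChange(
            fold_change=np.nan, reciprocal=np.nan, defined=False,
            note="mutant percent difference <= 0: qualitative loss",
        )
    fc = wt_percent_diff / mut_percent_diff
    return StrainFoldChange(fold_change=float(fc), reciprocal=float(1.0 / fc), defined=True)


def stratify_domains(
    domains: pd.DataFrame,
    signal: np.ndarray,
    top_fraction: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split domains into (high, low) sets by per-domain mark signal.

    The top ``top_fraction`` by signal are "high"; ties at the boundary are
    broken by genomic order so the split is deterministic and exactly
    floor(n * top_fraction) domains are high.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) != len(domains):
        raise ValueError("signal must be defined for every domain")
    if not np.isfinite(signal).all():
        raise ValueError("signal must be finite for every domain")
    d = domains.reset_index(drop=True)
    order = np.lexsort(
        (d["start"].to_numpy(), d["chrom"].to_numpy().astype(str), -signal)
    )
    k = int(len(d) * top_fraction)
    high_idx = np.sort(order[:k])
    low_idx = np.sort(order[k:])
    return d.iloc[high_idx].reset_index(drop=True), d.iloc[low_idx].reset_index(drop=True)
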