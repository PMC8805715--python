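"""Aggregated contact analysis (ACA) over binding-site pairs.

Many weak regulatory interactions are individually undetectable; averaging
the normalized contact map in small windows centered on candidate site
pairs ("pileup" / aggregate peak analysis) reveals them as central
enrichment. The statistic is the log2 fold change of the central cell of
the aggregated window over the mean of the remaining cells. Significance
comes from a permutation null: random site pairs matched to the observed
pairs in distance and in the accessibility of both ends, so that the
assay's accessibility bias cannot masquerade as interaction signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ContactMatrix
from .util import bh_qvalues, intervals_overlap_any, merge_intervals

logger = logging.getLogger(__name__)


@dataclass
class ACAResult:
    """Aggregated window (odd side length) and its central enrichment."""

    grid: np.ndarray
    n: int
    n_skipped: int
    center: float
    background: float

    @property
    def statistic(self) -> float:
        """log2(center / mean of the other cells)."""
        return float(np.log2(self.center / self.background))


@dataclass
class NullTestResult:
    observed: float
    null_stats: np.ndarray = field(repr=False)
    p: float


@dataclass
class DifferentialACAResult:
    intercept: float
    slope: float
    table: pd.DataFrame


def sample_site_contacts(
    sites: pd.DataFrame,
    d_min: float = 20_000.0,
    d_max: float = 1_000_000.0,
    max_contacts: int | None = 50_000,
    seed: int | None = None,
    anchor_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """All same-chromosome site pairs with midpoint distance in [d_min, d_max],
    uniformly subsampled without replacement to ``max_contacts`` if exceeded.

    ``anchor_mask`` restricts to pairs with at least one end among the masked
    sites (the "regulated target" mode). Site position is the interval
    midpoint. Deterministic given ``seed``.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    sites = sites.reset_index(drop=True)
    mid = ((sites["start"].to_numpy() + sites["end"].to_numpy()) // 2).astype(np.int64)
    order = np.lexsort((mid, sites["chrom"].to_numpy().astype(str)))
    rows = []
    for chrom in pd.unique(sites["chrom"].astype(str)):
        idx = order[sites["chrom"].to_numpy().astype(str)[order] == chrom]
        m = mid[idx]
        lo = np.searchsorted(m, m + d_min, side="left")
        hi = np.searchsorted(m, m + d_max, side="right")
        for k, (a, b) in enumerate(zip(lo, hi)):
            if b > a:
                js = idx[a:b]
                rows.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "site_i": idx[k],
                            "site_j": js,
                            "pos1": m[k],
                            "pos2": mid[js],
                        }
                    )
                )
    if not rows:
        raise ValueError("no eligible site pairs in the distance range")
    pairs = pd.concat(rows, ignore_index=True)
    if anchor_mask is not None:
        anchor_mask = np.asarray(anchor_mask, dtype=bool)
        keep = anchor_mask[pairs["site_i"]] | anchor_mask[pairs["site_j"]]
        pairs = pairs[keep].reset_index(drop=True)
        if len(pairs) == 0:
            raise ValueError("no eligible site pairs touch the anchor subset")
    pairs["distance"] = np.abs(pairs["pos2"] - pairs["pos1"])
    if max_contacts is not None and len(pairs) > max_contacts:
        rng = np.random.default_rng(seed)
        take = np.sort(rng.choice(len(pairs), size=max_contacts, replace=False))
        pairs = pairs.iloc[take].reset_index(drop=True)
    return pairs


class DenseMaps:
    """Dense per-chromosome views of a (normalized) contact matrix, with
    summed-area tables for O(1) window sums. Built lazily per chromosome."""

    def __init__(self, cm: ContactMatrix, max_dense_bins: int = 12_000):
        self.cm = cm
        self.max_dense_bins = max_dense_bins
        self._dense: dict[str, np.ndarray] = {}
        self._sat: dict[str, np.ndarray] = {}

    def dense(self, chrom: str) -> np.ndarray:
        if chrom not in self._dense:
            n = len(self.cm.binning.starts(chrom))
            if n > self.max_dense_bins:
                raise MemoryError(
                    f"chromosome {chrom!r} has {n} bins; raise max_dense_bins to densify"
                )
            self._dense[chrom] = np.asarray(self.cm.sym(chrom).todense())
        return self._dense[chrom]

    def sat(self, chrom: str) -> np.ndarray:
        if chrom not in self._sat:
            d = self.dense(chrom)
            s = np.zeros((d.shape[0] + 1, d.shape[1] + 1))
            np.cumsum(np.cumsum(d, axis=0), axis=1, out=s[1:, 1:])
            self._sat[chrom] = s
        return self._sat[chrom]

    def n_bins(self, chrom: str) -> int:
        return len(self.cm.binning.starts(chrom))

    def window_center_rest(
        self, chrom: str, bi: np.ndarray, bj: np.ndarray, h: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Center value and mean of the other cells for (2h+1)^2 windows
        centered at (bi, bj); callers must ensure windows are inside."""
        d = self.dense(chrom)
        s = self.sat(chrom)
        k = 2 * h + 1
        total = (
            s[bi + h + 1, bj + h + 1]
            - s[bi - h, bj + h + 1]
            - s[bi + h + 1, bj - h]
            + s[bi - h, bj - h]
        )
        center = d[bi, bj]
        rest = (total - center) / (k * k - 1)
        return center, rest


def _contact_bins(cm: ContactMatrix, contacts: pd.DataFrame):
    chroms = contacts["chrom"].to_numpy().astype(str)
    bi = np.empty(len(contacts), dtype=np.int64)
    bj = np.empty(len(contacts), dtype=np.int64)
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        bi[sel] = cm.binning.bin_of(chrom, contacts.loc[sel, "pos1"].to_numpy())
        bj[sel] = cm.binning.bin_of(chrom, contacts.loc[sel, "pos2"].to_numpy())
    swap = bj < bi
    bi2 = np.where(swap, bj, bi)
    bj2 = np.where(swap, bi, bj)
    return chroms, bi2, bj2


def aca(
    cm: ContactMatrix,
    contacts: pd.DataFrame,
    half_width: int = 10,
    maps: DenseMaps | None = None,
) -> ACAResult:
    """Aggregate (2*half_width+1)^2 windows of the normalized map centered on
    each contact; contacts whose window leaves the chromosome are skipped and
    counted. The matrix must be balanced and decay-normalized so that the
    background level is ~1 and the statistic reads as fold enrichment."""
    if not (cm.balanced and cm.decay_normalized):
        raise ValueError("aca expects a balanced, decay-normalized matrix")
    if maps is None:
        maps = DenseMaps(cm)
    h = half_width
    k = 2 * h + 1
    chroms, bi, bj = _contact_bins(cm, contacts)
    grid = np.zeros((k, k))
    n_used = 0
    n_skipped = 0
    offs = np.arange(-h, h + 1)
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        n = maps.n_bins(chrom)
        ci, cj = bi[sel], bj[sel]
        ok = (ci >= h) & (cj >= h) & (ci < n - h) & (cj < n - h)
        n_skipped += int((~ok).sum())
        ci, cj = ci[ok], cj[ok]
        if len(ci) == 0:
            continue
        d = maps.dense(chrom)
        for lo in range(0, len(ci), 1024):
            ii = ci[lo : lo + 1024, None] + offs[None, :]
            jj = cj[lo : lo + 1024, None] + offs[None, :]
            grid += d[ii[:, :, None], jj[:, None, :]].sum(axis=0)
        n_used += len(ci)
    if n_used == 0:
        raise ValueError("no contact window fits inside the matrix")
    grid /= n_used
    center = float(grid[h, h])
    background = float((grid.sum() - grid[h, h]) / (k * k - 1))
    return ACAResult(grid=grid, n=n_used, n_skipped=n_skipped, center=center, background=background)


class MatchedNullSampler:
    """Random site-pair generator matched on distance and end accessibility.

    The candidate universe is every same-chromosome site pair within the
    distance range whose window fits in the map. Distance strata are
    log-spaced over [d_min, d_max]; accessibility strata are deciles of the
    universe score (default score: raw cis coverage of the site's bin). For
    a requested (distance stratum, end-accessibility strata) key with no
    candidates, matching is widened to the distance stratum alone, then to
    the nearest nonempty distance stratum (logged).
    """

    def __init__(
        self,
        cm: ContactMatrix,
        universe: pd.DataFrame,
        d_min: float = 20_000.0,
        d_max: float = 1_000_000.0,
        half_width: int = 10,
        n_dist_strata: int = 20,
        n_acc_strata: int = 10,
        maps: DenseMaps | None = None,
    ):
        self.cm = cm
        self.maps = maps or DenseMaps(cm)
        self.h = half_width
        self.d_edges = np.geomspace(d_min, d_max, n_dist_strata + 1)
        universe = universe.reset_index(drop=True)
        if "score" in universe.columns and universe["score"].notna().all():
            acc = universe["score"].to_numpy(dtype=float)
        else:
            if cm.raw_coverage is None:
                raise ValueError("no accessibility scores and matrix lacks raw coverage")
            acc = np.empty(len(universe))
            chroms = universe["chrom"].to_numpy().astype(str)
            mids = (universe["start"].to_numpy() + universe["end"].to_numpy()) // 2
            for chrom in pd.unique(chroms):
                sel = chroms == chrom
                b = cm.binning.bin_of(chrom, mids[sel])
                acc[sel] = cm.raw_coverage[chrom][b]
        self.universe = universe
        self.acc = acc
        qs = np.quantile(acc, np.linspace(0, 1, n_acc_strata + 1)[1:-1])
        self.acc_edges = qs
        self.site_acc_stratum = np.searchsorted(qs, acc, side="right")
        pairs = sample_site_contacts(universe, d_min=d_min, d_max=d_max, max_contacts=None)
        chroms, bi, bj = _contact_bins(cm, pairs)
        inside = np.zeros(len(pairs), dtype=bool)
        for chrom in pd.unique(chroms):
            sel = chroms == chrom
            n = self.maps.n_bins(chrom)
            inside[sel] = (
                (bi[sel] >= self.h)
                & (bj[sel] >= self.h)
                & (bi[sel] < n - self.h)
                & (bj[sel] < n - self.h)
            )
        pairs = pairs[inside].reset_index(drop=True)
        chroms, bi, bj = chroms[inside], bi[inside], bj[inside]
        center = np.empty(len(pairs))
        rest = np.empty(len(pairs))
        for chrom in pd.unique(chroms):
            sel = chroms == chrom
            c, r = self.maps.window_center_rest(chrom, bi[sel], bj[sel], self.h)
            center[sel] = c
            rest[sel] = r
        self.center = center
        self.rest = rest
        self.keys = self._key_of(
            pairs["distance"].to_numpy(),
            self.site_acc_stratum[pairs["site_i"].to_numpy()],
            self.site_acc_stratum[pairs["site_j"].to_numpy()],
        )
        self.groups: dict[tuple, np.ndarray] = {}
        order = np.argsort(self.keys[0] * 10_000 + self.keys[1] * 100 + self.keys[2], kind="stable")
        key_arr = list(zip(*(k[order] for k in self.keys)))
        idx_sorted = np.arange(len(pairs))[order]
        start = 0
        for i in range(1, len(key_arr) + 1):
            if i == len(key_arr) or key_arr[i] != key_arr[start]:
                self.groups[key_arr[start]] = idx_sorted[start:i]
                start = i
        self.dist_groups: dict[int, np.ndarray] = {}
        for ds in np.unique(self.keys[0]):
            self.dist_groups[int(ds)] = np.flatnonzero(self.keys[0] == ds)

    def _key_of(self, dist, acc_i, acc_j):
        ds = np.clip(np.searchsorted(self.d_edges, dist, side="right") - 1, 0, len(self.d_edges) - 2)
        a = np.minimum(acc_i, acc_j)
        b = np.maximum(acc_i, acc_j)
        return ds.astype(np.int64), a.astype(np.int64), b.astype(np.int64)

    def candidates_for(self, key: tuple) -> np.ndarray:
        """Candidate pair indices for one observed key, widening if needed."""
        got = self.groups.get(key)
        if got is not None and len(got):
            return got
        ds = int(key[0])
        got = self.dist_groups.get(ds)
        if got is not None and len(got):
            logger.info("matched null: widened accessibility matching for stratum %s", key)
            return got
        avail = sorted(self.dist_groups)
        if not avail:
            raise ValueError("matched null: no candidate pairs at all")
        nearest = min(avail, key=lambda x: abs(x - ds))
        logger.info("matched null: widened distance stratum %d -> %d", ds, nearest)
        return self.dist_groups[nearest]

    def null_statistics(
        self, observed_keys: tuple, n_sets: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Statistic of ``n_sets`` matched random contact sets, each the same
        size and stratum composition as the observed set."""
        uniq, counts = np.unique(
            np.stack(observed_keys, axis=1), axis=0, return_counts=True
        )
        sum_c = np.zeros(n_sets)
        sum_r = np.zeros(n_sets)
        total = 0
        for key, cnt in zip(uniq, counts):
            cand = self.candidates_for(tuple(int(x) for x in key))
            draw = cand[rng.integers(0, len(cand), size=(int(cnt), n_sets))]
            sum_c += self.center[draw].sum(axis=0)
            sum_r += self.rest[draw].sum(axis=0)
            total += int(cnt)
        return np.log2((sum_c / total) / (sum_r / total))


def matched_null_test(
    cm: ContactMatrix,
    contacts: pd.DataFrame,
    universe: pd.DataFrame,
    n_sets: int = 1000,
    half_width: int = 10,
    d_min: float = 20_000.0,
    d_max: float = 1_000_000.0,
    seed: int | None = None,
    sampler: MatchedNullSampler | None = None,
    observed: ACAResult | None = None,
) -> NullTestResult:
    """Permutation p-value for the ACA statistic of ``contacts`` against
    ``n_sets`` matched random contact sets drawn from ``universe``.

    p = (1 + #{null >= observed}) / (n_sets + 1); across factors, BH-adjust
    the returned p-values (``util.bh_qvalues``).
    """
    rng = np.random.default_rng(seed)
    if sampler is None:
        sampler = MatchedNullSampler(
            cm, universe, d_min=d_min, d_max=d_max, half_width=half_width
        )
    if observed is None:
        observed = aca(cm, contacts, half_width=half_width, maps=sampler.maps)
    # windows that were skipped in the observed set are also absent from keys
    chroms, bi, bj = _contact_bins(cm, contacts)
    inside = np.zeros(len(contacts), dtype=bool)
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        n = sampler.maps.n_bins(chrom)
        inside[sel] = (
            (bi[sel] >= half_width)
            & (bj[sel] >= half_width)
            & (bi[sel] < n - half_width)
            & (bj[sel] < n - half_width)
        )
    kept = contacts[inside]
    acc_lookup_i = _site_acc(sampler, cm, kept, "pos1")
    acc_lookup_j = _site_acc(sampler, cm, kept, "pos2")
    keys = sampler._key_of(kept["distance"].to_numpy(), acc_lookup_i, acc_lookup_j)
    null_stats = sampler.null_statistics(keys, n_sets, rng)
    obs = observed.statistic
    p = (1 + int((null_stats >= obs).sum())) / (n_sets + 1)
    return NullTestResult(observed=obs, null_stats=null_stats, p=p)


def _site_acc(sampler: MatchedNullSampler, cm: ContactMatrix, contacts: pd.DataFrame, col: str):
    """Accessibility stratum of each contact end, via the sampler's edges."""
    chroms = contacts["chrom"].to_numpy().astype(str)
    acc = np.empty(len(contacts))
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        b = cm.binning.bin_of(chrom, contacts.loc[sel, col].to_numpy())
        if cm.raw_coverage is not None:
            acc[sel] = cm.raw_coverage[chrom][b]
        else:
            acc[sel] = 0.0
    return np.searchsorted(sampler.acc_edges, acc, side="right")


def filter_hot(
    peak_sets: dict[str, pd.DataFrame],
    top_fraction: float = 0.20,
    min_peaks: int = 300,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Remove highly occupied target (HOT) intervals from every peak set.

    The merged interval universe over all sets is scored by the number of
    factors calling each interval; the ``top_fraction`` by that rank (ties
    broken by genomic order) are removed from every set. Sets left with
    fewer than ``min_peaks`` peaks are dropped; the report lists per-factor
    peak counts before/after and whether the set was kept.
    """
    if not peak_sets:
        raise ValueError("need at least one peak set")
    allp = pd.concat(
        [df[["chrom", "start", "end"]] for df in peak_sets.values()], ignore_index=True
    ).sort_values(["chrom", "start"])
    merged = []
    for chrom, sub in allp.groupby("chrom", sort=True):
        s, e = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        merged.append(pd.DataFrame({"chrom": str(chrom), "start": s, "end": e}))
    universe = pd.concat(merged, ignore_index=True)
    score = np.zeros(len(universe), dtype=int)
    uni_by_chrom = {
        str(c): (sub.index.to_numpy(), sub["start"].to_numpy(), sub["end"].to_numpy())
        for c, sub in universe.groupby("chrom", sort=False)
    }
    for df in peak_sets.values():
        hit_any = np.zeros(len(universe), dtype=bool)
        for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom", sort=False):
            entry = uni_by_chrom.get(str(chrom))
            if entry is None:
                continue
            uidx, us, ue = entry
            ps, pe = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
            hit = intervals_overlap_any(us, ue, ps, pe)
            hit_any[uidx[hit]] = True
        score += hit_any
    n_remove = int(np.floor(len(universe) * top_fraction + 0.5))
    order = np.lexsort(
        (universe["start"].to_numpy(), universe["chrom"].to_numpy().astype(str), -score)
    )
    hot_idx = order[:n_remove]
    hot = universe.iloc[hot_idx]
    hot_by_chrom = {
        str(c): merge_intervals(
            sub.sort_values("start")["start"].to_numpy(), sub.sort_values("start")["end"].to_numpy()
        )
        for c, sub in hot.groupby("chrom", sort=False)
    }
    filtered: dict[str, pd.DataFrame] = {}
    report_rows = []
    for name, df in peak_sets.items():
        df = df.reset_index(drop=True)
        keep = np.ones(len(df), dtype=bool)
        chroms = df["chrom"].to_numpy().astype(str)
        for chrom in pd.unique(chroms):
            entry = hot_by_chrom.get(chrom)
            if entry is None:
                continue
            s, e = entry
            sel = chroms == chrom
            hit = intervals_overlap_any(
                df.loc[sel, "start"].to_numpy(), df.loc[sel, "end"].to_numpy(), s, e
            )
            keep[np.flatnonzero(sel)[hit]] = False
        kept_df = df[keep].reset_index(drop=True)
        ok = len(kept_df) >= min_peaks
        report_rows.append(
            {"factor": name, "n_before": len(df), "n_after": len(kept_df), "kept": ok}
        )
        if ok:
            filtered[name] = kept_df
    return filtered, pd.DataFrame(report_rows)


def differential_aca(
    wt: pd.Series,
    mut: pd.Series,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> DifferentialACAResult:
    """Differential ACA between genotypes via residuals from a linear fit.

    Overall accessibility differences shift all factors together, so the
    mutant statistics are first regressed on the wild-type statistics
    (mut = a + b*wt across factors); each factor's residual measures its
    specific change. Two-sided p-values come from resampling the residual
    distribution ``n_boot`` times; q-values are BH-adjusted.
    """
    factors = list(wt.index)
    if list(mut.index) != factors:
        mut = mut.reindex(factors)
    if mut.isna().any() or len(factors) < 3:
        raise ValueError("need the same >= 3 factors in both genotypes")
    x = wt.to_numpy(dtype=float)
    y = mut.to_numpy(dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    rng = np.random.default_rng(seed)
    draws = rng.choice(resid, size=n_boot, replace=True)
    p = np.array(
        [(1 + int((np.abs(draws) >= abs(r)).sum())) / (n_boot + 1) for r in resid]
    )
    q = bh_qvalues(p)
    table = pd.DataFrame(
        {
            "factor": factors,
            "wt": x,
            "mut": y,
            "fitted": intercept + slope * x,
            "residual": resid,
            "p": p,
            "q": q,
        }
    )
    return DifferentialACAResult(intercept=float(intercept), slope=float(slope), table=table)
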