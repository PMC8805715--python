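"""Per-chromosome sparse contact matrices and their normalizations.

Counts live in upper-triangular CSR matrices (one per chromosome) over a
GenomeBinning. Balancing uses the Knight-Ruiz algorithm, which finds a
positive diagonal scaling diag(x) A diag(x) with constant row sums.
Distance-dependent background F(d) — the mean per-pair contact frequency at
genomic distance d — is modeled by a smoothing spline in log-log space,
fitted in two passes so that strong specific interactions do not inflate
the background (the Fit-Hi-C convention). Map-level decay normalization is
used for aggregate contact analyses; interaction calling (module
``calling``) works on raw counts with its own expected model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.interpolate import UnivariateSpline
from scipy.stats import pearsonr

from .binning import GenomeBinning
from .util import bh_qvalues, binomial_sf


class ConvergenceError(RuntimeError):
    """Balancing failed to reach the requested tolerance."""

    def __init__(self, message: str, iterations: int, residual: float):
        super().__init__(message)
        self.iterations = iterations
        self.residual = residual


@dataclass
class ContactMatrix:
    """Symmetric cis contact counts over a binning (upper triangle stored).

    ``n_cis`` is the total number of cis pair counts per chromosome (the
    binomial N of the calling model); it refers to the raw counts and is
    carried through balancing/normalization unchanged. ``raw_coverage`` is
    the per-bin row sum of the raw counts (diagonal counted once).
    """

    binning: GenomeBinning
    counts: dict[str, sp.csr_matrix]
    n_cis: dict[str, int]
    weights: dict[str, np.ndarray] | None = None
    raw_coverage: dict[str, np.ndarray] | None = None
    balanced: bool = False
    decay_normalized: bool = False
    decay_range: tuple[float, float] | None = None

    def chroms(self) -> list[str]:
        return list(self.counts)

    def sym(self, chrom: str) -> sp.csr_matrix:
        """Full symmetric matrix for one chromosome."""
        u = self.counts[chrom]
        d = sp.diags(u.diagonal())
        return (u + u.T - d).tocsr()

    def row_sums(self, chrom: str) -> np.ndarray:
        """Per-bin coverage: sum over partners, a diagonal entry counted once."""
        return np.asarray(self.sym(chrom).sum(axis=1)).ravel()

    def get(self, chrom: str, i: int, j: int) -> float:
        i, j = (i, j) if i <= j else (j, i)
        return self.counts[chrom][i, j]

    def total_counts(self, chrom: str) -> float:
        return float(self.counts[chrom].sum())

    def to_triplets(self, chrom: str) -> pd.DataFrame:
        coo = self.counts[chrom].tocoo()
        offset = self.binning.chrom_slice(chrom).start
        return pd.DataFrame(
            {
                "bin_id1": coo.row + offset,
                "bin_id2": coo.col + offset,
                "value": coo.data,
            }
        )


def count_contacts(pairs: pd.DataFrame, binning: GenomeBinning) -> ContactMatrix:
    """Count cis pairs into per-chromosome upper-triangular matrices.

    Each pair increments exactly one cell (i <= j, local indices); pairs with
    both ends in the same bin land on the diagonal. Trans pairs violate the
    cis-only contract and raise.
    """
    if len(pairs) and (pairs["chrom1"].to_numpy() != pairs["chrom2"].to_numpy()).any():
        raise ValueError("count_contacts expects cis pairs only (chrom1 == chrom2)")
    counts: dict[str, sp.csr_matrix] = {}
    n_cis: dict[str, int] = {}
    for chrom in binning.chroms():
        n = len(binning.starts(chrom))
        sub = pairs[pairs["chrom1"] == chrom] if len(pairs) else pairs
        if len(sub):
            bi = binning.bin_of(chrom, sub["pos1"].to_numpy())
            bj = binning.bin_of(chrom, sub["pos2"].to_numpy())
            lo = np.minimum(bi, bj)
            hi = np.maximum(bi, bj)
            m = sp.coo_matrix(
                (np.ones(len(sub)), (lo, hi)), shape=(n, n)
            ).tocsr()
            m.sum_duplicates()
        else:
            m = sp.csr_matrix((n, n))
        counts[chrom] = m
        n_cis[chrom] = int(len(sub))
    extra = set(map(str, pairs["chrom1"].unique())) - set(binning.chroms()) if len(pairs) else set()
    if extra:
        raise ValueError(f"pairs on chromosome absent from binning: {sorted(extra)[0]!r}")
    cm = ContactMatrix(binning=binning, counts=counts, n_cis=n_cis)
    cm.raw_coverage = {c: cm.row_sums(c) for c in cm.chroms()}
    return cm


def _kr_core(A: sp.csr_matrix, tol: float, max_outer: int) -> tuple[np.ndarray, float, int]:
    """Knight-Ruiz balancing of a symmetric nonnegative matrix.

    Inner-outer Newton iteration using only mat-vec products; returns x such
    that diag(x) A diag(x) has unit row sums. Input rows must have positive
    sums.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    rt = tol**2
    delta, Delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    stop_tol = tol * 0.5
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = float(rk @ rk)
    rout = rold = rho_km1
    outer = 0
    while rout > rt and outer < max_outer:
        outer += 1
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        Z = p = None
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = float(rk @ Z)
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            denom = float(p @ w)
            if denom <= 0:
                break
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                neg = ap < 0
                gamma = ((delta - y[neg]) / ap[neg]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                big = ynew > Delta
                gamma = ((Delta - y[big]) / ap[big]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = float(rk @ Z)
            if k > n:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = float(rk @ rk)
        rout = rho_km1
        rat = rout / rold if rold > 0 else 0.0
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o**2 > 0.1:
            eta = max(eta, g * eta_o**2)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, 1e-300))
    return x, float(np.sqrt(rout)), outer


def kr_balance(
    cm: ContactMatrix, tol: float = 1e-8, max_iter: int = 200
) -> ContactMatrix:
    """Knight-Ruiz balance each chromosome; returns a new balanced matrix.

    Bins with no off-diagonal counts are masked out before balancing (their
    weight is NaN and their cells are dropped). Row sums of the balanced
    matrix equal 1 on unmasked bins to within ``tol``.
    """
    new_counts: dict[str, sp.csr_matrix] = {}
    weights: dict[str, np.ndarray] = {}
    for chrom in cm.chroms():
        S = cm.sym(chrom).astype(float)
        n = S.shape[0]
        offdiag = np.asarray(S.sum(axis=1)).ravel() - S.diagonal()
        keep = offdiag > 0
        w = np.full(n, np.nan)
        if keep.sum() == 0:
            if (np.asarray(S.sum(axis=1)).ravel() > 0).any():
                raise ValueError(
                    f"chromosome {chrom!r}: no bin has an off-diagonal contact; cannot balance"
                )
            new_counts[chrom] = sp.csr_matrix((n, n))
            weights[chrom] = w
            continue
        idx = np.flatnonzero(keep)
        Asub = S[idx][:, idx].tocsr()
        x, residual, iters = _kr_core(Asub, tol=tol, max_outer=max_iter)
        check = x * (Asub @ x)
        if np.abs(check - 1.0).max() > max(1e-5, tol * 100):
            raise ConvergenceError(
                f"KR balancing did not converge on {chrom!r} "
                f"(residual {residual:.3e} after {iters} outer iterations)",
                iterations=iters,
                residual=residual,
            )
        w[idx] = x
        u = cm.counts[chrom].tocoo()
        wi = w[u.row]
        wj = w[u.col]
        data = u.data * wi * wj
        ok = np.isfinite(data)
        new_counts[chrom] = sp.coo_matrix(
            (data[ok], (u.row[ok], u.col[ok])), shape=(n, n)
        ).tocsr()
        weights[chrom] = w
    return replace(
        cm,
        counts=new_counts,
        weights=weights,
        balanced=True,
        raw_coverage=cm.raw_coverage or {c: cm.row_sums(c) for c in cm.chroms()},
    )


@dataclass
class DistanceDecayModel:
    """Smoothed mean contact frequency F(d) per chromosome, log-log spline.

    ``frequency`` returns the per-pair contact probability at distance d;
    outside the fitted range it returns NaN. ``table`` keeps the stratum
    diagnostics (distance, pair count, count sum, mean frequency) per pass.
    """

    d_min: float
    d_max: float
    splines: dict[str, object] = field(repr=False, default_factory=dict)
    table: pd.DataFrame | None = field(repr=False, default=None)

    def frequency(self, chrom: str, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        out = np.full(d.shape, np.nan)
        inside = (d >= self.d_min) & (d <= self.d_max)
        if inside.any():
            out[inside] = np.exp(self.splines[chrom](np.log(d[inside])))
        return out


def _pairs_with_distance_at_least(mids: np.ndarray, t: float) -> int:
    """Number of bin pairs (i<j) whose midpoint distance is >= t (t > 0)."""
    j = np.searchsorted(mids, mids + t, side="left")
    return int(np.sum(len(mids) - j))


def _stratum_pair_counts(mids: np.ndarray, edges: np.ndarray) -> np.ndarray:
    cum = np.array([_pairs_with_distance_at_least(mids, t) for t in edges])
    return cum[:-1] - cum[1:]


def _cell_distances(cm: ContactMatrix, chrom: str):
    mids = cm.binning.midpoints(chrom)
    u = cm.counts[chrom].tocoo()
    off = u.row != u.col
    row, col, data = u.row[off], u.col[off], u.data[off]
    return mids, row, col, data, mids[col] - mids[row]


def fit_distance_decay(
    cm: ContactMatrix,
    d_min: float = 1_000.0,
    d_max: float = 1_000_000.0,
    n_strata: int = 80,
    two_pass: bool = True,
    outlier_fdr: float = 0.05,
    min_strata: int = 10,
    visibility=None,
) -> DistanceDecayModel:
    """Fit the distance-decay background F(d) on [d_min, d_max].

    Pass 1 fits a cubic smoothing spline to log mean frequency vs log
    distance over log-spaced distance strata (zero-count bin pairs included
    in the stratum denominators). Bin pairs significant under the pass-1
    model (one-sided binomial, BH at ``outlier_fdr``) are then removed from
    the strata and the spline refitted, so planted or real loops do not
    inflate the background. Same-bin (diagonal) counts never enter the fit.

    When a ``calling.VisibilityModel`` is given, counts are divided by
    v_i * v_j before averaging and removed intervals are excluded entirely,
    so that the fitted F(d) is calibrated for the expectation
    f_ij = v_i * v_j * F(d_ij) used by the interaction caller.
    """
    if not (0 < d_min < d_max):
        raise ValueError("require 0 < d_min < d_max")
    edges = np.geomspace(d_min, d_max, n_strata + 1)
    mids_of_stratum = np.sqrt(edges[:-1] * edges[1:])
    splines: dict[str, object] = {}
    tables = []
    for chrom in cm.chroms():
        N = cm.n_cis[chrom]
        if N == 0:
            raise ValueError(f"chromosome {chrom!r} has no cis contacts")
        mids, row, col, data, d_cell = _cell_distances(cm, chrom)
        vprod = None
        if visibility is not None:
            keep_bins = visibility.retained(chrom)
            v = visibility.v(chrom)
            cell_keep = keep_bins[row] & keep_bins[col]
            row, col, d_cell = row[cell_keep], col[cell_keep], d_cell[cell_keep]
            data = data[cell_keep]
            vprod = v[row] * v[col]
            mids = mids[keep_bins]
        npairs = _stratum_pair_counts(mids, edges).astype(float)
        inside = (d_cell >= d_min) & (d_cell <= d_max)
        stratum = np.clip(np.searchsorted(edges, d_cell[inside], side="right") - 1, 0, n_strata - 1)
        eff = data if vprod is None else data / vprod
        sums = np.bincount(stratum, weights=eff[inside], minlength=n_strata)
        raw_sums = np.bincount(stratum, weights=data[inside], minlength=n_strata)

        def _fit(sums_, npairs_, raw_sums_):
            use = (npairs_ > 0) & (sums_ > 0)
            if use.sum() < min_strata:
                raise ValueError(
                    f"chromosome {chrom!r}: only {int(use.sum())} usable distance strata "
                    f"(need >= {min_strata})"
                )
            x = np.log(mids_of_stratum[use])
            y = np.log(sums_[use] / npairs_[use] / N)
            # Poisson-motivated weights: sd(log mean) ~ 1/sqrt(total raw count)
            w = np.sqrt(raw_sums_[use])
            return UnivariateSpline(x, y, w=w, k=3)

        spl = _fit(sums, npairs, raw_sums)
        tab = pd.DataFrame(
            {
                "chrom": chrom,
                "distance": mids_of_stratum,
                "n_pairs": npairs,
                "count_sum": sums,
                "pass": 1,
            }
        )
        if two_pass:
            freq1 = np.exp(spl(np.log(d_cell[inside])))
            if vprod is not None:
                freq1 = freq1 * vprod[inside]
            pvals = binomial_sf(
                data[inside].astype(np.int64), N, np.clip(freq1, 1e-300, 1 - 1e-12)
            )
            m_tested = int(npairs.sum())
            q = bh_qvalues(pvals, n_tests=m_tested)
            drop = q < outlier_fdr
            sums2 = sums - np.bincount(stratum[drop], weights=eff[inside][drop], minlength=n_strata)
            raw_sums2 = raw_sums - np.bincount(stratum[drop], weights=data[inside][drop], minlength=n_strata)
            npairs2 = npairs - np.bincount(stratum[drop], minlength=n_strata)
            spl = _fit(sums2, npairs2, raw_sums2)
            tab2 = tab.copy()
            tab2["n_pairs"] = npairs2
            tab2["count_sum"] = sums2
            tab2["pass"] = 2
            tables.extend([tab, tab2])
        else:
            tables.append(tab)
        splines[chrom] = spl
    return DistanceDecayModel(
        d_min=float(d_min), d_max=float(d_max), splines=splines, table=pd.concat(tables, ignore_index=True)
    )


def normalize_distance(cm: ContactMatrix, model: DistanceDecayModel) -> ContactMatrix:
    """Divide each cell by its expected value N * F(d); cells outside the
    model range (including the diagonal) are masked to zero and the masked
    range is recorded in ``decay_range``. Stratum means of the result are ~1
    when the model was fitted on this matrix."""
    if not cm.balanced:
        raise ValueError("normalize_distance expects a balanced matrix")
    new_counts = {}
    for chrom in cm.chroms():
        mids = cm.binning.midpoints(chrom)
        u = cm.counts[chrom].tocoo()
        d = np.abs(mids[u.col] - mids[u.row])
        f = model.frequency(chrom, d) * cm.n_cis[chrom]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = u.data / f
        ok = np.isfinite(vals)
        n = u.shape[0]
        new_counts[chrom] = sp.coo_matrix(
            (vals[ok], (u.row[ok], u.col[ok])), shape=(n, n)
        ).tocsr()
    return replace(
        cm, counts=new_counts, decay_normalized=True,
        decay_range=(model.d_min, model.d_max),
    )


def insulation_profile(cm: ContactMatrix, window: int) -> pd.DataFrame:
    """Insulation score per bin: mean contact signal in the window x window
    square crossing the diagonal at the bin's left edge, log2-scaled relative
    to the chromosome mean. Requires a fixed-width binning; bins whose window
    leaves the chromosome are masked (NaN)."""
    rows = []
    for chrom in cm.chroms():
        widths = cm.binning.widths(chrom)
        bw = int(widths[0])
        if len(widths) > 1 and not (widths[:-1] == bw).all():
            raise ValueError("insulation_profile requires fixed-width bins")
        if window % bw != 0:
            raise ValueError("window must be a multiple of the bin width")
        w = window // bw
        if w < 2:
            raise ValueError("window must span at least 2 bins")
        n = len(widths)
        u = cm.counts[chrom].tocoo()
        off = u.col > u.row
        i, j, v = u.row[off], u.col[off], u.data[off]
        # cell (i,j) enters the square at b for b in [max(i+1, j-w+1), min(i+w, j)]
        lo = np.maximum(i + 1, j - w + 1)
        hi = np.minimum(i + w, j)
        ok = lo <= hi
        diff = np.zeros(n + 1)
        np.add.at(diff, lo[ok], v[ok])
        np.add.at(diff, hi[ok] + 1, -v[ok])
        sums = np.cumsum(diff)[:n]
        score = sums / (w * w)
        valid = (np.arange(n) >= w) & (np.arange(n) <= n - w)
        score = np.where(valid, score, np.nan)
        mean = np.nanmean(score)
        with np.errstate(invalid="ignore", divide="ignore"):
            insul = np.log2(score / mean)
        sub = cm.binning.chrom_bins(chrom)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin_id": sub["bin_id"].to_numpy(),
                    "start": sub["start"].to_numpy(),
                    "end": sub["end"].to_numpy(),
                    "score": score,
                    "insulation": insul,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def estimate_correction_exponent(
    cm: ContactMatrix, exponent_grid=None
) -> tuple[float, pd.DataFrame]:
    """Exponent a maximizing the Pearson correlation between the balancing
    correction factors and reciprocal coverage^a.

    A cheap stand-in for matrix balancing: if the correlation peaks at a,
    coverage^(-a) approximates the KR factors. Requires a balanced matrix
    (weights present) and its raw coverage; constant coverage makes the
    correlation undefined and raises."""
    if cm.weights is None or cm.raw_coverage is None:
        raise ValueError("estimate_correction_exponent needs a balanced matrix with raw coverage")
    if exponent_grid is None:
        exponent_grid = np.round(np.arange(0.30, 1.51, 0.01), 2)
    grid = np.asarray(exponent_grid, dtype=float)
    x = np.concatenate([cm.weights[c] for c in cm.chroms()])
    c = np.concatenate([cm.raw_coverage[c] for c in cm.chroms()])
    keep = np.isfinite(x) & (c > 0)
    x, c = x[keep], c[keep]
    if len(x) < 3 or np.ptp(c) == 0:
        raise ValueError("coverage is constant (or too few bins); correlation undefined")
    corrs = np.array([pearsonr(x, c**(-a))[0] for a in grid])
    best = grid[int(np.argmax(corrs))]
    return float(best), pd.DataFrame({"alpha": grid, "correlation": corrs})


def matrix_to_store(cm: ContactMatrix, prefix: str) -> None:
    """Write the sparse triplet TSV + binning BED store."""
    trips = pd.concat([cm.to_triplets(c) for c in cm.chroms()], ignore_index=True)
    trips.to_csv(f"{prefix}.triplets.tsv", sep="\t", index=False)
    cm.binning.to_bed(f"{prefix}.bins.bed")
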