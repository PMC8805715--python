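"""Expression correlation between genes linked by promoter-promoter interactions.

If promoter-promoter contacts reflect shared regulation, linked genes
should be co-expressed across cell types beyond what genomic proximity
alone produces. Pearson correlations of linked pairs are compared to
distance-matched random pairs drawn from the same gene set; pairs are
further stratified by the coefficient of variation (CV = sd/mean across
cell types), separating widely expressed genes (low CV) from genes with
regulated, tissue-biased expression (high CV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def coefficient_of_variation(expr: pd.DataFrame, ddof: int = 1) -> pd.Series:
    """Per-gene CV (sd/mean) across cell types; NaN for genes with mean <= 0."""
    mean = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=ddof)
    cv = sd / mean
    cv[mean <= 0] = np.nan
    return cv


def _pearson_rows(expr: pd.DataFrame, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r between expression profiles of gene pairs."""
    x = expr.loc[g1].to_numpy(dtype=float)
    y = expr.loc[g2].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def linked_pair_correlations(
    links: pd.DataFrame, expr: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Pearson r of expression across cell types for each linked gene pair.

    ``links`` needs gene1/gene2 columns; an optional ``link_id`` column
    groups alternative candidate pairs for one link (bidirectional
    promoters), of which the maximum-r pair is retained. Pairs with a gene
    missing from the matrix or with zero expression variance are dropped and
    counted in the report.
    """
    df = links.copy()
    if "link_id" not in df.columns:
        df["link_id"] = np.arange(len(df))
    present = df["gene1"].isin(expr.index) & df["gene2"].isin(expr.index)
    n_missing = int((~present).sum())
    df = df[present]
    r = _pearson_rows(expr, df["gene1"].to_numpy(), df["gene2"].to_numpy())
    df = df.assign(r=r)
    n_zero_var = int(df["r"].isna().sum())
    df = df.dropna(subset=["r"])
    df = (
        df.sort_values(["link_id", "r"], ascending=[True, False])
        .drop_duplicates("link_id", keep="first")
        .reset_index(drop=True)
    )
    report = {"n_input": len(links), "n_missing_gene": n_missing,
              "n_zero_variance": n_zero_var, "n_retained": len(df)}
    return df[["link_id", "gene1", "gene2", "r"]], report


def stratify_by_cv(
    pairs: pd.DataFrame, expr: pd.DataFrame, low_fraction: float = 0.30
) -> dict[str, pd.DataFrame]:
    """Subsets of linked pairs by expression CV of both genes.

    "both_low": both genes in the bottom ``low_fraction`` of the CV
    distribution over all genes in the matrix (widely expressed);
    "both_high": both in the complementary top fraction (regulated
    expression). The cut is rank-based with ties broken by gene order, so
    exactly floor(n * low_fraction) genes are low even with tied CVs.
    """
    cv = coefficient_of_variation(expr).dropna()
    order = np.lexsort((np.arange(len(cv)), cv.to_numpy()))
    k = int(len(cv) * low_fraction)
    low_genes = set(cv.index[order[:k]])
    high_genes = set(cv.index[order[k:]])
    in_low = pairs["gene1"].isin(low_genes) & pairs["gene2"].isin(low_genes)
    in_high = pairs["gene1"].isin(high_genes) & pairs["gene2"].isin(high_genes)
    return {
        "all": pairs.reset_index(drop=True),
        "both_low": pairs[in_low].reset_index(drop=True),
        "both_high": pairs[in_high].reset_index(drop=True),
    }


@dataclass
class ControlResult:
    control: pd.DataFrame = field(repr=False)
    mean_observed: float
    mean_control: float
    t_statistic: float
    p: float


def matched_random_control(
    pairs: pd.DataFrame,
    expr: pd.DataFrame,
    coords: pd.DataFrame,
    seed: int | None = None,
    n_strata: int = 10,
) -> ControlResult:
    """Distance-matched random gene pairs from the linked gene set.

    ``coords`` maps genes to (chrom, tss); pair distance is between gene 5'
    ends. The control has the same number of pairs as observed, drawn per
    observed distance stratum from all same-chromosome pairs of the linked
    genes; strata with no candidates are merged with their neighbor
    (logged). Difference in mean r is a two-sided Welch t-test.
    """
    coords = coords.set_index("gene") if "gene" in coords.columns else coords
    obs = pairs[pairs["gene1"].isin(coords.index) & pairs["gene2"].isin(coords.index)].copy()
    c1 = coords.loc[obs["gene1"], "chrom"].to_numpy().astype(str)
    c2 = coords.loc[obs["gene2"], "chrom"].to_numpy().astype(str)
    t1 = coords.loc[obs["gene1"], "tss"].to_numpy()
    t2 = coords.loc[obs["gene2"], "tss"].to_numpy()
    cis = c1 == c2
    if (~cis).any():
        logger.info("dropping %d trans gene pairs from distance matching", int((~cis).sum()))
    obs = obs[cis].reset_index(drop=True)
    obs_dist = np.abs(t1 - t2)[cis]
    if len(obs) == 0:
        raise ValueError("no same-chromosome observed pairs with coordinates")
    edges = np.quantile(obs_dist, np.linspace(0, 1, n_strata + 1))
    edges = np.unique(edges)
    obs_stratum = np.clip(np.searchsorted(edges, obs_dist, side="right") - 1, 0, len(edges) - 2)

    genes = pd.unique(pd.concat([obs["gene1"], obs["gene2"]]))
    genes = [g for g in genes if g in expr.index]
    gc = coords.loc[genes]
    cand1, cand2, cand_d = [], [], []
    for chrom, sub in gc.groupby("chrom", sort=False):
        names = sub.index.to_numpy()
        tss = sub["tss"].to_numpy()
        o = np.argsort(tss, kind="stable")
        names, tss = names[o], tss[o]
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                cand1.append(names[i])
                cand2.append(names[j])
                cand_d.append(tss[j] - tss[i])
    cand1 = np.asarray(cand1, dtype=object)
    cand2 = np.asarray(cand2, dtype=object)
    cand_d = np.asarray(cand_d, dtype=float)
    cand_stratum = np.clip(np.searchsorted(edges, cand_d, side="right") - 1, 0, len(edges) - 2)
    rng = np.random.default_rng(seed)
    sel1, sel2 = [], []
    for s in range(len(edges) - 1):
        need = int((obs_stratum == s).sum())
        if need == 0:
            continue
        pool = np.flatnonzero(cand_stratum == s)
        width = 1
        while len(pool) == 0 and width < len(edges):
            lo, hi = max(0, s - width), min(len(edges) - 2, s + width)
            pool = np.flatnonzero((cand_stratum >= lo) & (cand_stratum <= hi))
            width += 1
            logger.info("control matching: widened distance stratum %d", s)
        if len(pool) == 0:
            raise ValueError("no candidate control pairs at any distance")
        take = pool[rng.integers(0, len(pool), size=need)]
        sel1.extend(cand1[take])
        sel2.extend(cand2[take])
    r_ctrl = _pearson_rows(expr, np.asarray(sel1, dtype=object), np.asarray(sel2, dtype=object))
    ctrl = pd.DataFrame({"gene1": sel1, "gene2": sel2, "r": r_ctrl}).dropna(subset=["r"])
    t_stat, p = stats.ttest_ind(obs["r"], ctrl["r"], equal_var=False)
    return ControlResult(
        control=ctrl,
        mean_observed=float(obs["r"].mean()),
        mean_control=float(ctrl["r"].mean()),
        t_statistic=float(t_stat),
        p=float(p),
    )


def mark_genes_by_signal(signal: pd.Series, factor: float = 1.5) -> pd.Series:
    """Flag genes whose average mark signal exceeds ``factor`` times the
    median over genes (strictly greater, so uniform signal marks nothing)."""
    signal = signal.astype(float)
    if not np.isfinite(signal).all():
        raise ValueError("signal must be finite")
    return signal > factor * signal.median()
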