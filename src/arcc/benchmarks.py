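"""Canonical simulation conditions and end-to-end benchmark runs.

Each function simulates a dataset with known planted structure, runs the
relevant pipeline stage(s) and returns the measured quantities next to the
planted values. The configurations here are the package's reference study
conditions; tests and the reproduction script both call into this module so
that the numbers they report come from one place.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import aggregation, binning, calling, domains, matrix, pairs, simulate


def orientation_calibration(seed: int, n_pairs: int = 100_000) -> dict[str, float]:
    """Percent of each end-orientation configuration among simulated ligation
    pairs mapping >600 bp apart (independent uniform strands).

    Pairs are drawn on a 1-Mb chromosome with inter-end distances uniform in
    [601 bp, 100 kb]; each configuration should sit at ~25%.
    """
    cfg = simulate.SimConfig(
        seed=seed,
        chrom_sizes={"chrS1": 1_000_000},
        n_pairs=n_pairs,
        distance_law="uniform",
        uniform_range=(601, 100_000),
        re_density=0.0,
    )
    ann = simulate.simulate_annotation(cfg)
    pr, _ = simulate.simulate_pairs(cfg, ann)
    dist = np.abs(pr["pos1"] - pr["pos2"])
    informative = pr[dist > 600]
    prof = pairs.orientation_profile(informative, [600, 10_000_000])
    return {o: 100.0 * float(prof[o].iloc[0]) for o in pairs.ORIENTATIONS}


def fdr_condition(seed: int) -> simulate.SimConfig:
    """One 5-Mb chromosome, 500-bp bins, 2M cis pairs, d^-1 decay, lognormal
    per-bin visibility bias (sigma 0.5), 200 planted 8-fold interactions."""
    return simulate.SimConfig(
        seed=seed,
        chrom_sizes={"chrS1": 5_000_000},
        bin_width=500,
        n_pairs=2_000_000,
        decay_exponent=1.0,
        re_density=0.0,
        bias_lognorm_sigma=0.5,
        n_loops=200,
        loop_fold=8.0,
        loop_distance_range=(2_000, 100_000),
    )


def run_calling_pipeline(
    cfg: simulate.SimConfig,
    alpha: float = 0.87,
    fdr_level: float = 0.05,
    support_min: int = 5,
    d_min: float = 1_000.0,
    d_max: float = 1_000_000.0,
):
    """Simulate, classify, count at the simulation bin width and call
    interactions; returns (calls, truth, binning)."""
    ann = simulate.simulate_annotation(cfg)
    pr, truth = simulate.simulate_pairs(cfg, ann)
    labeled, _ = pairs.classify_pairs(pr, cfg.chrom_sizes)
    labeled, _ = pairs.deduplicate(labeled)
    cis = labeled[labeled["label"] == "cis_informative"]
    bins = binning.make_fixed_bins(cfg.chrom_sizes, cfg.bin_width)
    cm = matrix.count_contacts(cis, bins)
    vis = calling.compute_visibility(cm, alpha=alpha)
    decay = matrix.fit_distance_decay(cm, d_min=d_min, d_max=d_max, visibility=vis)
    calls = calling.call_interactions(
        cm, vis, decay, d_min=d_min, d_max=d_max,
        fdr_level=fdr_level, support_min=support_min,
    )
    return calls, truth, bins


def fdr_benchmark(seed: int, n_seeds: int = 10) -> dict:
    """Mean false-discovery proportion of the calling pipeline over
    ``n_seeds`` replicate simulations of the FDR condition."""
    fdps = []
    sens = []
    for k in range(n_seeds):
        calls, truth, bins = run_calling_pipeline(fdr_condition(seed + 1000 * k))
        rec = simulate.evaluate_recovery(calls, truth, bins)
        fdps.append(rec["fdp"])
        sens.append(rec["sensitivity"])
    return {
        "mean_fdp": float(np.mean(fdps)),
        "per_seed_fdp": fdps,
        "mean_sensitivity": float(np.mean(sens)),
    }


def decay_recovery(seed: int) -> dict:
    """Recover the planted distance-decay exponent (gamma = 1) from the
    fitted background by log-log regression over 2 kb - 500 kb."""
    cfg = simulate.SimConfig(
        seed=seed,
        chrom_sizes={"chrS1": 5_000_000},
        n_pairs=1_000_000,
        decay_exponent=1.0,
        re_density=0.21,
        bias_lognorm_sigma=0.25,
    )
    ann = simulate.simulate_annotation(cfg)
    pr, truth = simulate.simulate_pairs(cfg, ann)
    labeled, _ = pairs.classify_pairs(pr, cfg.chrom_sizes)
    cis = labeled[labeled["label"] == "cis_informative"]
    bins = binning.make_fixed_bins(cfg.chrom_sizes, cfg.bin_width)
    cm = matrix.count_contacts(cis, bins)
    model = matrix.fit_distance_decay(cm, d_min=1_000, d_max=1_000_000, two_pass=False)
    grid = np.geomspace(2_000, 500_000, 50)
    logf = np.log(model.frequency("chrS1", grid))
    slope = np.polyfit(np.log(grid), logf, 1)[0]
    return {"planted_gamma": cfg.decay_exponent, "fitted_slope": float(slope)}


def _normalized_matrix(cfg: simulate.SimConfig, bin_width: int):
    ann = simulate.simulate_annotation(cfg)
    pr, truth = simulate.simulate_pairs(cfg, ann)
    labeled, _ = pairs.classify_pairs(pr, cfg.chrom_sizes)
    cis = labeled[labeled["label"] == "cis_informative"]
    bins = binning.make_fixed_bins(cfg.chrom_sizes, bin_width)
    cm = matrix.count_contacts(cis, bins)
    cm = matrix.kr_balance(cm)
    dmax = max(cfg.chrom_sizes.values()) * 0.9
    model = matrix.fit_distance_decay(
        cm, d_min=bin_width, d_max=dmax, two_pass=False
    )
    return matrix.normalize_distance(cm, model), ann, truth


def domain_recovery(seed: int) -> dict:
    """Recover planted within-domain enrichment (e = 1.2) and same-type
    compartment preference (r = 1.5) as percent differences at 5-kb bins."""
    cfg = simulate.SimConfig(
        seed=seed,
        chrom_sizes={"chrS1": 5_000_000, "chrS2": 5_000_000},
        n_pairs=2_000_000,
        domain_enrichment=1.2,
        compartment_preference=1.5,
        re_density=0.21,
        bias_lognorm_sigma=0.25,
    )
    norm, ann, truth = _normalized_matrix(cfg, 5_000)
    intra = domains.aggregate_intra_domain(norm, ann.domains, "active")
    intra_k27 = domains.aggregate_intra_domain(norm, ann.domains, "H3K27me3")
    same = domains.aggregate_inter_domain(norm, ann.domains, "same_type")
    cross = domains.aggregate_inter_domain(norm, ann.domains, "cross_type")
    return {
        "planted_enrichment_percent": 100.0 * (cfg.domain_enrichment - 1.0),
        "tad_percent_difference_active": intra.percent_difference,
        "tad_percent_difference_h3k27me3": intra_k27.percent_difference,
        "planted_compartment_percent": 100.0 * (cfg.compartment_preference - 1.0),
        "compartment_percent_difference": domains.compartment_strength(same, cross),
    }


def loop_aca_recovery(seed: int) -> dict:
    """Recover a planted 3-fold loop boost as the ACA central enrichment,
    log2(3), at 1-kb resolution."""
    cfg = simulate.SimConfig(
        seed=seed,
        chrom_sizes={"chrS1": 5_000_000},
        bin_width=1_000,
        n_pairs=3_000_000,
        n_loops=300,
        loop_fold=3.0,
        loop_distance_range=(25_000, 250_000),
        re_density=0.21,
        bias_lognorm_sigma=0.25,
    )
    norm, ann, truth = _normalized_matrix(cfg, 1_000)
    contacts = truth.loops.rename(columns={"chrom": "chrom"})[["chrom", "pos1", "pos2"]].copy()
    contacts["distance"] = np.abs(contacts["pos2"] - contacts["pos1"])
    res = aggregation.aca(norm, contacts, half_width=10)
    return {
        "planted_log2": float(np.log2(cfg.loop_fold)),
        "aca_statistic": res.statistic,
        "n_aggregated": res.n,
    }


def exponent_benchmark(seed: int) -> dict:
    """Pure bin-bias simulation (no distance structure): the correction
    exponent that best approximates the KR factors should be ~1.0."""
    cfg = simulate.SimConfig(
        seed=seed,
        chrom_sizes={"chrS1": 2_000_000},
        n_pairs=1_000_000,
        distance_law="flat",
        re_density=0.0,
        bias_lognorm_sigma=0.5,
    )
    ann = simulate.simulate_annotation(cfg)
    pr, _ = simulate.simulate_pairs(cfg, ann)
    labeled, _ = pairs.classify_pairs(pr, cfg.chrom_sizes)
    cis = labeled[labeled["label"] == "cis_informative"]
    bins = binning.make_fixed_bins(cfg.chrom_sizes, cfg.bin_width)
    cm = matrix.count_contacts(cis, bins)
    cm = matrix.kr_balance(cm)
    alpha, curve = matrix.estimate_correction_exponent(cm)
    return {"alpha": alpha}


def permutation_calibration(
    seed: int, n_factors: int = 200, sites_per_factor: int = 40, n_sets: int = 1000
) -> dict:
    """ACA permutation p-values for null factors (random site subsets of the
    universe) should be uniform; returns the p-values and a KS test."""
    from scipy import stats

    cfg = simulate.SimConfig(
        seed=seed,
        chrom_sizes={"chrS1": 5_000_000},
        bin_width=1_000,
        n_pairs=2_000_000,
        re_density=0.21,
        bias_lognorm_sigma=0.25,
        n_site_sets=1,
        sites_per_set=2_000,
    )
    norm, ann, truth = _normalized_matrix(cfg, 1_000)
    universe = ann.site_sets["factor000"]
    sampler = aggregation.MatchedNullSampler(norm, universe)
    rng = np.random.default_rng(seed + 77)
    pvals = []
    for _ in range(n_factors):
        take = np.sort(rng.choice(len(universe), size=sites_per_factor, replace=False))
        sites = universe.iloc[take].reset_index(drop=True)
        contacts = aggregation.sample_site_contacts(sites, seed=int(rng.integers(2**31)))
        res = aggregation.matched_null_test(
            norm, contacts, universe, n_sets=n_sets,
            seed=int(rng.integers(2**31)), sampler=sampler,
        )
        pvals.append(res.p)
    ks = stats.kstest(pvals, "uniform")
    return {"p_values": pvals, "ks_p": float(ks.pvalue)}
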