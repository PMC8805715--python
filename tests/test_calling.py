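"""Visibility model and binomial interaction calling."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import binom

from arcc import binning, calling, matrix, simulate, util
from arcc.matrix import ContactMatrix


def exact_binom_sf(n_obs: int, N: int, f: float) -> float:
    """P(X >= n_obs) for X ~ Binomial(N, f) by direct tail summation with a
    term recurrence, independent of scipy's survival function.

    The first term's log binomial coefficient is accumulated as a product of
    small ratios (not lgamma differences), so no precision is lost to
    cancellation at large N.
    """
    if n_obs <= 0:
        return 1.0
    log_coeff = sum(math.log((N - n_obs + i) / i) for i in range(1, n_obs + 1))
    log_term = log_coeff + n_obs * math.log(f) + (N - n_obs) * math.log1p(-f)
    term = math.exp(log_term)
    total = term
    k = n_obs
    ratio_f = f / (1.0 - f)
    while k < N and term > total * 1e-18:
        term *= (N - k) / (k + 1) * ratio_f
        total += term
        k += 1
    return min(total, 1.0)


def _matrix_from_dense(dense, n_cis=None):
    n = dense.shape[0]
    b = binning.make_fixed_bins({"c": n * 100}, 100)
    cm = ContactMatrix(
        binning=b, counts={"c": sp.csr_matrix(np.triu(dense))},
        n_cis={"c": n_cis or int(dense.sum())},
    )
    cm.raw_coverage = {"c": cm.row_sums("c")}
    return cm


class TestVisibility:
    def _toy_matrix(self, coverages, rng):
        """Build a matrix whose per-bin coverage roughly follows `coverages`."""
        n = len(coverages)
        dense = np.outer(coverages, coverages).astype(float)
        np.fill_diagonal(dense, 0)
        dense *= 1000 / dense.sum()
        return _matrix_from_dense(dense)

    def test_median_interval_has_unit_visibility(self, rng):
        cov = np.linspace(1, 3, 30)
        cm = self._toy_matrix(cov, rng)
        vis = calling.compute_visibility(cm, alpha=0.87)
        tab = vis.tables["c"]
        kept = tab[~tab["removed"]]
        med = kept["c_offpeak"].median()
        closest = (kept["c_offpeak"] - med).abs().idxmin()
        assert tab.loc[closest, "v"] == pytest.approx(1.0, abs=0.05)

    def test_power_law_scaling_of_visibility(self):
        # interval at 2x the median off-peak coverage: v = 2^0.87
        tab = pd.DataFrame({"c_offpeak": [1.0, 2.0], "removed": [False, False]})
        v = (tab["c_offpeak"] / 1.0) ** 0.87
        assert v.iloc[1] == pytest.approx(2 ** 0.87)
        assert 2 ** 0.87 == pytest.approx(1.8277, abs=1e-4)

    def test_bottom_decile_removed_top_decile_peaked(self, rng):
        cov = np.arange(1, 41).astype(float)
        cm = self._toy_matrix(cov, rng)
        vis = calling.compute_visibility(cm)
        tab = vis.tables["c"]
        assert tab["removed"].sum() >= 4
        assert tab["is_peak"].sum() >= 4
        assert tab.loc[tab["removed"], "v"].isna().all()
        # removed intervals occupy the low-coverage end
        assert tab.loc[tab["removed"], "c_cis"].max() <= tab.loc[~tab["removed"], "c_cis"].min()

    def test_offpeak_excludes_peak_partners(self):
        # bin 0 contacts bins 1 (peak) and 2 (not peak)
        dense = np.zeros((10, 10))
        dense[0, 1] = dense[1, 0] = 50.0
        dense[0, 2] = dense[2, 0] = 5.0
        for i in range(3, 10):
            dense[1, i] = dense[i, 1] = 30.0
        cm = _matrix_from_dense(dense)
        vis = calling.compute_visibility(cm, peak_quantile=0.85, drop_quantile=0.01)
        tab = vis.tables["c"]
        assert tab.loc[1, "is_peak"]
        assert tab.loc[0, "c_offpeak"] == 5.0

    def test_all_removed_errors(self):
        dense = np.zeros((4, 4))
        cm = _matrix_from_dense(dense, n_cis=1)
        with pytest.raises(ValueError):
            calling.compute_visibility(cm)


class TestBinomialOracle:
    def test_pvalues_match_exact_summation(self, rng):
        for _ in range(300):
            N = int(rng.integers(10_000, 5_000_000))
            f = float(10 ** rng.uniform(-8, -4))
            n_obs = int(rng.integers(0, 30))
            expected = exact_binom_sf(n_obs, N, f)
            got = util.binomial_sf(n_obs, N, f)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_one_million_trials_example(self):
        expected = exact_binom_sf(8, 1_000_000, 1e-6)
        got = util.binomial_sf(8, 1_000_000, 1e-6)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_count_has_p_one(self):
        assert util.binomial_sf(0, 1_000, 1e-4) == 1.0

    def test_scipy_fallback_regime_agrees(self):
        # huge expected count: tail summation infeasible, scipy takes over
        p = util.binomial_sf(5, 5_000_000, 0.01)
        assert p == pytest.approx(float(binom.sf(4, 5_000_000, 0.01)))


def _called_simulation(seed=31, **kw):
    cfg = simulate.SimConfig(
        seed=seed, chrom_sizes={"chrS1": 2_000_000}, n_pairs=600_000,
        re_density=0.0, bias_lognorm_sigma=0.4, **kw,
    )
    ann = simulate.simulate_annotation(cfg)
    pr, truth = simulate.simulate_pairs(cfg, ann)
    cis = pr[np.abs(pr["pos1"] - pr["pos2"]) > 600]
    bins = binning.make_fixed_bins(cfg.chrom_sizes, 500)
    cm = matrix.count_contacts(cis, bins)
    vis = calling.compute_visibility(cm)
    decay = matrix.fit_distance_decay(cm, 1_000, 1_000_000, visibility=vis)
    return cm, vis, decay, truth, bins


class TestCallInteractions:
    def test_support_filter_is_strict(self):
        cm, vis, decay, _, _ = _called_simulation()
        calls = calling.call_interactions(cm, vis, decay, support_min=5)
        assert (calls.loc[calls["passed"], "n"] > 5).all()
        # no call with exactly 5 reads may pass, however small its q
        low = calls[(calls["n"] == 5) & (calls["q"] < 0.05)]
        assert not low["passed"].any()

    def test_distance_range_respected(self):
        cm, vis, decay, _, _ = _called_simulation()
        calls = calling.call_interactions(cm, vis, decay, d_min=1_000, d_max=1_000_000)
        assert calls["distance"].between(1_000, 1_000_000).all()

    def test_removed_intervals_never_called(self):
        cm, vis, decay, _, _ = _called_simulation()
        calls = calling.call_interactions(cm, vis, decay)
        removed = set(np.flatnonzero(vis.tables["chrS1"]["removed"].to_numpy()))
        assert not (calls["bin_id1"].isin(removed) | calls["bin_id2"].isin(removed)).any()

    def test_planted_interactions_recovered_and_boost_monotonic(self):
        hits = []
        for fold in (4.0, 16.0):
            cfg_kw = dict(n_loops=40, loop_fold=fold, loop_distance_range=(2_000, 20_000))
            cm, vis, decay, truth, bins = _called_simulation(seed=33, **cfg_kw)
            calls = calling.call_interactions(cm, vis, decay)
            rec = simulate.evaluate_recovery(calls, truth, bins)
            hits.append(rec["sensitivity"])
        assert hits[1] >= hits[0]
        assert hits[1] > 0.5

    def test_zero_n_cis_errors(self):
        b = binning.make_fixed_bins({"c": 10_000}, 500)
        cm = ContactMatrix(binning=b, counts={"c": sp.csr_matrix((20, 20))}, n_cis={"c": 0})
        vis_tab = pd.DataFrame(
            {"c_cis": 0.0, "is_peak": False, "removed": False, "c_offpeak": 1.0, "v": 1.0},
            index=range(20),
        )
        vis = calling.VisibilityModel(alpha=0.87, tables={"c": vis_tab})
        model = matrix.DistanceDecayModel(d_min=1_000, d_max=9_000, splines={"c": lambda x: x})
        with pytest.raises(ValueError):
            calling.call_interactions(cm, vis, model, d_min=1_000, d_max=9_000)

    def test_visibility_invariant_to_interval_permutation(self):
        # visibility factors depend on coverages, not on interval order:
        # reversing the chromosome yields mirrored v values
        dense = np.zeros((12, 12))
        rng = np.random.default_rng(0)
        a = rng.random((12, 12)) + 0.2
        dense = np.triu(a + a.T, 1)
        dense = dense + dense.T
        cm = _matrix_from_dense(dense)
        rev = _matrix_from_dense(dense[::-1, ::-1])
        v1 = calling.compute_visibility(cm).tables["c"]["v"].to_numpy()
        v2 = calling.compute_visibility(rev).tables["c"]["v"].to_numpy()
        np.testing.assert_allclose(v1, v2[::-1])


class TestAnnotateCalls:
    def test_end_type_labels(self):
        calls = pd.DataFrame(
            {
                "chrom1": ["c", "c"], "start1": [0, 500], "end1": [500, 1_000],
                "chrom2": ["c", "c"], "start2": [5_000, 8_000], "end2": [5_500, 8_500],
            }
        )
        ann = {
            "P": pd.DataFrame({"chrom": ["c", "c"], "start": [100, 5_100], "end": [200, 5_200]}),
            "E": pd.DataFrame({"chrom": ["c"], "start": [600], "end": [700]}),
        }
        out = calling.annotate_calls(calls, ann)
        assert list(out["interaction_type"]) == ["P-P", "E-other"]

    def test_overlap_counts_match_bruteforce(self, rng):
        m = 60
        starts1 = rng.integers(0, 50_000, m)
        calls = pd.DataFrame(
            {
                "chrom1": "c", "start1": starts1, "end1": starts1 + 400,
                "chrom2": "c", "start2": starts1 + 10_000, "end2": starts1 + 10_400,
            }
        )
        ps = np.sort(rng.choice(np.arange(0, 70_000, 700), 40, replace=False))
        ann = {"P": pd.DataFrame({"chrom": "c", "start": ps, "end": ps + 300})}
        out = calling.annotate_calls(calls, ann)

        def brute(qs, qe):
            return any(s < qe and qs < e for s, e in zip(ps, ps + 300))

        for _, row in out.iterrows():
            assert (row["type1"] == "P") == brute(row["start1"], row["end1"])
            assert (row["type2"] == "P") == brute(row["start2"], row["end2"])
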