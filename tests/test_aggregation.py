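"""Aggregate contact analysis, matched nulls, HOT filtering, differential ACA."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from arcc import aggregation, binning
from arcc.matrix import ContactMatrix


def sites_df(positions, chrom="c", width=100, score=None):
    df = pd.DataFrame(
        {"chrom": chrom, "start": [p - width // 2 for p in positions],
         "end": [p + width // 2 for p in positions]}
    )
    if score is not None:
        df["score"] = score
    return df


class TestSampleSiteContacts:
    def test_three_sites_give_three_pairs(self):
        sites = sites_df([100_000, 150_000, 200_000])
        out = aggregation.sample_site_contacts(sites, d_min=20_000, d_max=1_000_000)
        assert len(out) == 3

    def test_cap_subsamples_exactly(self):
        sites = sites_df(list(range(50_000, 50_000 + 400 * 2_000, 2_000)))
        out = aggregation.sample_site_contacts(sites, max_contacts=5_000, seed=1)
        assert len(out) == 5_000

    def test_close_pairs_excluded(self):
        sites = sites_df([100_000, 110_000])  # 10 kb apart
        with pytest.raises(ValueError):
            aggregation.sample_site_contacts(sites, d_min=20_000, d_max=1_000_000)

    def test_deterministic_given_seed(self):
        sites = sites_df(list(range(50_000, 450_000, 1_000)))
        a = aggregation.sample_site_contacts(sites, max_contacts=500, seed=9)
        b = aggregation.sample_site_contacts(sites, max_contacts=500, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_anchor_mask_requires_one_end(self):
        sites = sites_df([100_000, 150_000, 200_000, 260_000])
        mask = np.array([True, False, False, False])
        out = aggregation.sample_site_contacts(sites, anchor_mask=mask)
        assert ((out["site_i"] == 0) | (out["site_j"] == 0)).all()


def normalized_from_dense(dense, bin_width=1_000):
    n = dense.shape[0]
    b = binning.make_fixed_bins({"c": n * bin_width}, bin_width)
    cm = ContactMatrix(
        binning=b, counts={"c": sp.csr_matrix(np.triu(dense))}, n_cis={"c": int(dense.sum())},
        balanced=True, decay_normalized=True,
    )
    cm.raw_coverage = {"c": cm.row_sums("c")}
    return cm


class TestACA:
    def test_uniform_matrix_gives_zero_statistic(self):
        cm = normalized_from_dense(np.ones((120, 120)))
        contacts = pd.DataFrame(
            {"chrom": "c", "pos1": [30_500, 40_500], "pos2": [80_500, 90_500]}
        )
        res = aggregation.aca(cm, contacts, half_width=10)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_planted_threefold_enrichment_recovered(self):
        dense = np.ones((150, 150))
        centers = [(20, 90), (35, 100), (50, 130), (60, 110)]
        for i, j in centers:
            dense[i, j] = dense[j, i] = 3.0
        cm = normalized_from_dense(dense)
        contacts = pd.DataFrame(
            {
                "chrom": "c",
                "pos1": [i * 1_000 + 500 for i, _ in centers],
                "pos2": [j * 1_000 + 500 for _, j in centers],
            }
        )
        res = aggregation.aca(cm, contacts, half_width=10)
        assert res.statistic == pytest.approx(np.log2(3.0), abs=1e-9)
        assert res.n == len(centers)

    def test_statistic_invariant_to_global_scaling(self):
        rng = np.random.default_rng(3)
        dense = rng.random((120, 120)) + 0.5
        dense = dense + dense.T
        contacts = pd.DataFrame({"chrom": "c", "pos1": [30_500], "pos2": [80_500]})
        r1 = aggregation.aca(normalized_from_dense(dense), contacts)
        r2 = aggregation.aca(normalized_from_dense(dense * 7.3), contacts)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_windows_leaving_matrix_are_skipped(self):
        cm = normalized_from_dense(np.ones((50, 50)))
        contacts = pd.DataFrame(
            {"chrom": "c", "pos1": [500, 15_500], "pos2": [48_500, 35_500]}
        )
        res = aggregation.aca(cm, contacts, half_width=10)
        assert res.n == 1 and res.n_skipped == 1

    def test_all_skipped_errors(self):
        cm = normalized_from_dense(np.ones((30, 30)))
        contacts = pd.DataFrame({"chrom": "c", "pos1": [500], "pos2": [29_500]})
        with pytest.raises(ValueError):
            aggregation.aca(cm, contacts, half_width=10)


class TestMatchedNull:
    def _setup(self, rng, enrich_pairs=None):
        n = 600
        dense = rng.lognormal(0, 0.3, size=(n, n))
        dense = (dense + dense.T) / 2
        if enrich_pairs is not None:
            for i, j in enrich_pairs:
                dense[i, j] = dense[j, i] = dense[i, j] * 4.0
        cm = normalized_from_dense(dense)
        universe = sites_df(
            [p * 1_000 + 500 for p in range(20, 580, 2)],
            score=rng.random(280),
        )
        return cm, universe

    def test_null_contacts_give_mid_p(self, rng):
        cm, universe = self._setup(rng)
        take = rng.choice(len(universe), 30, replace=False)
        contacts = aggregation.sample_site_contacts(
            universe.iloc[np.sort(take)].reset_index(drop=True),
            d_min=20_000, d_max=500_000,
        )
        res = aggregation.matched_null_test(
            cm, contacts, universe, n_sets=200, seed=5,
            d_min=20_000, d_max=500_000,
        )
        assert 0.02 < res.p < 0.98

    def test_planted_enrichment_hits_p_floor(self, rng):
        idx = [(50, 150), (80, 260), (120, 300), (200, 390), (260, 480), (300, 500)]
        cm, universe = self._setup(rng, enrich_pairs=idx)
        contacts = pd.DataFrame(
            {
                "chrom": "c",
                "pos1": [i * 1_000 + 500 for i, _ in idx],
                "pos2": [j * 1_000 + 500 for _, j in idx],
            }
        )
        contacts["distance"] = contacts["pos2"] - contacts["pos1"]
        n_sets = 200
        res = aggregation.matched_null_test(
            cm, contacts, universe, n_sets=n_sets, seed=5,
            d_min=20_000, d_max=500_000,
        )
        assert res.p == pytest.approx(1 / (n_sets + 1))

    def test_null_draws_preserve_distance_strata(self, rng):
        cm, universe = self._setup(rng)
        sampler = aggregation.MatchedNullSampler(
            cm, universe, d_min=20_000, d_max=500_000
        )
        for key, idx in list(sampler.groups.items())[:25]:
            ds = sampler.keys[0][idx]
            assert (ds == key[0]).all()


class TestFilterHot:
    def _sets(self, n_factors=20, n_intervals=50):
        # interval k is called by factors 0..min(k, n_factors)-1, so high-k
        # intervals are the promiscuous ("HOT") ones
        sets = {}
        for fct in range(n_factors):
            rows = [
                ("c", 1_000 * k, 1_000 * k + 500)
                for k in range(n_intervals)
                if min(k * n_factors // n_intervals, n_factors - 1) >= fct
            ]
            sets[f"f{fct}"] = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return sets

    def test_top_fraction_removed_everywhere(self):
        sets = self._sets()
        filtered, report = aggregation.filter_hot(sets, top_fraction=0.2, min_peaks=1)
        # the 10 highest-occupancy intervals (k >= 40) are gone from every set
        for df in filtered.values():
            assert (df["start"] < 40_000).all()

    def test_sets_below_min_peaks_dropped(self):
        sets = self._sets()
        filtered, report = aggregation.filter_hot(sets, top_fraction=0.2, min_peaks=30)
        dropped = report[~report["kept"]]
        assert len(dropped) > 0
        assert set(filtered) == set(report.loc[report["kept"], "factor"])

    def test_all_tied_removes_exact_fraction_deterministically(self):
        df = pd.DataFrame(
            [("c", 1_000 * k, 1_000 * k + 500) for k in range(10)],
            columns=["chrom", "start", "end"],
        )
        filtered, _ = aggregation.filter_hot({"f": df}, top_fraction=0.2, min_peaks=1)
        out = filtered["f"]
        assert len(out) == 8
        # ties broken by genomic order: the first two intervals are removed
        assert out["start"].min() == 2_000


class TestDifferentialACA:
    def test_identity_relation_gives_no_significance(self):
        wt = pd.Series({f"f{i}": v for i, v in enumerate(np.linspace(0.1, 2.0, 12))})
        res = aggregation.differential_aca(wt, wt.copy(), n_boot=2_000, seed=0)
        assert np.allclose(res.table["residual"], 0.0)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_single_reduced_factor_has_most_negative_residual(self, rng):
        wt = pd.Series({f"f{i}": v for i, v in enumerate(np.linspace(0.2, 2.0, 15))})
        mut = wt + rng.normal(0, 0.02, len(wt))
        mut["f3"] = wt["f3"] - 1.0
        res = aggregation.differential_aca(wt, mut, n_boot=2_000, seed=0)
        tab = res.table.set_index("factor")
        assert tab["residual"].idxmin() == "f3"
        assert tab.loc["f3", "p"] < 0.2

    def test_regression_recovery_with_noise(self, rng):
        wt = pd.Series({f"f{i}": v for i, v in enumerate(np.linspace(0.0, 2.0, 40))})
        mut = 0.3 + 1.2 * wt + rng.normal(0, 0.05, len(wt))
        res = aggregation.differential_aca(wt, pd.Series(mut, index=wt.index), n_boot=500, seed=0)
        assert res.intercept == pytest.approx(0.3, abs=0.08)
        assert res.slope == pytest.approx(1.2, abs=0.08)

    def test_too_few_factors_errors(self):
        wt = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError):
            aggregation.differential_aca(wt, wt, n_boot=10, seed=0)
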