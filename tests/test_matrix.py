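"""Contact matrices: counting, KR balancing, decay models, insulation."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from arcc import binning, matrix, simulate
from arcc.matrix import ContactMatrix

from conftest import make_pair, pairs_frame


def cis_pairs(rows):
    return pairs_frame(rows)


@pytest.fixture
def small_binning():
    return binning.make_fixed_bins({"c": 10_000}, 500)


class TestCountContacts:
    def test_counts_and_symmetric_query(self, small_binning):
        rows = [make_pair("c", 2_100, "c", 4_600) for _ in range(3)]
        cm = matrix.count_contacts(cis_pairs(rows), small_binning)
        assert cm.get("c", 4, 9) == 3
        assert cm.get("c", 9, 4) == 3
        assert cm.n_cis["c"] == 3

    def test_same_bin_pair_hits_diagonal(self, small_binning):
        cm = matrix.count_contacts(
            cis_pairs([make_pair("c", 3_500, "c", 3_900)]), small_binning
        )
        assert cm.get("c", 7, 7) == 1

    def test_trans_pair_rejected(self, small_binning):
        with pytest.raises(ValueError):
            matrix.count_contacts(
                cis_pairs([make_pair("c", 100, "d", 100)]), small_binning
            )

    def test_conserves_pair_count(self, small_binning, rng):
        rows = [
            make_pair("c", int(rng.integers(0, 10_000)), "c", int(rng.integers(0, 10_000)))
            for _ in range(200)
        ]
        cm = matrix.count_contacts(cis_pairs(rows), small_binning)
        assert cm.total_counts("c") == 200


def _matrix_from_dense(dense: np.ndarray, n_cis: int | None = None) -> ContactMatrix:
    n = dense.shape[0]
    b = binning.make_fixed_bins({"c": n * 100}, 100)
    upper = sp.csr_matrix(np.triu(dense))
    cm = ContactMatrix(binning=b, counts={"c": upper}, n_cis={"c": n_cis or int(dense.sum() // 2)})
    cm.raw_coverage = {"c": cm.row_sums("c")}
    return cm


def sinkhorn_weights(A: np.ndarray, iters: int = 20_000) -> np.ndarray:
    """Iterative proportional fitting oracle for symmetric balancing."""
    x = np.ones(A.shape[0])
    for _ in range(iters):
        x = x / (A @ x * x) ** 0.5
    return x


class TestKRBalance:
    def test_two_by_two_analytic(self):
        cm = _matrix_from_dense(np.array([[0.0, 2.0], [2.0, 0.0]]))
        out = matrix.kr_balance(cm)
        np.testing.assert_allclose(out.weights["c"], [1 / np.sqrt(2)] * 2, rtol=1e-6)
        s = out.sym("c").toarray()
        np.testing.assert_allclose(s.sum(axis=1), 1.0, rtol=1e-6)

    def test_matches_ipf_oracle(self, rng):
        n = 50
        A = rng.random((n, n)) + 0.05
        A = A + A.T
        cm = _matrix_from_dense(A)
        out = matrix.kr_balance(cm, tol=1e-10)
        oracle = sinkhorn_weights(A)
        np.testing.assert_allclose(out.weights["c"], oracle, rtol=1e-6)

    def test_row_sum_cv_small_and_idempotent(self, rng):
        n = 120
        A = rng.random((n, n)) + 0.01
        A = A + A.T
        out = matrix.kr_balance(_matrix_from_dense(A), tol=1e-10)
        rows = np.asarray(out.sym("c").sum(axis=1)).ravel()
        assert rows.std() / rows.mean() < 1e-6
        again = matrix.kr_balance(out, tol=1e-10)
        np.testing.assert_allclose(again.weights["c"], 1.0, atol=1e-5)

    def test_all_zero_rows_masked(self):
        A = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0.0]])
        out = matrix.kr_balance(_matrix_from_dense(A))
        assert np.isnan(out.weights["c"][2])
        assert np.isfinite(out.weights["c"][:2]).all()


def _simulated_matrix(seed=11, **overrides):
    cfg = simulate.SimConfig(
        seed=seed, chrom_sizes={"chrS1": 2_000_000}, n_pairs=400_000,
        re_density=0.0, **overrides,
    )
    ann = simulate.simulate_annotation(cfg)
    pr, truth = simulate.simulate_pairs(cfg, ann)
    cis = pr[np.abs(pr["pos1"] - pr["pos2"]) > 600]
    bins = binning.make_fixed_bins(cfg.chrom_sizes, cfg.bin_width)
    return matrix.count_contacts(cis, bins), truth


class TestDistanceDecay:
    def test_planted_powerlaw_slope_recovered(self):
        cm, _ = _simulated_matrix(decay_exponent=1.0)
        model = matrix.fit_distance_decay(cm, 1_000, 1_000_000, two_pass=False)
        grid = np.geomspace(2_000, 500_000, 40)
        slope = np.polyfit(np.log(grid), np.log(model.frequency("chrS1", grid)), 1)[0]
        assert abs(slope + 1.0) < 0.1

    def test_flat_law_gives_flat_background(self):
        cm, _ = _simulated_matrix(distance_law="flat")
        model = matrix.fit_distance_decay(cm, 1_000, 1_000_000, two_pass=False)
        grid = np.geomspace(2_000, 500_000, 40)
        slope = np.polyfit(np.log(grid), np.log(model.frequency("chrS1", grid)), 1)[0]
        assert abs(slope) < 0.1

    def test_two_pass_sits_below_pass1_at_loop_distances(self):
        cm, truth = _simulated_matrix(
            seed=12, n_loops=60, loop_fold=40.0, loop_distance_range=(20_000, 60_000)
        )
        one = matrix.fit_distance_decay(cm, 1_000, 1_000_000, two_pass=False)
        two = matrix.fit_distance_decay(cm, 1_000, 1_000_000, two_pass=True)
        d = np.geomspace(21_000, 59_000, 10)
        assert (two.frequency("chrS1", d) <= one.frequency("chrS1", d)).all()

    def test_outside_range_is_nan(self):
        cm, _ = _simulated_matrix()
        model = matrix.fit_distance_decay(cm, 1_000, 1_000_000, two_pass=False)
        assert np.isnan(model.frequency("chrS1", [500.0])[0])
        assert np.isnan(model.frequency("chrS1", [2_000_000.0])[0])

    def test_too_few_strata_errors(self, small_binning):
        cm = matrix.count_contacts(
            cis_pairs([make_pair("c", 100, "c", 5_000)]), small_binning
        )
        with pytest.raises(ValueError, match="strata"):
            matrix.fit_distance_decay(cm, 1_000, 9_000)


class TestNormalizeDistance:
    def test_stratum_means_near_one(self):
        cm, _ = _simulated_matrix()
        bal = matrix.kr_balance(cm)
        model = matrix.fit_distance_decay(bal, 1_000, 1_500_000, two_pass=False)
        norm = matrix.normalize_distance(bal, model)
        mids = norm.binning.midpoints("chrS1")
        u = norm.counts["chrS1"].tocoo()
        d = np.abs(mids[u.col] - mids[u.row])
        for lo, hi in [(2e3, 1e4), (1e4, 1e5), (1e5, 1e6)]:
            npairs = matrix._pairs_with_distance_at_least(mids, lo) - \
                matrix._pairs_with_distance_at_least(mids, hi)
            mean = u.data[(d >= lo) & (d < hi)].sum() / npairs
            assert abs(mean - 1.0) < 0.1

    def test_out_of_range_cells_masked(self):
        cm, _ = _simulated_matrix()
        bal = matrix.kr_balance(cm)
        model = matrix.fit_distance_decay(bal, 1_000, 1_000_000, two_pass=False)
        norm = matrix.normalize_distance(bal, model)
        assert norm.decay_range == (1_000, 1_000_000)
        assert np.allclose(norm.counts["chrS1"].diagonal(), 0.0)

    def test_requires_balanced(self):
        cm, _ = _simulated_matrix()
        model = matrix.fit_distance_decay(cm, 1_000, 1_000_000, two_pass=False)
        with pytest.raises(ValueError):
            matrix.normalize_distance(cm, model)


def brute_insulation(dense: np.ndarray, w: int) -> np.ndarray:
    n = dense.shape[0]
    score = np.full(n, np.nan)
    for b in range(w, n - w + 1):
        score[b] = dense[b - w : b, b : b + w].mean()
    return score


class TestInsulation:
    def test_uniform_matrix_gives_flat_profile(self):
        dense = np.ones((40, 40))
        cm = _matrix_from_dense(dense)
        prof = matrix.insulation_profile(cm, 500)  # 5-bin window at 100-bp bins
        vals = prof["insulation"].dropna()
        np.testing.assert_allclose(vals, 0.0, atol=1e-12)

    def test_matches_brute_force(self, rng):
        n = 60
        dense = rng.random((n, n))
        dense = dense + dense.T
        cm = _matrix_from_dense(dense)
        w = 6
        prof = matrix.insulation_profile(cm, w * 100)
        expected = brute_insulation(dense, w)
        got = prof["score"].to_numpy()
        mask = np.isfinite(expected) & np.isfinite(got)
        assert mask.sum() > 30
        np.testing.assert_allclose(got[mask], expected[mask], rtol=1e-9)

    def test_two_block_matrix_minimum_at_boundary(self):
        n = 40
        dense = np.ones((n, n)) * 0.05
        dense[:20, :20] = 1.0
        dense[20:, 20:] = 1.0
        cm = _matrix_from_dense(dense)
        prof = matrix.insulation_profile(cm, 500)
        assert prof["insulation"].idxmin() == 20

    def test_window_validation(self):
        cm = _matrix_from_dense(np.ones((20, 20)))
        with pytest.raises(ValueError):
            matrix.insulation_profile(cm, 150)  # not a bin-width multiple
        with pytest.raises(ValueError):
            matrix.insulation_profile(cm, 100)  # single bin


class TestCorrectionExponent:
    def test_constructed_half_exponent_identity(self, rng):
        n = 80
        A = rng.random((n, n)) + 0.1
        A = A + A.T
        cm = _matrix_from_dense(A)
        cov = cm.row_sums("c")
        cm.weights = {"c": cov ** (-0.5)}
        cm.balanced = True
        best, curve = matrix.estimate_correction_exponent(cm)
        assert best == pytest.approx(0.5)
        assert curve.loc[curve["alpha"] == 0.5, "correlation"].iloc[0] == pytest.approx(1.0)

    def test_pure_bias_simulation_gives_alpha_one(self):
        cfg = simulate.SimConfig(
            seed=21, chrom_sizes={"chrS1": 1_500_000}, n_pairs=600_000,
            distance_law="flat", re_density=0.0, bias_lognorm_sigma=0.5,
        )
        ann = simulate.simulate_annotation(cfg)
        pr, _ = simulate.simulate_pairs(cfg, ann)
        cis = pr[np.abs(pr["pos1"] - pr["pos2"]) > 600]
        bins = binning.make_fixed_bins(cfg.chrom_sizes, 500)
        cm = matrix.kr_balance(matrix.count_contacts(cis, bins))
        best, _ = matrix.estimate_correction_exponent(cm)
        assert abs(best - 1.0) <= 0.05

    def test_constant_coverage_errors(self):
        cm = _matrix_from_dense(np.ones((10, 10)))
        cm.weights = {"c": np.ones(10)}
        with pytest.raises(ValueError):
            matrix.estimate_correction_exponent(cm)
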