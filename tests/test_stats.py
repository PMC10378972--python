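import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import comb

from ctxsub import (ContextMatrix, ati, at_class, binomial_point_null_bf10,
                    bootstrap_eq_at, compare_sets, complement_transform,
                    cpg_tables, eq_at, odds_ratio, row_rates,
                    stationary_vector, transition_matrix, ts_tv_rates)

A, C, G, T = 0, 1, 2, 3


def cm(M, ctx="AAAA", sc="NC"):
    return ContextMatrix(ctx, sc, np.asarray(M))


class TestRowRates:
    def test_row_rate_from_definition(self):
        M = np.zeros((4, 4), dtype=int)
        M[A] = [90, 4, 3, 3]
        rf, _ = row_rates(cm(M))
        assert rf[A] == pytest.approx(0.10)

    def test_diagonal_only_matrix_has_zero_overall_rate(self):
        _, overall = row_rates(cm(np.diag([10, 20, 30, 40])))
        assert overall == 0.0

    def test_overall_rate(self):
        M = np.diag([250, 250, 250, 225])
        M[A, G] = 25
        _, overall = row_rates(cm(M))
        assert overall == pytest.approx(0.025)

    def test_all_zero_matrix_reports_missing_not_zero(self):
        rf, overall = row_rates(cm(np.zeros((4, 4))))
        assert np.isnan(rf).all() and math.isnan(overall)

    def test_overall_is_count_weighted_mean_of_row_rates(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            M = rng.integers(0, 40, (4, 4))
            rf, overall = row_rates(cm(M))
            w = M.sum(axis=1)
            ok = w > 0
            assert overall == pytest.approx(np.sum(rf[ok] * w[ok]) / w.sum())


class TestTsTv:
    def test_pure_transition_matrix_has_undefined_ts_tv(self):
        M = np.zeros((4, 4), dtype=int)
        M[A, G] = 7
        ts, tv, r = ts_tv_rates(cm(M))
        assert tv == 0 and math.isnan(r)

    def test_equal_cells_give_half(self):
        M = np.ones((4, 4), dtype=int)
        np.fill_diagonal(M, 0)
        assert ts_tv_rates(cm(M))[2] == pytest.approx(0.5)

    def test_against_cell_classification_oracle(self):
        purine = {A, G}
        rng = np.random.default_rng(9)
        for _ in range(10):
            M = rng.integers(0, 30, (4, 4))
            ts = tv = 0
            for a in range(4):
                for d in range(4):
                    if a == d:
                        continue
                    if (a in purine) == (d in purine):
                        ts += M[a, d]
                    else:
                        tv += M[a, d]
            got_ts, got_tv, _ = ts_tv_rates(cm(M))
            assert got_ts == pytest.approx(ts / M.sum())
            assert got_tv == pytest.approx(tv / M.sum())

    def test_ts_plus_tv_equals_overall_exactly(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            M = rng.integers(0, 50, (4, 4))
            if M.sum() == 0:
                continue
            ts, tv, _ = ts_tv_rates(cm(M))
            _, overall = row_rates(cm(M))
            assert ts + tv == pytest.approx(overall, rel=1e-15, abs=0)


class TestATI:
    @pytest.mark.parametrize("ctx,score,cls", [
        ("ATAT", 10, "AT_rich"),
        ("GCCG", 0, "GC_rich"),
        ("ACGT", 4, "GC_rich"),   # 2 + 0 + 0 + 2
        ("AAGC", 5, "mid"),
    ])
    def test_weighted_at_count(self, ctx, score, cls):
        assert ati(ctx) == score
        assert at_class(ctx) == cls


def power_iteration_pi(P, steps=10**6, tol=1e-14):
    pi = np.full(4, 0.25)
    for _ in range(steps):
        nxt = pi @ P
        if np.abs(nxt - pi).max() < tol:
            return nxt
        pi = nxt
    return pi


class TestStationary:
    def test_doubly_stochastic_gives_uniform(self):
        M = np.full((4, 4), 5, dtype=int)
        np.fill_diagonal(M, 85)
        pi = stationary_vector(cm(M))
        assert pi == pytest.approx(np.full(4, 0.25), abs=1e-12)

    def test_matches_power_iteration_oracle(self):
        M = np.array([[98, 0, 2, 0],
                      [5, 90, 0, 5],
                      [5, 0, 90, 5],
                      [0, 2, 0, 98]])
        pi = stationary_vector(cm(M))
        oracle = power_iteration_pi(transition_matrix(cm(M)))
        assert np.abs(pi - oracle).max() < 1e-8

    def test_reversible_construction_recovers_closed_form_pi(self):
        # a symmetric count matrix is a reversible walk on a weighted graph:
        # its stationary distribution is exactly the normalized row sums
        rng = np.random.default_rng(6)
        for _ in range(10):
            S = rng.integers(1, 100, (4, 4))
            S = S + S.T
            target = S.sum(axis=1) / S.sum()
            pi = stationary_vector(cm(S))
            assert pi == pytest.approx(target, abs=1e-12)

    def test_fixed_point_residual_below_1e9(self, nc_sim):
        from ctxsub import build_folded_matrices
        folded = build_folded_matrices(nc_sim[3])["NC"]
        checked = 0
        for cmx in folded.values():
            pi = stationary_vector(cmx)
            if pi is None:
                continue
            P = transition_matrix(cmx)
            assert np.abs(pi @ P - pi).max() < 1e-9
            checked += 1
        assert checked > 50

    def test_reducible_chain_flagged_missing(self):
        M = np.diag([10, 10, 10, 10])  # absorbing everywhere
        assert stationary_vector(cm(M)) is None
        M2 = np.zeros((4, 4), dtype=int)
        M2[:2, :2] = [[5, 5], [5, 5]]
        M2[2:, 2:] = [[5, 5], [5, 5]]   # two closed classes
        assert stationary_vector(cm(M2)) is None

    def test_zero_row_flagged_missing(self):
        M = np.ones((4, 4), dtype=int)
        M[1] = 0
        assert stationary_vector(cm(M)) is None

    def test_eq_at_invariant_under_complement_transform(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            M = rng.integers(1, 60, (4, 4))
            pi1 = stationary_vector(cm(M))
            pi2 = stationary_vector(cm(complement_transform(M)))
            assert eq_at(pi1) == pytest.approx(eq_at(pi2), abs=1e-12)


class TestBootstrap:
    def well_filled(self):
        M = np.array([[800, 40, 80, 30],
                      [50, 700, 35, 120],
                      [45, 130, 750, 40],
                      [25, 60, 55, 900]])
        return cm(M)

    def test_same_seed_reproduces(self):
        a = bootstrap_eq_at(self.well_filled(), n_boot=200, seed=42)
        b = bootstrap_eq_at(self.well_filled(), n_boot=200, seed=42)
        assert a == b

    def test_single_cell_rows_have_zero_variance(self):
        # single off-diagonal cell per row, arranged as an irreducible cycle
        M = np.diag([90, 90, 90, 90])
        M[A, C] = 10
        M[C, G] = 10
        M[G, T] = 10
        M[T, A] = 10
        mean, sd = bootstrap_eq_at(cm(M), n_boot=300, seed=0)
        assert sd == 0.0
        assert mean == pytest.approx(eq_at(stationary_vector(cm(M))), abs=1e-12)

    def test_invalid_n_boot_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_eq_at(self.well_filled(), n_boot=0)

    def test_mean_converges_to_point_estimate(self):
        mx = self.well_filled()
        point = eq_at(stationary_vector(mx))
        mean, sd = bootstrap_eq_at(mx, n_boot=10_000, seed=1)
        # bootstrap mean within a few Monte-Carlo standard errors of the point
        assert abs(mean - point) < 4 * sd / math.sqrt(10_000) + 1e-3


class TestCpG:
    def test_direct_arithmetic(self):
        assert odds_ratio(2, 1, 1, 2) == pytest.approx(4.0)
        assert odds_ratio(10, 20, 5, 10) == pytest.approx(1.0)

    def test_invariant_under_row_scaling(self):
        base = odds_ratio(6, 14, 11, 32)
        assert odds_ratio(18, 42, 11, 32) == pytest.approx(base)
        assert odds_ratio(6, 14, 55, 160) == pytest.approx(base)

    def test_zero_cell_flagged(self):
        assert math.isnan(odds_ratio(5, 0, 3, 2))

    def test_aggregation_by_immediate_neighbor(self):
        folded = {}
        for ctx in ("ACGA", "ACCA", "CCGA"):
            folded[ctx] = ContextMatrix(ctx, "NC")
        folded["ACGA"].M[C, T] = 8   # R1 == G -> CG row for C>T
        folded["ACGA"].M[C, A] = 2
        folded["ACCA"].M[C, T] = 3   # R1 == C -> CH row
        folded["ACCA"].M[C, G] = 5
        folded["CCGA"].M[G, A] = 4   # L1 == C -> CG row for G>A
        folded["CCGA"].M[G, T] = 6
        g_tab, c_tab = cpg_tables(folded, "NC")
        assert g_tab.counts == ((4, 6), (0, 0))
        assert c_tab.counts == ((8, 2), (3, 5))
        assert c_tab.odds_ratio == pytest.approx((8 / 2) / (3 / 5))

    def test_mismatched_site_class_rejected(self):
        folded = {"ACGA": ContextMatrix("ACGA", "NC")}
        with pytest.raises(ValueError):
            cpg_tables(folded, "FFD")


class TestCompareSets:
    def test_identical_sets(self):
        x = {f"c{i}": float(i) for i in range(10)}
        res = compare_sets(x, dict(x))
        assert res["r2"] == pytest.approx(1.0)
        assert res["pct_x_gt_y"] == 0.0  # no strict inequalities

    def test_too_few_shared_contexts(self):
        assert compare_sets({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0}) is None

    def test_independent_noise_has_near_zero_r2(self):
        rng = np.random.default_rng(8)
        keys = [f"c{i}" for i in range(2000)]
        x = dict(zip(keys, rng.random(2000)))
        y = dict(zip(keys, rng.random(2000)))
        assert compare_sets(x, y)["r2"] < 0.01

    @pytest.mark.parametrize("k,n", [(5, 10), (76, 136), (40, 50)])
    def test_bayes_factor_against_quadrature_oracle(self, k, n):
        like = lambda p: comb(n, k) * p**k * (1 - p)**(n - k)
        marginal, _ = quad(like, 0, 1)
        oracle = marginal / like(0.5)
        assert binomial_point_null_bf10(k, n) == pytest.approx(oracle, rel=1e-6)
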