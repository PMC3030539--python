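"""Spearman, correlation t-test, local fdr, Fisher-Z differential tests."""

import numpy as np
import pytest
from scipy import stats

from metcornet import (correlation_pvalue, correlation_table,
                       differential_correlation_table, fisher_z_difference,
                       local_fdr, spearman_matrix)

from conftest import make_profile


class TestSpearman:
    def test_monotone_map_gives_perfect_correlation(self):
        x = np.array([0.1, 1.0, 2.5, 4.0, 9.0, 12.0])
        pm = make_profile(np.vstack([x, np.exp(x)]))
        tab = spearman_matrix(pm)
        assert tab["r"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_rank_formula(self):
        # x=[1..5], y=[2,1,4,3,5]: sum d^2 = 4 -> r = 1 - 24/120 = 0.8
        pm = make_profile([[1, 2, 3, 4, 5], [2, 1, 4, 3, 5]])
        tab = spearman_matrix(pm)
        assert tab["r"].iloc[0] == pytest.approx(0.8)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            X = rng.standard_normal((10, 8))
            tab = spearman_matrix(make_profile(X))
            ranks = np.apply_along_axis(stats.rankdata, 1, X)
            oracle = np.corrcoef(ranks)
            for u, v, r, _ in tab.itertuples(index=False):
                i, j = int(u[1:]), int(v[1:])
                assert r == pytest.approx(oracle[i, j], abs=1e-12)

    def test_constant_metabolite_is_excluded(self):
        pm = make_profile([[1, 1, 1, 1, 1], [1, 2, 3, 4, 5]])
        tab = spearman_matrix(pm)
        assert np.isnan(tab["r"].iloc[0])

    def test_pairwise_complete_n_is_recorded(self):
        X = np.array([
            [1.0, 2, 3, 4, 5, 6],
            [2.0, 1, 4, 3, 6, np.nan],
            [1.0, 3, 2, 5, 4, 6],
        ])
        tab = spearman_matrix(make_profile(X))
        ns = dict(((u, v), n) for u, v, _, n in tab.itertuples(index=False))
        assert ns[("m0", "m1")] == 5
        assert ns[("m0", "m2")] == 6

    def test_pair_below_four_samples_reported_missing(self):
        X = np.full((2, 6), np.nan)
        X[0, :3] = [1, 2, 3]
        X[1, :3] = [1, 2, 3]
        X[0, 3:] = [1, 2, 3]
        tab = spearman_matrix(make_profile(X))
        assert np.isnan(tab["r"].iloc[0]) and tab["n"].iloc[0] == 3

    def test_invariant_under_monotone_transform_of_rows(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((6, 12))
        Y = X.copy()
        Y[0] = np.exp(Y[0])
        Y[1] = Y[1] ** 3
        Y[2] = 2 * Y[2] + 7
        a = spearman_matrix(make_profile(X))["r"]
        b = spearman_matrix(make_profile(Y))["r"]
        assert np.allclose(a, b, atol=1e-12)


class TestCorrelationPValue:
    def test_zero_correlation_gives_p_one(self):
        t, p = correlation_pvalue(0.0, 20)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_known_t_statistic_and_p(self):
        # r = 0.5, n = 20: t = 0.5 * sqrt(18 / 0.75) = sqrt(6)
        t, p = correlation_pvalue(0.5, 20)
        assert t == pytest.approx(np.sqrt(6), abs=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(np.sqrt(6), 18), abs=1e-12)
        assert p == pytest.approx(0.0248, abs=2e-4)

    def test_p_decreases_monotonically_toward_perfect_r(self):
        rs = np.linspace(0.0, 0.999, 50)
        _, ps = correlation_pvalue(rs, 20)
        assert np.all(np.diff(ps) < 0)

    def test_perfect_correlation_p_zero_by_convention(self):
        t, p = correlation_pvalue(1.0, 10)
        assert p == 0.0 and np.isinf(t)


class TestLocalFdr:
    def test_pure_null_yields_fdr_near_one_and_no_calls(self):
        rng = np.random.default_rng(1)
        call_rates = []
        medians = []
        for _ in range(200):
            p = rng.random(500)
            fdr = local_fdr(p)
            call_rates.append(np.mean(fdr < 0.05))
            medians.append(np.median(fdr))
        assert np.mean(call_rates) < 0.01
        assert np.mean(medians) > 0.9

    def test_signal_component_is_called_with_high_precision(self):
        rng = np.random.default_rng(2)
        precisions = []
        for _ in range(50):
            null = rng.random(800)
            sig = rng.beta(0.05, 1, 200)
            p = np.concatenate([null, sig])
            fdr = local_fdr(p)
            called = fdr < 0.05
            if called.sum():
                precisions.append(called[800:].sum() / called.sum())
        assert np.mean(precisions) > 0.9

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            local_fdr([])

    def test_nan_pvalues_pass_through_as_nan(self):
        p = np.concatenate([np.random.default_rng(0).random(100), [np.nan]])
        fdr = local_fdr(p)
        assert np.isnan(fdr[-1]) and not np.isnan(fdr[:-1]).any()


class TestFisherZ:
    def test_equal_correlations_give_zero_statistic(self):
        z1, z2, Z, p = fisher_z_difference(0.6, 30, 0.6, 12)
        assert Z == 0.0 and p == pytest.approx(1.0)

    def test_known_difference_statistic(self):
        # z1 = atanh(0.9) = 1.4722, z2 = atanh(0.2) = 0.2027, n = 20 each
        z1, z2, Z, p = fisher_z_difference(0.9, 20, 0.2, 20)
        assert z1 == pytest.approx(np.arctanh(0.9), abs=1e-12)
        assert Z == pytest.approx(
            (np.arctanh(0.9) - np.arctanh(0.2)) / np.sqrt(2 / 17), abs=1e-12)
        assert Z == pytest.approx(3.70, abs=0.01)
        assert p == pytest.approx(2 * stats.norm.sf(Z), abs=1e-15)
        assert p == pytest.approx(2.2e-4, rel=0.05)

    def test_swapping_conditions_negates_z_and_preserves_p(self):
        _, _, Za, pa = fisher_z_difference(0.7, 15, 0.3, 25)
        _, _, Zb, pb = fisher_z_difference(0.3, 25, 0.7, 15)
        assert Za == pytest.approx(-Zb)
        assert pa == pytest.approx(pb)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_difference(1.0, 20, 0.5, 20)


class TestDifferentialTable:
    def _two_condition_toy(self):
        """6 metabolites; condition A has 2 perfect modules, B breaks one."""
        rng = np.random.default_rng(7)
        base = rng.standard_normal((6, 30))
        A = base.copy()
        A[1] = A[0] * 2 + rng.normal(0, 0.1, 30)       # pair (0,1) tight
        A[3] = A[2] + rng.normal(0, 0.1, 30)           # pair (2,3) tight
        B = rng.standard_normal((6, 30))
        B[1] = B[0] * 2 + rng.normal(0, 0.1, 30)       # (0,1) kept
        return make_profile(A), make_profile(B)         # (2,3) broken in B

    def test_counts_follow_hand_reasoning_on_toy(self):
        pm_a, pm_b = self._two_condition_toy()
        ca = correlation_table(pm_a)
        cb = correlation_table(pm_b)
        # condition A: exactly the two engineered pairs are near-perfect
        top_a = set(map(tuple, ca.nlargest(2, "r")[["u", "v"]].to_numpy()))
        assert top_a == {("m0", "m1"), ("m2", "m3")}
        diff = differential_correlation_table(ca, cb)
        # the broken pair has the most extreme differential statistic
        best = diff.loc[diff["p_diff"].idxmin()]
        assert {best["u"], best["v"]} == {"m2", "m3"}
        assert best["p_diff"] < 1e-6
        assert best["delta"] == pytest.approx(
            best["r1"] - best["r2"], abs=1e-12)

    def test_comparing_a_condition_with_itself_calls_nothing(self):
        pm_a, _ = self._two_condition_toy()
        ca = correlation_table(pm_a)
        diff = differential_correlation_table(ca, ca)
        testable = diff["Z"].dropna()
        assert np.allclose(testable, 0.0)
        assert int(diff["significant"].sum()) == 0

    def test_sign_convention_z_follows_z1_minus_z2(self):
        pm_a, pm_b = self._two_condition_toy()
        diff = differential_correlation_table(
            correlation_table(pm_a), correlation_table(pm_b))
        ok = diff.dropna(subset=["Z"])
        assert np.all(np.sign(ok["Z"]) == np.sign(ok["z1"] - ok["z2"]))
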