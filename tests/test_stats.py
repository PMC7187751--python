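"""Permutation correlation, bootstrap, rank tests, kappa, and the screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from affectflow import (
    average_pairwise_kappa,
    bootstrap_ci,
    cohens_kappa,
    correlation_screen,
    mann_whitney,
    normality_check,
    partial_corr,
    pearson_r,
    perm_corr_test,
)
from affectflow.stats import (
    ScreenConfig,
    assign_tier,
    partial_r_from_pairwise,
    perm_partial_corr,
    screen_to_frame,
)


def exhaustive_perm_p(x, y):
    """Oracle: two-sided permutation p over all n! relabelings of y."""
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    count = total = 0
    for perm in itertools.permutations(y):
        if abs(np.corrcoef(x, perm)[0, 1]) >= r_obs - 1e-12:
            count += 1
        total += 1
    return count / total


class TestPermCorr:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = perm_corr_test(x, 2 * x, n_perm=999, seed=1)
        assert r == pytest.approx(1.0)
        # the minimum attainable p, plus at most one sampled permutation
        # that is itself exactly monotone (|r_perm| = 1 ties the observed)
        assert 1 / 1000 <= p <= 2 / 1000

    def test_r_matches_closed_form(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            r, _ = perm_corr_test(x, y, n_perm=10, seed=0)
            assert r == pytest.approx(pearson_r(x, y), abs=1e-12)
            assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_sampled_p_near_exhaustive_n6(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        p_exact = exhaustive_perm_p(x, y)
        _, p_sampled = perm_corr_test(x, y, n_perm=4000, seed=11)
        mc_err = 4 * np.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(p_sampled - p_exact) < mc_err + 1e-3

    def test_p_range_invariant(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            x, y = rng.normal(size=(2, 12))
            _, p = perm_corr_test(x, y, n_perm=99, seed=3)
            assert 1 / 100 <= p <= 1.0

    def test_joint_shuffle_invariance(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=(2, 20))
        r1, p1 = perm_corr_test(x, y, n_perm=999, seed=5)
        order = rng.permutation(20)
        r2, p2 = perm_corr_test(x[order], y[order], n_perm=999, seed=5)
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=0.05)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            perm_corr_test(np.ones(10), np.arange(10.0))


class TestBootstrap:
    def test_identical_vectors_collapse_to_one(self):
        x = np.arange(20.0)
        lo, hi = bootstrap_ci(x, x, n_boot=200, seed=1)
        assert (lo, hi) == (1.0, 1.0)

    def test_same_seed_same_interval(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=(2, 30))
        assert bootstrap_ci(x, y, seed=9) == bootstrap_ci(x, y, seed=9)

    def test_interval_orders_and_brackets_r(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200) * np.sqrt(0.75)
        lo, hi = bootstrap_ci(x, y, n_boot=2000, seed=2)
        r = pearson_r(x, y)
        assert lo <= r <= hi
        assert hi - lo < 0.3

    def test_coverage_at_rho_half(self):
        """Seeded mini coverage study: the 95% interval should contain
        the true correlation in most replicates."""
        rng = np.random.default_rng(12)
        rho, n, hits, reps = 0.5, 200, 0, 60
        for i in range(reps):
            x = rng.normal(size=n)
            y = rho * x + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
            lo, hi = bootstrap_ci(x, y, n_boot=400, seed=rng)
            hits += lo <= rho <= hi
        assert hits / reps > 0.85


class TestPartialCorr:
    def test_arithmetic_oracle(self):
        assert partial_r_from_pairwise(0.29, 0.5, 0.6) == pytest.approx(
            -0.01 / np.sqrt(0.48), abs=1e-12)

    def test_vanishing_numerator(self):
        assert partial_r_from_pairwise(0.3, 0.5, 0.6) == pytest.approx(0.0)

    def test_collinear_control_rejected(self):
        x = np.arange(10.0)
        y = np.random.default_rng(0).normal(size=10)
        with pytest.raises(ValueError, match="degenerate"):
            partial_corr(x, y, 2 * x + 1)

    def test_independent_control_leaves_r_unchanged(self):
        rng = np.random.default_rng(14)
        n = 500
        x = rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)
        z = rng.normal(size=n)
        r_xy = pearson_r(x, y)
        r_part, _ = partial_corr(x, y, z)
        assert r_part == pytest.approx(r_xy, abs=0.05)

    def test_matches_residual_regression(self):
        """Independent route: correlate OLS residuals of x|z and y|z."""
        rng = np.random.default_rng(15)
        n = 120
        z = rng.normal(size=n)
        x = 0.6 * z + rng.normal(size=n)
        y = -0.5 * z + 0.3 * x + rng.normal(size=n)
        d = np.column_stack([np.ones(n), z])
        rx = x - d @ np.linalg.lstsq(d, x, rcond=None)[0]
        ry = y - d @ np.linalg.lstsq(d, y, rcond=None)[0]
        r_part, p = partial_corr(x, y, z)
        assert r_part == pytest.approx(pearson_r(rx, ry), abs=1e-10)
        assert 0 <= p <= 1

    def test_permutation_variant_agrees(self):
        rng = np.random.default_rng(16)
        n = 60
        z = rng.normal(size=n)
        x = 0.5 * z + rng.normal(size=n)
        y = 0.5 * z + rng.normal(size=n)
        r_t, p_t = partial_corr(x, y, z)
        r_p, p_p = perm_partial_corr(x, y, z, n_perm=2000, seed=1)
        assert r_t == pytest.approx(r_p, abs=1e-12)
        assert abs(p_t - p_p) < 0.1


class TestMannWhitney:
    def test_complete_separation_maximal_u(self):
        x = [10.0, 11, 12, 13]
        y = [1.0, 2, 3]
        u, z, p = mann_whitney(x, y)
        assert u == len(x) * len(y)
        assert p < 0.1

    def test_identical_multisets(self):
        x = [1.0, 2, 3, 4]
        u, z, p = mann_whitney(x, x)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_u_matches_pairwise_enumeration(self):
        """Oracle: U = #{(i, j): x_i > y_j} + half the ties."""
        rng = np.random.default_rng(18)
        for _ in range(25):
            x = rng.integers(0, 6, size=4).astype(float)
            y = rng.integers(0, 6, size=4).astype(float)
            u, _, _ = mann_whitney(x, y)
            u_brute = sum((xi > yj) + 0.5 * (xi == yj)
                          for xi in x for yj in y)
            assert u == pytest.approx(u_brute)

    def test_u_matches_scipy(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=8)
        y = rng.normal(size=6)
        u, _, _ = mann_whitney(x, y)
        assert u == sps.mannwhitneyu(x, y, alternative="two-sided").statistic

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKappa:
    def test_identical_vectors(self):
        assert cohens_kappa(["+", "-", "0"], ["+", "-", "0"]) == 1.0

    def test_hand_computed_two_by_two(self):
        # p_o = 0.5 and balanced marginals give p_e = 0.5, so kappa = 0
        assert cohens_kappa(["+", "+", "-", "-"],
                            ["+", "-", "+", "-"]) == pytest.approx(0.0)

    def test_symmetry(self):
        rng = np.random.default_rng(20)
        a = list(rng.choice(["+", "-", "0", "±"], size=40))
        b = list(rng.choice(["+", "-", "0", "±"], size=40))
        assert cohens_kappa(a, b) == pytest.approx(cohens_kappa(b, a))

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(21)
        for _ in range(10):
            a = list(rng.choice(list("abc"), size=30))
            b = list(rng.choice(list("abc"), size=30))
            assert cohens_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12)

    def test_random_labels_kappa_near_zero(self):
        rng = np.random.default_rng(22)
        ks = []
        for _ in range(200):
            a = list(rng.choice(["x", "y"], size=50))
            b = list(rng.choice(["x", "y"], size=50))
            ks.append(cohens_kappa(a, b))
        assert abs(np.mean(ks)) < 0.03

    def test_average_pairwise(self):
        a = ["+", "+", "-", "-"]
        b = ["+", "+", "-", "-"]       # kappa(a, b) = 1
        c = ["+", "-", "+", "-"]       # kappa(a, c) = kappa(b, c) = 0
        assert average_pairwise_kappa([a, b, c]) == pytest.approx(1 / 3)

    def test_constant_raters(self):
        # identical constant ratings agree perfectly; different constant
        # ratings have zero chance agreement and zero observed agreement
        assert cohens_kappa(["x", "x"], ["x", "x"]) == 1.0
        assert cohens_kappa(["x", "x"], ["y", "y"]) == 0.0


class TestNormality:
    def test_normal_sample_usually_passes(self):
        rng = np.random.default_rng(23)
        passes = sum(normality_check(rng.normal(size=70))[1] > 0.05
                     for _ in range(100))
        assert passes >= 85

    def test_exponential_sample_usually_rejected(self):
        rng = np.random.default_rng(24)
        rejects = sum(normality_check(rng.exponential(size=70))[1] < 0.05
                      for _ in range(100))
        assert rejects >= 80

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            normality_check(np.ones(10))


class TestScreen:
    def _tables(self, n=100, seed=25, n_feat=4):
        rng = np.random.default_rng(seed)
        users = [f"u{i}" for i in range(n)]
        scales = pd.DataFrame(
            rng.normal(size=(n, 2)), index=users, columns=["neu", "cesd"])
        feats = pd.DataFrame(
            rng.normal(size=(n, n_feat)), index=users,
            columns=[f"f{j}" for j in range(n_feat)])
        return scales, feats

    def test_planted_signal_reaches_significant_tier(self):
        scales, feats = self._tables()
        # plant r ~ 0.5 between neu and f0
        feats["f0"] = scales["neu"] + np.random.default_rng(26).normal(
            size=len(feats)) * np.sqrt(3)
        res = correlation_screen(feats, scales,
                                 ScreenConfig(n_perm=999, n_boot=200, seed=1))
        hit = [r for r in res
               if r.scale_name == "neu" and r.feature_name == "f0"]
        assert hit[0].tier == "significant"
        assert hit[0].r > 0.3

    def test_structural_count_and_tiers(self):
        scales, feats = self._tables(n=40, n_feat=3)
        res = correlation_screen(feats, scales,
                                 ScreenConfig(n_perm=199, n_boot=100, seed=2))
        assert len(res) == 2 * 3
        frame = screen_to_frame(res)
        assert set(frame["tier"]) <= {"significant", "trend", "ns"}
        assert np.allclose(frame["r2"], frame["r"] ** 2)
        assert ((frame["ci_lo"] <= frame["ci_hi"]).all())

    def test_bit_identical_under_same_seed(self):
        scales, feats = self._tables(n=30)
        cfg = ScreenConfig(n_perm=199, n_boot=100, seed=7)
        f1 = screen_to_frame(correlation_screen(feats, scales, cfg))
        f2 = screen_to_frame(correlation_screen(feats, scales, cfg))
        pd.testing.assert_frame_equal(f1, f2)

    def test_result_independent_of_column_order(self):
        scales, feats = self._tables(n=30)
        cfg = ScreenConfig(n_perm=499, n_boot=100, seed=7)
        res1 = correlation_screen(feats, scales, cfg)
        res2 = correlation_screen(feats[list(feats.columns)[::-1]], scales,
                                  cfg)
        d1 = {(r.scale_name, r.feature_name): r.r for r in res1}
        d2 = {(r.scale_name, r.feature_name): r.r for r in res2}
        assert d1 == d2

    def test_user_mismatch_rejected(self):
        scales, feats = self._tables(n=10)
        with pytest.raises(ValueError, match="mismatch"):
            correlation_screen(feats.iloc[:8], scales)

    def test_tier_boundaries(self):
        assert assign_tier(0.009) == "significant"
        assert assign_tier(0.01) == "trend"
        assert assign_tier(0.049) == "trend"
        assert assign_tier(0.05) == "ns"
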