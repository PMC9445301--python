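"""Shared statistics: exact U enumeration, Levene, ANOVA/Dunnett, Pearson."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from burstmosaic.stats_core import anova_dunnett, levene_test, mann_whitney_u, pearson


def brute_force_u_p(a, b):
    """Independent oracle: U from pairwise wins, p by full label enumeration."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)

    def u_of(group_a_idx):
        ga = pooled[list(group_a_idx)]
        gb = pooled[[i for i in range(n1 + n2) if i not in group_a_idx]]
        wins = sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)
        return wins

    u_obs = u_of(tuple(range(n1)))
    mu = n1 * n2 / 2.0
    hits = sum(
        1
        for idx in combinations(range(n1 + n2), n1)
        if abs(u_of(idx) - mu) >= abs(u_obs - mu) - 1e-9
    )
    return u_obs, hits / comb(n1 + n2, n1)


class TestMannWhitney:
    def test_identical_singletons(self):
        assert mann_whitney_u([1.0], [1.0])["p_two_sided"] == 1.0

    def test_separated_triples(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res["U"] == 0
        assert res["p_two_sided"] == pytest.approx(0.1)
        assert res["exact"]

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 6, size=2)
        a = rng.integers(0, 8, n1).astype(float)  # with ties
        b = rng.integers(0, 8, n2).astype(float)
        u_exp, p_exp = brute_force_u_p(a, b)
        res = mann_whitney_u(a, b)
        assert res["U"] == pytest.approx(u_exp)
        assert res["p_two_sided"] == pytest.approx(p_exp)

    @pytest.mark.parametrize("seed", range(8))
    def test_asymptotic_close_to_exact_at_crossover(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.normal(size=7)
        b = rng.normal(0.5, size=7)
        p_exact = mann_whitney_u(a, b, method="exact")["p_two_sided"]
        p_approx = mann_whitney_u(a, b, method="asymptotic")["p_two_sided"]
        # worst case of the continuity-corrected normal at this size is ~0.012
        assert abs(p_exact - p_approx) < 0.013

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=5), rng.normal(size=6)
        res = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res["U"] == pytest.approx(ref.statistic)
        assert res["p_two_sided"] == pytest.approx(ref.pvalue, abs=1e-12)

    @given(st.floats(-50, 50))
    def test_shift_invariance(self, c):
        a = np.array([1.0, 3.0, 5.0, 7.0])
        b = np.array([2.0, 4.0, 9.0])
        assert mann_whitney_u(a + c, b + c)["p_two_sided"] == pytest.approx(
            mann_whitney_u(a, b)["p_two_sided"]
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestLevene:
    def test_shifted_copies_give_p_one(self):
        g = np.array([1.0, 2.0, 4.0, 8.0])
        res = levene_test([g, g + 100.0])
        assert res["W"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_degrees_of_freedom_four_groups(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(size=n) for n in (40, 35, 32, 30)]  # N = 137
        assert levene_test(groups)["df"] == (3, 133)

    def test_matches_anova_on_deviation_scores(self):
        # Levene's W is a one-way ANOVA of |x - group mean|
        groups = [[1.0, 4.0, 7.0], [2.0, 2.0, 9.0], [0.0, 5.0, 5.0]]
        devs = [np.abs(np.array(g) - np.mean(g)) for g in groups]
        f_ref, p_ref = sps.f_oneway(*devs)
        res = levene_test(groups)
        assert res["W"] == pytest.approx(f_ref)
        assert res["p"] == pytest.approx(p_ref)

    def test_constant_groups_flagged(self):
        res = levene_test([[1.0, 1.0], [2.0, 2.0]])
        assert res["degenerate"]

    def test_median_centering_option(self):
        rng = np.random.default_rng(5)
        g1, g2 = rng.normal(size=20), rng.normal(0, 2, size=20)
        ref = sps.levene(g1, g2, center="median")
        res = levene_test([g1, g2], center="median")
        assert res["W"] == pytest.approx(ref.statistic)


class TestAnovaDunnett:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        res = anova_dunnett({"ctrl": g, "a": g, "b": g}, "ctrl", n_mc=5000)
        assert res["F"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)
        assert all(p == pytest.approx(1.0) for p in res["dunnett_p"].values())

    def test_degrees_of_freedom_reported_design(self):
        rng = np.random.default_rng(1)
        groups = {
            "donor": rng.normal(size=12),
            "h84": rng.normal(size=6),
            "h45": rng.normal(size=6),
            "h36": rng.normal(size=6),
        }
        assert anova_dunnett(groups, "donor", n_mc=2000)["df"] == (3, 26)

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError):
            anova_dunnett({"a": [1.0, 2.0]}, "ctrl")

    @pytest.mark.parametrize("seed", range(4))
    def test_adjusted_p_not_below_unadjusted_t(self, seed):
        rng = np.random.default_rng(200 + seed)
        groups = {
            "ctrl": rng.normal(size=8),
            "a": rng.normal(0.5, size=8),
            "b": rng.normal(1.0, size=8),
            "c": rng.normal(size=8),
        }
        res = anova_dunnett(groups, "ctrl", n_mc=40000)
        for lab in ("a", "b", "c"):
            t_p = sps.ttest_ind(groups[lab], groups["ctrl"]).pvalue
            assert res["dunnett_p"][lab] >= t_p - 0.02

    def test_matches_scipy_dunnett(self):
        rng = np.random.default_rng(7)
        ctrl = rng.normal(size=10)
        a = rng.normal(0.8, size=8)
        b = rng.normal(-0.3, size=9)
        res = anova_dunnett({"ctrl": ctrl, "a": a, "b": b}, "ctrl", n_mc=200000)
        ref = sps.dunnett(a, b, control=ctrl)
        assert res["dunnett_p"]["a"] == pytest.approx(ref.pvalue[0], abs=0.01)
        assert res["dunnett_p"]["b"] == pytest.approx(ref.pvalue[1], abs=0.01)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(x, x)["r"] == pytest.approx(1.0)
        assert pearson(x, -x)["r"] == pytest.approx(-1.0)

    def test_matches_summation_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 9.0, 8.0])
        n = len(x)
        r_hand = (n * np.sum(x * y) - x.sum() * y.sum()) / np.sqrt(
            (n * np.sum(x**2) - x.sum() ** 2) * (n * np.sum(y**2) - y.sum() ** 2)
        )
        assert pearson(x, y)["r"] == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_flagged(self):
        res = pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res["degenerate"]

    @given(st.floats(0.1, 20), st.floats(-5, 5))
    def test_scale_and_shift_leave_r_unchanged(self, scale, shift):
        x = np.array([1.0, 2.0, 4.0, 8.0, 9.0])
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        r0 = pearson(x, y)["r"]
        assert pearson(x * scale + shift, y)["r"] == pytest.approx(r0, abs=1e-9)
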