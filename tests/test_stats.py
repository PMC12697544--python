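import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import hippomorph as hm


def brute_force_mwu(a, b):
    """Independent enumeration oracle: tail of U = min(U_a, U_b)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    base = na * (na + 1) / 2
    ua = ranks[:na].sum() - base
    u_obs = min(ua, na * nb - ua)
    count = 0
    total = math.comb(na + nb, na)
    for comb in itertools.combinations(range(na + nb), na):
        u = ranks[list(comb)].sum() - base
        if min(u, na * nb - u) <= u_obs + 1e-9:
            count += 1
    return u_obs, count / total


class TestMannWhitney:
    def test_separated_pairs(self):
        u, p = hm.mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_tied_groups(self):
        u, p = hm.mann_whitney_u([5, 5], [5, 5])
        assert u == 2.0 and p == 1.0

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            hm.mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("na,nb", [(2, 3), (3, 3), (4, 4), (2, 6), (5, 5)])
    def test_exact_matches_enumeration_oracle(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        for _ in range(5):
            a = rng.integers(0, 6, size=na).astype(float)  # ties likely
            b = rng.integers(0, 6, size=nb).astype(float)
            assert hm.mann_whitney_u(a, b, "exact") == pytest.approx(brute_force_mwu(a, b))

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=5)
            b = rng.normal(size=4)
            u, p = hm.mann_whitney_u(a, b, "exact")
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == min(ref.statistic, 20 - ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_exact_close_to_approx_at_n16(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            _, pe = hm.mann_whitney_u(a, b, "exact")
            _, pa = hm.mann_whitney_u(a, b, "approx")
            assert abs(pe - pa) < 0.05


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = hm.spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = hm.spearman_rho([1, 2, 3, 4], [40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            hm.spearman_rho([1, 1, 1], [1, 2, 3])

    def test_exact_p_is_permutation_fraction(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            rho, p = hm.spearman_rho(x, y, "exact")
            rx, ry = sps.rankdata(x), sps.rankdata(y)
            obs = np.corrcoef(rx, ry)[0, 1]
            count = sum(
                abs(np.corrcoef(rx, np.asarray(perm))[0, 1]) >= abs(obs) - 1e-9
                for perm in itertools.permutations(ry)
            )
            assert p == pytest.approx(count / math.factorial(5))

    def test_approx_matches_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        rho, p = hm.spearman_rho(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestBenjaminiHochberg:
    def test_step_up_example(self):
        assert hm.benjamini_hochberg([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert hm.benjamini_hochberg([0.2]) == pytest.approx([0.2])

    def test_equal_ps_unchanged(self):
        assert hm.benjamini_hochberg([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            hm.benjamini_hochberg([0.5, 1.5])

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 15)))
            assert hm.benjamini_hochberg(p) == pytest.approx(
                multipletests(p, method="fdr_bh")[1])

    def test_adjusted_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.random(10)
            adj = hm.benjamini_hochberg(p)
            assert (adj >= p - 1e-12).all()
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-12).all()

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_step_up_invariants_hold_for_any_p_vector(self, p):
        adj = hm.benjamini_hochberg(p)
        p = np.asarray(p)
        assert ((adj >= p - 1e-12) & (adj <= 1.0 + 1e-12)).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()  # monotone in raw p

    def test_family_separation_changes_adjustment(self):
        results = [
            hm.StatResult("o", f"c{i}", "U", 1.0, p, "famA" if i < 3 else "famB", None, 10)
            for i, p in enumerate([0.01, 0.02, 0.04, 0.5, 0.6, 0.7])
        ]
        adjusted = hm.adjust_within_families(results)
        a = [r.p_adjusted for r in adjusted if r.family == "famA"]
        assert a == pytest.approx([0.03, 0.03, 0.04])
        # pooled into one family the small p-values get larger adjustments
        pooled = hm.benjamini_hochberg([0.01, 0.02, 0.04, 0.5, 0.6, 0.7])
        assert pooled[0] > a[0]
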