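"""Exact-test battery: frozen worked examples, naive-enumeration oracles,
cross-checks against scipy/statsmodels, and distribution-free invariants."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ggn_tfc import (
    ContingencyTable,
    PairedBinary,
    bonferroni_posthoc,
    fisher_exact,
    kruskal_wallis,
    mann_whitney_u,
    mcnemar_exact,
    median_quartiles,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------------------
# naive oracles (independent of the implementation's enumeration paths)


def oracle_fisher_2x2(a, b, c, d):
    """Probability-ordering two-sided Fisher p via the univariate hypergeometric."""
    r1, n1 = a + b, a + c
    n = a + b + c + d
    denom = math.comb(n, r1)

    def prob(x):
        return Fraction(math.comb(n1, x) * math.comb(n - n1, r1 - x), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, r1 - (n - n1)), min(r1, n1) + 1):
        if prob(x) <= p_obs:
            total += prob(x)
    return float(total)


def oracle_fisher_rxc(counts):
    """Freeman-Halton p by exhaustive cell enumeration with exact rationals."""
    counts = np.asarray(counts)
    rm, cm = counts.sum(axis=1), counts.sum(axis=0)
    n = counts.sum()
    base = Fraction(
        math.prod(math.factorial(int(x)) for x in rm)
        * math.prod(math.factorial(int(x)) for x in cm),
        math.factorial(int(n)),
    )

    def prob(t):
        return base / math.prod(math.factorial(int(x)) for x in np.ravel(t))

    cells = [range(int(min(rm[i], cm[j])) + 1) for i in range(len(rm) - 1) for j in range(len(cm) - 1)]
    p_obs = prob(counts)
    total = Fraction(0)
    for combo in itertools.product(*cells):
        t = np.zeros_like(counts)
        t[: -1, : -1] = np.reshape(combo, (len(rm) - 1, len(cm) - 1))
        t[:-1, -1] = rm[:-1] - t[:-1, :-1].sum(axis=1)
        t[-1, :] = cm - t[:-1, :].sum(axis=0)
        if (t >= 0).all():
            if prob(t) <= p_obs:
                total += prob(t)
    return float(total)


def oracle_mcnemar(b, c):
    nd = b + c
    k = min(b, c)
    tail = Fraction(sum(math.comb(nd, i) for i in range(k + 1)), 2**nd)
    return float(min(1, 2 * tail))


def oracle_wilcoxon(before, after):
    """Doubled-smaller-tail exact p by brute force over all sign assignments."""
    diffs = np.asarray(after, float) - np.asarray(before, float)
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    w_all = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    p_le = sum(w <= w_obs + 1e-9 for w in w_all) / 2**n
    p_ge = sum(w >= w_obs - 1e-9 for w in w_all) / 2**n
    return min(1.0, 2 * min(p_le, p_ge))


def oracle_mann_whitney(a, b):
    """Exact p by enumerating group assignments; U from direct pairwise comparisons."""
    a, b = list(a), list(b)
    m = len(a)
    pooled = a + b

    def u_stat(first, second):
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in first for y in second
        )

    u_obs = u_stat(a, b)
    us = []
    for idx in itertools.combinations(range(len(pooled)), m):
        grp_a = [pooled[i] for i in idx]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(grp_a, grp_b))
    p_le = sum(u <= u_obs + 1e-9 for u in us) / len(us)
    p_ge = sum(u >= u_obs - 1e-9 for u in us) / len(us)
    return min(1.0, 2 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# Fisher / Freeman-Halton


class TestFisherExact:
    def test_printed_2x2(self):
        """Adenocarcinoma vs AIS visual positivity: p = 0.0018, printed 0.002."""
        res = fisher_exact(ContingencyTable([[22, 3], [1, 5]]))
        assert res.p_value == pytest.approx(0.001787361, abs=1e-6)
        assert round(res.p_value, 3) == 0.002

    def test_two_equiprobable_tables(self):
        assert fisher_exact(ContingencyTable([[1, 0], [0, 1]])).p_value == pytest.approx(1.0)

    def test_diagonal_5x5(self):
        res = fisher_exact(ContingencyTable([[5, 0], [0, 5]]))
        assert res.p_value == pytest.approx(2 / 252, abs=1e-12)

    def test_three_group_visual_table(self):
        """Visual positivity across the three pathology groups: prints 0.001."""
        res = fisher_exact(ContingencyTable([[22, 3], [4, 5], [1, 5]]))
        assert round(res.p_value, 3) == 0.001

    def test_matches_scipy_on_2x2(self):
        for table in ([[3, 7], [5, 2]], [[8, 2], [1, 9]], [[4, 4], [4, 4]], [[12, 0], [3, 5]]):
            mine = fisher_exact(ContingencyTable(table)).p_value
            ref = sps.fisher_exact(table)[1]
            assert mine == pytest.approx(ref, rel=1e-9)

    def test_enumeration_bound_enforced(self):
        with pytest.raises(ValueError, match="chi-square"):
            fisher_exact(ContingencyTable([[150, 10], [20, 30]]))
        with pytest.raises(ValueError, match="chi-square"):
            fisher_exact(ContingencyTable(np.ones((5, 2), dtype=int)))

    def test_row_and_column_permutation_invariance(self):
        base = [[7, 2, 1], [3, 5, 4]]
        p0 = fisher_exact(ContingencyTable(base)).p_value
        arr = np.array(base)
        for perm in itertools.permutations(range(3)):
            assert fisher_exact(ContingencyTable(arr[:, perm])).p_value == pytest.approx(p0, abs=1e-12)
        assert fisher_exact(ContingencyTable(arr[::-1])).p_value == pytest.approx(p0, abs=1e-12)

    def test_oracle_sweep_2x2(self):
        """Full agreement with the naive hypergeometric oracle, total <= 12."""
        for total in range(1, 13):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        d = total - a - b - c
                        mine = fisher_exact(ContingencyTable([[a, b], [c, d]])).p_value
                        assert mine == pytest.approx(
                            oracle_fisher_2x2(a, b, c, d), abs=1e-12
                        ), (a, b, c, d)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(
        cells=st.lists(st.integers(0, 4), min_size=6, max_size=6).filter(
            lambda c: 1 <= sum(c) <= 12
        )
    )
    def test_oracle_sweep_2x3(self, cells):
        table = [cells[:3], cells[3:]]
        mine = fisher_exact(ContingencyTable(table)).p_value
        assert mine == pytest.approx(oracle_fisher_rxc(table), abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        cells=st.lists(st.integers(0, 3), min_size=9, max_size=9).filter(
            lambda c: 1 <= sum(c) <= 12
        )
    )
    def test_oracle_sweep_3x3(self, cells):
        table = [cells[:3], cells[3:6], cells[6:]]
        mine = fisher_exact(ContingencyTable(table)).p_value
        assert mine == pytest.approx(oracle_fisher_rxc(table), abs=1e-12)


# ---------------------------------------------------------------------------
# McNemar


class TestMcNemar:
    def test_forced_discordance_is_highly_significant(self):
        """0 vs 18 discordant pairs: p = 2 * 0.5^18, far below 0.001."""
        res = mcnemar_exact(PairedBinary(b=0, c=18))
        assert res.p_value == pytest.approx(2 * 0.5**18, rel=1e-12)
        assert res.p_value < 0.001

    def test_symmetric_discordance(self):
        assert mcnemar_exact(PairedBinary(5, 5)).p_value == 1.0

    def test_small_tail_example(self):
        res = mcnemar_exact(PairedBinary(b=1, c=9))
        assert res.p_value == pytest.approx(0.021484375, abs=1e-12)

    def test_no_discordant_pairs_degenerate(self):
        res = mcnemar_exact(PairedBinary(0, 0, n_concordant=10))
        assert res.p_value == 1.0
        assert "degenerate" in res.note

    def test_oracle_sweep(self):
        for b in range(13):
            for c in range(13 - b):
                if b + c == 0:
                    continue
                mine = mcnemar_exact(PairedBinary(b, c)).p_value
                assert mine == pytest.approx(oracle_mcnemar(b, c), abs=1e-12), (b, c)

    def test_matches_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c, conc in [(2, 9, 5), (0, 7, 3), (4, 4, 0), (1, 15, 10)]:
            table = [[conc, b], [c, 0]]
            ref = sm_mcnemar(table, exact=True).pvalue
            assert mcnemar_exact(PairedBinary(b, c, conc)).p_value == pytest.approx(ref, rel=1e-9)

    def test_large_sample_uses_continuity_corrected_chi2(self):
        res = mcnemar_exact(PairedBinary(b=5, c=40))
        assert not res.exact
        assert res.statistic == pytest.approx((abs(5 - 40) - 1) ** 2 / 45)


# ---------------------------------------------------------------------------
# Kruskal-Wallis


class TestKruskalWallis:
    def test_hand_computed_h(self):
        res = kruskal_wallis([[1, 2], [3, 4]])
        assert res.statistic == pytest.approx(2.4)
        assert res.p_value == pytest.approx(sps.chi2.sf(2.4, 1), rel=1e-9)

    def test_identical_groups_degenerate(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0], [2.0, 2.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_group_relabeling_invariance(self):
        groups = [[1.2, 3.4, 2.2], [0.5, 0.7], [5.0, 4.1, 3.3, 2.8]]
        p0 = kruskal_wallis(groups).p_value
        for perm in itertools.permutations(groups):
            assert kruskal_wallis(list(perm)).p_value == pytest.approx(p0, abs=1e-12)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


class TestWilcoxon:
    def test_all_shifted_up_five_pairs(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert res.p_value == pytest.approx(2 / 32, abs=1e-12)

    def test_single_pair_capped(self):
        assert wilcoxon_signed_rank([1.0], [2.0]).p_value == 1.0

    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0
        assert "degenerate" in res.note

    def test_forty_amplified_pairs_extreme(self):
        """Dividing every value by k < 1 forces the extreme tail: p < 0.001."""
        rng = np.random.default_rng(0)
        before = rng.lognormal(0.3, 0.4, size=40)
        after = before / 0.55
        res = wilcoxon_signed_rank(before, after)
        assert res.p_value < 0.001
        assert not res.exact  # 40 pairs: normal approximation

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        diffs=st.lists(
            st.integers(-5, 5).filter(lambda d: d != 0), min_size=1, max_size=11
        )
    )
    def test_oracle_sweep(self, diffs):
        before = [0.0] * len(diffs)
        after = [float(d) for d in diffs]
        mine = wilcoxon_signed_rank(before, after).p_value
        assert mine == pytest.approx(oracle_wilcoxon(before, after), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            diffs = rng.normal(0.4, 1.0, size=12)
            ref = sps.wilcoxon(diffs, method="exact").pvalue
            mine = wilcoxon_signed_rank(np.zeros(12), diffs).p_value
            assert mine == pytest.approx(ref, rel=1e-9)


# ---------------------------------------------------------------------------
# Mann-Whitney U


class TestMannWhitney:
    def test_separated_pairs(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 6, abs=1e-12)

    def test_separated_triples(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples(self):
        assert mann_whitney_u([2, 2, 2], [2, 2]).p_value == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        a=st.lists(st.integers(0, 6), min_size=1, max_size=6),
        b=st.lists(st.integers(0, 6), min_size=1, max_size=6),
    )
    def test_oracle_sweep(self, a, b):
        mine = mann_whitney_u(a, b).p_value
        assert mine == pytest.approx(oracle_mann_whitney(a, b), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            a = rng.normal(0, 1, size=8)
            b = rng.normal(0.8, 1, size=7)
            ref = sps.mannwhitneyu(a, b, method="exact").pvalue
            assert mann_whitney_u(a, b).p_value == pytest.approx(ref, rel=1e-9)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, size=30)
        b = rng.normal(1, 1, size=25)
        res = mann_whitney_u(a, b)
        assert not res.exact
        ref = sps.mannwhitneyu(a, b, method="asymptotic").pvalue
        assert res.p_value == pytest.approx(ref, rel=0.05)


# ---------------------------------------------------------------------------
# Bonferroni, quantiles, generic p-value invariants


class TestBonferroniAndQuantiles:
    @pytest.mark.parametrize(
        "ps, expected",
        [
            ([0.01, 0.20, 0.50], [0.03, 0.60, 1.0]),
            ([0.4, 0.4], [0.8, 0.8]),
            ([0.37], [0.37]),
        ],
    )
    def test_bonferroni(self, ps, expected):
        assert bonferroni_posthoc(ps) == pytest.approx(expected)

    def test_bonferroni_never_decreases(self):
        ps = [0.001, 0.049, 0.7, 1.0]
        assert all(adj >= p for adj, p in zip(bonferroni_posthoc(ps), ps))

    def test_bonferroni_rejects_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_posthoc([1.2])

    def test_weighted_average_percentiles(self):
        assert median_quartiles([0.5, 0.6, 0.9]) == pytest.approx((0.6, 0.5, 0.9))
        assert median_quartiles([1.0, 3.0]) == pytest.approx((2.0, 1.0, 3.0))
        assert median_quartiles([4.2]) == pytest.approx((4.2, 4.2, 4.2))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    a=st.lists(st.floats(0.1, 9.9), min_size=2, max_size=8),
    b=st.lists(st.floats(0.1, 9.9), min_size=2, max_size=8),
)
def test_all_p_values_in_unit_interval(a, b):
    results = [
        mann_whitney_u(a, b),
        kruskal_wallis([a, b]),
        wilcoxon_signed_rank(a[: min(len(a), len(b))], b[: min(len(a), len(b))]),
    ]
    for res in results:
        assert 0.0 <= res.p_value <= 1.0
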