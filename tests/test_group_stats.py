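"""ANOVA, Duncan letter displays, and Kruskal-Wallis behavior."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from aromadrivers.group_stats import (
    GroupSummary,
    anova_oneway,
    duncan_letters,
    friedman,
    kruskal_wallis,
)


def summary(means, sds, n=3, labels=None):
    k = len(means)
    labels = labels or tuple(f"G{i + 1}" for i in range(k))
    return GroupSummary(tuple(labels), tuple(means), tuple(sds), (n,) * k)


class TestAnova:
    def test_identical_group_means_give_zero_f(self):
        res = anova_oneway(summary([5.0, 5.0, 5.0], [1.0, 2.0, 1.5]))
        assert res.f == 0.0
        assert res.p == 1.0

    def test_two_groups_f_equals_squared_pooled_t(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 3), rng.normal(1, 1, 3)
        res = anova_oneway({"a": a, "b": b})
        t, p_t = sps.ttest_ind(a, b)
        assert res.f == pytest.approx(t**2, rel=1e-10)
        assert res.p == pytest.approx(p_t, rel=1e-10)

    def test_summary_route_equals_raw_route(self):
        rng = np.random.default_rng(11)
        groups = {f"G{i}": rng.normal(i, 1.0, 4) for i in range(4)}
        raw = anova_oneway(groups)
        summ = anova_oneway(GroupSummary.from_raw(groups))
        assert summ.f == pytest.approx(raw.f, rel=1e-10)
        assert summ.ms_error == pytest.approx(raw.ms_error, rel=1e-10)
        # independent cross-check against scipy's raw-data ANOVA
        f_sp, p_sp = sps.f_oneway(*groups.values())
        assert raw.f == pytest.approx(float(f_sp), rel=1e-10)
        assert raw.p == pytest.approx(float(p_sp), rel=1e-10)

    def test_single_replicate_group_rejected(self):
        with pytest.raises(ValueError):
            GroupSummary(("a", "b"), (1.0, 2.0), (0.1, 0.1), (1, 3))


def oracle_pairwise_significance(s: GroupSummary, alpha=0.05):
    """Brute-force Duncan decisions: every pair compared against the critical
    range for the span it covers in the ordered means."""
    res = anova_oneway(s)
    n = s.ns[0]
    order = np.argsort(s.means, kind="stable")
    rank_of = {s.labels[i]: r for r, i in enumerate(order)}
    sig = {}
    for la, lb in combinations(s.labels, 2):
        ra, rb = sorted((rank_of[la], rank_of[lb]))
        p = rb - ra + 1
        q = sps.studentized_range.ppf((1 - alpha) ** (p - 1), p, res.df_within)
        r_crit = q * np.sqrt(res.ms_error / n)
        diff = abs(
            s.means[s.labels.index(la)] - s.means[s.labels.index(lb)]
        )
        sig[frozenset((la, lb))] = diff > r_crit
    return sig


class TestDuncanLetters:
    def test_identical_groups_share_letter_a(self):
        letters = duncan_letters(summary([4.0, 4.0, 4.0], [0.5, 0.5, 0.5]))
        assert set(letters.values()) == {"a"}

    def test_widely_separated_groups_get_distinct_letters(self):
        letters = duncan_letters(
            summary([0.0, 100.0], [1.0, 1.0], labels=("low", "high"))
        )
        assert letters == {"low": "a", "high": "b"}

    def test_smallest_mean_gets_letter_a(self):
        letters = duncan_letters(
            summary([30.0, 10.0, 10.1], [0.5, 0.5, 0.5],
                    labels=("big", "small", "mid"))
        )
        assert "a" in letters["small"]
        assert "a" not in letters["big"]

    def test_three_group_toy_matches_pairwise_oracle(self):
        s = summary([10.0, 10.1, 30.0], [0.5, 0.5, 0.5])
        letters = duncan_letters(s)
        for pair, significant in oracle_pairwise_significance(s).items():
            la, lb = sorted(pair)
            shares = bool(set(letters[la]) & set(letters[lb]))
            assert shares != significant, (pair, letters)

    @pytest.mark.parametrize("seed", range(12))
    def test_random_six_group_toys_match_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = summary(
            means=list(rng.uniform(0, 8, 6)),
            sds=list(rng.uniform(0.3, 2.0, 6)),
            n=3,
        )
        letters = duncan_letters(s)
        for pair, significant in oracle_pairwise_significance(s).items():
            la, lb = sorted(pair)
            shares = bool(set(letters[la]) & set(letters[lb]))
            assert shares != significant, (pair, letters)

    def test_acetic_acid_row_is_one_letter_group(self, bundle):
        # huge replicate sds swamp the product differences for acetic acid
        row = bundle.concentrations.mean[19]
        sds = bundle.concentrations.sd[19]
        s = GroupSummary(
            tuple(row.index), tuple(row), tuple(sds), (3,) * len(row)
        )
        letters = duncan_letters(s)
        assert set(letters.values()) == {"a"}

    def test_equal_means_never_split(self):
        letters = duncan_letters(summary([5.0, 5.0, 9.0], [0.1, 0.1, 0.1]))
        assert letters["G1"] == letters["G2"]

    def test_two_groups_match_fisher_lsd_decision(self):
        # with k = 2 Duncan's critical range reduces to the LSD at alpha
        for means in ([0.0, 1.0], [0.0, 3.0]):
            s = summary(means, [1.0, 1.0], n=3)
            letters = duncan_letters(s)
            res = anova_oneway(s)
            t_crit = sps.t.ppf(0.975, res.df_within)
            lsd = t_crit * np.sqrt(2 * res.ms_error / 3)
            split = abs(means[1] - means[0]) > lsd
            assert (letters["G1"] != letters["G2"]) == split

    def test_unbalanced_design_rejected_with_guidance(self):
        s = GroupSummary(("a", "b"), (1.0, 2.0), (0.1, 0.1), (3, 4))
        with pytest.raises(ValueError, match="equal group sizes"):
            duncan_letters(s)


class TestKruskalWallis:
    def test_identical_distributions_give_zero_h(self):
        scores = pd.DataFrame({"A": [1, 4, 7, 3], "B": [7, 3, 1, 4]})
        h, p = kruskal_wallis(scores)
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_all_identical_values_degenerate_case(self):
        scores = pd.DataFrame({"A": [4, 4], "B": [4, 4]})
        assert kruskal_wallis(scores) == (0.0, 1.0)

    def test_exact_p_matches_permutation_oracle(self):
        scores = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [4.0, 5.0, 6.0]})
        h, p = kruskal_wallis(scores, method="exact")
        # oracle: for 2 groups KW is equivalent to the two-sided rank-sum
        # test; enumerate all C(6,3)=20 splits of ranks 1..6
        from itertools import combinations as comb

        obs = abs(1 + 2 + 3 - 3 * 3.5)
        extreme = sum(
            1
            for c in comb(range(1, 7), 3)
            if abs(sum(c) - 10.5) >= obs - 1e-12
        )
        assert p == pytest.approx(extreme / 20)

    def test_h_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = pd.DataFrame(
            rng.integers(1, 8, size=(20, 3)), columns=list("ABC")
        ).astype(float)
        h1, _ = kruskal_wallis(scores)
        h2, _ = kruskal_wallis(np.exp(scores) + 5)
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_empty_product_rejected(self):
        scores = pd.DataFrame({"A": [1.0, 2.0], "B": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="B"):
            kruskal_wallis(scores)

    def test_friedman_runs_on_complete_panel(self):
        rng = np.random.default_rng(5)
        scores = pd.DataFrame(
            rng.integers(1, 8, size=(15, 4)).astype(float), columns=list("ABCD")
        )
        stat, p = friedman(scores)
        assert stat >= 0 and 0 <= p <= 1
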