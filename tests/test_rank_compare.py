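"""Rankings, pairwise tests, FDR, and exact-permutation correlation
statistics against hand computations and exhaustive oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from citecascade.rank_compare import (
    MetricDistribution,
    as_rank_vector,
    build_distributions,
    fdr_adjust,
    kendall_w,
    load_ranking_csv,
    pairwise_tests,
    rank_correlation,
    rank_groups,
    ranks_from_scores,
)


def dist(group, values):
    return MetricDistribution(group, tuple(float(v) for v in values))


class TestBuildDistributions:
    def test_groups_split_and_missing_dropped(self):
        df = pd.DataFrame(
            {
                "specialty": ["A", "A", "A", "B", "B", "B"],
                "structural_depth": [1.0, 2.0, 3.0, np.nan, 5.0, 6.0],
            }
        )
        out = build_distributions(df, "structural_depth")
        assert [d.group for d in out] == ["A", "B"]
        assert out[0].values == (1.0, 2.0, 3.0)
        assert out[1].values == (5.0, 6.0)

    def test_all_undefined_group_excluded(self):
        df = pd.DataFrame(
            {"specialty": ["A", "B"], "structural_depth": [1.0, np.nan]}
        )
        out = build_distributions(df, "structural_depth")
        assert [d.group for d in out] == ["A"]

    def test_median_matches_hand_sorted_middle(self):
        df = pd.DataFrame({"specialty": ["A"] * 3, "size": [9.0, 1.0, 4.0]})
        (d,) = build_distributions(df, "size")
        assert d.median == 4.0

    def test_unknown_column_is_error(self):
        df = pd.DataFrame({"specialty": ["A"], "size": [1.0]})
        with pytest.raises(KeyError):
            build_distributions(df, "nope")


class TestRankGroups:
    def test_distinct_medians_no_tiebreak(self):
        out = rank_groups([dist("A", [5, 5]), dist("B", [3, 3]), dist("C", [1, 1])])
        assert out.labels() == ["A", "B", "C"]
        assert set(out.table["tie_break"]) == {"none"}

    def test_median_tie_broken_by_p75(self):
        # both medians 3; p75 of A = 3.75 > p75 of B = 3.25
        out = rank_groups([dist("B", [2, 3, 3, 4]), dist("A", [1, 3, 3, 6])])
        assert out.labels() == ["A", "B"]
        assert set(out.table["tie_break"]) == {"p75"}

    def test_identical_distributions_ordered_by_label(self):
        out = rank_groups([dist("b", [1, 2]), dist("a", [1, 2]), dist("c", [1, 2])])
        assert out.labels() == ["a", "b", "c"]
        assert set(out.table["tie_break"]) == {"label"}

    def test_order_is_total_for_adversarial_ties(self):
        groups = [dist(g, [1, 1, 1, 9]) for g in "zyxw"]
        out = rank_groups(groups)
        assert out.labels() == ["w", "x", "y", "z"]

    def test_ranks_start_at_one(self):
        out = rank_groups([dist("A", [5]), dist("B", [1])])
        assert out.ranks().tolist() == [1, 2]


class TestPairwiseTests:
    def test_five_groups_make_symmetric_ten_pair_matrix(self):
        rng = np.random.default_rng(0)
        dists = [dist(g, rng.normal(size=30)) for g in "ABCDE"]
        m = pairwise_tests(dists, test="mann_whitney")
        assert len(m.to_long()) == 10
        assert np.allclose(m.raw_p.values, m.raw_p.values.T, equal_nan=True)
        assert np.isnan(np.diag(m.raw_p.values)).all()

    @pytest.mark.parametrize("test", ["mann_whitney", "kolmogorov_smirnov"])
    def test_shifted_distributions_significant_after_fdr(self, test):
        rng = np.random.default_rng(1)
        a = dist("A", rng.normal(0, 1, size=200))
        b = dist("B", rng.normal(3, 1, size=200))  # 3 sd location shift
        m = pairwise_tests([a, b], test=test)
        assert bool(m.significant.at["A", "B"])
        assert m.adjusted_p.at["A", "B"] >= m.raw_p.at["A", "B"]

    def test_single_value_group_is_error_naming_group(self):
        with pytest.raises(ValueError, match="tiny"):
            pairwise_tests([dist("tiny", [1.0]), dist("B", [1, 2, 3])])

    def test_fewer_than_two_groups_is_error(self):
        with pytest.raises(ValueError):
            pairwise_tests([dist("A", [1, 2])])


class TestFdrAdjust:
    def test_hand_worked_example(self):
        assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.3]) == [0.3]

    def test_equal_ps_all_unchanged(self):
        assert fdr_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        raw = rng.uniform(size=25)
        adj = np.array(fdr_adjust(raw))
        assert (adj >= raw - 1e-15).all() and (adj <= 1).all()
        order_raw = np.argsort(raw, kind="stable")
        assert (np.diff(adj[order_raw]) >= -1e-15).all()

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


def brute_force_perm_p(a, b, coef):
    """Two-sided permutation p by exhaustive enumeration with scipy."""
    obs = coef(a, b)
    n = len(b)
    count = sum(
        1
        for perm in itertools.permutations(b)
        if abs(coef(a, list(perm))) >= abs(obs) - 1e-12
    )
    return obs, count / math.factorial(n)


class TestRankCorrelation:
    def test_identical_rankings_coefficient_one(self):
        r = rank_correlation(list("abcde"), list("abcde"))
        assert r.coefficient == pytest.approx(1.0)

    def test_reversed_rankings_coefficient_minus_one(self):
        r = rank_correlation(list("abcde"), list("edcba"), method="kendall_tau")
        assert r.coefficient == pytest.approx(-1.0)

    @pytest.mark.parametrize("method, scipy_fn", [
        ("spearman", lambda a, b: stats.spearmanr(a, b).statistic),
        ("kendall_tau", lambda a, b: stats.kendalltau(a, b).statistic),
    ])
    def test_exact_p_matches_exhaustive_enumeration(self, method, scipy_fn):
        """At n = 4, the exact p must equal brute force over all 24
        permutations, and the coefficient must match scipy."""
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.0, 1.0, 4.0, 3.0]
        labels = list("wxyz")
        r = rank_correlation(
            dict(zip(labels, a)), dict(zip(labels, b)), method=method
        )
        obs, p = brute_force_perm_p(a, b, scipy_fn)
        assert r.coefficient == pytest.approx(obs)
        assert r.p_value == pytest.approx(p)
        assert r.p_mode == "enumeration" and r.n_permutations == 24

    def test_midrank_ties_match_scipy_coefficient(self):
        a = {"a": 1.0, "b": 2.5, "c": 2.5, "d": 4.0}
        b = {"a": 2.0, "b": 1.0, "c": 3.5, "d": 3.5}
        labels = sorted(a)
        r = rank_correlation(a, b, method="spearman")
        expected = stats.spearmanr(
            [a[l] for l in labels], [b[l] for l in labels]
        ).statistic
        assert r.coefficient == pytest.approx(expected)

    def test_monte_carlo_agrees_with_enumeration(self):
        """For n ≤ 6 the Monte-Carlo p must land within 3 standard errors
        of the exact enumerated p."""
        a = dict(zip("abcdef", [1, 2, 3, 4, 5, 6]))
        b = dict(zip("abcdef", [2, 1, 3, 5, 4, 6]))
        exact = rank_correlation(a, b)
        mc = rank_correlation(a, b, exact_threshold=0, mc_reps=100_000, seed=11)
        assert mc.p_mode == "monte_carlo" and mc.seed == 11
        se = math.sqrt(exact.p_value * (1 - exact.p_value) / 100_000)
        assert abs(mc.p_value - exact.p_value) <= 3 * se

    def test_monte_carlo_reproducible_given_seed(self):
        a = dict(zip("abcdefghij", range(1, 11)))
        b = dict(zip("abcdefghij", [3, 1, 2, 5, 4, 7, 6, 9, 10, 8]))
        r1 = rank_correlation(a, b, mc_reps=20_000, seed=5)
        r2 = rank_correlation(a, b, mc_reps=20_000, seed=5)
        assert r1.p_value == r2.p_value and r1.p_mode == "monte_carlo"

    def test_monte_carlo_without_seed_is_error(self):
        a = dict(zip("abcdefghij", range(1, 11)))
        with pytest.raises(ValueError, match="seed"):
            rank_correlation(a, a, exact_threshold=2, seed=None)

    def test_label_mismatch_lists_difference(self):
        with pytest.raises(ValueError, match="only in first"):
            rank_correlation(list("abc"), list("abd"))


def w_oracle(R):
    """W via the mean pairwise Spearman identity for untied rankings:
    W = ((m − 1) · mean_rho + 1) / m."""
    m = len(R)
    rhos = [
        stats.spearmanr(R[i], R[j]).statistic
        for i in range(m)
        for j in range(i + 1, m)
    ]
    return ((m - 1) * float(np.mean(rhos)) + 1) / m


class TestKendallW:
    def test_identical_untied_rankings_give_one(self):
        r = kendall_w([list("abcd")] * 3)
        assert r.coefficient == pytest.approx(1.0)

    def test_two_reversed_rankings_give_zero(self):
        r = kendall_w([list("abcd"), list("dcba")])
        assert r.coefficient == pytest.approx(0.0)

    def test_matches_pairwise_spearman_identity_oracle(self):
        rng = np.random.default_rng(8)
        n, m = 5, 3
        R = [list(rng.permutation(np.arange(1, n + 1))) for _ in range(m)]
        labels = list("abcde")
        r = kendall_w(
            [dict(zip(labels, row)) for row in R],
            enumeration_cap=0, seed=1,
        )
        assert r.coefficient == pytest.approx(w_oracle(R))

    def test_exact_p_matches_exhaustive_enumeration(self):
        """n = 4, m = 2: W and its one-sided p against brute force over
        all 24 permutations of the second ranking."""
        labels = list("wxyz")
        a = [1, 2, 3, 4]
        b = [2, 1, 3, 4]
        r = kendall_w([dict(zip(labels, a)), dict(zip(labels, b))])
        assert r.p_mode == "enumeration" and r.n_permutations == 24
        count = 0
        w_obs = w_oracle([a, b])
        for perm in itertools.permutations(b):
            if w_oracle([a, list(perm)]) >= w_obs - 1e-12:
                count += 1
        assert r.coefficient == pytest.approx(w_obs)
        assert r.p_value == pytest.approx(count / 24)

    def test_monte_carlo_mode_recorded_and_reproducible(self):
        labels = [f"g{i}" for i in range(10)]
        rng = np.random.default_rng(3)
        rankings = [
            dict(zip(labels, rng.permutation(np.arange(1, 11))))
            for _ in range(3)
        ]
        r1 = kendall_w(rankings, mc_reps=20_000, seed=4)
        r2 = kendall_w(rankings, mc_reps=20_000, seed=4)
        assert r1.p_mode == "monte_carlo"
        assert r1.p_value == r2.p_value

    def test_label_mismatch_is_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            kendall_w([list("abc"), list("abd")])


class TestRankVectors:
    def test_ordered_labels_become_ranks(self):
        v = as_rank_vector(["top", "mid", "low"])
        assert v["top"] == 1 and v["low"] == 3

    def test_scores_to_midranks(self):
        r = ranks_from_scores({"a": 10.0, "b": 5.0, "c": 5.0, "d": 1.0})
        assert r["a"] == 1.0 and r["b"] == r["c"] == 2.5 and r["d"] == 4.0

    def test_load_ranking_csv(self, tmp_path):
        path = tmp_path / "rank.csv"
        path.write_text("label,value\nA,12\nB,7\n")
        s = load_ranking_csv(path)
        assert s["A"] == 12.0 and s["B"] == 7.0
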