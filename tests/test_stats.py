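import itertools

import numpy as np
import pytest
from scipy import stats as sps

from conntraj import stats as st


def oracle_exact_friedman_p(wide):
    """Independent exact permutation oracle: permute each row's raw values
    across columns, recompute the tie-corrected statistic from scratch."""
    wide = np.asarray(wide, dtype=float)
    n, k = wide.shape

    def statistic(mat):
        ranks = np.array([sps.rankdata(row) for row in mat])
        col = ranks.sum(axis=0)
        A = (ranks ** 2).sum()
        C = n * k * (k + 1) ** 2 / 4
        if A - C <= 0:
            return 0.0
        return (k - 1) * ((col - n * (k + 1) / 2) ** 2).sum() / (A - C)

    obs = statistic(wide)
    perms = list(itertools.permutations(range(k)))
    count = total = 0
    for combo in itertools.product(perms, repeat=n):
        mat = np.array([wide[i, list(p)] for i, p in enumerate(combo)])
        total += 1
        if statistic(mat) >= obs - 1e-12:
            count += 1
    return count / total


class TestFriedman:
    def test_perfect_concordance_w_is_one(self):
        wide = np.array([[1, 5, 9, 12]] * 6, float) + np.arange(6)[:, None]
        res = st.friedman_test(wide, method="asymptotic")
        assert res.kendalls_w == pytest.approx(1.0)
        assert res.statistic == pytest.approx(6 * 3)  # n (k-1)

    def test_constant_rows_null(self):
        wide = np.full((5, 4), 7.0)
        res = st.friedman_test(wide, method="asymptotic")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy_asymptotic(self, rng):
        wide = rng.normal(size=(10, 4))
        res = st.friedman_test(wide, method="asymptotic")
        stat, p = sps.friedmanchisquare(*wide.T)
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)

    @pytest.mark.parametrize("data", [
        [[1, 2, 3], [1, 3, 2], [2, 1, 3], [1, 2, 3]],
        [[10, 12, 11], [9, 14, 13], [8, 8, 15], [7, 9, 11]],  # includes a tie
    ])
    def test_exact_matches_enumeration_oracle(self, data):
        wide = np.array(data, float)
        res = st.friedman_test(wide, method="exact")
        assert res.p_value == pytest.approx(oracle_exact_friedman_p(wide), abs=1e-12)

    def test_w_invariant_to_monotone_transform(self, rng):
        wide = rng.normal(size=(8, 4))
        w1 = st.friedman_test(wide, method="asymptotic").kendalls_w
        w2 = st.friedman_test(np.exp(wide), method="asymptotic").kendalls_w
        assert w1 == pytest.approx(w2)
        assert 0 <= w1 <= 1

    def test_missing_cells_rejected(self):
        wide = np.array([[1.0, 2, np.nan], [3, 2, 1]])
        with pytest.raises(ValueError, match="missing"):
            st.friedman_test(wide)


class TestDunnFriedman:
    def test_constant_matrix_all_adjusted_one(self):
        table = st.dunn_posthoc_friedman(np.full((5, 4), 3.0))
        assert (table["p_adjusted"] == 1.0).all()

    def test_monotone_trend_extreme_pair_smallest_p(self):
        base = np.arange(6, dtype=float)[:, None]
        wide = base + np.array([0.0, 10.0, 20.0, 30.0])
        table = st.dunn_posthoc_friedman(wide, level_names=list("abcd"))
        best = table.loc[table["p_adjusted"].idxmin()]
        assert {best["level_a"], best["level_b"]} == {"a", "d"}

    def test_bonferroni_identity_and_monotonicity(self, rng):
        wide = rng.normal(size=(8, 4))
        table = st.dunn_posthoc_friedman(wide)
        m = 6  # k(k-1)/2 pairs
        assert np.allclose(table["p_adjusted"],
                           np.minimum(1.0, table["p_raw"] * m))
        assert (table["p_adjusted"] >= table["p_raw"]).all()
        assert (table["p_adjusted"] <= 1).all()


class TestCompareClusters:
    def test_identical_values_stat_zero(self):
        res, post = st.compare_clusters_numeric({"1": [2.0, 2, 2], "2": [2.0, 2]})
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert post is None

    def test_two_groups_matches_rank_sum(self, rng):
        """With two clusters the Kruskal-Wallis p equals the two-sided
        rank-sum p (chi-square with 1 df = z squared)."""
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
        res, _ = st.compare_clusters_numeric({"a": a, "b": b}, posthoc="never")
        stat, p = sps.ranksums(a, b)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_posthoc_trigger_and_adjustment(self, rng):
        groups = {"1": rng.normal(0, 1, 10), "2": rng.normal(5, 1, 10),
                  "3": rng.normal(10, 1, 10)}
        res, post = st.compare_clusters_numeric(groups)
        assert res.p_value < 0.05
        assert post is not None
        assert (post["p_adjusted"] >= post["p_raw"]).all()

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            st.compare_clusters_numeric({"1": [1.0, 2.0]})

    def test_power_on_strongly_associated_ratings(self):
        """Ratings deterministically tied to cluster separate at n=22, K=5
        in at least 90% of seeds."""
        import pandas as pd
        from conntraj.synthetic import simulate_structural_ratings

        labels = pd.Series(
            np.repeat([1, 2, 3, 4, 5], [2, 5, 6, 3, 6]),
            index=[f"s{i}" for i in range(22)],
        )
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            df = simulate_structural_ratings(labels, 1.0, seed=seed)
            sub = df[df["tract_class"] == "CST"].set_index("subject_id")
            groups = {
                str(k): sub.loc[labels.index[labels == k], "integrity"].to_numpy(float)
                for k in range(1, 6)
            }
            res, _ = st.compare_clusters_numeric(groups)
            if res.p_value < 0.05:
                hits += 1
        assert hits >= 0.9 * n_seeds


class TestTwoGroupGate:
    def test_heavy_ties_choose_rank_sum(self):
        a = np.array([1.0, 1, 1, 1, 2, 2, 2])
        b = np.array([1.0, 1, 2, 2, 2, 2, 2])
        res = st.compare_two_groups_continuous(a, b)
        assert res.test_used == "wilcoxon_rank_sum"
        assert "shapiro_p_a" in res.gating_trace

    def test_normal_samples_choose_t_and_calibrate(self):
        """Two standard-normal samples usually pass the gate to a t-test, and
        the overall type-I error stays near 5%."""
        rng = np.random.default_rng(2024)
        t_chosen = rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a, b = rng.normal(size=(2, 50))
            res = st.compare_two_groups_continuous(a, b)
            t_chosen += res.test_used == "t_test"
            rejections += res.p_value < 0.05
        assert t_chosen > n_rep / 2
        assert abs(rejections / n_rep - 0.05) < 0.02

    def test_identical_groups_p_one(self):
        a = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        res = st.compare_two_groups_continuous(a, a.copy(), bonferroni_m=3)
        assert res.p_value == 1.0

    def test_bonferroni_applied(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(2, 1, 20)
        r1 = st.compare_two_groups_continuous(a, b, bonferroni_m=1)
        r4 = st.compare_two_groups_continuous(a, b, bonferroni_m=4)
        assert r4.p_value == pytest.approx(min(1.0, r1.p_value * 4))

    def test_tiny_group_skips_gate(self):
        res = st.compare_two_groups_continuous([1.0, 2.0], [3.0, 4.0, 5.0])
        assert res.test_used == "wilcoxon_rank_sum"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            st.compare_two_groups_continuous([], [1.0])


class TestCategoricalAssociation:
    def test_crossed_table_fisher_exact(self):
        res = st.categorical_association([[5, 0], [0, 5]])
        assert res.test_used == "fisher_exact"
        assert res.p_value == pytest.approx(2 / 252, abs=1e-12)

    def test_large_expected_uses_yates(self):
        res = st.categorical_association([[20, 30], [25, 25]])
        assert res.test_used == "chi_square_yates"
        stat, p, _, _ = sps.chi2_contingency([[20, 30], [25, 25]], correction=True)
        assert res.p_value == pytest.approx(p)

    def test_row_permutation_invariant(self):
        t = [[5, 1], [2, 8]]
        assert (st.categorical_association(t).p_value
                == pytest.approx(st.categorical_association(t[::-1]).p_value))

    def test_sparse_rxc_falls_back_with_warning(self):
        res = st.categorical_association([[3, 0, 1], [0, 4, 1], [1, 1, 2]])
        assert res.test_used == "chi_square"
        assert "warning" in res.gating_trace

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            st.categorical_association([[0, 0], [0, 0]])
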