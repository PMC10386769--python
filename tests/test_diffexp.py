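"""Differential expression: test statistics against independent oracles,
degenerate-input conventions, and pipeline-level properties."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import txplore as tx
from txplore.containers import DataError
from txplore.diffexp import _rank_sum_counts
from oracles import wilcoxon_two_sided_by_enumeration


class TestLog2FoldChange:
    def test_round_numbers(self):
        assert tx.log2_fold_change([3, 3], [1, 1], 1.0) == pytest.approx(1.0)

    def test_identity_and_antisymmetry(self, rng):
        a = rng.random(5) * 10
        b = rng.random(7) * 10
        assert tx.log2_fold_change(a, a.copy()) == 0.0
        assert tx.log2_fold_change(a, b) == pytest.approx(-tx.log2_fold_change(b, a))

    def test_empty_group_errors(self):
        with pytest.raises(DataError):
            tx.log2_fold_change([], [1.0])


class TestWelch:
    def test_identical_groups(self):
        t, _, p = tx.welch_t_test([1, 2, 3], [1, 2, 3])
        assert (t, p) == (0.0, 1.0)

    def test_hand_derived_example(self):
        t, df, p = tx.welch_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742, abs=1e-4)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.0213, abs=1e-3)

    def test_matches_scipy_to_1e10(self, rng):
        for _ in range(50):
            a = rng.normal(size=rng.integers(2, 12))
            b = rng.normal(loc=rng.normal(), size=rng.integers(2, 12))
            t, _, p = tx.welch_t_test(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_scale_invariance(self, rng):
        a, b = rng.random(4), rng.random(5)
        t1, _, p1 = tx.welch_t_test(a, b)
        t2, _, p2 = tx.welch_t_test(a * 3.7, b * 3.7)
        assert t1 == pytest.approx(t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_conventions(self):
        with pytest.raises(DataError):
            tx.welch_t_test([1.0], [1, 2])
        with pytest.warns(RuntimeWarning):
            t, _, p = tx.welch_t_test([2, 2], [5, 5])
        assert p == 0.0 and t < 0


class TestWilcoxon:
    def test_spec_example_exact(self):
        w, p = tx.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1)

    def test_all_tied_gives_p_one(self):
        _, p = tx.wilcoxon_rank_sum([5, 5, 5], [5, 5])
        assert p == 1.0

    @pytest.mark.parametrize("n_a,n_b", [(2, 2), (3, 4), (5, 5), (6, 6), (2, 6)])
    def test_exact_matches_enumeration_oracle(self, n_a, n_b, rng):
        for _ in range(20):
            a = rng.normal(size=n_a)
            b = rng.normal(loc=rng.normal(), size=n_b)
            _, p = tx.wilcoxon_rank_sum(a, b)
            assert p == pytest.approx(
                wilcoxon_two_sided_by_enumeration(a, b), abs=1e-12
            )

    def test_exact_matches_scipy_mannwhitney(self, rng):
        for _ in range(20):
            a = rng.normal(size=8)
            b = rng.normal(size=9)
            _, p = tx.wilcoxon_rank_sum(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_and_approximate_branches_agree(self, rng):
        # n=15 vs 15 untied: exact DP vs tie-corrected normal approximation
        diffs = []
        for _ in range(30):
            a = rng.normal(size=15)
            b = rng.normal(size=15)
            _, p_exact = tx.wilcoxon_rank_sum(a, b)
            # force the approximation branch on the same data
            from txplore import diffexp

            saved = diffexp.EXACT_WILCOXON_MAX
            try:
                diffexp.EXACT_WILCOXON_MAX = 0
                _, p_approx = tx.wilcoxon_rank_sum(a, b)
            finally:
                diffexp.EXACT_WILCOXON_MAX = saved
            diffs.append(abs(p_exact - p_approx))
        assert max(diffs) < 0.02

    def test_rank_sum_null_counts_total(self):
        # DP distribution sums to C(N, n) for several shapes
        import math

        for n, total in [(3, 6), (5, 10), (10, 20)]:
            assert _rank_sum_counts(n, total).sum() == math.comb(total, n)


class TestBenjaminiHochberg:
    def test_hand_applied_step_up(self):
        q = tx.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_all_ones(self):
        assert tx.benjamini_hochberg([0.3]) == pytest.approx([0.3])
        assert np.allclose(tx.benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(200)
        q = tx.benjamini_hochberg(p)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_ref, atol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_each_input(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(20)
        q = tx.benjamini_hochberg(p)
        i = rng.integers(0, 20)
        p2 = p.copy()
        p2[i] *= rng.random()  # decrease one p
        q2 = tx.benjamini_hochberg(p2)
        assert (q2 <= q + 1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(DataError):
            tx.benjamini_hochberg([0.5, 1.5])


class TestRunDifferentialExpression:
    def test_counts_are_refused(self, bundle):
        with pytest.raises(DataError, match="normaliz"):
            tx.run_differential_expression(bundle.matrix, bundle.groups, "A", "B")

    def test_same_label_twice_errors(self, cpm_matrix, bundle):
        with pytest.raises(DataError):
            tx.run_differential_expression(cpm_matrix, bundle.groups, "A", "A")

    def test_planted_gene_attains_minimum_q(self, rng):
        n = 60
        values = rng.lognormal(3, 0.2, size=(n, 8))
        values[0, :4] *= 100  # planted: high in A, near-baseline in B
        frame = pd.DataFrame(
            values,
            index=[f"g{i:03d}" for i in range(n)],
            columns=[f"s{j}" for j in range(8)],
        )
        matrix = tx.ExpressionMatrix(frame, "CPM")
        groups = tx.SampleGroups(
            {"A": [f"s{j}" for j in range(4)], "B": [f"s{j}" for j in range(4, 8)]}
        )
        de = tx.run_differential_expression(matrix, groups, "A", "B", "welch")
        best = de.table.loc[de.table["q_value"].idxmin(), "gene"]
        assert best == "g000"

    def test_all_zero_gene_dropped_and_counted(self, bundle, cpm_matrix):
        values = cpm_matrix.data.copy()
        values.iloc[5, :] = 0.0
        matrix = tx.ExpressionMatrix(values, "CPM")
        de = tx.run_differential_expression(matrix, bundle.groups, "A", "B")
        assert de.n_dropped_all_zero == 1
        assert len(de.table) == matrix.n_genes - 1

    def test_label_swap_flips_effect_and_keeps_p(self, cpm_matrix, bundle):
        de_ab = tx.run_differential_expression(cpm_matrix, bundle.groups, "A", "B", "welch")
        de_ba = tx.run_differential_expression(cpm_matrix, bundle.groups, "B", "A", "welch")
        assert np.allclose(
            de_ab.table["log2_fold_change"], -de_ba.table["log2_fold_change"]
        )
        assert np.allclose(de_ab.table["statistic"], -de_ba.table["statistic"])
        assert np.allclose(de_ab.table["p_value"], de_ba.table["p_value"], atol=1e-12)
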