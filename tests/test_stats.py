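"""Statistical stages against hand-coded oracles and reference formulas."""

import numpy as np
import pytest
from scipy import stats as sps

from sccmet.stats import (
    anova_tukey_bonferroni,
    bh_adjust,
    ddct_relative_expression,
    log_ratio,
    paired_t,
    welch_t_logratio,
)


def _reference_paired_t(x, y):
    d = np.asarray(x) - np.asarray(y)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    return t, 2 * sps.t.sf(abs(t), n - 1)


def _reference_welch(a, b):
    a, b = np.asarray(a), np.asarray(b)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    return t, 2 * sps.t.sf(abs(t), df)


class TestPairedT:
    def test_identical_pairs_give_null_result(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0
        assert res.flag == "zero-variance"

    def test_constant_nonzero_difference_degenerate_path(self):
        res = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.pvalue == 0.0 and np.isinf(res.statistic)
        assert res.flag == "zero-variance"

    def test_agrees_with_reference_formula(self, rng):
        for _ in range(200):
            n = rng.integers(3, 20)
            x, y = rng.standard_normal(n), rng.standard_normal(n)
            res = paired_t(x, y)
            t_ref, p_ref = _reference_paired_t(x, y)
            assert res.statistic == pytest.approx(t_ref, abs=1e-10)
            assert res.pvalue == pytest.approx(p_ref, abs=1e-8)

    def test_type_one_error_near_nominal(self, rng):
        n_rep, n = 4000, 10
        x = rng.standard_normal((n_rep, n))
        y = rng.standard_normal((n_rep, n))
        d = x - y
        t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n))
        p = 2 * sps.t.sf(np.abs(t), n - 1)
        rate = (p < 0.05).mean()
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)
        # vectorised null agrees with the scalar implementation
        res = paired_t(x[0], y[0])
        assert res.pvalue == pytest.approx(p[0], abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])


class TestWelch:
    def test_identical_groups_null(self):
        res = welch_t_logratio([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_agrees_with_reference_formula(self, rng):
        for _ in range(200):
            a = rng.standard_normal(rng.integers(3, 15))
            b = rng.standard_normal(rng.integers(3, 15)) * rng.uniform(0.5, 2)
            res = welch_t_logratio(a, b)
            t_ref, p_ref = _reference_welch(a, b)
            assert res.statistic == pytest.approx(t_ref, abs=1e-10)
            assert res.pvalue == pytest.approx(p_ref, abs=1e-8)

    def test_approaches_pooled_t_for_equal_variances(self, rng):
        a = rng.standard_normal(400)
        b = rng.standard_normal(400) + 0.1
        welch = welch_t_logratio(a, b)
        pooled = sps.ttest_ind(a, b, equal_var=True)
        assert welch.statistic == pytest.approx(pooled.statistic, rel=1e-3)
        assert welch.pvalue == pytest.approx(pooled.pvalue, rel=1e-2)

    def test_log_ratio_drops_incomplete_pairs(self):
        lr = log_ratio([2.0, 4.0, np.nan, -1.0], [1.0, 2.0, 1.0, 1.0])
        np.testing.assert_allclose(lr, [1.0, 1.0])


class TestAnovaTukey:
    def test_identical_groups_flat(self):
        g = {"NC": [1.0, 1.0, 1.0], "AdC": [1.0, 1.0, 1.0],
             "SCC": [1.0, 1.0, 1.0]}
        res = anova_tukey_bonferroni(g, n_genes_tested=10)
        assert res.f_statistic == 0.0
        assert all(p == 1.0 for p, padj in res.comparisons.values())

    def test_bonferroni_identity_when_one_gene(self, rng):
        g = {"NC": rng.standard_normal(8), "SCC": rng.standard_normal(8) + 2}
        res = anova_tukey_bonferroni(g, n_genes_tested=1)
        p, padj = res.comparisons[("NC", "SCC")]
        assert padj == p

    def test_matches_r_tukey_hsd(self):
        # oracle from R: TukeyHSD(aov(y ~ g)) on the fixed data below
        g = {
            "a": np.array([1.0, 2.0, 3.0, 4.0]),
            "b": np.array([2.0, 3.0, 4.0, 5.0]),
            "c": np.array([5.0, 6.0, 7.0, 8.0]),
        }
        res = anova_tukey_bonferroni(g)
        assert res.comparisons[("a", "b")][0] == pytest.approx(0.5402482,
                                                               abs=1e-6)
        assert res.comparisons[("a", "c")][0] == pytest.approx(0.0045122,
                                                               abs=1e-6)
        assert res.comparisons[("b", "c")][0] == pytest.approx(0.0231730,
                                                               abs=1e-6)

    def test_familywise_error_bounded(self, rng):
        # Tukey HSD at alpha=0.05: P(any pairwise rejection) under the null
        n_rep, n, k = 3000, 10, 3
        crit = sps.studentized_range.ppf(0.95, k, k * n - k)
        data = rng.standard_normal((n_rep, k, n))
        means = data.mean(axis=2)
        sse = ((data - means[..., None]) ** 2).sum(axis=(1, 2))
        mse = sse / (k * n - k)
        q = (means.max(axis=1) - means.min(axis=1)) / np.sqrt(mse / n)
        fwer = (q > crit).mean()
        assert abs(fwer - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)
        # the package's per-dataset p agrees with the q/crit decision
        for i in range(40):
            res = anova_tukey_bonferroni(
                {f"g{j}": data[i, j] for j in range(k)}
            )
            min_p = min(p for p, _ in res.comparisons.values())
            assert (min_p < 0.05) == (q[i] > crit)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey_bonferroni({"a": [1.0, 2.0], "b": [1.0]})


class TestAdjustments:
    def test_bh_step_up_hand_computation(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_bh_identity_cases(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)
        np.testing.assert_allclose(bh_adjust([0.031]), [0.031])

    def test_bh_monotone_in_rank(self, rng):
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestDdct:
    @pytest.mark.parametrize("dct,expected", [(5.0, 1.0), (4.0, 2.0),
                                              (6.0, 0.5)])
    def test_relative_expression(self, dct, expected):
        out = ddct_relative_expression([dct + 20.0], [20.0],
                                       control_mean_dct=5.0)
        assert out[0] == pytest.approx(expected)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ValueError):
            ddct_relative_expression([np.nan], [20.0], 5.0)
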