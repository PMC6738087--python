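"""Gene filtering, normalisation, clustering, PCA and signature selection."""

import numpy as np
import pandas as pd
import pytest

from sccmet.signature import (
    ExpressionCohort,
    SignatureModel,
    filter_metabolic_genes,
    hierarchical_cluster,
    normalize_to_nc_median,
    overlap_top_genes,
    run_pca,
    select_signature,
    signature_score,
    uncentered_correlation_distance,
)
from sccmet.simulate import CohortSpec, generate_annotation, generate_expression_cohort


class TestFilter:
    def _cohort(self, genes):
        samples = ["S0", "S1", "S2", "S3"]
        matrix = pd.DataFrame(1.0, index=genes, columns=samples)
        meta = pd.DataFrame({"tissue": ["NC", "NC", "NC", "SCC"]},
                            index=pd.Index(samples, name="sample_id"))
        return ExpressionCohort(matrix, meta)

    def test_keeps_catalytic_with_class_drops_others(self):
        ann = pd.DataFrame(
            {"catalytic": [1, 1, 0], "classes": ["sugar", "", "nucleotide"]},
            index=["KEEP", "NOCLASS", "NOCAT"],
        )
        out = filter_metabolic_genes(self._cohort(["KEEP", "NOCLASS",
                                                   "NOCAT"]), ann)
        assert list(out.matrix.index) == ["KEEP"]

    def test_empty_result_raises(self):
        ann = pd.DataFrame({"catalytic": [0], "classes": ["sugar"]},
                           index=["A"])
        with pytest.raises(ValueError, match="no genes"):
            filter_metabolic_genes(self._cohort(["A"]), ann)

    def test_unknown_class_rejected(self):
        ann = pd.DataFrame({"catalytic": [1], "classes": ["lipids"]},
                           index=["A"])
        with pytest.raises(ValueError, match="unknown"):
            filter_metabolic_genes(self._cohort(["A"]), ann)


class TestNormalise:
    def test_nc_median_is_exactly_one(self, tiny_cohort):
        ratios = normalize_to_nc_median(tiny_cohort)
        nc = tiny_cohort.samples_of("NC")
        np.testing.assert_allclose(ratios[nc].median(axis=1), 1.0)
        # GENE_UP: NC values (1,2,3), median 2
        np.testing.assert_allclose(
            ratios.loc["GENE_UP", nc], [0.5, 1.0, 1.5]
        )
        # tumour value 4 / NC median 2 = 2
        assert ratios.loc["GENE_UP", "S6"] == pytest.approx(2.0)
        np.testing.assert_allclose(ratios.loc["GENE_FLAT"], 1.0)


class TestClustering:
    def test_identical_rows_merge_at_zero_distance(self):
        X = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                          [-1.0, 5.0, 0.1]], index=["a", "b", "c"])
        res = hierarchical_cluster(X, k=2)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert res.labels["a"] == res.labels["b"] != res.labels["c"]

    def test_anticorrelated_rows_at_maximal_distance(self):
        X = np.array([[1.0, -2.0, 3.0], [-1.0, 2.0, -3.0]])
        d = uncentered_correlation_distance(X)
        assert d[0] == pytest.approx(2.0)

    def test_planted_two_blocks_recovered_noise_free(self):
        rng = np.random.default_rng(0)
        pattern1 = rng.standard_normal(20)
        pattern2 = rng.standard_normal(20)
        X = pd.DataFrame(
            [pattern1 * s for s in (1.0, 1.1, 0.9, 1.05)]
            + [pattern2 * s for s in (1.0, 0.95, 1.2, 1.1)],
            index=[f"g{i}" for i in range(8)],
        )
        labels = hierarchical_cluster(X, k=2).labels
        assert len(set(labels[:4])) == 1
        assert len(set(labels[4:])) == 1
        assert labels.iloc[0] != labels.iloc[-1]


class TestPCA:
    def test_line_data_explains_everything_on_pc1(self):
        t = np.linspace(-1, 1, 10)
        X = pd.DataFrame(np.outer([2.0, -1.0, 0.5], t),
                         index=["a", "b", "c"], columns=[f"s{i}" for i in range(10)])
        res = run_pca(X)
        assert res.r2x[0] == pytest.approx(1.0)

    def test_loadings_are_unit_norm_and_r2x_monotone(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((15, 12)))
        res = run_pca(X)
        np.testing.assert_allclose(
            np.linalg.norm(res.loadings.to_numpy(), axis=0), 1.0
        )
        assert np.all(np.diff(res.r2x) <= 1e-12)
        assert res.r2x.sum() <= 1.0 + 1e-9

    def test_isotropic_noise_spreads_variance(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((30, 200)))
        res = run_pca(X)
        # no component should dominate white noise
        assert res.r2x[0] < 3.0 / 30


class TestSelection:
    def test_flags_intersection_contract(self):
        spec = CohortSpec(seed=21, n_genes=80, n_nc=20, n_adc=15, n_scc=15,
                          noise_sd=0.4)
        cohort = generate_expression_cohort(spec)
        ratios = normalize_to_nc_median(cohort)
        logr = np.log2(ratios)
        clustering = hierarchical_cluster(logr, k=6)
        pca = run_pca(logr)
        res = select_signature(pca, clustering, logr, cohort.tissue)
        f = res.flags
        all_three = f["criterion1"] & f["criterion2"] & f["criterion3"]
        assert set(res.genes) == set(f.index[all_three])
        # a gene failing any criterion is excluded
        failing = f.index[~all_three]
        assert not set(res.genes) & set(failing)

    def test_pipeline_invariant_to_gene_and_sample_order(self):
        spec = CohortSpec(seed=33, n_genes=70, n_nc=15, n_adc=10, n_scc=10)
        cohort = generate_expression_cohort(spec)
        res1 = SignatureModel(cohort).fit()
        rng = np.random.default_rng(0)
        gperm = rng.permutation(cohort.matrix.index)
        sperm = rng.permutation(cohort.matrix.columns)
        shuffled = ExpressionCohort(
            cohort.matrix.loc[gperm, sperm],
            cohort.metadata.loc[sperm],
        )
        res2 = SignatureModel(shuffled).fit()
        assert set(res1.genes) == set(res2.genes)


class TestOverlap:
    def test_three_of_four_rule(self):
        lists = [
            ["A", "B"] + [f"x{i}" for i in range(38)],
            ["A", "C"] + [f"y{i}" for i in range(38)],
            ["A", "B"] + [f"z{i}" for i in range(38)],
            ["D", "E"] + [f"w{i}" for i in range(38)],
        ]
        out = overlap_top_genes(lists, top_frac=0.05, min_lists=3)
        assert out == {"A"}  # top-5% of 40 = 2 genes; B only in 2 lists

    def test_identical_lists_return_their_head(self):
        ranked = [f"g{i}" for i in range(100)]
        out = overlap_top_genes([ranked] * 4, top_frac=0.05, min_lists=3)
        assert out == set(ranked[:5])

    def test_too_few_lists_rejected(self):
        with pytest.raises(ValueError):
            overlap_top_genes([["a"], ["b"]], min_lists=3)


class TestScore:
    def test_all_unity_ratios_score_zero(self):
        ratios = pd.DataFrame(1.0, index=["g1", "g2"],
                              columns=[f"s{i}" for i in range(6)])
        out = signature_score(ratios, ["g1", "g2"])
        np.testing.assert_allclose(out["score"], 0.0)

    def test_doubled_sample_scores_one_log2_unit(self):
        ratios = pd.DataFrame(1.0, index=["g1", "g2"],
                              columns=[f"s{i}" for i in range(9)])
        ratios["s0"] = 2.0
        out = signature_score(ratios, ["g1", "g2"])
        assert out.loc["s0", "score"] == pytest.approx(1.0)
        assert bool(out.loc["s0", "upper_tertile"])

    def test_nine_samples_flag_exactly_three(self):
        rng = np.random.default_rng(8)
        ratios = pd.DataFrame(
            2.0 ** rng.standard_normal((3, 9)),
            index=["a", "b", "c"], columns=[f"s{i}" for i in range(9)],
        )
        out = signature_score(ratios, ["a", "b", "c"])
        assert int(out["upper_tertile"].sum()) == 3

    def test_missing_signature_rejected(self):
        ratios = pd.DataFrame(1.0, index=["g1"], columns=["s1"])
        with pytest.raises(ValueError):
            signature_score(ratios, ["nope"])
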