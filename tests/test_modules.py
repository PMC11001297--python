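import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from dopavuln.clustering import normalize_log
from dopavuln.modules import (
    ScoreLossRegression,
    compare_scores,
    de_wilcoxon,
    score_module,
    select_module_genes,
)

from conftest import make_adata


def norm_adata(counts, symbols=None):
    return normalize_log(make_adata(counts, symbols=symbols))


class TestDeWilcoxon:
    def test_all_vs_none_gene_is_extreme(self):
        # gene expressed in every target nucleus, none of the reference
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(100, 10)) + 1
        counts[:50, 0] = rng.poisson(20, size=50) + 5
        counts[50:, 0] = 0
        adata = norm_adata(counts)
        mask = np.zeros(100, dtype=bool)
        mask[:50] = True
        out = de_wilcoxon(adata, mask)
        assert "G0" in out.index
        assert out.loc["G0", "avg_log2FC"] > 0
        # exact rank-sum tail for complete separation at n=50/50 is far below
        # any Bonferroni threshold; the normal approximation must agree
        assert out.loc["G0", "p_adj"] < 1e-10
        assert out.loc["G0", "pct_in"] == 1.0 and out.loc["G0", "pct_out"] == 0.0

    def test_identical_distribution_excluded_by_logfc_threshold(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5, size=(80, 5)) + 1
        adata = norm_adata(counts)
        mask = np.zeros(80, dtype=bool)
        mask[:40] = True
        out = de_wilcoxon(adata, mask, logfc_threshold=0.25)
        assert len(out) == 0

    def test_rarely_detected_gene_excluded_by_min_pct(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(5, size=(100, 4)) + 1
        counts[:, 0] = 0
        counts[::25, 0] = 50  # detected in 4% of both groups, huge FC
        adata = norm_adata(counts)
        mask = np.zeros(100, dtype=bool)
        mask[:50] = True
        out = de_wilcoxon(adata, mask, min_pct=0.1)
        assert "G0" not in out.index

    def test_pvalue_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(4, size=(60, 3)) + 1
        counts[:30, 1] += 6
        adata = norm_adata(counts)
        mask = np.zeros(60, dtype=bool)
        mask[:30] = True
        out = de_wilcoxon(adata, mask, logfc_threshold=0.0, min_pct=0.0)
        dense = np.asarray(adata.X.todense())
        _, p_ref = mannwhitneyu(
            dense[:30, 1], dense[30:, 1], alternative="two-sided", method="asymptotic"
        )
        assert out.loc["G1", "p"] == pytest.approx(p_ref, rel=1e-12)
        assert out.loc["G1", "p_adj"] == pytest.approx(min(1.0, p_ref * 3), rel=1e-12)

    def test_empty_group_rejected(self):
        adata = norm_adata(np.ones((10, 3), dtype=int))
        with pytest.raises(ValueError, match="nonempty"):
            de_wilcoxon(adata, np.zeros(10, dtype=bool))


def de_table(genes, fc, p_adj):
    return pd.DataFrame({"avg_log2FC": fc, "p_adj": p_adj, "p": p_adj, "pct_in": 1.0,
                         "pct_out": 0.5}, index=genes)


class TestSelectModuleGenes:
    def losses(self):
        return pd.Series({0: 0.95, 1: 0.93, 2: 0.6, 3: 0.2})

    def test_commonly_means_every_qualifying_cluster(self):
        de = {
            0: de_table(["A", "B", "C"], [1.0, 1.0, 1.0], [1e-4] * 3),
            1: de_table(["A", "B"], [0.8, 0.3], [1e-4, 1e-4]),  # B fails FC in cluster 1
        }
        mod = select_module_genes(self.losses(), de, "vulnerability")
        assert mod.genes == ["A"]
        assert mod.input_clusters == [0, 1]

    def test_ranking_by_mean_log2fc_descending(self):
        de = {
            0: de_table(["A", "B"], [1.0, 1.4], [1e-4] * 2),
            1: de_table(["A", "B"], [0.6, 1.0], [1e-4] * 2),
        }
        mod = select_module_genes(self.losses(), de, "vulnerability")
        assert mod.genes == ["B", "A"]  # means 1.2 vs 0.8

    def test_truncation_and_tie_break(self):
        genes = [f"g{i}" for i in range(5)]
        de = {0: de_table(genes, [1.0] * 5, [1e-4] * 5), 1: de_table(genes, [1.0] * 5, [1e-4] * 5)}
        mod = select_module_genes(self.losses(), de, "vulnerability", top_n=3)
        assert mod.genes == ["g0", "g1", "g2"]  # lexicographic among ties

    def test_monotone_in_log2fc_cutoff(self):
        de = {
            0: de_table(["A", "B", "C"], [1.5, 0.9, 0.6], [1e-4] * 3),
            1: de_table(["A", "B", "C"], [1.2, 0.8, 0.55], [1e-4] * 3),
        }
        lo = select_module_genes(self.losses(), de, "vulnerability", log2fc_cutoff=0.5)
        hi = select_module_genes(self.losses(), de, "vulnerability", log2fc_cutoff=0.85)
        assert set(hi.genes) <= set(lo.genes)

    def test_resilience_uses_low_loss_clusters_and_top8_default(self):
        losses = pd.Series({0: 0.95, 1: 0.3, 2: 0.4})
        genes = [f"r{i}" for i in range(12)]
        de = {
            1: de_table(genes, np.linspace(2, 0.9, 12), [1e-4] * 12),
            2: de_table(genes, np.linspace(2, 0.9, 12), [1e-4] * 12),
        }
        mod = select_module_genes(losses, de, "resilience")
        assert len(mod.genes) == 8
        assert mod.input_clusters == [1, 2]

    def test_excluded_gene_dropped(self):
        de = {
            0: de_table(["Slc6a3", "A"], [2.0, 1.0], [1e-4] * 2),
            1: de_table(["Slc6a3", "A"], [2.0, 1.0], [1e-4] * 2),
        }
        mod = select_module_genes(self.losses(), de, "vulnerability", exclude_gene="Slc6a3")
        assert mod.genes == ["A"] and mod.excluded_gene == "Slc6a3"

    def test_no_qualifying_cluster_raises(self):
        with pytest.raises(ValueError, match="loss cutoff"):
            select_module_genes(pd.Series({0: 0.5}), {}, "vulnerability")

    def test_no_common_genes_gives_empty_module(self):
        de = {
            0: de_table(["A"], [1.0], [1e-4]),
            1: de_table(["B"], [1.0], [1e-4]),
        }
        mod = select_module_genes(self.losses(), de, "vulnerability")
        assert mod.genes == []


class TestScoreModule:
    def test_score_zero_when_controls_equal_signal(self):
        # two bins; module genes expressed identically to their bin-mates
        rng = np.random.default_rng(0)
        lo = rng.poisson(2, size=(40, 1))
        counts = np.hstack([np.tile(lo, (1, 4)), np.tile(lo * 10 + 1, (1, 4))])
        adata = norm_adata(counts)
        scores = score_module(adata, ["G5"], n_bins=2, n_ctrl=3, seed=0)
        assert np.allclose(scores.to_numpy(), 0.0, atol=1e-10)

    def test_upscaling_module_gene_increases_score(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5, size=(30, 12)) + 1
        boosted = counts.copy()
        boosted[0, 0] *= 4
        s0 = score_module(norm_adata(counts), ["G0"], n_bins=3, n_ctrl=3, seed=2)
        s1 = score_module(norm_adata(boosted), ["G0"], n_bins=3, n_ctrl=3, seed=2)
        assert s1.iloc[0] > s0.iloc[0]

    def test_toy_closed_form_with_all_binmates_as_controls(self):
        # 5 genes, 2 bins; controls exhaust the module gene's bin
        counts = np.array([[1, 2, 3, 50, 60], [2, 1, 4, 40, 70]])
        adata = norm_adata(counts)
        dense = np.asarray(adata.X.todense())
        means = dense.mean(axis=0)
        # bins by average expression: {G0,G1,G2} lower, {G3,G4} upper
        scores = score_module(adata, ["G3"], n_bins=2, n_ctrl=1, seed=0)
        # only one candidate control in G3's bin: G4
        expected = dense[:, 3] - dense[:, 4]
        assert np.allclose(scores.to_numpy(), expected)

    def test_translation_invariance_per_nucleus(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(6, size=(20, 10)) + 1
        adata = norm_adata(counts)
        shifted = adata.copy()
        dense = np.asarray(shifted.X.todense())
        dense[5] += 2.5  # constant shift of one nucleus across all genes
        shifted.X = sp.csr_matrix(dense)
        s0 = score_module(adata, ["G0", "G1"], n_bins=2, n_ctrl=4, seed=4)
        s1 = score_module(shifted, ["G0", "G1"], n_bins=2, n_ctrl=4, seed=4)
        assert s1.iloc[5] == pytest.approx(s0.iloc[5], abs=1e-9)

    def test_small_bin_samples_with_replacement_and_warns(self):
        counts = np.random.default_rng(5).poisson(5, size=(15, 6)) + 1
        adata = norm_adata(counts)
        with pytest.warns(UserWarning, match="replacement"):
            score_module(adata, ["G0"], n_bins=2, n_ctrl=50, seed=0)

    def test_missing_module_gene_rejected(self):
        adata = norm_adata(np.ones((5, 3), dtype=int))
        with pytest.raises(KeyError, match="absent"):
            score_module(adata, ["NotAGene"])


class TestCompareScores:
    def test_identical_distributions_no_rejections(self):
        rng = np.random.default_rng(6)
        scores = pd.Series(rng.normal(size=90))
        groups = pd.Series(np.repeat(["a", "b", "c"], 30))
        res = compare_scores(scores, groups)
        assert not res.any_rejection

    def test_shifted_group_rejected_in_its_pairs(self):
        rng = np.random.default_rng(7)
        scores = pd.Series(np.concatenate([rng.normal(0, 1, 40), rng.normal(0, 1, 40),
                                           rng.normal(1.2, 1, 40)]))
        groups = pd.Series(np.repeat(["a", "b", "c"], 40))
        res = compare_scores(scores, groups)
        tab = res.pairwise
        with_c = tab[(tab["group1"] == "c") | (tab["group2"] == "c")]
        assert with_c["reject"].all()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            compare_scores(pd.Series([1.0, 2.0]), pd.Series(["a", "a"]))


class TestScoreLossRegression:
    def test_affine_relation_recovers_r2_one(self):
        score = pd.Series({c: 0.1 * c for c in range(6)})
        loss = np.sqrt(score) * 0.8 + 0.05  # affine in sqrt(score)
        fit = ScoreLossRegression(pd.Series(loss), score).fit()
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.slope == pytest.approx(0.8, abs=1e-8)
        assert fit.intercept == pytest.approx(0.05, abs=1e-8)

    def test_matches_normal_equations_oracle(self):
        x = pd.Series([0.04, 0.09, 0.16, 0.25, 0.36, 0.49])
        y = pd.Series([0.11, 0.19, 0.28, 0.35, 0.52, 0.58])
        fit = ScoreLossRegression(y, x, transform="sqrt").fit()
        X = np.column_stack([np.ones(6), np.sqrt(x)])
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(coef[0], abs=1e-10)
        assert fit.slope == pytest.approx(coef[1], abs=1e-10)
        resid = y - X @ coef
        r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    def test_negative_scores_shifted_before_sqrt(self):
        score = pd.Series([-0.2, -0.1, 0.0, 0.1, 0.3])
        loss = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5])
        fit = ScoreLossRegression(loss, score).fit()
        assert "shift" in fit.transform

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ScoreLossRegression(
                pd.Series([0.1, 0.2, 0.3]), pd.Series([1.0, 1.0, 1.0])
            ).fit()

    def test_input_clusters_excluded(self):
        score = pd.Series({c: 0.1 * (c + 1) for c in range(6)})
        loss = pd.Series({c: 0.15 * (c + 1) for c in range(6)})
        fit = ScoreLossRegression(loss, score, exclude=[0, 1]).fit()
        assert fit.n == 4 and fit.excluded_clusters == [0, 1]

    def test_too_few_clusters_after_exclusion(self):
        with pytest.raises(ValueError, match=">= 3"):
            ScoreLossRegression(
                pd.Series([0.1, 0.2, 0.3]), pd.Series([0.1, 0.2, 0.3]), exclude=[0]
            )

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(8)
        x = pd.Series(rng.uniform(0, 1, 10))
        y = pd.Series(0.5 * np.sqrt(x) + rng.normal(0, 0.05, 10))
        fit = ScoreLossRegression(y, x).fit()
        assert fit.conf_int.loc["slope", "lo"] <= fit.slope <= fit.conf_int.loc["slope", "hi"]
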