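"""QC filtering, Wilcoxon DE, BH-FDR, 2D volcano, pathways, markers."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from olspatial import (
    ExprSimConfig,
    bh_fdr,
    exact_ranksum_p,
    find_markers,
    gen_expression_matrix,
    log_fold_change,
    normalize_log1p,
    pathway_embed,
    qc_filter,
    volcano2d,
    wilcoxon_de,
)
from olspatial.de import _ranksum_p


def adata_from_counts(X, **obs):
    obs = pd.DataFrame(obs, index=[f"c{i}" for i in range(len(X))])
    a = ad.AnnData(X=np.asarray(X, dtype=float), obs=obs)
    a.var_names = [f"g{j}" for j in range(a.n_vars)]
    return a


class TestQcFilter:
    def make(self, n_genes_detected, mito):
        n = len(n_genes_detected)
        X = np.zeros((n, 4000))
        for i, k in enumerate(n_genes_detected):
            X[i, :k] = 1.0
        return adata_from_counts(X, mito_frac=mito)

    def test_corpus_callosum_preset_bounds(self):
        a = self.make([150, 250, 3500], [0.0, 0.0, 0.0])
        kept, report = qc_filter(a, preset="corpus_callosum")
        assert kept.n_obs == 1
        assert report["removed_min_genes"] == 1 and report["removed_max_genes"] == 1

    def test_spinal_cord_preset_admits_six_percent_mito(self):
        a = self.make([600, 600], [0.06, 0.12])
        kept, report = qc_filter(a, preset="spinal_cord")
        assert kept.n_obs == 1 and report["removed_mito"] == 1

    def test_mito_threshold_is_strict_inequality(self):
        a = self.make([600], [0.10])
        kept, _ = qc_filter(a, preset="spinal_cord")
        assert kept.n_obs == 0

    def test_all_cells_within_bounds_is_identity(self):
        a = self.make([500, 600], [0.0, 0.01])
        kept, report = qc_filter(a, min_genes=200, max_genes=3000, max_mito=0.05)
        assert kept.n_obs == 2 and report["kept"] == 2

    def test_report_attributes_each_removal_once(self):
        a = self.make([100, 250, 3500, 600], [0.0, 0.0, 0.9, 0.9])
        _, report = qc_filter(a, min_genes=200, max_genes=3000, max_mito=0.05)
        removed = (
            report["removed_min_genes"] + report["removed_max_genes"] + report["removed_mito"]
        )
        assert report["kept"] + removed == report["input_cells"]
        assert report["removed_max_genes"] == 1  # mito failure attributed to max_genes first

    def test_empty_result_warns_not_raises(self):
        a = self.make([100], [0.0])
        with pytest.warns(UserWarning, match="every cell"):
            kept, _ = qc_filter(a, min_genes=200, max_genes=300, max_mito=0.05)
        assert kept.n_obs == 0


class TestLogFoldChange:
    def test_identical_means_give_zero(self, rng):
        x = rng.uniform(size=(5, 8))
        assert np.allclose(log_fold_change(x, x.copy()), 0.0)

    def test_direct_evaluation_with_pseudocount(self):
        a = np.full((4, 1), 3.0)
        b = np.full((4, 1), 1.0)
        assert log_fold_change(a, b, pseudocount=1.0)[0] == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            log_fold_change(np.empty((0, 3)), np.ones((2, 3)))

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetric_under_group_swap(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(0, 5, (3, 6)), rng.uniform(0, 5, (4, 6))
        assert np.allclose(log_fold_change(a, b), -log_fold_change(b, a))


class TestRankSum:
    def test_exact_p_by_enumeration(self):
        assert exact_ranksum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_constant_groups_give_one(self):
        assert _ranksum_p(np.array([2.0, 2.0]), np.array([2.0, 2.0, 2.0])) == 1.0

    def test_exact_handles_ties_via_midranks(self):
        p = exact_ranksum_p([1, 1, 2], [2, 3, 3])
        assert 0.0 < p <= 1.0

    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 3), (2, 4), (3, 3), (3, 4), (4, 4)])
    def test_normal_approximation_close_to_exact(self, n1, n2, rng):
        """The tie-corrected normal approximation tracks exact enumeration:
        within 0.05 once both groups have >= 6 combined observations; at
        2x2 / 2x3 the discrete null admits so few p values (e.g. {1/3, 2/3,
        1} at 2x2) that no continuous approximation gets closer than ~0.09."""
        from scipy import stats

        bound = 0.05 if n1 + n2 >= 6 else 0.09
        for _ in range(20):
            a = rng.normal(size=n1)
            b = rng.normal(loc=rng.uniform(-2, 2), size=n2)
            exact = exact_ranksum_p(a, b)
            approx = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
            assert abs(exact - approx) < bound


class TestWilcoxonDe:
    def planted(self, seed=0, **kw):
        # gene count kept realistic: with very few genes, strong planted DE
        # shifts library totals and per-cell normalization then leaks
        # spurious signal into null genes (composition artifact)
        cfg = ExprSimConfig(
            n_cells=kw.pop("n_cells", 200), n_genes=kw.pop("n_genes", 600),
            n_de_genes=kw.pop("n_de_genes", 20), de_lfc=kw.pop("de_lfc", 1.0),
            n_spatial_genes=0, marker_genes_per_cluster=0, seed=seed,
        )
        return gen_expression_matrix(cfg)

    def test_planted_de_genes_rank_first(self):
        adata = self.planted(seed=1)
        de = wilcoxon_de(adata, None, ("injury", "control"))
        truth = adata.var["is_de"].to_numpy()
        sig = (de["q"] < 0.01).to_numpy()
        sens = (sig & truth).sum() / truth.sum()
        fdr = (sig & ~truth).sum() / max(sig.sum(), 1)
        assert sens >= 0.9 and fdr <= 0.05

    def test_empty_condition_group_rejected(self):
        adata = self.planted(seed=2)
        with pytest.raises(ValueError, match="empty"):
            wilcoxon_de(adata, None, ("injury", "nonexistent"))

    def test_per_sample_average_mode_ranks_samples(self):
        adata = self.planted(seed=3)
        de = wilcoxon_de(adata, None, ("injury", "control"), mode="per_sample_average")
        # 2 samples per condition -> coarse exact p grid, floor 2/C(4,2)
        assert de["p"].min() >= 2.0 / 6.0 - 1e-12

    def test_population_restriction_subsets_cells(self):
        adata = self.planted(seed=4)
        pop = adata.obs["cluster"].iloc[0]
        de = wilcoxon_de(adata, pop, ("injury", "control"))
        assert len(de) == adata.n_vars


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_step_up_example(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.5]))

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_q_dominates_p_and_preserves_order(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=20)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestVolcano2d:
    def de_table(self, genes, p, lfc):
        return pd.DataFrame(
            {"lfc": lfc, "p": p, "q": bh_fdr(np.asarray(p))}, index=pd.Index(genes, name="gene")
        )

    def test_plotted_p_is_minimum_of_comparisons(self):
        d1 = self.de_table(["g1"], [0.01], [1.0])
        d2 = self.de_table(["g1"], [0.05], [-0.5])
        v = volcano2d(d1, d2)
        assert v.loc["g1", "p_plot"] == pytest.approx(0.01)

    def test_equal_p_keeps_that_value(self):
        d = self.de_table(["g1"], [0.02], [1.0])
        assert volcano2d(d, d.copy()).loc["g1", "p_plot"] == pytest.approx(0.02)

    def test_gene_missing_from_one_comparison_excluded(self):
        d1 = self.de_table(["g1", "g2"], [0.01, 0.02], [1.0, 2.0])
        d2 = self.de_table(["g1"], [0.05], [-0.5])
        v = volcano2d(d1, d2)
        assert list(v.index) == ["g1"]

    def test_empty_overlap_rejected(self):
        d1 = self.de_table(["g1"], [0.01], [1.0])
        d2 = self.de_table(["g2"], [0.01], [1.0])
        with pytest.raises(ValueError, match="shared"):
            volcano2d(d1, d2)

    def test_permutation_invariant_over_genes(self):
        genes = [f"g{i}" for i in range(10)]
        rng = np.random.default_rng(0)
        d1 = self.de_table(genes, rng.uniform(size=10), rng.normal(size=10))
        d2 = self.de_table(genes, rng.uniform(size=10), rng.normal(size=10))
        v = volcano2d(d1, d2)
        shuffled = volcano2d(d1.sample(frac=1, random_state=1), d2)
        pd.testing.assert_frame_equal(v.sort_index(), shuffled.sort_index())


class TestPathwayEmbed:
    def volcano(self):
        return pd.DataFrame(
            {"lfc_1": [1.0, 3.0, -1.0], "lfc_2": [0.5, 0.5, 2.0]},
            index=pd.Index(["g1", "g2", "g3"], name="gene"),
        )

    def test_pathway_lfc_is_member_mean(self):
        out = pathway_embed({"path": ["g1", "g2"]}, self.volcano())
        assert out.loc["path", "lfc_1"] == pytest.approx(2.0)
        assert out.loc["path", "n_genes"] == 2

    def test_singleton_set_equals_gene_point(self):
        out = pathway_embed({"solo": ["g3"]}, self.volcano())
        assert out.loc["solo", "lfc_1"] == pytest.approx(-1.0)
        assert out.loc["solo", "lfc_2"] == pytest.approx(2.0)

    def test_set_without_present_genes_excluded(self):
        out = pathway_embed({"ghost": ["nope"]}, self.volcano())
        assert "ghost" not in out.index

    def test_members_restricted_to_present_genes(self):
        out = pathway_embed({"mix": ["g1", "absent"]}, self.volcano())
        assert out.loc["mix", "n_genes"] == 1


class TestFindMarkers:
    def test_planted_cluster_markers_appear_in_top_list(self):
        cfg = ExprSimConfig(
            n_cells=400, n_genes=80, n_de_genes=0, n_spatial_genes=0,
            marker_genes_per_cluster=4, marker_lfc=3.0, seed=5,
        )
        adata = gen_expression_matrix(cfg)
        mk = find_markers(adata)
        for cl, planted in adata.uns["marker_of_cluster"].items():
            found = set(mk[mk["cluster"] == cl]["gene"])
            assert set(planted) <= found

    def test_all_reported_markers_pass_lfc_cutoff(self):
        cfg = ExprSimConfig(n_cells=300, n_genes=60, marker_genes_per_cluster=3, seed=6)
        mk = find_markers(gen_expression_matrix(cfg))
        assert (mk["lfc"] >= 0.25).all()
        assert (mk["q"] < 0.01).all()

    def test_flat_gene_never_reported(self, rng):
        X = rng.poisson(5.0, size=(60, 10)).astype(float)
        X[:, 0] = 5.0  # identical across clusters
        a = adata_from_counts(X, cluster=np.repeat(["a", "b"], 30))
        mk = find_markers(a, cluster_col="cluster")
        assert "g0" not in set(mk["gene"])

    def test_fewer_than_two_clusters_rejected(self, rng):
        a = adata_from_counts(rng.poisson(5, (20, 5)).astype(float), cluster=["a"] * 20)
        with pytest.raises(ValueError):
            find_markers(a, cluster_col="cluster")
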