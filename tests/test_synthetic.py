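"""Generator contracts: determinism, calibration, ledger consistency."""

import numpy as np
import pandas as pd
import pytest

from olspatial import (
    ExprSimConfig,
    Region,
    SimConfig,
    default_barcode_book,
    gen_expression_matrix,
    gen_iss_spots,
    gen_puncta_counts,
    gen_tissue,
    render_nuclei_image,
)
from olspatial.io import write_counts_mtx


def one_region_config(**kw):
    shape = kw.pop("field_shape", (512, 512))
    defaults = dict(
        n_nuclei=kw.pop("n_nuclei", 40),
        field_shape=shape,
        regions=[Region("WM", 0.0, float(shape[1]))],
        proportions={"WM": kw.pop("props", {"MOL2": 1.0})},
        seed=kw.pop("seed", 0),
    )
    return SimConfig(**defaults, **kw)


class TestGenTissue:
    def test_same_config_and_seed_gives_identical_tissue(self):
        a = gen_tissue(SimConfig(n_nuclei=30, seed=5)).cells
        b = gen_tissue(SimConfig(n_nuclei=30, seed=5)).cells
        pd.testing.assert_frame_equal(a, b)

    def test_single_population_labels_every_cell(self):
        t = gen_tissue(one_region_config())
        assert (t.cells["population"] == "MOL2").all()

    def test_nuclei_respect_minimum_separation(self, small_tissue):
        xy = small_tissue.cells[["x", "y"]].to_numpy()
        d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        cfg = small_tissue.config
        assert d.min() > 2 * cfg.radius_range[1] + cfg.min_separation_margin

    def test_population_fraction_matches_binomial_sampling(self):
        # WM proportion MOL2=0.3 at n=500 -> within 3 binomial SEs
        cfg = SimConfig(
            n_nuclei=500,
            field_shape=(1600, 1600),
            regions=[Region("WM", 0, 1600)],
            proportions={"WM": {"MOL2": 0.3, "MOL5/6": 0.7}},
            seed=11,
        )
        t = gen_tissue(cfg)
        frac = (t.cells["population"] == "MOL2").mean()
        se = np.sqrt(0.3 * 0.7 / 500)
        assert abs(frac - 0.3) < 3 * se

    def test_infeasible_packing_raises(self):
        cfg = SimConfig(n_nuclei=500, field_shape=(64, 64))
        with pytest.raises(RuntimeError, match="could not place"):
            gen_tissue(cfg)


class TestRenderNuclei:
    def test_empty_tissue_renders_blank(self):
        t = gen_tissue(SimConfig(n_nuclei=0))
        image, labels = render_nuclei_image(t)
        assert labels.max() == 0
        assert image.min() == image.max()

    def test_label_count_equals_cell_count(self, small_tissue):
        _, labels = render_nuclei_image(small_tissue)
        assert len(np.unique(labels)) - 1 == 50

    def test_nucleus_center_brighter_than_background(self, small_tissue):
        image, _ = render_nuclei_image(small_tissue, background=1000, foreground=30000)
        row = small_tissue.cells.iloc[0]
        assert image[int(row.y), int(row.x)] > 1000


class TestGenIssSpots:
    def test_noise_free_spots_are_one_hot_on_true_barcode(self, small_tissue, book):
        spots, ledger = gen_iss_spots(small_tissue, book)
        cols = [f"cycle{c}_ch{k}" for c in range(1, 5) for k in range(4)]
        I = spots[cols].to_numpy().reshape(len(spots), 4, 4)
        called = ["".join("ACGT"[k] for k in row) for row in I.argmax(2)]
        assert called == list(ledger["barcode"])

    def test_zero_background_rate_means_every_spot_has_a_cell(self, small_tissue, book):
        _, ledger = gen_iss_spots(small_tissue, book)
        assert (ledger["cell_id"] > 0).all()
        assert not ledger["background"].any()

    def test_gene_missing_from_book_raises_with_name(self, small_tissue):
        from olspatial import BarcodeBook

        tiny = BarcodeBook({"Sox10": "ACGT"})
        with pytest.raises(KeyError, match="Plp1"):
            gen_iss_spots(small_tissue, tiny)

    def test_spot_count_mean_matches_configured_rate(self, book):
        # mean 12 Ptgds spots per MOL5/6 cell, >=100 cells, 3 SE tolerance
        cfg = one_region_config(
            n_nuclei=120,
            props={"MOL5/6": 1.0},
            field_shape=(1024, 1024),
            seed=3,
        )
        tissue = gen_tissue(cfg)
        _, ledger = gen_iss_spots(tissue, book, cfg)
        per_cell = (
            ledger[ledger["gene"] == "Ptgds"].groupby("cell_id").size()
            .reindex(tissue.cells["cell_id"], fill_value=0)
        )
        se = np.sqrt(12.0 / len(per_cell))  # Poisson SE of the mean
        assert abs(per_cell.mean() - 12.0) < 3 * se

    def test_spots_fall_inside_their_generating_cell(self, small_tissue, book):
        spots, ledger = gen_iss_spots(small_tissue, book)
        cells = small_tissue.cells.set_index("cell_id")
        cx = cells.loc[ledger["cell_id"], "x"].to_numpy()
        cy = cells.loc[ledger["cell_id"], "y"].to_numpy()
        r = cells.loc[ledger["cell_id"], "radius"].to_numpy()
        d = np.hypot(spots["x"] - cx, spots["y"] - cy)
        assert (d <= r + 1e-9).all()


class TestGenPuncta:
    def test_fixed_seed_reproduces_table(self, small_tissue):
        a = gen_puncta_counts(small_tissue)
        b = gen_puncta_counts(small_tissue)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_mean_marker_gives_all_zero_counts(self):
        cfg = one_region_config(props={"MOL2": 1.0})
        cfg.puncta = {"MOL2": {"Klk6": 12.0, "Ptgds": 0.0}}
        table = gen_puncta_counts(gen_tissue(cfg), cfg)
        assert (table["Ptgds"] == 0).all()

    def test_poisson_limit_variance_tracks_mean(self):
        cfg = one_region_config(n_nuclei=200, props={"MOL2": 1.0}, field_shape=(2048, 2048))
        cfg.puncta = {"MOL2": {"Klk6": 12.0}}
        cfg.puncta_dispersion = None  # Poisson limit
        counts = gen_puncta_counts(gen_tissue(cfg), cfg)["Klk6"]
        # var/mean for Poisson: 1 +- ~sqrt(2/n)
        ratio = counts.var(ddof=1) / counts.mean()
        assert abs(ratio - 1.0) < 3 * np.sqrt(2.0 / len(counts))

    def test_negative_binomial_is_overdispersed(self):
        cfg = one_region_config(n_nuclei=200, props={"MOL2": 1.0}, field_shape=(2048, 2048))
        cfg.puncta = {"MOL2": {"Klk6": 30.0}}
        cfg.puncta_dispersion = 2.0
        counts = gen_puncta_counts(gen_tissue(cfg), cfg)["Klk6"]
        assert counts.var(ddof=1) > 2 * counts.mean()


class TestGenExpressionMatrix:
    def test_ledger_marks_zero_lfc_genes_non_de(self):
        cfg = ExprSimConfig(n_cells=50, n_genes=30, n_de_genes=0, n_spatial_genes=0, seed=2)
        adata = gen_expression_matrix(cfg)
        assert not adata.var["is_de"].any()

    def test_noise_free_spatial_gene_is_exact_function_of_embedding(self):
        cfg = ExprSimConfig(
            n_cells=80, n_genes=30, n_de_genes=0, n_spatial_genes=5,
            marker_genes_per_cluster=0, count_noise=False, seed=4,
            low_count_frac=0.0, high_count_frac=0.0,
        )
        adata = gen_expression_matrix(cfg)
        emb = adata.obsm["X_embed3d"]
        X = np.asarray(adata.X.todense())
        design = np.column_stack([np.ones(len(emb)), emb])
        for j in np.flatnonzero(adata.var["is_spatial"].to_numpy()):
            y = np.log2(X[:, j])
            resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
            assert np.abs(resid).max() < 1e-8

    def test_mtx_output_is_byte_identical_on_rerun(self, tmp_path):
        cfg = ExprSimConfig(n_cells=100, n_genes=40, seed=9)
        for d in ("a", "b"):
            adata = gen_expression_matrix(cfg)
            df = pd.DataFrame(
                np.asarray(adata.X.todense()), index=adata.obs_names, columns=adata.var_names
            )
            write_counts_mtx(tmp_path / d, df)
        assert (tmp_path / "a/matrix.mtx").read_bytes() == (tmp_path / "b/matrix.mtx").read_bytes()

    def test_planted_outliers_are_recorded_and_extreme(self):
        cfg = ExprSimConfig(n_cells=300, n_genes=60, seed=6)
        adata = gen_expression_matrix(cfg)
        mito = adata.obs["mito_frac"]
        out = adata.obs["true_mito_outlier"]
        assert out.sum() == round(cfg.mito_outlier_frac * cfg.n_cells)
        assert mito[out].min() >= cfg.mito_outlier_range[0]
        totals = np.asarray(adata.X.sum(axis=1)).ravel()
        low = adata.obs["true_low_count"].to_numpy()
        assert totals[low].mean() < 0.2 * totals[~low].mean()
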