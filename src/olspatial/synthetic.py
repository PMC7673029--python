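"""Ground-truthed synthetic data generators.

Every generator is a pure function of its configuration (including the
seed): rerunning with the same config yields identical output. Each
generator draws from an independent seeded stream so that, e.g., adding
background spots does not perturb the tissue layout.

The generators emulate the statistical structure the downstream stages
assume — nothing more: nuclei are flat disks (no point-spread function),
regions are vertical strips, and the mitochondrial fraction is simulated
directly as metadata because the QC filter only ever consumes the fraction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from skimage.draw import disk as _disk

from .config import BASES, ExprSimConfig, Region, SimConfig, region_of
from .decoding import BarcodeBook

_MAX_PLACEMENT_TRIES = 2000

# stream tags so each generator has an independent reproducible stream
_TISSUE, _ISS, _PUNCTA, _EXPR = 1, 2, 3, 4


@dataclass
class Tissue:
    """Simulated tissue: one row per nucleus, plus the generating config."""

    cells: pd.DataFrame  # cell_id, x, y, radius, region, population, sox10
    config: SimConfig

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _draw_counts(rng: np.random.Generator, mean, dispersion, size) -> np.ndarray:
    """Negative-binomial counts with size parameter ``dispersion``;
    ``dispersion=None`` is the Poisson limit (variance = mean)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion is None or not np.isfinite(dispersion):
        return rng.poisson(mean, size=size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def gen_tissue(config: SimConfig) -> Tissue:
    """Place non-overlapping nuclei and assign region-dependent populations.

    Nucleus centers keep a pairwise distance greater than
    ``2*r_max + min_separation_margin`` (dart throwing with a bounded retry
    budget), so that segmentation and spot-assignment ground truth is
    unambiguous even after label expansion.
    """
    rng = np.random.default_rng([config.seed, _TISSUE])
    h, w = config.field_shape
    r_lo, r_hi = config.radius_range
    min_dist = 2.0 * r_hi + config.min_separation_margin

    xs: list[float] = []
    ys: list[float] = []
    radii: list[float] = []
    tries = 0
    while len(xs) < config.n_nuclei:
        if tries >= _MAX_PLACEMENT_TRIES * max(config.n_nuclei, 1):
            raise RuntimeError(
                f"could not place {config.n_nuclei} nuclei of radius <= {r_hi} "
                f"in a {h}x{w} field after {tries} tries; reduce n_nuclei or radii"
            )
        tries += 1
        r = rng.uniform(r_lo, r_hi)
        # keep the whole disk (and its expansion margin) inside the field
        pad = r + 1.0
        x = rng.uniform(pad, w - pad)
        y = rng.uniform(pad, h - pad)
        if xs:
            d2 = (np.array(xs) - x) ** 2 + (np.array(ys) - y) ** 2
            if d2.min() <= min_dist**2:
                continue
        xs.append(x)
        ys.append(y)
        radii.append(r)

    regions = [region_of(x, config.regions) for x in xs]
    pops = []
    for reg in regions:
        props = config.proportions[reg]
        names = list(props)
        pops.append(rng.choice(names, p=[props[n] for n in names]))

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, config.n_nuclei + 1),
            "x": xs,
            "y": ys,
            "radius": radii,
            "region": regions,
            "population": pops,
        }
    )
    cells["sox10"] = ~cells["population"].isin(config.sox10_negative_populations)
    return Tissue(cells=cells, config=config)


def render_nuclei_image(
    tissue: Tissue,
    background: int = 1000,
    foreground: int = 30000,
) -> tuple[np.ndarray, np.ndarray]:
    """Render nuclei as filled disks on a 16-bit grayscale field.

    Returns ``(image, labels)`` where ``labels`` holds the true integer
    label (= cell_id) of every nucleus pixel.
    """
    h, w = tissue.config.field_shape
    image = np.full((h, w), background, dtype=np.uint16)
    labels = np.zeros((h, w), dtype=np.int32)
    for row in tissue.cells.itertuples():
        rr, cc = _disk((row.y, row.x), row.radius, shape=(h, w))
        image[rr, cc] = foreground
        labels[rr, cc] = row.cell_id
    return image, labels


def _uniform_in_disk(rng, cx, cy, radius, n):
    rho = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return cx + rho * np.cos(theta), cy + rho * np.sin(theta)


def gen_iss_spots(
    tissue: Tissue, book: BarcodeBook, config: SimConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate decoded-able ISS spot intensities over four sequencing cycles.

    Per cell and expressed gene, the spot count is drawn from the configured
    mean; each spot sits uniformly inside its nucleus disk and carries a
    cycles x channels intensity matrix that is one-hot on the barcode's
    channel per cycle (amplitude A), plus a crosstalk fraction of A on every
    other channel, plus additive Gaussian noise truncated at zero.
    Background spots (off-target rolling-circle products) carry barcodes
    drawn uniformly from the full 4^L space and no generating cell.

    Returns ``(spots, ledger)``: the spot intensity table with
    ``cycle{c}_ch{k}`` columns and the ground-truth ledger (spot_id,
    cell_id, gene, barcode, background flag).
    """
    config = config or tissue.config
    rng = np.random.default_rng([config.seed, _ISS])
    L, K = config.cycles, config.channels
    for pop in tissue.cells["population"].unique():
        for gene in config.expression.get(pop, {}):
            if gene not in book.entries:
                raise KeyError(f"gene {gene!r} expressed by {pop!r} missing from barcode book")

    rec_cell, rec_gene, rec_bc, rec_x, rec_y = [], [], [], [], []
    for row in tissue.cells.itertuples():
        means = config.expression.get(row.population, {})
        for gene, mu in means.items():
            n = int(_draw_counts(rng, mu, config.dispersion, size=None))
            if n == 0:
                continue
            sx, sy = _uniform_in_disk(rng, row.x, row.y, row.radius, n)
            rec_cell.extend([row.cell_id] * n)
            rec_gene.extend([gene] * n)
            rec_bc.extend([book.entries[gene]] * n)
            rec_x.extend(sx)
            rec_y.extend(sy)

    n_true = len(rec_cell)
    n_bg = int(rng.poisson(config.background_rate * n_true)) if config.background_rate else 0
    if n_bg:
        h, w = config.field_shape
        all_bcs = ["".join(p) for p in itertools.product(BASES, repeat=L)]
        rec_cell.extend([-1] * n_bg)
        rec_gene.extend([None] * n_bg)
        rec_bc.extend(rng.choice(all_bcs, size=n_bg))
        rec_x.extend(rng.uniform(0, w - 1, size=n_bg))
        rec_y.extend(rng.uniform(0, h - 1, size=n_bg))

    n_spots = len(rec_cell)
    A = config.amplitude
    intens = np.full((n_spots, L, K), A * config.crosstalk)
    for i, bc in enumerate(rec_bc):
        for c, base in enumerate(bc):
            ch = book.channel_of(base)
            intens[i, c, :] = A * config.crosstalk
            intens[i, c, ch] = A
    if config.noise_level > 0:
        intens += rng.normal(0.0, config.noise_level * A, size=intens.shape)
        np.clip(intens, 0.0, None, out=intens)

    spot_ids = np.arange(n_spots)
    spots = pd.DataFrame({"spot_id": spot_ids, "x": rec_x, "y": rec_y})
    for c in range(L):
        for k in range(K):
            spots[f"cycle{c + 1}_ch{k}"] = intens[:, c, k]
    ledger = pd.DataFrame(
        {
            "spot_id": spot_ids,
            "cell_id": rec_cell,
            "gene": rec_gene,
            "barcode": rec_bc,
            "background": [c == -1 for c in rec_cell],
        }
    )
    return spots, ledger


def gen_puncta_counts(tissue: Tissue, config: SimConfig | None = None) -> pd.DataFrame:
    """RNAscope-style per-cell marker puncta counts.

    Counts are negative-binomial with population-specific means chosen to
    straddle the molecule cutoffs used for population calling (the default
    config puts each population's own marker 3x above its cutoff and all
    other markers 3x below).
    """
    config = config or tissue.config
    rng = np.random.default_rng([config.seed, _PUNCTA])
    markers: list[str] = []
    for m in config.puncta.values():
        for name in m:
            if name not in markers:
                markers.append(name)
    out = tissue.cells[["cell_id", "region", "population", "sox10"]].copy()
    for marker in markers:
        mus = np.array(
            [config.puncta.get(p, {}).get(marker, 0.0) for p in out["population"]]
        )
        counts = np.zeros(len(out), dtype=np.int64)
        pos = mus > 0
        if pos.any():
            counts[pos] = _draw_counts(rng, mus[pos], config.puncta_dispersion, size=pos.sum())
        out[marker] = counts
    return out


def gen_expression_matrix(config: ExprSimConfig) -> ad.AnnData:
    """Synthetic cells x genes count matrix with planted ground truth.

    Plants, and records in ``.var`` / ``.obs``:

    - cluster structure: ``marker_genes_per_cluster`` genes upregulated by
      ``marker_lfc`` (log2) in one cluster each;
    - condition DE: the first ``n_de_genes`` genes shifted by ``de_lfc``
      (log2) in the non-control conditions, within every cluster;
    - spatial genes: the next ``n_spatial_genes`` genes whose log-rate is a
      smooth linear field over a 3D cluster-blob embedding (strength =
      ``spatial_strength`` SDs of the field);
    - mitochondrial-fraction outliers and low/high library-size cells.

    With ``count_noise=False`` the spatial genes carry their exact rate
    instead of a Poisson/NB draw (useful for oracle tests).
    """
    rng = np.random.default_rng([config.seed, _EXPR])
    n, g = config.n_cells, config.n_genes

    genes = np.array([f"g{j:04d}" for j in range(g)])
    clusters = rng.integers(0, config.n_clusters, size=n)
    conditions = np.array(config.conditions)[rng.integers(0, len(config.conditions), size=n)]
    sample_ids = np.array(
        [
            f"{cond}_s{rng.integers(config.n_samples_per_condition)}"
            for cond in conditions
        ]
    )

    # 3D embedding: one Gaussian blob per cluster on a simplex-ish layout
    centers = rng.normal(0.0, 1.0, size=(config.n_clusters, 3))
    centers *= config.embedding_sep / max(
        1e-9, np.linalg.norm(centers[0] - centers[1])
    )
    emb = centers[clusters] + rng.normal(0.0, 1.0, size=(n, 3))

    base = rng.lognormal(config.base_mean_log_mu, config.base_mean_log_sigma, size=g)
    log2fc = np.zeros((n, g))

    de_idx = np.arange(config.n_de_genes)
    # a fold change on a nearly-undetected gene is unidentifiable, so DE is
    # planted on expressed genes only
    base[de_idx] = np.maximum(base[de_idx], config.de_base_mean_min)
    is_injured = conditions != config.conditions[0]
    # balanced up/down regulation keeps library sizes comparable between
    # conditions (the implicit assumption of per-cell normalization)
    de_sign = np.where(np.arange(config.n_de_genes) % 2 == 0, 1.0, -1.0)
    true_lfc = np.zeros(g)
    true_lfc[de_idx] = config.de_lfc * de_sign
    log2fc[np.ix_(is_injured, de_idx)] += true_lfc[de_idx]

    sp_idx = np.arange(config.n_de_genes, config.n_de_genes + config.n_spatial_genes)
    directions = rng.normal(size=(len(sp_idx), 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    field = emb @ directions.T  # (n, n_spatial) smooth linear field
    field = (field - field.mean(0)) / np.where(field.std(0) > 0, field.std(0), 1.0)
    log2fc[:, sp_idx] += config.spatial_strength * field

    marker_start = config.n_de_genes + config.n_spatial_genes
    marker_of_cluster: dict[int, list[str]] = {}
    for c in range(config.n_clusters):
        lo = marker_start + c * config.marker_genes_per_cluster
        hi = min(lo + config.marker_genes_per_cluster, g)
        idx = np.arange(lo, hi)
        marker_of_cluster[c] = list(genes[idx])
        log2fc[np.ix_(clusters == c, idx)] += config.marker_lfc

    size_factor = np.ones(n)
    n_low = int(round(config.low_count_frac * n))
    n_high = int(round(config.high_count_frac * n))
    outlier_cells = rng.choice(n, size=n_low + n_high, replace=False)
    low_cells, high_cells = outlier_cells[:n_low], outlier_cells[n_low:]
    size_factor[low_cells] = config.low_count_scale
    size_factor[high_cells] = config.high_count_scale

    lam = base[None, :] * 2.0**log2fc * size_factor[:, None]
    if config.count_noise:
        X = _draw_counts(rng, lam, config.dispersion, size=lam.shape).astype(float)
    else:
        X = lam.copy()

    mito = rng.beta(*config.mito_beta, size=n)
    n_mito = int(round(config.mito_outlier_frac * n))
    mito_out = rng.choice(n, size=n_mito, replace=False)
    mito[mito_out] = rng.uniform(*config.mito_outlier_range, size=n_mito)

    obs = pd.DataFrame(
        {
            "sample": sample_ids,
            "condition": conditions,
            "cluster": pd.Categorical([f"c{c}" for c in clusters]),
            "mito_frac": mito,
            "true_low_count": np.isin(np.arange(n), low_cells),
            "true_high_count": np.isin(np.arange(n), high_cells),
            "true_mito_outlier": np.isin(np.arange(n), mito_out),
        },
        index=[f"cell{i:05d}" for i in range(n)],
    )
    var = pd.DataFrame(
        {
            "is_de": np.isin(np.arange(g), de_idx) & (true_lfc != 0),
            "true_lfc": true_lfc,
            "is_spatial": np.isin(np.arange(g), sp_idx),
            "spatial_strength": np.where(
                np.isin(np.arange(g), sp_idx), config.spatial_strength, 0.0
            ),
        },
        index=genes,
    )
    adata = ad.AnnData(X=sparse.csr_matrix(X), obs=obs, var=var)
    adata.obsm["X_embed3d"] = emb
    adata.uns["marker_of_cluster"] = {f"c{c}": v for c, v in marker_of_cluster.items()}
    return adata


def default_barcode_book() -> BarcodeBook:
    """12-gene barcode book over 4 cycles (study marker panel)."""
    return BarcodeBook(
        {
            "Sox10": "ACGT",
            "Plp1": "CAGT",
            "Klk6": "GTCA",
            "Anxa5": "TGAC",
            "Hopx": "AAGG",
            "Ptgds": "CCTT",
            "Car2": "GGAA",
            "Grm3": "TTCC",
            "Ptprz1": "AGTC",
            "Egr2": "CTAG",
            "Aspa": "GACT",
            "Mbp": "TCGA",
        }
    )
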