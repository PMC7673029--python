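"""scRNA-seq QC, Wilcoxon differential expression, 2D volcano assembly,
pathway LFC embedding and marker finding.

Counts are normalized per cell to 10,000 total and log1p-transformed
before any fold change or rank test (the standard scRNA-seq scaling).
Fold changes are log2((mean_A + pc) / (mean_B + pc)) on the normalized
scale with pseudocount 1, antisymmetric under group swap. Rank-sum tests
enumerate the exact permutation distribution for combined n <= 10 and use
the tie-corrected normal approximation otherwise; both cells and
per-sample averages are supported as the test unit. FDR control is
Benjamini-Hochberg with the q < 0.01 significance convention, and 2D
volcano points carry the lower of the two comparisons' p values.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: QC presets: (min_genes, max_genes, max_mito_fraction)
QC_PRESETS: dict[str, tuple[int, int, float]] = {
    "corpus_callosum": (200, 3000, 0.05),
    "spinal_cord": (500, 7000, 0.10),
}

EXACT_MAX_N = 10  # combined group size up to which the rank test is exact
LFC_PSEUDOCOUNT = 1.0
NORM_TOTAL = 1e4


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)


def normalize_log1p(X, total: float = NORM_TOTAL) -> np.ndarray:
    """log(1 + count * total / cell_total) per-cell library normalization."""
    X = _dense(X)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return np.log1p(X * (total / lib))


def qc_filter(
    adata: ad.AnnData,
    min_genes: int | None = None,
    max_genes: int | None = None,
    max_mito: float | None = None,
    preset: str | None = None,
    mito_col: str = "mito_frac",
) -> tuple[ad.AnnData, dict]:
    """Filter cells on detected-gene count and mitochondrial fraction.

    Keeps cells with ``min_genes <= detected genes <= max_genes`` and mito
    fraction strictly below ``max_mito``. Cells removed are attributed to
    the first failing criterion in the order min_genes, max_genes, mito,
    so the report's removed counts plus kept cells equal the input.
    """
    if preset is not None:
        if preset not in QC_PRESETS:
            raise KeyError(f"unknown preset {preset!r}; have {sorted(QC_PRESETS)}")
        p_min, p_max, p_mito = QC_PRESETS[preset]
        min_genes = p_min if min_genes is None else min_genes
        max_genes = p_max if max_genes is None else max_genes
        max_mito = p_mito if max_mito is None else max_mito
    if min_genes is None or max_genes is None or max_mito is None:
        raise ValueError("provide min_genes, max_genes and max_mito (or a preset)")
    if min_genes <= 0 or max_genes <= 0 or min_genes >= max_genes:
        raise ValueError("need 0 < min_genes < max_genes")

    n_genes = np.asarray((_dense(adata.X) > 0).sum(axis=1)).ravel()
    mito = adata.obs[mito_col].to_numpy(dtype=float)
    fail_min = n_genes < min_genes
    fail_max = ~fail_min & (n_genes > max_genes)
    fail_mito = ~fail_min & ~fail_max & (mito >= max_mito)
    keep = ~(fail_min | fail_max | fail_mito)
    report = {
        "input_cells": int(adata.n_obs),
        "kept": int(keep.sum()),
        "removed_min_genes": int(fail_min.sum()),
        "removed_max_genes": int(fail_max.sum()),
        "removed_mito": int(fail_mito.sum()),
        "min_genes": int(min_genes),
        "max_genes": int(max_genes),
        "max_mito": float(max_mito),
    }
    if report["kept"] == 0:
        warnings.warn("QC filter removed every cell")
    return adata[keep].copy(), report


def log_fold_change(
    a: np.ndarray, b: np.ndarray, pseudocount: float = LFC_PSEUDOCOUNT
) -> np.ndarray:
    """Per-gene log2 fold change of group means on normalized expression.

    ``a`` and ``b`` are cells x genes normalized matrices;
    LFC = log2((mean_a + pc) / (mean_b + pc)), antisymmetric in (a, b).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    return np.log2((a.mean(axis=0) + pseudocount) / (b.mean(axis=0) + pseudocount))


def exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by full enumeration (midranks for ties).

    Two-sided p = min(1, 2 * min(P(W <= w_obs), P(W >= w_obs))) over all
    C(n, n1) assignments of the pooled ranks to group A.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n, n1 = len(pooled), len(a)
    if n1 == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    lo = hi = total = 0
    for comb in combinations(range(n), n1):
        w = ranks[list(comb)].sum()
        total += 1
        if w <= w_obs + 1e-9:
            lo += 1
        if w >= w_obs - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p: exact for combined n <= EXACT_MAX_N, else
    tie-corrected normal approximation with continuity correction."""
    if np.ptp(np.concatenate([a, b])) == 0.0:
        return 1.0
    if len(a) + len(b) <= EXACT_MAX_N:
        if min(len(a), len(b)) < 2:
            warnings.warn("single-unit group in exact mode; p set to 1")
            return 1.0
        return exact_ranksum_p(a, b)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)


def wilcoxon_de(
    adata: ad.AnnData,
    population: str | None,
    comparison: tuple[str, str],
    mode: str = "per_cell",
    population_col: str = "cluster",
    condition_col: str = "condition",
    sample_col: str = "sample",
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE between two conditions in a population.

    ``mode='per_cell'`` ranks cells; ``mode='per_sample_average'`` first
    averages normalized expression within each sample and ranks samples
    (the cluster-averaged reading of the test). Returns a per-gene table
    with group means (normalized), log2 fold change (group1 over group2),
    two-sided p, and BH-FDR q.
    """
    cond1, cond2 = comparison
    mask = np.ones(adata.n_obs, dtype=bool)
    if population is not None:
        mask &= (adata.obs[population_col] == population).to_numpy()
    sub = adata[mask]
    norm = normalize_log1p(sub.X)
    in1 = (sub.obs[condition_col] == cond1).to_numpy()
    in2 = (sub.obs[condition_col] == cond2).to_numpy()
    if in1.sum() == 0 or in2.sum() == 0:
        raise ValueError(f"empty condition group in comparison {comparison}")

    if mode == "per_cell":
        A, B = norm[in1], norm[in2]
    elif mode == "per_sample_average":
        samples = sub.obs[sample_col].to_numpy()
        A = np.vstack([norm[in1 & (samples == s)].mean(axis=0) for s in np.unique(samples[in1])])
        B = np.vstack([norm[in2 & (samples == s)].mean(axis=0) for s in np.unique(samples[in2])])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    lfc = log_fold_change(A, B)
    n_units = A.shape[0] + B.shape[0]
    if n_units > EXACT_MAX_N:
        # vectorized tie-corrected asymptotic test across genes
        res = stats.mannwhitneyu(A, B, alternative="two-sided", method="asymptotic", axis=0)
        p = np.asarray(res.pvalue, dtype=float)
        flat = np.array([np.ptp(np.concatenate([A[:, j], B[:, j]])) == 0 for j in range(A.shape[1])])
        p[flat] = 1.0
    else:
        p = np.array([_ranksum_p(A[:, j], B[:, j]) for j in range(A.shape[1])])
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "gene": sub.var_names,
            "mean_1": A.mean(axis=0),
            "mean_2": B.mean(axis=0),
            "lfc": lfc,
            "p": p,
            "q": q,
        }
    ).set_index("gene")


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def volcano2d(
    de1: pd.DataFrame, de2: pd.DataFrame, q_threshold: float = 0.01
) -> pd.DataFrame:
    """Combine two DE comparisons into a 2D-volcano table.

    Per gene present in both tables: LFC on each axis and plotted
    p = min(p1, p2) (q alongside); genes missing from either comparison are
    excluded and logged. ``significant`` flags min(q1, q2) < q_threshold.
    """
    common = de1.index.intersection(de2.index)
    if len(common) == 0:
        raise ValueError("no genes shared between the two comparisons")
    dropped = sorted(set(de1.index).symmetric_difference(de2.index))
    if dropped:
        logger.info("volcano2d: excluded %d genes absent from one comparison: %s",
                    len(dropped), dropped[:10])
    out = pd.DataFrame(
        {
            "lfc_1": de1.loc[common, "lfc"],
            "lfc_2": de2.loc[common, "lfc"],
            "p_1": de1.loc[common, "p"],
            "p_2": de2.loc[common, "p"],
            "q_1": de1.loc[common, "q"],
            "q_2": de2.loc[common, "q"],
        },
        index=common,
    )
    out["p_plot"] = out[["p_1", "p_2"]].min(axis=1)
    out["q_min"] = out[["q_1", "q_2"]].min(axis=1)
    out["significant"] = out["q_min"] < q_threshold
    return out


def pathway_embed(gene_sets: dict[str, list[str]], volcano: pd.DataFrame) -> pd.DataFrame:
    """Embed gene sets into a 2D volcano by averaging member-gene LFCs.

    Each pathway's coordinate on each axis is the arithmetic mean of the
    LFCs of its member genes present in the volcano table; sets with no
    member present are excluded (and logged).
    """
    rows = []
    for name, members in gene_sets.items():
        present = [g for g in members if g in volcano.index]
        if not present:
            logger.info("pathway_embed: %r has no genes in the table; excluded", name)
            continue
        rows.append(
            {
                "pathway": name,
                "lfc_1": float(volcano.loc[present, "lfc_1"].mean()),
                "lfc_2": float(volcano.loc[present, "lfc_2"].mean()),
                "n_genes": len(present),
            }
        )
    return pd.DataFrame(rows).set_index("pathway") if rows else pd.DataFrame(
        columns=["lfc_1", "lfc_2", "n_genes"]
    )


def find_markers(
    adata: ad.AnnData,
    cluster_col: str = "cluster",
    min_lfc: float = 0.25,
    top_n: int = 20,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker finding with LFC cutoff and z-score ranking.

    Per cluster: per-cell rank-sum test of cluster vs all other cells,
    BH-FDR over genes, log2 fold change on normalized expression; markers
    require LFC >= ``min_lfc`` (0.25-fold-change convention) and
    q < ``q_threshold``; the top ``top_n`` per cluster are ranked by the
    enrichment z score (cluster mean - global mean) / global SD of
    normalized expression. Clusters with a single cell are skipped.
    """
    labels = adata.obs[cluster_col].to_numpy()
    clusters = pd.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    norm = normalize_log1p(adata.X)
    gmean = norm.mean(axis=0)
    gsd = norm.std(axis=0)
    gsd_safe = np.where(gsd > 0, gsd, np.inf)

    frames = []
    for cl in clusters:
        inside = labels == cl
        if inside.sum() < 2:
            warnings.warn(f"cluster {cl!r} has <2 cells; skipped")
            continue
        A, B = norm[inside], norm[~inside]
        res = stats.mannwhitneyu(A, B, alternative="two-sided", method="asymptotic", axis=0)
        p = np.asarray(res.pvalue, dtype=float)
        flat = gsd == 0
        p[flat] = 1.0
        q = bh_fdr(p)
        lfc = log_fold_change(A, B)
        z = (A.mean(axis=0) - gmean) / gsd_safe
        df = pd.DataFrame(
            {
                "cluster": cl,
                "gene": adata.var_names,
                "lfc": lfc,
                "p": p,
                "q": q,
                "z": z,
            }
        )
        df = df[(df["lfc"] >= min_lfc) & (df["q"] < q_threshold)]
        df = df.sort_values("z", ascending=False).head(top_n)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["cluster", "gene", "lfc", "p", "q", "z"])
    return pd.concat(frames, ignore_index=True)
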