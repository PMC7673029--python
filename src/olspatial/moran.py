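"""Moran's-I feature selection on a cell-manifold embedding, and
hierarchical subclustering on the filtered gene set.

Spatial proximity between cells is inferred from a low-dimensional (3D)
embedding: a k-nearest-neighbour graph (union-symmetrized, row-
standardized) defines the weights W of the spatial autocorrelation
statistic

    I = (N / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with S0 the total weight. Significance is assessed by Monte-Carlo
permutation of the expression values over cells, with the add-one
estimator p = (1 + #{I_perm >= I_obs}) / (1 + nperm), so p is never
exactly zero. Genes are filtered iteratively: each round keeps genes with
p <= alpha; optionally the embedding/graph is recomputed from the retained
genes between rounds (the pluggable re-embed hook), as when the procedure
is run to convergence on real data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import sparse
from sklearn.cluster import AgglomerativeClustering
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

DEFAULT_K = 15
DEFAULT_ALPHA = 0.01
DEFAULT_NPERM = 999
DEFAULT_MAX_ROUNDS = 30


@dataclass
class EmbeddingGraph:
    """Row-standardized kNN weight matrix over an embedding."""

    coords: np.ndarray  # (N, d)
    W: sparse.csr_matrix  # (N, N), zero diagonal, rows sum to 1

    @property
    def n_cells(self) -> int:
        return self.W.shape[0]

    @property
    def s0(self) -> float:
        return float(self.W.sum())


def knn_graph(coords: np.ndarray, k: int = DEFAULT_K) -> EmbeddingGraph:
    """Union-symmetrized, row-standardized kNN graph on embedding coordinates.

    Edges are the union of each cell's k nearest neighbours (symmetrized by
    elementwise max), then every row is scaled to sum 1. Distance ties are
    broken toward the lower cell index, making the graph deterministic.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2:
        raise ValueError("coords must be (N, d)")
    if not np.isfinite(coords).all():
        raise ValueError("coords must be finite")
    n = len(coords)
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < N, got k={k}, N={n}")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="auto")
    nn.fit(coords)
    dist, idx = nn.kneighbors(coords)
    # drop self (distance 0 column); sklearn orders ties by index already,
    # but enforce the lower-index rule explicitly for exact determinism
    rows, cols = [], []
    for i in range(n):
        order = np.lexsort((idx[i], dist[i]))
        neigh = [j for j in idx[i][order] if j != i][:k]
        rows.extend([i] * len(neigh))
        cols.extend(neigh)
    A = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    A = A.maximum(A.T)  # union symmetrization
    A.setdiag(0)
    A.eliminate_zeros()
    deg = np.asarray(A.sum(axis=1)).ravel()
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    W = sparse.diags(inv) @ A
    return EmbeddingGraph(coords=coords, W=W.tocsr())


def morans_i(x: np.ndarray, graph: EmbeddingGraph) -> float:
    """Moran's I of per-cell values over the graph (sparse evaluation)."""
    x = np.asarray(x, dtype=float).ravel()
    n = graph.n_cells
    if len(x) != n:
        raise ValueError(f"x has length {len(x)}, graph has {n} cells")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("Moran's I is undefined for constant input")
    numer = float(z @ (graph.W @ z))
    return (n / graph.s0) * numer / denom


def morans_i_dense(x: np.ndarray, graph: EmbeddingGraph) -> float:
    """Brute-force double-sum evaluation of Moran's I (oracle for tests)."""
    x = np.asarray(x, dtype=float).ravel()
    W = graph.W.toarray()
    n = len(x)
    z = x - x.mean()
    numer = 0.0
    for i in range(n):
        for j in range(n):
            numer += W[i, j] * z[i] * z[j]
    return (n / W.sum()) * numer / float((z**2).sum())


def mc_pvalue(
    x: np.ndarray, graph: EmbeddingGraph, nperm: int = DEFAULT_NPERM, seed: int = 0
) -> float:
    """Monte-Carlo permutation p for positive spatial autocorrelation.

    Permutations are uniform relabelings of x over cells;
    p = (1 + #{I_perm >= I_obs}) / (1 + nperm).
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    x = np.asarray(x, dtype=float).ravel()
    i_obs = morans_i(x, graph)
    rng = np.random.default_rng(seed)
    i_perm = _perm_morans(x, graph, nperm, rng)
    return (1.0 + int((i_perm >= i_obs - 1e-12).sum())) / (1.0 + nperm)


def _perm_morans(
    x: np.ndarray, graph: EmbeddingGraph, nperm: int, rng: np.random.Generator
) -> np.ndarray:
    """Moran's I of ``nperm`` permutations of x, vectorized over permutations."""
    n = graph.n_cells
    z = x - x.mean()
    denom = float(z @ z)
    idx = rng.permuted(np.tile(np.arange(n), (nperm, 1)), axis=1)
    Zt = z[idx].T  # (n, nperm)
    numer = np.einsum("ij,ij->j", Zt, graph.W @ Zt)
    return (n / graph.s0) * numer / denom


@dataclass
class FilterResult:
    rounds: list[list[str]]  # retained gene names after each round
    pvalues: "np.ndarray | None"  # last-round p per tested gene
    converged: bool

    @property
    def final(self) -> list[str]:
        return self.rounds[-1] if self.rounds else []


def iterative_spatial_filter(
    X: np.ndarray,
    genes: list[str],
    graph: EmbeddingGraph,
    alpha: float = DEFAULT_ALPHA,
    nperm: int = DEFAULT_NPERM,
    max_rounds: int = DEFAULT_MAX_ROUNDS,
    seed: int = 0,
    reembed: Optional[Callable[[np.ndarray], EmbeddingGraph]] = None,
) -> FilterResult:
    """Iterative rounds of Moran's-I spatial filtering of genes.

    ``X`` is cells x genes (normalized expression). Round r tests every
    gene retained after round r-1 (round 1 tests all) and keeps those with
    Monte-Carlo p <= alpha. With a ``reembed`` hook the graph is recomputed
    from the retained gene submatrix between rounds; with the default fixed
    graph the retained sets are nested and the filter converges as soon as
    a round removes nothing. Constant genes are untestable and dropped.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(genes):
        raise ValueError("X must be cells x genes matching the gene list")
    if X.shape[0] != graph.n_cells:
        raise ValueError("X and graph disagree on the number of cells")

    retained = list(genes)
    col = {gname: j for j, gname in enumerate(genes)}
    rounds: list[list[str]] = []
    pvals = None
    cur_graph = graph
    converged = False
    for r in range(1, max_rounds + 1):
        keep: list[str] = []
        pvals = np.ones(len(retained))
        for gi, gname in enumerate(retained):
            xg = X[:, col[gname]]
            if np.ptp(xg) == 0.0:
                logger.info("round %d: dropping constant gene %s", r, gname)
                continue
            rng = np.random.default_rng([seed, r, col[gname]])
            i_obs = morans_i(xg, cur_graph)
            i_perm = _perm_morans(xg, cur_graph, nperm, rng)
            p = (1.0 + int((i_perm >= i_obs - 1e-12).sum())) / (1.0 + nperm)
            pvals[gi] = p
            if p <= alpha:
                keep.append(gname)
        rounds.append(keep)
        logger.info("round %d: retained %d / %d genes", r, len(keep), len(retained))
        if not keep:
            warnings.warn(f"spatial filter retained no genes at round {r}; stopping")
            break
        if set(keep) == set(retained):
            retained = keep
            converged = True
            break
        retained = keep
        if reembed is not None:
            sub = X[:, [col[gname] for gname in retained]]
            cur_graph = reembed(sub)
    return FilterResult(rounds=rounds, pvalues=pvals, converged=converged)


def hierarchical_subcluster(
    X: np.ndarray, n_clusters: int
) -> np.ndarray:
    """Ward agglomerative clustering of cells on scaled retained genes.

    Genes are standardized to zero mean / unit variance (constant genes
    left at zero) before Euclidean Ward linkage cut at ``n_clusters``.
    Deterministic for fixed input.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be cells x (>=1) genes")
    n = X.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValueError(f"need 1 <= n_clusters <= {n}")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Xs = (X - mu) / np.where(sd > 0, sd, 1.0)
    if n_clusters == 1:
        return np.zeros(n, dtype=int)
    model = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward")
    return model.fit_predict(Xs)
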