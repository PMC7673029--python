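#!/usr/bin/env python
"""Manifold feature selection: Moran's I of each gene over a kNN graph on
the 3D embedding, Monte-Carlo significance (999 permutations), iterative
filtering at alpha = 0.01, then Ward hierarchical subclustering on the
retained genes. Reports recovery of the planted spatial genes and the
agreement of the subclusters with the planted cluster labels.
"""

import os

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from olspatial import (
    ExprSimConfig,
    gen_expression_matrix,
    hierarchical_subcluster,
    iterative_spatial_filter,
    knn_graph,
    normalize_log1p,
)

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
os.makedirs(OUT, exist_ok=True)

cfg = ExprSimConfig(n_cells=500, n_genes=200, n_spatial_genes=20, seed=42)
adata = gen_expression_matrix(cfg)
graph = knn_graph(adata.obsm["X_embed3d"], k=15)
X = normalize_log1p(adata.X)
res = iterative_spatial_filter(
    X, list(adata.var_names), graph, alpha=0.01, nperm=999, seed=42
)

planted = set(adata.var_names[adata.var["is_spatial"]])
markers = set(g for v in adata.uns["marker_of_cluster"].values() for g in v)
per_round = pd.DataFrame(
    {
        "round": range(1, len(res.rounds) + 1),
        "retained": [len(r) for r in res.rounds],
        "planted_spatial": [len(planted & set(r)) for r in res.rounds],
        "cluster_markers": [len(markers & set(r)) for r in res.rounds],
    }
)
per_round.to_csv(os.path.join(OUT, "moran_filter_rounds.csv"), index=False)
pd.Series(sorted(res.final)).to_csv(
    os.path.join(OUT, "moran_retained_genes.txt"), index=False, header=False
)

cols = [adata.var_names.get_loc(g) for g in res.final]
labels = hierarchical_subcluster(X[:, cols], cfg.n_clusters)
ari = adjusted_rand_score(adata.obs["cluster"].cat.codes, labels)
pd.DataFrame({"cell": adata.obs_names, "subcluster": labels}).to_csv(
    os.path.join(OUT, "subclusters.csv"), index=False
)

print("Iterative Moran's-I filtering (alpha=0.01, 999 permutations):")
print(per_round.to_string(index=False))
print(f"\nFinal set: {len(res.final)} genes — {len(planted & set(res.final))}/20 planted "
      f"spatial genes and {len(markers & set(res.final))} cluster markers (markers are "
      "genuinely autocorrelated on the embedding: clusters are blobs there).")
print(f"Ward subclustering on the retained genes vs planted clusters: ARI = {ari:.3f}")
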