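"""Readers/writers for the on-disk exchange formats.

Count matrices travel as MatrixMarket (MTX) plus ``genes.tsv`` /
``cells.tsv`` sidecars; images as TIFF (16-bit grayscale stain, 32-bit
integer labels); everything tabular as CSV. Gene sets load from a
two-column TSV (set, gene) or GMT.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import tifffile
from scipy import io as sio
from scipy import sparse


def write_image(path, image: np.ndarray) -> None:
    tifffile.imwrite(path, image)


def read_image(path) -> np.ndarray:
    return tifffile.imread(path)


def write_counts_mtx(out_dir, counts: pd.DataFrame) -> None:
    """Cell x gene DataFrame -> matrix.mtx + cells.tsv + genes.tsv."""
    os.makedirs(out_dir, exist_ok=True)
    mat = sparse.csr_matrix(counts.to_numpy())
    sio.mmwrite(os.path.join(out_dir, "matrix.mtx"), mat)
    pd.Series(counts.index.astype(str)).to_csv(
        os.path.join(out_dir, "cells.tsv"), index=False, header=False, sep="\t"
    )
    pd.Series(counts.columns.astype(str)).to_csv(
        os.path.join(out_dir, "genes.tsv"), index=False, header=False, sep="\t"
    )


def read_counts_mtx(in_dir) -> pd.DataFrame:
    mat = sio.mmread(os.path.join(in_dir, "matrix.mtx"))
    cells = pd.read_csv(os.path.join(in_dir, "cells.tsv"), header=None, sep="\t")[0]
    genes = pd.read_csv(os.path.join(in_dir, "genes.tsv"), header=None, sep="\t")[0]
    return pd.DataFrame(
        np.asarray(mat.todense() if sparse.issparse(mat) else mat),
        index=cells,
        columns=genes,
    )


def read_gene_sets(path) -> dict[str, list[str]]:
    """Gene sets from two-column TSV (set, gene) or GMT (.gmt)."""
    path = str(path)
    sets: dict[str, list[str]] = {}
    if path.endswith(".gmt"):
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 3:
                    sets[parts[0]] = [g for g in parts[2:] if g]
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"])
        for name, grp in df.groupby("set"):
            sets[str(name)] = list(grp["gene"].astype(str))
    return sets
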