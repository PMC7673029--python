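"""Nuclei segmentation, label expansion into cell territories, and
spot-to-cell assignment.

Segmentation is the canonical watershed recipe for blob-like nuclei:
Otsu foreground, distance-transform peaks as seeds (minimum separation on
the order of the nucleus radius), watershed over the negative distance
transform. Territories are obtained by growing each nucleus label outward
by a Euclidean radius; equidistant ties go to the lower label id and labels
never overwrite each other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .config import Region, region_of

DEFAULT_EXPANSION_RADIUS = 10.0


@dataclass
class CellByGeneMatrix:
    """Decoded-read counts per segmented cell per gene.

    ``counts`` is indexed by cell label; ``cells`` carries centroids and
    region labels; ``unassigned`` tallies assigned-status spots that fell on
    background, per gene.
    """

    counts: pd.DataFrame
    cells: pd.DataFrame  # cell_id, x, y, region
    unassigned: pd.Series

    @property
    def total_assigned(self) -> int:
        return int(self.counts.to_numpy().sum() + self.unassigned.sum())


def segment_nuclei(
    image: np.ndarray, min_separation: int = 7
) -> np.ndarray:
    """Watershed-segment nuclei from a grayscale nuclear-stain image.

    Foreground by Otsu's threshold; seeds are local maxima of the Euclidean
    distance transform at least ``min_separation`` pixels apart (set this to
    roughly the expected nucleus radius); basins from watershed on the
    negative distance transform restricted to the foreground.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {image.shape}")
    if image.max() == image.min():
        return np.zeros(image.shape, dtype=np.int32)
    fg = image > threshold_otsu(image)
    if not fg.any():
        return np.zeros(image.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(fg)
    coords = peak_local_max(
        dist, min_distance=min_separation, labels=fg, exclude_border=False
    )
    seeds = np.zeros(image.shape, dtype=bool)
    seeds[tuple(coords.T)] = True
    markers, _ = ndi.label(seeds)
    return watershed(-dist, markers, mask=fg).astype(np.int32)


def expand_labels(labels: np.ndarray, radius: float = DEFAULT_EXPANSION_RADIUS) -> np.ndarray:
    """Grow each label into the background by a Euclidean ``radius``.

    Every background pixel within ``radius`` of a labelled pixel takes the
    label of its nearest labelled pixel; exact-tie pixels take the lowest
    competing label id. Existing labels are never overwritten, so the
    territory at radius r1 is a subset of the territory at r2 >= r1.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    labels = np.asarray(labels)
    out = labels.copy()
    if radius == 0 or labels.max() == 0:
        return out
    # candidate background pixels via the EDT, exact assignment via a KD-tree
    bg_dist = ndi.distance_transform_edt(labels == 0)
    grow = (labels == 0) & (bg_dist <= radius + 1e-9)
    if not grow.any():
        return out
    lab_pts = np.argwhere(labels > 0)
    lab_vals = labels[lab_pts[:, 0], lab_pts[:, 1]]
    tree = cKDTree(lab_pts)
    q = np.argwhere(grow)
    k = min(2, len(lab_pts))
    d, idx = tree.query(q, k=k)
    if k == 1:
        out[q[:, 0], q[:, 1]] = lab_vals[idx]
        return out
    chosen = lab_vals[idx[:, 0]]
    tie = (d[:, 1] - d[:, 0] < 1e-9) & (lab_vals[idx[:, 1]] != chosen)
    if tie.any():
        # re-query the rare >=2-way ties for every equidistant labelled pixel
        for qi in np.flatnonzero(tie):
            near = tree.query_ball_point(q[qi], r=d[qi, 0] + 1e-9)
            chosen[qi] = lab_vals[near].min()
    out[q[:, 0], q[:, 1]] = chosen
    return out


def _centroids(labels: np.ndarray, ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cents = ndi.center_of_mass(np.ones_like(labels), labels, ids)
    cents = np.asarray(cents, dtype=float).reshape(len(ids), 2)
    return cents[:, 1], cents[:, 0]  # x = col, y = row


def assign_spots(
    decoded: pd.DataFrame,
    territories: np.ndarray,
    regions: list[Region] | None = None,
    nuclei_labels: np.ndarray | None = None,
) -> CellByGeneMatrix:
    """Assign decoded spots to cell territories, building a cell x gene matrix.

    Only status ``assigned`` spots are counted; each increments the cell
    whose territory covers its (rounded) pixel, or the per-gene unassigned
    tally when that pixel is background. Cells are annotated with the region
    containing their nucleus centroid (``nuclei_labels``; falls back to the
    territory centroid when only territories are available).
    """
    territories = np.asarray(territories)
    h, w = territories.shape
    use = decoded[decoded["status"] == "assigned"]
    rows = np.rint(use["y"].to_numpy(dtype=float)).astype(int)
    cols = np.rint(use["x"].to_numpy(dtype=float)).astype(int)
    oob = (rows < 0) | (rows >= h) | (cols < 0) | (cols >= w)
    if oob.any():
        bad = use["spot_id"].to_numpy()[oob]
        raise ValueError(f"spots out of image bounds: {bad[:10].tolist()}")

    labels_at = territories[rows, cols]
    genes = use["gene"].astype(str).to_numpy()
    gene_names = sorted(set(genes))
    cell_ids = np.unique(territories)
    cell_ids = cell_ids[cell_ids > 0]

    counts = pd.DataFrame(
        0, index=pd.Index(cell_ids, name="cell_id"), columns=gene_names, dtype=np.int64
    )
    unassigned = pd.Series(0, index=gene_names, dtype=np.int64, name="unassigned")
    df = pd.DataFrame({"cell": labels_at, "gene": genes})
    grouped = df.groupby(["cell", "gene"]).size()
    for (cell, gene), n in grouped.items():
        if cell == 0:
            unassigned[gene] += n
        else:
            counts.at[cell, gene] += n

    centroid_src = nuclei_labels if nuclei_labels is not None else territories
    cx, cy = _centroids(np.asarray(centroid_src), cell_ids)
    cells = pd.DataFrame({"cell_id": cell_ids, "x": cx, "y": cy})
    if regions:
        cells["region"] = [region_of(x, regions) for x in cells["x"]]
        if cells["region"].isna().any():
            warnings.warn("some cell centroids fall outside every region strip")
    else:
        cells["region"] = None
    return CellByGeneMatrix(counts=counts, cells=cells.set_index("cell_id"), unassigned=unassigned)
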