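"""ISS barcode decoding: base calling, quality scoring, thresholding.

Each rolling-circle product is read over L sequencing cycles on four
fluorescence channels (A, C, G, T in fixed channel order). Per cycle the
called base is the channel with the highest intensity and its quality is
``max / sum`` of the four channel intensities — 1 for an unambiguous
one-hot signal, 0.25 for a completely uninformative one. The overall spot
quality is the minimum per-cycle quality: one bad cycle invalidates the
barcode. Spots below the quality threshold are ``low_quality``; spots whose
barcode is absent from the book are ``unexpected``; the rest are
``assigned`` to their gene and keep their 2D coordinates for mapping.
No crosstalk unmixing is applied before calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import BASES

#: default quality threshold — midpoint between uninformative (0.25) and perfect (1)
DEFAULT_QMIN = 0.5


@dataclass(frozen=True)
class BarcodeBook:
    """Gene -> barcode dictionary with the fixed base/channel mapping."""

    entries: dict[str, str]
    length: int = 4

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("barcode book is empty")
        seen: dict[str, str] = {}
        for gene, bc in self.entries.items():
            if len(bc) != self.length:
                raise ValueError(f"barcode {bc!r} for {gene!r} is not length {self.length}")
            if set(bc) - set(BASES):
                raise ValueError(f"barcode {bc!r} for {gene!r} uses bases outside ACGT")
            if bc in seen:
                raise ValueError(f"barcode {bc!r} shared by {seen[bc]!r} and {gene!r}")
            seen[bc] = gene
        object.__setattr__(self, "_by_barcode", seen)

    def channel_of(self, base: str) -> int:
        return BASES.index(base)

    def gene_of(self, barcode: str) -> Optional[str]:
        return self._by_barcode.get(barcode)

    @classmethod
    def from_csv(cls, path, length: int = 4) -> "BarcodeBook":
        df = pd.read_csv(path)
        return cls(dict(zip(df["gene"], df["barcode"])), length=length)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"gene": list(self.entries), "barcode": list(self.entries.values())}
        ).to_csv(path, index=False)


@dataclass
class DecodedSpot:
    spot_id: int
    x: float
    y: float
    barcode: str
    qualities: tuple[float, ...]
    gene: Optional[str] = None
    status: str = "low_quality"

    @property
    def quality(self) -> float:
        return min(self.qualities)


def call_bases(intensities: np.ndarray) -> tuple[str, np.ndarray]:
    """Call one base per cycle and compute per-cycle quality scores.

    ``intensities`` is an (L, 4) matrix of non-negative channel intensities.
    Per cycle the base is the argmax channel (ties break to the lowest
    channel index, i.e. A before C before G before T) and the quality is
    ``max / sum``. A cycle with zero total intensity yields quality 0 and
    the tie-rule base.
    """
    I = np.asarray(intensities, dtype=float)
    if I.ndim != 2 or I.shape[1] != len(BASES):
        raise ValueError(f"intensity matrix must be (cycles, {len(BASES)}), got {I.shape}")
    if not np.isfinite(I).all() or (I < 0).any():
        raise ValueError("intensities must be finite and non-negative")
    best = I.argmax(axis=1)
    totals = I.sum(axis=1)
    q = np.zeros(len(I))
    pos = totals > 0
    q[pos] = I[pos, best[pos]] / totals[pos]
    barcode = "".join(BASES[k] for k in best)
    return barcode, q


def decode_spots(
    spots: pd.DataFrame, book: BarcodeBook, q_min: float = DEFAULT_QMIN
) -> pd.DataFrame:
    """Decode a spot intensity table into genes with quality thresholding.

    ``spots`` needs columns spot_id, x, y and ``cycle{c}_ch{k}`` intensity
    columns (c = 1..L, k = 0..3). Returns one row per spot with the called
    barcode, the overall quality Q = min over cycles, the gene (where the
    barcode is in the book) and a status in {assigned, unexpected,
    low_quality}.
    """
    if not 0.0 <= q_min <= 1.0:
        raise ValueError("q_min must be in [0, 1]")
    L = book.length
    cols = [f"cycle{c}_ch{k}" for c in range(1, L + 1) for k in range(len(BASES))]
    missing = [c for c in cols if c not in spots.columns]
    if missing:
        raise KeyError(f"spot table lacks intensity columns: {missing[:4]}...")
    I = spots[cols].to_numpy(dtype=float).reshape(len(spots), L, len(BASES))
    if not np.isfinite(I).all() or (I < 0).any():
        raise ValueError("intensities must be finite and non-negative")

    best = I.argmax(axis=2)  # ties -> lowest channel index
    totals = I.sum(axis=2)
    q = np.zeros_like(totals)
    np.divide(
        np.take_along_axis(I, best[:, :, None], axis=2)[:, :, 0],
        totals,
        out=q,
        where=totals > 0,
    )
    Q = q.min(axis=1)
    base_arr = np.array(list(BASES))
    barcodes = ["".join(row) for row in base_arr[best]]
    genes = [book.gene_of(bc) for bc in barcodes]
    status = np.where(
        Q < q_min,
        "low_quality",
        np.where([g is not None for g in genes], "assigned", "unexpected"),
    )
    out = pd.DataFrame(
        {
            "spot_id": spots["spot_id"].to_numpy(),
            "x": spots["x"].to_numpy(),
            "y": spots["y"].to_numpy(),
            "barcode": barcodes,
            "quality": Q,
            "gene": genes,
            "status": status,
        }
    )
    out.loc[out["status"] != "assigned", "gene"] = None
    return out


def barcode_frequency(decoded: pd.DataFrame) -> pd.DataFrame:
    """Frequency of each decoded sequence, partitioned by status.

    Assigned barcodes are labelled with their gene; others with their
    status category. Counts sum to the number of input spots.
    """
    if decoded.empty:
        return pd.DataFrame(columns=["barcode", "label", "count"])
    label = decoded["gene"].where(decoded["status"] == "assigned", decoded["status"])
    out = (
        decoded.assign(label=label)
        .groupby(["barcode", "label"], observed=True)
        .size()
        .reset_index(name="count")
        .sort_values("count", ascending=False, ignore_index=True)
    )
    return out
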