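"""Marker-based calling of oligodendrocyte-lineage populations.

Two quantification modes mirror the two imaging readouts:

- *puncta* mode (RNAscope-style): a cell is lineage if Sox10-positive, and
  carries a population flag when its single diagnostic marker reaches a
  molecule cutoff — defaults Ptgds>=12 (MOL5/6), Klk6>=4 (MOL2), Egr2>=3
  (MOL1), Ptprz1>=7 (OPC/COP), derived from average expression in scRNA-seq.
- *ISS* mode: lineage requires Sox10 and Plp1 co-labelling at a read
  threshold t, and a population flag requires triple/quadruple
  co-expression — at least one configured marker pair with both genes >= t
  (MOL2: Anxa5&Klk6 or Anxa5&Hopx; MOL5/6: Ptgds&Car2 or Ptgds&Grm3).
  OPC/COP requires only Ptprz1 and Sox10 (Plp1 is also found in processes
  outside segmented cells, so it is not required for progenitors).

Population flags are deliberately non-exclusive: each population's
percentage is computed independently over the lineage denominator, matching
how the per-population quantification is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_PUNCTA_CUTOFFS: dict[str, tuple[str, int]] = {
    "MOL5/6": ("Ptgds", 12),
    "MOL2": ("Klk6", 4),
    "MOL1": ("Egr2", 3),
    "OPC/COP": ("Ptprz1", 7),
}

DEFAULT_ISS_PAIRS: dict[str, list[tuple[str, str]]] = {
    "MOL2": [("Anxa5", "Klk6"), ("Anxa5", "Hopx")],
    "MOL5/6": [("Ptgds", "Car2"), ("Ptgds", "Grm3")],
}


@dataclass
class MarkerRuleSet:
    """Marker rules for both quantification modes."""

    puncta_cutoffs: dict[str, tuple[str, int]] = field(
        default_factory=lambda: dict(DEFAULT_PUNCTA_CUTOFFS)
    )
    iss_pairs: dict[str, list[tuple[str, str]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_ISS_PAIRS.items()}
    )
    gate_genes: tuple[str, str] = ("Sox10", "Plp1")
    opc_marker: str = "Ptprz1"
    iss_threshold: int = 1  # decoded reads per gene per cell to count as positive

    def __post_init__(self) -> None:
        for pop, (marker, cutoff) in self.puncta_cutoffs.items():
            if cutoff <= 0 or int(cutoff) != cutoff:
                raise ValueError(f"cutoff for {pop!r} must be a positive integer")
        if self.iss_threshold < 1:
            raise ValueError("iss_threshold must be >= 1")


def classify_puncta(
    table: pd.DataFrame,
    rules: MarkerRuleSet | None = None,
    sox10_col: str = "sox10",
    reporter_col: str | None = None,
) -> pd.DataFrame:
    """Call populations from per-cell marker puncta counts.

    ``table`` needs a boolean Sox10-status column and one count column per
    rule marker. Returns per cell: ``lineage`` (Sox10+), one boolean column
    per population (count >= cutoff, only for lineage cells, flags
    non-exclusive), and ``reporter`` passed through when fate-mapping mode
    is on (the reporter then restricts the denominator downstream).
    """
    rules = rules or MarkerRuleSet()
    if sox10_col not in table.columns:
        raise KeyError(f"missing Sox10 status column {sox10_col!r}")
    for pop, (marker, _) in rules.puncta_cutoffs.items():
        if marker not in table.columns:
            raise KeyError(f"missing marker column {marker!r} required for {pop!r}")
    out = pd.DataFrame(index=table.index)
    if "cell_id" in table.columns:
        out["cell_id"] = table["cell_id"]
    if "region" in table.columns:
        out["region"] = table["region"]
    lineage = table[sox10_col].astype(bool)
    out["lineage"] = lineage
    for pop, (marker, cutoff) in rules.puncta_cutoffs.items():
        out[pop] = lineage & (table[marker] >= cutoff)
    if reporter_col is not None:
        if reporter_col not in table.columns:
            raise KeyError(f"missing reporter column {reporter_col!r}")
        out["reporter"] = table[reporter_col].astype(bool)
    if "Aspa" in table.columns:
        out["aspa"] = table["Aspa"] >= 1
    return out


def classify_iss(
    counts: pd.DataFrame,
    rules: MarkerRuleSet | None = None,
    cells: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Call populations from an ISS cell x gene read-count matrix.

    Lineage = Sox10 >= t AND Plp1 >= t; a population flag additionally
    requires one of its marker pairs fully at >= t (triple/quadruple
    co-expression). OPC/COP = Ptprz1 >= t AND Sox10 >= t, without the Plp1
    requirement. ``cells`` (optional) contributes a region column.
    """
    rules = rules or MarkerRuleSet()
    t = rules.iss_threshold
    sox10, plp1 = rules.gate_genes
    needed = {sox10, plp1, rules.opc_marker}
    for pairs in rules.iss_pairs.values():
        for a, b in pairs:
            needed |= {a, b}
    missing = sorted(needed - set(counts.columns))
    if missing:
        raise KeyError(f"cell x gene matrix lacks gene columns: {missing}")

    pos = counts >= t
    out = pd.DataFrame(index=counts.index)
    lineage = pos[sox10] & pos[plp1]
    out["lineage"] = lineage
    for pop, pairs in rules.iss_pairs.items():
        any_pair = np.zeros(len(counts), dtype=bool)
        for a, b in pairs:
            any_pair |= (pos[a] & pos[b]).to_numpy()
        out[pop] = lineage & any_pair
    out["OPC/COP"] = pos[sox10] & pos[rules.opc_marker]
    if cells is not None and "region" in cells.columns:
        out["region"] = cells["region"].reindex(counts.index)
    return out


def population_percentages(
    calls: pd.DataFrame,
    populations: list[str] | None = None,
    region_col: str = "region",
    denominator: str = "lineage",
) -> pd.DataFrame:
    """Per-region population percentages over a configurable denominator.

    ``denominator`` is one of:

    - ``lineage``: OL-lineage (Sox10+) cells — the standard quantification;
    - ``all_nuclei``: every segmented cell;
    - ``aspa``: Aspa+ mature oligodendrocytes (conditional-knockout mode);
    - ``reporter_lineage``: Sox10+ reporter+ cells (fate-mapping mode).

    Regions with a zero denominator get a missing percentage and a warning.
    """
    if region_col not in calls.columns:
        raise KeyError(f"calls table lacks region column {region_col!r}")
    reserved = {"cell_id", region_col, "lineage", "reporter", "aspa"}
    if populations is None:
        populations = [c for c in calls.columns if c not in reserved]
    if denominator == "lineage":
        denom_mask = calls["lineage"]
    elif denominator == "all_nuclei":
        denom_mask = pd.Series(True, index=calls.index)
    elif denominator == "aspa":
        denom_mask = calls["aspa"]
    elif denominator == "reporter_lineage":
        denom_mask = calls["lineage"] & calls["reporter"]
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")

    rows = []
    for region, grp in calls.groupby(region_col, dropna=False, observed=True):
        denom = int(denom_mask.loc[grp.index].sum())
        for pop in populations:
            n = int((grp[pop] & denom_mask.loc[grp.index]).sum())
            if denom == 0:
                warnings.warn(f"region {region!r} has a zero denominator; percentage missing")
                pct = np.nan
            else:
                pct = 100.0 * n / denom
            rows.append(
                {
                    "region": region,
                    "population": pop,
                    "n_flagged": n,
                    "denominator": denom,
                    "percentage": pct,
                }
            )
    return pd.DataFrame(rows)
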