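"""Cluster/population composition statistics.

Frequencies are made comparable across samples by column normalization
(each sample's cluster counts scaled to percentages summing to 100);
between-condition changes are reported in absolute percentage points.
Region x age/condition effects on per-animal percentages are tested with a
two-way ANOVA (Type-II sums of squares, suited to the unbalanced n=3-9
animals-per-cell designs typical here) and pairwise cell-mean contrasts on
the pooled residual variance with Sidak multiplicity correction,
p' = 1 - (1 - p)^m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats


def column_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each column (sample) of a cluster x sample count table to sum 100."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"zero-total columns left missing: {list(counts.columns[zero])}")
    out = 100.0 * counts / totals.replace(0, np.nan)
    return out


def composition_change(pct_a: pd.DataFrame, pct_b: pd.DataFrame) -> pd.DataFrame:
    """Percentage-point change B - A for matching population rows.

    Returns the wide change matrix; use :func:`to_long` for the
    heatmap-ready long format.
    """
    if set(pct_a.index) != set(pct_b.index):
        only_a = sorted(set(pct_a.index) - set(pct_b.index))
        only_b = sorted(set(pct_b.index) - set(pct_a.index))
        raise ValueError(f"row sets differ; only in A: {only_a}, only in B: {only_b}")
    return pct_b.reindex(pct_a.index) - pct_a


def to_long(change: pd.DataFrame, value_name: str = "delta_pct") -> pd.DataFrame:
    """Long-format (row, column, value) view of a change matrix for heatmaps."""
    out = change.reset_index(names="population").melt(
        id_vars="population", var_name="column", value_name=value_name
    )
    return out


def sidak_adjust(p: float | np.ndarray, m: int) -> np.ndarray:
    """Sidak multiplicity correction p' = 1 - (1 - p)^m for m comparisons."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    return 1.0 - (1.0 - p) ** m


@dataclass
class AnovaResult:
    """Two-way ANOVA effects plus Sidak-corrected pairwise comparisons."""

    effects: pd.DataFrame  # index: factor A, factor B, interaction, residual
    comparisons: pd.DataFrame  # group1, group2, diff, t, df, p_raw, p_sidak, m
    n_obs: int


def two_way_anova_sidak(
    data: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    comparisons: list[tuple[dict, dict]] | None = None,
) -> AnovaResult:
    """Two-way factorial ANOVA with Sidak-corrected pairwise contrasts.

    ``data`` holds one row per observation (per animal); ``comparisons`` is
    a list of pairs of cell selectors, e.g.
    ``({factor_a: "WM", factor_b: "P20"}, {factor_a: "WM", factor_b: "P60"})``
    — the within-region age contrasts typical of the composition figures.
    When omitted, all within-level-of-A contrasts of B's levels are used.
    Raw pairwise p comes from the pooled-residual t statistic; the Sidak
    family size m is the number of requested comparisons.
    """
    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise KeyError(f"data lacks column {col!r}")
    if data[factor_a].nunique() < 2 or data[factor_b].nunique() < 2:
        raise ValueError("each factor needs >= 2 levels")

    model = smf.ols(
        f"Q('{value}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))", data=data
    ).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table.index = [factor_a, factor_b, f"{factor_a}:{factor_b}", "residual"]
    mse = float(table.loc["residual", "sum_sq"] / table.loc["residual", "df"])
    df_resid = float(table.loc["residual", "df"])

    if comparisons is None:
        b_levels = sorted(data[factor_b].unique())
        comparisons = [
            ({factor_a: a, factor_b: b1}, {factor_a: a, factor_b: b2})
            for a in sorted(data[factor_a].unique())
            for i, b1 in enumerate(b_levels)
            for b2 in b_levels[i + 1 :]
        ]
    m = len(comparisons)

    rows = []
    for sel1, sel2 in comparisons:
        g1 = _select(data, sel1)[value].astype(float)
        g2 = _select(data, sel2)[value].astype(float)
        if len(g1) == 0 or len(g2) == 0:
            raise ValueError(f"empty cell in comparison {sel1} vs {sel2}")
        diff = g1.mean() - g2.mean()
        se = np.sqrt(mse * (1.0 / len(g1) + 1.0 / len(g2)))
        t = diff / se if se > 0 else np.nan
        p_raw = 2.0 * stats.t.sf(abs(t), df_resid) if np.isfinite(t) else np.nan
        rows.append(
            {
                "group1": _fmt(sel1),
                "group2": _fmt(sel2),
                "diff": diff,
                "t": t,
                "df": df_resid,
                "p_raw": p_raw,
                "p_sidak": float(sidak_adjust(p_raw, m)) if np.isfinite(t) else np.nan,
                "m": m,
            }
        )
    return AnovaResult(effects=table, comparisons=pd.DataFrame(rows), n_obs=len(data))


def _select(data: pd.DataFrame, sel: dict) -> pd.DataFrame:
    mask = pd.Series(True, index=data.index)
    for col, level in sel.items():
        mask &= data[col] == level
    return data[mask]


def _fmt(sel: dict) -> str:
    return "/".join(f"{k}={v}" for k, v in sel.items())
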