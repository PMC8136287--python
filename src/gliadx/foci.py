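"""Summary and comparison of per-nucleus ribonuclear foci counts."""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats

from .tables import FociTable


def summarize_foci(table: FociTable) -> pd.DataFrame:
    """Exact mean count and positive fraction per (cell_type, genotype)."""
    rows = []
    for (cell_type, genotype), grp in table.df.groupby(["cell_type", "genotype"]):
        counts = grp["foci_count"]
        if len(counts) == 0:  # pragma: no cover - groupby never yields empties
            warnings.warn(f"empty group {cell_type}/{genotype} omitted")
            continue
        rows.append(
            {
                "cell_type": cell_type,
                "genotype": genotype,
                "n_cells": int(len(counts)),
                "fraction_positive": float((counts > 0).mean()),
                "mean_foci": float(counts.mean()),
            }
        )
    return pd.DataFrame(rows)


def compare_foci_groups(
    table: FociTable,
    cell_types: list[str] | None = None,
    genotype: str = "DM",
    method: str = "anova",
) -> tuple[float, float]:
    """One-way comparison of foci counts across cell types (DM nuclei).

    ``method="anova"`` is the standard one-way ANOVA on raw counts;
    ``method="kruskal"`` is the rank-based alternative for the count
    non-normality purists.
    """
    df = table.df[table.df["genotype"] == genotype]
    if cell_types is not None:
        df = df[df["cell_type"].isin(set(cell_types))]
    groups = [g["foci_count"].to_numpy() for _, g in df.groupby("cell_type")]
    if len(groups) < 2:
        raise ValueError("need >= 2 cell types to compare")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs >= 2 cells")
    if method == "anova":
        res = stats.f_oneway(*groups)
    elif method == "kruskal":
        res = stats.kruskal(*groups)
    else:
        raise ValueError("method must be 'anova' or 'kruskal'")
    return float(res.statistic), float(res.pvalue)
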