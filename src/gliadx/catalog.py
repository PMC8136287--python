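"""Differentiation catalogs: features regulated across WT maturation.

A catalog lists genes (expression layer) or splicing events whose level
changes between a precursor and a differentiated WT stage, under the
same thresholds used for the genotype comparisons.  Catalogs from two
stage pairs of one trajectory can be merged into a union catalog with
per-entry provenance.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .expression import apply_de_filter, differential_expression, normalize_counts
from .splicing import apply_splicing_filter, differential_splicing
from .tables import GeneCountTable, SampleSheet, SplicingEventTable


def _stage_groups(sheet: SampleSheet, stage_from: str, stage_to: str):
    g1 = sheet.select(genotype="WT", stage=stage_from)
    g2 = sheet.select(genotype="WT", stage=stage_to)
    if not g1 or not g2:
        missing = stage_from if not g1 else stage_to
        raise ValueError(f"no WT samples at stage {missing!r}")
    return g1, g2


def build_expression_catalog(
    counts: GeneCountTable,
    sheet: SampleSheet,
    stage_from: str = "precursor",
    stage_to: str = "differentiated",
    fc_threshold: float = 1.4,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genes regulated during WT differentiation, with direction.

    Direction is the sign of the stage log2 fold change
    (differentiated vs precursor): ``up`` means activated with maturation.
    """
    g1, g2 = _stage_groups(sheet, stage_from, stage_to)
    sub = GeneCountTable(counts.df[["gene_id", *g1, *g2]].copy())
    _, normalized = normalize_counts(sub)
    records = differential_expression(normalized, g1, g2)
    sig = apply_de_filter(records, fc_threshold=fc_threshold, alpha=alpha)
    return pd.DataFrame(
        {
            "feature_id": sig["gene_id"],
            "layer": "expression",
            "direction": ["up" if x > 0 else "down" for x in sig["log2fc"]],
            "log2fc_diff": sig["log2fc"],
            "stage_pairs": f"{stage_from}->{stage_to}",
        }
    )


def build_splicing_catalog(
    events: SplicingEventTable,
    sheet: SampleSheet,
    stage_from: str = "precursor",
    stage_to: str = "differentiated",
    categories: Sequence[str] | None = None,
    dpsi_threshold: float = 10.0,
    alpha: float = 0.05,
    min_reads: int = 10,
) -> pd.DataFrame:
    """Splicing events regulated during WT differentiation.

    ``delta_psi_diff`` is differentiated minus precursor PSI;
    ``categories`` optionally restricts the census (e.g. to the three
    exon-block categories).
    """
    g1, g2 = _stage_groups(sheet, stage_from, stage_to)
    records = differential_splicing(events, g1, g2, min_reads=min_reads)
    if categories is not None:
        records = records[records["category"].isin(set(categories))].copy()
    sig = apply_splicing_filter(records, dpsi_threshold=dpsi_threshold, alpha=alpha)
    return pd.DataFrame(
        {
            "feature_id": sig["event_id"],
            "layer": "splicing",
            "direction": ["up" if x > 0 else "down" for x in sig["delta_psi"]],
            "delta_psi_diff": sig["delta_psi"],
            "category": sig["category"],
            "stage_pairs": f"{stage_from}->{stage_to}",
        }
    )


def merge_trajectory_stages(
    catalog_long: pd.DataFrame, catalog_late: pd.DataFrame
) -> pd.DataFrame:
    """Union of two stage-pair catalogs of one trajectory.

    Provenance (``stage_pairs``) records which screen(s) contributed.
    If a feature appears in both with conflicting directions, the entry
    from the longer (first) transition wins and ``direction_conflict``
    is flagged rather than silently resolved.
    """
    a = catalog_long.set_index("feature_id")
    b = catalog_late.set_index("feature_id")
    shared = a.index.intersection(b.index)
    merged = a.copy()
    merged["direction_conflict"] = False
    merged.loc[shared, "stage_pairs"] = (
        a.loc[shared, "stage_pairs"] + ";" + b.loc[shared, "stage_pairs"]
    )
    conflict = a.loc[shared, "direction"] != b.loc[shared, "direction"]
    merged.loc[shared[conflict], "direction_conflict"] = True
    only_b = b.loc[b.index.difference(a.index)].copy()
    only_b["direction_conflict"] = False
    out = pd.concat([merged, only_b]).reset_index()
    return out
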