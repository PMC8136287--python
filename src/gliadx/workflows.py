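"""End-to-end pipelines: generate a synthetic dataset, run the stage(s),
and collect the census numbers.

These are the units the numbered analysis scripts, the test suite and
the acceptance script all share, so a census printed anywhere is always
recomputed from a generated dataset at call time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .catalog import (
    build_expression_catalog,
    build_splicing_catalog,
    merge_trajectory_stages,
)
from .concordance import (
    ConcordanceReport,
    classify_expression_concordance,
    classify_splicing_concordance,
    cross_celltype_overlap,
    direction_bias_test,
    overlap_test,
)
from .config import SimulationConfig
from .expression import apply_de_filter, differential_expression, normalize_counts
from .phospho import census_direction, differential_phospho, splicing_phospho_overlap
from .foci import compare_foci_groups, summarize_foci
from .simulate import (
    generate_expression_dataset,
    generate_foci_counts,
    generate_phospho_dataset,
    generate_splicing_dataset,
)
from .splicing import apply_splicing_filter, differential_splicing
from .tables import EXON_CATEGORIES, SampleSheet, SimulationTruth


@dataclass
class StageResult:
    """One differential comparison: full records plus the significant set."""

    records: pd.DataFrame
    significant: pd.DataFrame
    sheet: SampleSheet
    truth: SimulationTruth
    extra: dict = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return len(self.significant)


def recovery_stats(
    called: set[str], truth: SimulationTruth, positive_labels: tuple[str, ...]
) -> dict:
    """Sensitivity and false-discovery proportion against planted truth."""
    planted = truth.features(*positive_labels)
    tp = len(called & planted)
    return {
        "n_called": len(called),
        "n_planted": len(planted),
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "fdp": (len(called) - tp) / len(called) if called else 0.0,
    }


def expression_census(config: SimulationConfig, seed: int) -> StageResult:
    """Genotype DE census at the comparison stage of one cell type."""
    counts, sheet, truth = generate_expression_dataset(config, seed)
    stage = config.expression.comparison_stage
    wt = sheet.select(genotype="WT", stage=stage)
    dm = sheet.select(genotype="DM", stage=stage)
    _, normalized = normalize_counts(counts)
    records = differential_expression(normalized, wt, dm)
    sig = apply_de_filter(records, config.fc_threshold, config.alpha)
    n_up = int((sig["log2fc"] > 0).sum())
    return StageResult(
        records,
        sig,
        sheet,
        truth,
        extra={
            "counts": counts,
            "normalized": normalized,
            "n_up": n_up,
            "n_down": len(sig) - n_up,
            "recovery": recovery_stats(
                set(sig["gene_id"]), truth, ("de_up", "de_down")
            ),
        },
    )


def splicing_census(config: SimulationConfig, seed: int) -> StageResult:
    """Genotype splicing census (all five categories) of one cell type."""
    events, sheet, truth = generate_splicing_dataset(config, seed)
    stage = config.splicing.comparison_stage
    wt = sheet.select(genotype="WT", stage=stage)
    dm = sheet.select(genotype="DM", stage=stage)
    records = differential_splicing(events, wt, dm, min_reads=config.min_reads)
    sig = apply_splicing_filter(records, config.dpsi_threshold, config.alpha)
    by_category = sig["category"].value_counts().to_dict()
    return StageResult(
        records,
        sig,
        sheet,
        truth,
        extra={
            "events": events,
            "by_category": by_category,
            "universe": set(records.loc[records["testable"], "event_id"]),
            "recovery": recovery_stats(
                set(sig["event_id"]), truth, ("splice_up", "splice_down")
            ),
        },
    )


def expression_concordance(config: SimulationConfig, seed: int) -> dict:
    """Disease DE vs the WT differentiation program (expression layer).

    Returns the overlap report (universe = genes testable in both
    comparisons), the per-gene concordance classes and their counts.
    """
    result = expression_census(config, seed)
    counts = result.extra["counts"]
    stages = config.expression.stages
    catalog = build_expression_catalog(
        counts,
        result.sheet,
        stage_from=stages[0],
        stage_to=config.expression.comparison_stage,
        fc_threshold=config.fc_threshold,
        alpha=config.alpha,
    )
    universe = set(result.records.loc[result.records["testable"], "gene_id"])
    report = overlap_test(
        set(result.significant["gene_id"]) & universe,
        set(catalog["feature_id"]) & universe,
        universe,
    )
    classes = classify_expression_concordance(result.significant, catalog)
    class_counts = classes.value_counts().to_dict()
    report.class_counts = class_counts
    failed = class_counts.get("failed_activation", 0)
    other = report.n_overlap - failed
    report.p_direction_bias = (
        direction_bias_test(failed, other) if report.n_overlap else None
    )
    return {
        "census": result,
        "catalog": catalog,
        "report": report,
        "classes": classes,
        "class_counts": class_counts,
    }


def splicing_concordance(config: SimulationConfig, seed: int) -> dict:
    """Disease splicing vs the WT differentiation splicing catalog.

    Exon-block events only (cassette, multi-exon, mutually exclusive).
    With a three-stage trajectory config the catalog is the union of the
    precursor->differentiated and intermediate->differentiated screens.
    """
    result = splicing_census(config, seed)
    events = result.extra["events"]
    stages = config.splicing.stages
    kwargs = dict(
        categories=EXON_CATEGORIES,
        dpsi_threshold=config.dpsi_threshold,
        alpha=config.alpha,
        min_reads=config.min_reads,
    )
    if len(stages) == 3:
        cat_long = build_splicing_catalog(
            events, result.sheet, stages[0], stages[2], **kwargs
        )
        cat_late = build_splicing_catalog(
            events, result.sheet, stages[1], stages[2], **kwargs
        )
        catalog = merge_trajectory_stages(cat_long, cat_late)
        catalog_parts = {
            "long": len(cat_long),
            "late": len(cat_late),
            "shared": len(set(cat_long["feature_id"]) & set(cat_late["feature_id"])),
        }
    else:
        catalog = build_splicing_catalog(
            events, result.sheet, stages[0], stages[1], **kwargs
        )
        catalog["direction_conflict"] = False
        catalog_parts = {"long": len(catalog), "late": 0, "shared": 0}

    disease_exon = result.significant[
        result.significant["category"].isin(EXON_CATEGORIES)
    ]
    classes = classify_splicing_concordance(disease_exon, catalog)
    class_counts = classes.value_counts().to_dict()
    n_imm = class_counts.get("immature_shift", 0)
    n_mat = class_counts.get("mature_shift", 0)

    testable_exon = result.records.loc[
        result.records["testable"]
        & result.records["category"].isin(EXON_CATEGORIES),
        "event_id",
    ]
    universe = set(testable_exon)
    report = overlap_test(
        set(disease_exon["event_id"]) & universe,
        set(catalog["feature_id"]) & universe,
        universe,
    )
    report.class_counts = class_counts
    report.p_direction_bias = (
        direction_bias_test(n_imm, n_mat) if (n_imm + n_mat) else None
    )
    return {
        "census": result,
        "catalog": catalog,
        "catalog_parts": catalog_parts,
        "classes": classes,
        "class_counts": class_counts,
        "n_immature": n_imm,
        "n_mature": n_mat,
        "report": report,
    }


def glial_splicing_overlap(
    config_a: SimulationConfig, config_b: SimulationConfig, seed: int
) -> dict:
    """Splicing censuses of two glial cell types and their event overlap."""
    res_a = splicing_census(config_a, seed)
    res_b = splicing_census(config_b, seed + 1)
    table = cross_celltype_overlap(
        {
            config_a.cell_type: set(res_a.significant["event_id"]),
            config_b.cell_type: set(res_b.significant["event_id"]),
        },
        {
            config_a.cell_type: res_a.extra["universe"],
            config_b.cell_type: res_b.extra["universe"],
        },
    )
    return {
        config_a.cell_type: res_a,
        config_b.cell_type: res_b,
        "overlap": table,
        "n_shared_called": int(table.iloc[0]["n_overlap"]),
    }


def phospho_census(config: SimulationConfig, seed: int) -> dict:
    """Differential phosphosite census plus the splicing cross-layer overlap.

    The misspliced gene set comes from the same config's splicing census
    (run at ``seed + 1``); proteins map to genes by their ``P_<gene>``
    naming, mirroring a leading-protein gene assignment.
    """
    table, sheet, truth = generate_phospho_dataset(config, seed)
    wt = sheet.select(genotype="WT")
    dm = sheet.select(genotype="DM")
    records = differential_phospho(
        table, wt, dm, fc_threshold=config.fc_threshold, alpha=config.alpha
    )
    n_up, n_down, p_bias = census_direction(records)
    sig = records[records["significant"]]
    sig_proteins = set(sig["protein_id"])

    splice_result = splicing_census(config, seed + 1)
    misspliced = set(splice_result.significant["gene_id"])
    protein_to_gene = {p: p[2:] for p in records["protein_id"]}
    gene_universe = set(protein_to_gene.values())
    overlap, n_unmapped = splicing_phospho_overlap(
        sig_proteins, misspliced & gene_universe, protein_to_gene, gene_universe
    )
    return {
        "records": records,
        "truth": truth,
        "n_significant_sites": int(records["significant"].sum()),
        "n_significant_proteins": len(sig_proteins),
        "n_up": n_up,
        "n_down": n_down,
        "p_direction_bias": p_bias,
        "overlap": overlap,
        "n_unmapped": n_unmapped,
        "recovery": recovery_stats(
            set(sig["site_id"]), truth, ("phospho_up", "phospho_down")
        ),
    }


def foci_census(configs: dict[str, SimulationConfig], seed: int) -> dict:
    """Foci summaries per cell type plus the DM cross-cell-type ANOVA."""
    frames = []
    for offset, (cell_type, cfg) in enumerate(sorted(configs.items())):
        table, _ = generate_foci_counts(cfg, seed + offset, cell_type=cell_type)
        frames.append(table.df)
    from .tables import FociTable

    combined = FociTable(pd.concat(frames, ignore_index=True))
    summary = summarize_foci(combined)
    f_stat, p = compare_foci_groups(combined, method="anova")
    return {"table": combined, "summary": summary, "anova_F": f_stat, "anova_p": p}
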