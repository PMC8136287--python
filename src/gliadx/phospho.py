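"""Differential phosphosite analysis under the dual detection rule.

A site is significant either by the detection rule — present in every
replicate of one genotype and absent from every replicate of the other
("genotype-exclusive") — or by the quantitative rule: Welch t on log2
intensities with |fold change| > 1.4 and BH q < 0.05.  Sites with
fewer than two observed values per group that are not fully partitioned
are untestable.  No imputation: missingness is informative here.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .concordance import ConcordanceReport, direction_bias_test, overlap_test
from .tables import PhosphoSiteTable

STATUSES = (
    "genotype_exclusive_DM",
    "genotype_exclusive_WT",
    "quantitative",
    "not_significant",
    "untestable",
)


def differential_phospho(
    table: PhosphoSiteTable,
    group_wt: list[str],
    group_dm: list[str],
    fc_threshold: float = 1.4,
    alpha: float = 0.05,
    min_present: int = 2,
    fold_change_scale: str = "linear",
) -> pd.DataFrame:
    """Per-site status, direction and (for the quantitative branch) p/q.

    Fold change is the ratio of arithmetic group means of linear-scale
    intensities (``fold_change_scale="log"`` switches to the ratio of
    geometric means).  BH runs over quantitative-branch sites only; the
    exclusive calls are rule-based, without a p-value.
    """
    if not group_wt or not group_dm:
        raise ValueError("both genotype groups need at least one sample")
    mat = table.matrix()
    x_wt = mat[group_wt].to_numpy(dtype=float)
    x_dm = mat[group_dm].to_numpy(dtype=float)
    present_wt = ~np.isnan(x_wt)
    present_dm = ~np.isnan(x_dm)
    n_wt = present_wt.sum(axis=1)
    n_dm = present_dm.sum(axis=1)

    excl_dm = (n_dm == len(group_dm)) & (n_wt == 0)
    excl_wt = (n_wt == len(group_wt)) & (n_dm == 0)
    quant = (~excl_dm) & (~excl_wt) & (n_wt >= min_present) & (n_dm >= min_present)

    log_wt = np.log2(x_wt)
    log_dm = np.log2(x_dm)
    with warnings.catch_warnings():
        # exclusive sites are all-NaN in one genotype; their fc is unused
        warnings.simplefilter("ignore", RuntimeWarning)
        if fold_change_scale == "linear":
            fc = np.nanmean(x_dm, axis=1) / np.nanmean(x_wt, axis=1)
        elif fold_change_scale == "log":
            fc = np.exp2(np.nanmean(log_dm, axis=1) - np.nanmean(log_wt, axis=1))
        else:
            raise ValueError("fold_change_scale must be 'linear' or 'log'")

    p = np.full(mat.shape[0], np.nan)
    idx = np.flatnonzero(quant)
    for i in idx:
        a = log_dm[i][present_dm[i]]
        b = log_wt[i][present_wt[i]]
        p[i] = stats.ttest_ind(a, b, equal_var=False)[1]
    q = np.full_like(p, np.nan)
    if len(idx):
        q[idx] = multipletests(p[idx], method="fdr_bh")[1]

    with np.errstate(invalid="ignore", divide="ignore"):
        abs_fc = np.maximum(fc, 1.0 / fc)
    quant_sig = quant & (abs_fc > fc_threshold) & (q < alpha)

    status = np.where(
        excl_dm,
        "genotype_exclusive_DM",
        np.where(
            excl_wt,
            "genotype_exclusive_WT",
            np.where(quant_sig, "quantitative",
                     np.where(quant, "not_significant", "untestable")),
        ),
    )
    direction = np.where(
        excl_dm, "up", np.where(excl_wt, "down", np.where(fc > 1, "up", "down"))
    )
    significant = excl_dm | excl_wt | quant_sig

    out = pd.DataFrame(
        {
            "site_id": mat.index,
            "protein_id": table.df["protein_id"].to_numpy(),
            "status": status,
            "direction": np.where(significant, direction, ""),
            "log2fc": np.where(quant, np.log2(fc), np.nan),
            "p": p,
            "q": q,
            "significant": significant,
        }
    ).reset_index(drop=True)
    return out


def census_direction(records: pd.DataFrame) -> tuple[int, int, float | None]:
    """(n_up, n_down) over significant sites plus the direction-bias p.

    Returns p = None (reported as NA downstream) when no site is
    significant.
    """
    sig = records[records["significant"]]
    n_up = int((sig["direction"] == "up").sum())
    n_down = int((sig["direction"] == "down").sum())
    if n_up + n_down == 0:
        return 0, 0, None
    return n_up, n_down, direction_bias_test(n_up, n_down)


def splicing_phospho_overlap(
    phospho_proteins: Iterable[str],
    misspliced_genes: Iterable[str],
    protein_to_gene: Mapping[str, str],
    universe_genes: Iterable[str],
) -> tuple[ConcordanceReport, int]:
    """Overlap between differentially phosphorylated proteins (mapped to
    genes) and misspliced genes; returns the report and the number of
    proteins excluded for lacking a gene mapping."""
    proteins = set(phospho_proteins)
    mapped = {protein_to_gene[p] for p in proteins if p in protein_to_gene}
    n_unmapped = len([p for p in proteins if p not in protein_to_gene])
    universe = set(universe_genes)
    report = overlap_test(mapped & universe, set(misspliced_genes) & universe, universe)
    return report, n_unmapped


def ora(
    hits: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Generic over-representation analysis of a hit set against term sets.

    One hypergeometric enrichment per term (restricted to the universe),
    BH-corrected across terms; empty terms are skipped.
    """
    hits = set(hits)
    universe = set(universe)
    if not hits <= universe:
        raise ValueError("hits must be contained in the universe")
    rows = []
    for term, members in annotation.items():
        members = set(members) & universe
        if not members:
            continue
        rep = overlap_test(hits, members, universe)
        rows.append(
            {
                "term": term,
                "n_term": len(members),
                "n_overlap": rep.n_overlap,
                "expected_overlap": rep.expected_overlap,
                "representation_factor": rep.representation_factor,
                "p": rep.p_hypergeom,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
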