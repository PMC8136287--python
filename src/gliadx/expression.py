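"""Differential gene expression between two sample groups.

Normalization is median-of-ratios: each sample's size factor is the
median, over genes detected in every sample, of the ratio between its
count and the gene's geometric mean across samples.  Testing is a Welch
t-test on log2(normalized count + pseudocount) with Benjamini-Hochberg
correction; the significance rule is |fold change| > 1.4 (strict) and
q < 0.05, applied to the raw (unshrunken) fold change.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import GeneCountTable

PSEUDOCOUNT = 0.5


def normalize_counts(counts: GeneCountTable) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized count matrix.

    Raises ``ValueError`` if no gene has a nonzero count in every sample
    (the geometric-mean reference would be empty); filter low-coverage
    genes first in that case.
    """
    mat = counts.matrix()
    arr = mat.to_numpy(dtype=float)
    all_pos = np.all(arr > 0, axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene detected in all samples; filter the count table before "
            "normalization"
        )
    ref = arr[all_pos]
    log_geo_mean = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_geo_mean[:, None]
    size_factors = pd.Series(
        np.exp(np.median(ratios, axis=0)), index=mat.columns, name="size_factor"
    )
    normalized = mat / size_factors
    return size_factors, normalized


def differential_expression(
    normalized: pd.DataFrame,
    group1: list[str],
    group2: list[str],
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene effect sizes and Welch-t p-values, group2 vs group1.

    Genes with zero counts in all samples of both groups are excluded
    from testing and from the BH denominator.  Returns a frame with
    ``gene_id, base_mean, fold_change, log2fc, p, q``.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group needs >= 2 samples (variance undefined)")
    for s in [*group1, *group2]:
        if s not in normalized.columns:
            raise KeyError(f"unknown sample {s!r}")
    x1 = normalized[group1].to_numpy(dtype=float)
    x2 = normalized[group2].to_numpy(dtype=float)

    testable = (x1.sum(axis=1) + x2.sum(axis=1)) > 0
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    base_mean = np.concatenate([x1, x2], axis=1).mean(axis=1)
    fold_change = (m2 + pseudocount) / (m1 + pseudocount)
    log2fc = np.log2(fold_change)

    l1 = np.log2(x1 + pseudocount)
    l2 = np.log2(x2 + pseudocount)
    with warnings.catch_warnings():
        # constant rows (e.g. all-zero genes) trigger a precision warning;
        # their p is forced to 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(l2, l1, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)

    q = np.full(len(p), np.nan)
    if testable.any():
        q[testable] = multipletests(p[testable], method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "gene_id": normalized.index,
            "base_mean": base_mean,
            "fold_change": fold_change,
            "log2fc": log2fc,
            "p": np.where(testable, p, np.nan),
            "q": q,
            "testable": testable,
        }
    ).reset_index(drop=True)
    return out


def apply_de_filter(
    records: pd.DataFrame, fc_threshold: float = 1.4, alpha: float = 0.05
) -> pd.DataFrame:
    """Keep records with |fold change| > fc_threshold and q < alpha (strict).

    "Absolute" fold change means max(fc, 1/fc), so 2-fold down passes the
    same 1.4 gate as 2-fold up.  Also annotates the input frame with a
    ``significant`` column in place.
    """
    fc = records["fold_change"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        abs_fc = np.maximum(fc, np.where(fc > 0, 1.0 / fc, np.inf))
    sig = (abs_fc > fc_threshold) & (records["q"].to_numpy() < alpha)
    sig &= records["testable"].to_numpy(dtype=bool) if "testable" in records else True
    records["significant"] = sig
    return records.loc[sig].reset_index(drop=True)
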