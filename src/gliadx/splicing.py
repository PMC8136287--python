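"""PSI quantification and differential splicing between two groups.

PSI is inclusion / (inclusion + exclusion), in percent, undefined (NaN)
when both counts are zero.  For the group comparison, replicate counts
are pooled within each group and a two-sided Fisher exact test is run on
the 2x2 table [[inc1, exc1], [inc2, exc2]]; events need >= ``min_reads``
pooled informative reads in BOTH groups to be testable.  BH correction
runs jointly over all testable events (all five categories at once), one
census per comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import SplicingEventTable

DEFAULT_MIN_READS = 10


def compute_psi(inclusion, exclusion):
    """Percent spliced in: 100 * inc / (inc + exc); NaN when both zero.

    Accepts scalars or arrays.
    """
    inc = np.asarray(inclusion, dtype=float)
    exc = np.asarray(exclusion, dtype=float)
    if np.any(inc < 0) or np.any(exc < 0):
        raise ValueError("counts must be nonnegative")
    total = inc + exc
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(total > 0, 100.0 * inc / total, np.nan)
    if psi.ndim == 0:
        return float(psi)
    return psi


def per_replicate_psi(events: SplicingEventTable) -> pd.DataFrame:
    """PSI per event and sample (inspection aid for the pooled test)."""
    inc = events.inclusion().to_numpy(dtype=float)
    exc = events.exclusion().to_numpy(dtype=float)
    psi = compute_psi(inc, exc)
    return pd.DataFrame(psi, index=events.df["event_id"], columns=events.samples)


def differential_splicing(
    events: SplicingEventTable,
    group1: list[str],
    group2: list[str],
    min_reads: int = DEFAULT_MIN_READS,
) -> pd.DataFrame:
    """Pooled-count Fisher test per event, group2 vs group1 (DM - WT).

    Returns ``event_id, gene_id, category, psi_group1, psi_group2,
    delta_psi, p, q, testable``; p and q are NaN for untestable events.
    """
    known = set(events.samples)
    for s in [*group1, *group2]:
        if s not in known:
            raise KeyError(f"unknown sample {s!r} in group specification")

    inc1 = events.inclusion(group1).sum(axis=1).to_numpy(dtype=np.int64)
    exc1 = events.exclusion(group1).sum(axis=1).to_numpy(dtype=np.int64)
    inc2 = events.inclusion(group2).sum(axis=1).to_numpy(dtype=np.int64)
    exc2 = events.exclusion(group2).sum(axis=1).to_numpy(dtype=np.int64)

    testable = ((inc1 + exc1) >= min_reads) & ((inc2 + exc2) >= min_reads)
    psi1 = compute_psi(inc1, exc1)
    psi2 = compute_psi(inc2, exc2)
    delta = psi2 - psi1

    p = np.full(len(testable), np.nan)
    cache: dict[tuple[int, int, int, int], float] = {}
    for i in np.flatnonzero(testable):
        key = (inc1[i], exc1[i], inc2[i], exc2[i])
        pv = cache.get(key)
        if pv is None:
            pv = stats.fisher_exact([[key[0], key[1]], [key[2], key[3]]])[1]
            cache[key] = pv
        p[i] = pv

    q = np.full(len(testable), np.nan)
    if testable.any():
        q[testable] = multipletests(p[testable], method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "event_id": events.df["event_id"],
            "gene_id": events.df["gene_id"],
            "category": events.df["category"],
            "psi_group1": psi1,
            "psi_group2": psi2,
            "delta_psi": delta,
            "p": p,
            "q": q,
            "testable": testable,
        }
    )


def apply_splicing_filter(
    records: pd.DataFrame, dpsi_threshold: float = 10.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Keep testable events with |delta PSI| > threshold and q < alpha (strict)."""
    delta = records["delta_psi"].to_numpy(dtype=float)
    q = records["q"].to_numpy(dtype=float)
    sig = (
        records["testable"].to_numpy(dtype=bool)
        & (np.abs(delta) > dpsi_threshold)
        & (q < alpha)
    )
    records["significant"] = sig
    return records.loc[sig].reset_index(drop=True)
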