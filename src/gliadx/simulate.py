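"""Synthetic dataset generators with planted, labeled effects.

Each generator draws from the statistical model the downstream stage
assumes (negative-binomial gene counts, binomial inclusion counts given
per-event PSI, Gaussian log-intensities with detection dropout,
zero-inflated Poisson foci counts) and emits a :class:`SimulationTruth`
table labelling every planted feature, so recovery can be scored without
external data.

Feature identifiers are deterministic functions of the configuration
(not of the random stream): planted features occupy the leading indices
of each category, and events shared between the two glial cell types use
a common ``SHGL`` namespace in both datasets, which is what links the
astrocyte and oligodendrocyte tables without passing objects around.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import ConfigError, FociSim, SimulationConfig
from .tables import (
    EXON_CATEGORIES,
    FociTable,
    GeneCountTable,
    PhosphoSiteTable,
    SampleSheet,
    SimulationTruth,
    SplicingEventTable,
)

_CAT_CODE = {
    "cassette": "CA",
    "multi_exon": "ME",
    "mutually_exclusive": "MX",
    "acceptor_switch": "AC",
    "donor_switch": "DO",
}
_CT_CODE = {"neuron": "NEU", "OPC": "OPC", "OL": "OLG", "astrocyte": "AST",
            "NSC": "NSC", "astrocyte_precursor": "ASP"}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _sample_sheet(cell_type: str, stages, n_replicates: int) -> SampleSheet:
    rows = []
    for stage in stages:
        for genotype in ("WT", "DM"):
            for r in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{cell_type}_{genotype}_{stage}_r{r}",
                        "genotype": genotype,
                        "cell_type": cell_type,
                        "stage": stage,
                        "replicate": r,
                    }
                )
    return SampleSheet(pd.DataFrame(rows))


# -- expression ---------------------------------------------------------------

def generate_expression_dataset(
    config: SimulationConfig, seed: int
) -> tuple[GeneCountTable, SampleSheet, SimulationTruth]:
    """Simulate gene-level counts with planted genotype and stage effects.

    Counts are NB-distributed around gene baselines (log-normal across
    genes) scaled by a per-sample size factor.  Planted disease genes
    change ``de_log2fc`` between genotypes at the comparison stage only;
    differentiation-program genes change between WT precursor and
    differentiated stages (DM follows WT except where a disease effect
    overrides the differentiated value).
    """
    config.validate()
    expr = config.expression
    rng = np.random.default_rng(seed)
    ct = config.cell_type
    sheet = _sample_sheet(ct, expr.stages, expr.n_replicates)

    n = expr.n_genes
    gene_ids = np.array([f"G_{_CT_CODE[ct]}_{i:06d}" for i in range(n)])

    plan = expr.concordance
    n_plan = plan.total if plan else 0
    # disease gene layout: [plan-classified | extra up | extra down]
    de_dir = np.zeros(n, dtype=int)       # genotype effect sign
    diff_dir = np.zeros(n, dtype=int)     # maturation effect sign
    idx = 0
    if plan:
        for count, d_dir, c_dir in (
            (plan.failed_activation, -1, +1),
            (plan.failed_repression, +1, -1),
            (plan.accentuated_up, +1, +1),
            (plan.accentuated_down, -1, -1),
        ):
            de_dir[idx : idx + count] = d_dir
            diff_dir[idx : idx + count] = c_dir
            idx += count
    used_up = int(np.sum(de_dir[:idx] == 1))
    used_down = int(np.sum(de_dir[:idx] == -1))
    extra_up = expr.n_de_up - used_up
    extra_down = expr.n_de_down - used_down
    de_dir[idx : idx + extra_up] = +1
    idx += extra_up
    de_dir[idx : idx + extra_down] = -1
    idx += extra_down
    n_de = idx  # == expr.n_de

    # remaining differentiation-program genes follow the disease block
    n_diff_extra = max(expr.n_diff_genes - n_plan, 0)
    diff_slice = slice(n_de, n_de + n_diff_extra)
    signs = np.where(np.arange(n_diff_extra) % 2 == 0, 1, -1)
    diff_dir[diff_slice] = signs

    planted = (de_dir != 0) | (diff_dir != 0)
    baseline = np.exp(rng.normal(expr.log_mu_mean, expr.log_mu_sigma, size=n))
    lo, hi = math.log(expr.planted_min_mu), math.log(expr.planted_max_mu)
    baseline[planted] = np.exp(rng.uniform(lo, hi, size=int(planted.sum())))

    sample_ids = sheet.sample_ids
    size_factors = np.exp(rng.normal(0.0, expr.size_factor_sigma, len(sample_ids)))
    counts = np.empty((n, len(sample_ids)), dtype=np.int64)
    precursor = expr.stages[0]
    for j, sid in enumerate(sample_ids):
        row = sheet.df.loc[sheet.df["sample_id"] == sid].iloc[0]
        mean = baseline.copy()
        if len(expr.stages) > 1 and row["stage"] == precursor:
            # differentiated level is the baseline; precursor departs from it
            mean = mean * 2.0 ** (-diff_dir * expr.diff_log2fc)
        if row["genotype"] == "DM" and row["stage"] == expr.comparison_stage:
            mean = mean * 2.0 ** (de_dir * expr.de_log2fc)
        counts[:, j] = _nb_draw(rng, mean * size_factors[j], expr.dispersion)

    table = GeneCountTable(
        pd.DataFrame({"gene_id": gene_ids, **{s: counts[:, j] for j, s in enumerate(sample_ids)}})
    )

    rows = []
    for i in range(n):
        if de_dir[i] != 0:
            rows.append((gene_ids[i], "expression",
                         "de_up" if de_dir[i] > 0 else "de_down",
                         de_dir[i] * expr.de_log2fc))
        if diff_dir[i] != 0:
            rows.append((gene_ids[i], "expression",
                         "differentiation_up" if diff_dir[i] > 0 else "differentiation_down",
                         diff_dir[i] * expr.diff_log2fc))
        if de_dir[i] == 0 and diff_dir[i] == 0:
            rows.append((gene_ids[i], "expression", "null", 0.0))
    truth = SimulationTruth(
        pd.DataFrame(rows, columns=["feature_id", "layer", "label", "effect"])
    )
    return table, sheet, truth


# -- splicing -----------------------------------------------------------------

@dataclass
class _Event:
    event_id: str
    gene_id: str
    category: str
    # psi[(stage, genotype)] in percent
    psi: dict
    disease_delta: float = 0.0     # DM - WT at the comparison stage
    diff_delta: float = 0.0        # maturation delta over the operative transition
    diff_group: str = ""           # "", "two_stage", "early_only", "late_only", "both"
    concordance: str = ""          # "", "immature", "mature"
    shared: bool = False


def _clip_psi(x: float) -> float:
    return float(min(max(x, 1.0), 99.0))


def _plan_events(config: SimulationConfig, rng: np.random.Generator) -> list[_Event]:
    spl = config.splicing
    ct = config.cell_type
    stages = spl.stages
    comp = spl.comparison_stage
    dpsi = spl.delta_psi
    ddpsi = spl.diff_delta_psi

    # concordance plan spread over exon-block categories (cassette-heavy)
    conc_by_cat = {c: [0, 0] for c in EXON_CATEGORIES}  # [immature, mature]
    if spl.concordance:
        weights = {"cassette": 0.8, "multi_exon": 0.13, "mutually_exclusive": 0.07}
        for k, total in (
            (0, spl.concordance.n_immature),
            (1, spl.concordance.n_mature),
        ):
            alloc = _largest_remainder(total, weights)
            for c in EXON_CATEGORIES:
                cap = spl.n_true.get(c, 0)
                conc_by_cat[c][k] = alloc[c]
            _rebalance(conc_by_cat, spl.n_true, k)

    # catalog-only events (differentiation-regulated, not disease)
    if spl.trajectory:
        n_cat_only = {
            "early_only": spl.trajectory.n_early_only - sum(
                v[0] + v[1] for v in conc_by_cat.values()
            ),
            "late_only": spl.trajectory.n_late_only,
            "both": spl.trajectory.n_both,
        }
    else:
        n_cat_only = {"two_stage": max(spl.n_diff_events - (spl.concordance.total if spl.concordance else 0), 0)}
    cat_only_weights = {"cassette": 0.7, "multi_exon": 0.2, "mutually_exclusive": 0.1}

    events: list[_Event] = []
    for category, total in spl.n_events.items():
        code = _CAT_CODE[category]
        n_true = spl.n_true.get(category, 0)
        offset = spl.plant_offsets.get(category, 0)
        n_imm, n_mat = conc_by_cat.get(category, (0, 0))
        # catalog-only allocation for this category
        cat_only_here = {}
        for group, n_group in n_cat_only.items():
            cat_only_here[group] = _largest_remainder(n_group, cat_only_weights).get(category, 0)

        for i in range(total):
            event_id = f"EV_{code}_{i:05d}"
            gene_id = f"G_{event_id}"
            ev = _Event(event_id, gene_id, category, {})
            j = i - offset  # index within this cell type's planted block
            if 0 <= j < n_true:
                # disease event; leading ones double as concordance events,
                # trailing cassette ones as cross-cell-type shared events
                if category == "cassette" and j >= n_true - spl.n_shared:
                    s = j - (n_true - spl.n_shared)
                    ev.event_id = f"{spl.shared_prefix}_{s:04d}"
                    ev.gene_id = f"G_{ev.event_id}"
                    ev.shared = True
                if j < n_imm + n_mat and category in EXON_CATEGORIES:
                    ev.concordance = "immature" if j < n_imm else "mature"
                    _plant_concordant(ev, stages, comp, rng, dpsi, ddpsi, spl)
                else:
                    _plant_disease(ev, stages, comp, rng, dpsi)
            else:
                # catalog-only events follow the planted block
                k = (i - offset - n_true) if j >= n_true else -1
                group = None
                acc = 0
                if k >= 0:
                    for g, n_g in cat_only_here.items():
                        if k < acc + n_g:
                            group = g
                            break
                        acc += n_g
                if group is not None:
                    _plant_catalog_only(ev, group, stages, rng, ddpsi)
                else:
                    psi0 = float(rng.uniform(5, 95))
                    ev.psi = {(s, g): psi0 for s in stages for g in ("WT", "DM")}
            events.append(ev)
    return events


def _largest_remainder(total: int, weights: dict) -> dict:
    """Integer allocation of `total` proportional to `weights` (sums exactly)."""
    keys = list(weights)
    raw = {k: total * weights[k] for k in keys}
    out = {k: int(math.floor(raw[k])) for k in keys}
    rem = total - sum(out.values())
    order = sorted(keys, key=lambda k: raw[k] - out[k], reverse=True)
    for k in order[:rem]:
        out[k] += 1
    return out


def _rebalance(conc_by_cat: dict, n_true: dict, k: int) -> None:
    """Shift allocation into cassette if a category lacks planted events."""
    overflow = 0
    for c in EXON_CATEGORIES:
        cap = n_true.get(c, 0)
        used = conc_by_cat[c][0] + conc_by_cat[c][1]
        if used > cap:
            over = used - cap
            take = min(over, conc_by_cat[c][k])
            conc_by_cat[c][k] -= take
            overflow += take
    conc_by_cat["cassette"][k] += overflow


def _plant_disease(ev: _Event, stages, comp, rng, dpsi) -> None:
    sign = 1 if rng.random() < 0.5 else -1
    base = float(rng.uniform(35, 65))
    ev.psi = {(s, g): base for s in stages for g in ("WT", "DM")}
    ev.psi[(comp, "DM")] = _clip_psi(base + sign * dpsi)
    ev.disease_delta = ev.psi[(comp, "DM")] - base


def _plant_catalog_only(ev: _Event, group: str, stages, rng, ddpsi) -> None:
    d = 1 if rng.random() < 0.5 else -1
    if group in ("two_stage", "early_only"):
        p0 = float(rng.uniform(10, 60)) if d > 0 else float(rng.uniform(40, 90))
        path = {stages[0]: p0}
        for s in stages[1:]:
            path[s] = p0 + d * ddpsi
        ev.diff_delta = d * ddpsi
    elif group == "late_only":
        # transient: intermediate departs, endpoints agree
        p_end = float(rng.uniform(40, 90)) if d > 0 else float(rng.uniform(10, 60))
        path = {stages[0]: p_end, stages[1]: p_end - d * ddpsi, stages[2]: p_end}
        ev.diff_delta = d * ddpsi  # over the late transition
    else:  # both: split across the two transitions
        p0 = float(rng.uniform(10, 50)) if d > 0 else float(rng.uniform(50, 90))
        step = (2 * ddpsi / 3.0, 4 * ddpsi / 3.0)  # AC delta larger than BC
        path = {
            stages[0]: p0,
            stages[1]: p0 + d * (step[1] - step[0]),
            stages[2]: p0 + d * step[1],
        }
        ev.diff_delta = d * step[1]
    ev.diff_group = group
    ev.psi = {
        (s, g): _clip_psi(path[s]) for s in stages for g in ("WT", "DM")
    }


def _plant_concordant(ev: _Event, stages, comp, rng, dpsi, ddpsi, spl) -> None:
    """A disease event that is also differentiation-regulated."""
    d = 1 if rng.random() < 0.5 else -1
    # headroom so that a mature (exaggerating) shift stays inside [1, 99]
    p0 = float(rng.uniform(10, 35)) if d > 0 else float(rng.uniform(65, 90))
    path = {stages[0]: p0}
    for s in stages[1:]:
        path[s] = p0 + d * ddpsi
    mature_shift = min(dpsi, 25.0)
    psi = {(s, g): _clip_psi(path[s]) for s in stages for g in ("WT", "DM")}
    wt_final = psi[(comp, "WT")]
    if ev.concordance == "immature":
        # disease reverts the matured PSI back to the precursor value
        psi[(comp, "DM")] = _clip_psi(p0)
    else:
        psi[(comp, "DM")] = _clip_psi(wt_final + d * mature_shift)
    ev.psi = psi
    ev.disease_delta = psi[(comp, "DM")] - wt_final
    ev.diff_delta = d * ddpsi
    ev.diff_group = "early_only" if spl.trajectory else "two_stage"


def generate_splicing_dataset(
    config: SimulationConfig, seed: int
) -> tuple[SplicingEventTable, SampleSheet, SimulationTruth]:
    """Simulate per-event inclusion/exclusion counts across samples.

    Per event and sample the informative read total is NB-distributed
    (default mean 100) and the inclusion count is binomial with the
    event's true PSI for that sample's (stage, genotype) group.
    """
    config.validate()
    spl = config.splicing
    rng = np.random.default_rng(seed)
    events = _plan_events(config, rng)
    sheet = _sample_sheet(config.cell_type, spl.stages, spl.n_replicates)

    n = len(events)
    data = {
        "event_id": [e.event_id for e in events],
        "gene_id": [e.gene_id for e in events],
        "category": [e.category for e in events],
    }
    for _, row in sheet.df.iterrows():
        key = (row["stage"], row["genotype"])
        psi = np.array([e.psi[key] for e in events]) / 100.0
        totals = _nb_draw(
            rng, np.full(n, spl.read_depth_mean), spl.read_depth_dispersion
        )
        inc = rng.binomial(totals, psi)
        data[f"inc_{row['sample_id']}"] = inc
        data[f"exc_{row['sample_id']}"] = totals - inc
    table = SplicingEventTable(pd.DataFrame(data))

    rows = []
    for e in events:
        labelled = False
        if e.disease_delta != 0:
            rows.append((e.event_id, "splicing",
                         "splice_up" if e.disease_delta > 0 else "splice_down",
                         e.disease_delta))
            labelled = True
        if e.diff_group:
            rows.append((e.event_id, "splicing",
                         "differentiation_up" if e.diff_delta > 0 else "differentiation_down",
                         e.diff_delta))
            labelled = True
        if e.concordance:
            rows.append((e.event_id, "splicing", f"{e.concordance}_shift",
                         e.disease_delta))
        if not labelled:
            rows.append((e.event_id, "splicing", "null", 0.0))
    truth = SimulationTruth(
        pd.DataFrame(rows, columns=["feature_id", "layer", "label", "effect"])
    )
    return table, sheet, truth


# -- phosphoproteome ----------------------------------------------------------

def misspliced_gene_ids(config: SimulationConfig) -> list[str]:
    """Gene ids of the planted disease cassette events (deterministic)."""
    spl = config.splicing
    n_true = spl.n_true.get("cassette", 0)
    offset = spl.plant_offsets.get("cassette", 0)
    out = []
    for j in range(n_true):
        if j >= n_true - spl.n_shared:
            s = j - (n_true - spl.n_shared)
            out.append(f"G_{spl.shared_prefix}_{s:04d}")
        else:
            out.append(f"G_EV_CA_{offset + j:05d}")
    return out


def generate_phospho_dataset(
    config: SimulationConfig, seed: int
) -> tuple[PhosphoSiteTable, SampleSheet, SimulationTruth]:
    """Simulate phosphosite intensities with planted differential sites.

    Quantitative planted sites shift their Gaussian log2 intensity by
    ``log2fc``; genotype-exclusive sites are present in every sample of
    one genotype and absent from every sample of the other.  Stochastic
    dropout (``missing_rate``) applies to null sites only, so missingness
    short of a complete genotype partition is never informative.

    Proteins are named ``P_<gene_id>``, tying each site to a gene in the
    same namespace the splicing generator uses; the first
    ``n_overlap_missplicing`` significant proteins take the gene ids of
    planted misspliced events, so the cross-layer overlap is planted too.
    """
    config.validate()
    if config.phospho is None:
        raise ConfigError("configuration has no phospho section")
    pho = config.phospho
    rng = np.random.default_rng(seed)
    sheet = _sample_sheet(config.cell_type, ("differentiated",), pho.n_replicates)
    wt = sheet.select(genotype="WT")
    dm = sheet.select(genotype="DM")

    n_sig = pho.n_significant
    n_prot_sig = pho.n_significant_proteins or n_sig
    # first (2*n_prot_sig - n_sig) proteins carry one site, the rest two
    n_single = 2 * n_prot_sig - n_sig
    if n_single < 0:
        raise ConfigError("n_significant_proteins too small for two sites/protein")

    misspliced = misspliced_gene_ids(config)
    if pho.n_overlap_missplicing > len(misspliced):
        raise ConfigError("not enough planted misspliced genes for the overlap")
    def _null_genes():
        # null cassette-event genes (past every cell type's planted block and
        # this cell type's catalog-only events), then an overflow namespace
        spl = config.splicing
        start = spl.plant_offsets.get("cassette", 0) + spl.n_true.get("cassette", 0) + 1000
        for i in range(start, spl.n_events.get("cassette", 0)):
            yield f"G_EV_CA_{i:05d}"
        i = 0
        while True:
            yield f"G_XTRA_{i:06d}"
            i += 1

    null_gene_pool = _null_genes()

    sig_genes = list(misspliced[: pho.n_overlap_missplicing])
    while len(sig_genes) < n_prot_sig:
        sig_genes.append(next(null_gene_pool))
    sig_proteins = [f"P_{g}" for g in sig_genes]

    site_protein: list[str] = []
    for k, prot in enumerate(sig_proteins):
        site_protein.append(prot)
        if k >= n_single:
            site_protein.append(prot)
    assert len(site_protein) == n_sig
    for _ in range(pho.n_sites - n_sig):
        site_protein.append(f"P_{next(null_gene_pool)}")

    counter: dict[str, int] = {}
    site_ids = []
    for prot in site_protein:
        counter[prot] = counter.get(prot, 0) + 1
        site_ids.append(f"{prot}_S{100 * counter[prot] + 15}")

    n_excl_up = round(pho.exclusive_fraction * pho.n_up)
    n_excl_down = round(pho.exclusive_fraction * pho.n_down)
    labels = (
        ["exclusive_up"] * n_excl_up
        + ["quant_up"] * (pho.n_up - n_excl_up)
        + ["exclusive_down"] * n_excl_down
        + ["quant_down"] * (pho.n_down - n_excl_down)
        + ["null"] * (pho.n_sites - n_sig)
    )

    baseline = rng.normal(pho.baseline_mean, pho.baseline_sd, pho.n_sites)
    log2 = {}
    for sid in wt + dm:
        log2[sid] = rng.normal(baseline, pho.residual_sd)
    for i, lab in enumerate(labels):
        if lab == "quant_up":
            for sid in dm:
                log2[sid][i] += pho.log2fc
        elif lab == "quant_down":
            for sid in dm:
                log2[sid][i] -= pho.log2fc
        elif lab == "exclusive_up":
            for sid in wt:
                log2[sid][i] = np.nan
        elif lab == "exclusive_down":
            for sid in dm:
                log2[sid][i] = np.nan
        else:  # stochastic dropout on null sites only
            for sid in wt + dm:
                if rng.random() < pho.missing_rate:
                    log2[sid][i] = np.nan

    df = pd.DataFrame({"site_id": site_ids, "protein_id": site_protein})
    for sid in wt + dm:
        df[sid] = np.exp2(log2[sid])
    table = PhosphoSiteTable(df)

    rows = []
    for i, lab in enumerate(labels):
        if lab == "null":
            rows.append((site_ids[i], "phospho", "null", 0.0))
        else:
            direction = "up" if lab.endswith("up") else "down"
            effect = pho.log2fc if direction == "up" else -pho.log2fc
            rows.append((site_ids[i], "phospho", f"phospho_{direction}", effect))
            if lab.startswith("exclusive"):
                rows.append((site_ids[i], "phospho", "genotype_exclusive", effect))
    truth = SimulationTruth(
        pd.DataFrame(rows, columns=["feature_id", "layer", "label", "effect"])
    )
    return table, sheet, truth


# -- foci ---------------------------------------------------------------------

def solve_zip_parameters(fraction_positive: float, mean_count: float) -> tuple[float, float]:
    """Solve (pi, lam) of a zero-inflated Poisson from positivity and mean.

    Constraints: ``(1-pi)(1-exp(-lam)) = fraction_positive`` and
    ``(1-pi) * lam = mean_count`` (mean over ALL nuclei).  Eliminating pi
    gives ``(1-exp(-lam))/lam = fraction_positive/mean_count``, solved by
    bracketed root finding; ``fraction_positive == 1`` degenerates to a
    plain Poisson with rate ``mean_count``.
    """
    if fraction_positive >= 1.0:
        return 0.0, mean_count
    ratio = fraction_positive / mean_count
    if ratio >= 1.0:
        raise ConfigError("infeasible foci parameters (fraction/mean >= 1)")

    def f(lam: float) -> float:
        return (1.0 - math.exp(-lam)) / lam - ratio

    lam = brentq(f, 1e-12, 1e6, xtol=1e-12, rtol=1e-14)
    occupancy = mean_count / lam
    if occupancy > 1.0 + 1e-9:
        raise ConfigError("infeasible foci parameters (occupancy > 1)")
    return 1.0 - occupancy, lam


def generate_foci_counts(
    config: SimulationConfig | FociSim,
    seed: int,
    cell_type: str | None = None,
) -> tuple[FociTable, SimulationTruth]:
    """Per-nucleus foci counts: zero-inflated Poisson for DM, zeros for WT."""
    if isinstance(config, SimulationConfig):
        config.validate()
        foci = config.foci
        cell_type = cell_type or config.cell_type
    else:
        foci = config
        foci.validate()
        if cell_type is None:
            raise ConfigError("cell_type required with a bare FociSim")
    rng = np.random.default_rng(seed)
    pi, lam = solve_zip_parameters(foci.fraction_positive, foci.mean_count)
    n = foci.n_cells
    zeros = rng.random(n) < pi
    counts = np.where(zeros, 0, rng.poisson(lam, n))
    rows = []
    for i, c in enumerate(counts):
        rows.append((f"{cell_type}_DM_c{i:04d}", cell_type, "DM", int(c)))
    for i in range(n):
        rows.append((f"{cell_type}_WT_c{i:04d}", cell_type, "WT", 0))
    table = FociTable(pd.DataFrame(rows, columns=["cell_id", "cell_type", "genotype", "foci_count"]))
    truth = SimulationTruth(
        pd.DataFrame(
            [
                (cell_type, "foci", "foci_mean", foci.mean_count),
                (cell_type, "foci", "foci_positive_fraction", foci.fraction_positive),
            ],
            columns=["feature_id", "layer", "label", "effect"],
        )
    )
    return table, truth
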