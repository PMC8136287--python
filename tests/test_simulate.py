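"""Generators: determinism, analytic moments, truth-label consistency."""

import math

import numpy as np
import pandas as pd
import pytest

from gliadx import (
    SimulationConfig,
    default_config,
    generate_expression_dataset,
    generate_foci_counts,
    generate_phospho_dataset,
    generate_splicing_dataset,
    null_config,
    solve_zip_parameters,
)
from gliadx.config import ConfigError, ExpressionSim, FociSim, SplicingSim
from gliadx.splicing import per_replicate_psi


# -- determinism --------------------------------------------------------------

def test_same_seed_reproduces_all_tables():
    cfg = null_config("OL", n_genes=300, n_events=200, n_sites=100)
    cfg.expression.n_de_up = 2
    a = generate_expression_dataset(cfg, 5)
    b = generate_expression_dataset(cfg, 5)
    pd.testing.assert_frame_equal(a[0].df, b[0].df)
    ea = generate_splicing_dataset(cfg, 5)[0]
    eb = generate_splicing_dataset(cfg, 5)[0]
    pd.testing.assert_frame_equal(ea.df, eb.df)
    pa = generate_phospho_dataset(cfg, 5)[0]
    pb = generate_phospho_dataset(cfg, 5)[0]
    pd.testing.assert_frame_equal(pa.df, pb.df)


def test_distinct_seeds_differ():
    cfg = null_config("OL", n_genes=200, n_events=100, n_sites=50)
    a = generate_expression_dataset(cfg, 1)[0]
    b = generate_expression_dataset(cfg, 2)[0]
    assert not a.df.equals(b.df)


# -- expression moments -------------------------------------------------------

def test_expression_counts_match_analytic_nb_moments():
    """With a fixed baseline the empirical mean/variance must match the
    negative-binomial mean mu and variance mu + disp*mu^2."""
    cfg = null_config("OL", n_genes=4000)
    cfg.expression.log_mu_sigma = 0.0       # all baselines equal exp(log_mu_mean)
    cfg.expression.log_mu_mean = math.log(200.0)
    cfg.expression.dispersion = 0.1
    cfg.expression.size_factor_sigma = 0.0
    counts, _, _ = generate_expression_dataset(cfg, 3)
    arr = counts.matrix().to_numpy(float)
    mu, disp = 200.0, 0.1
    n = arr.size
    grand_mean = arr.mean()
    se_mean = math.sqrt((mu + disp * mu**2) / n)
    assert abs(grand_mean - mu) < 3 * se_mean
    # variance across everything: SE of a variance estimate ~ sqrt(2/n)*var
    # for Gaussian; NB kurtosis inflates it, allow 5x
    var = arr.var()
    expected_var = mu + disp * mu**2
    assert abs(var - expected_var) < 5 * math.sqrt(2.0 / n) * expected_var


def test_null_config_group_ratios_center_on_one():
    cfg = null_config("OL", n_genes=2000)
    cfg.expression.size_factor_sigma = 0.0  # isolate the group effect
    counts, sheet, _ = generate_expression_dataset(cfg, 4)
    wt = sheet.select(genotype="WT")
    dm = sheet.select(genotype="DM")
    mat = counts.matrix()
    ratio = (mat[dm].mean(axis=1) + 0.5) / (mat[wt].mean(axis=1) + 0.5)
    assert abs(np.log2(ratio).mean()) < 0.05


# -- splicing -----------------------------------------------------------------

def test_null_events_have_small_centered_delta_psi():
    cfg = null_config("OL", n_events=500)
    events, sheet, truth = generate_splicing_dataset(cfg, 6)
    psi = per_replicate_psi(events)
    wt = sheet.select(genotype="WT")
    dm = sheet.select(genotype="DM")
    delta = psi[dm].mean(axis=1) - psi[wt].mean(axis=1)
    assert abs(delta.mean()) < 1.0
    assert (delta.abs() < 30).mean() > 0.99


def test_astrocyte_default_plants_printed_cassette_census():
    cfg = default_config("astrocyte")
    events, _, truth = generate_splicing_dataset(cfg, 1)
    planted = truth.df[truth.df["label"].isin(["splice_up", "splice_down"])]
    assert len(planted) == 264
    cat = events.df.set_index("event_id")["category"]
    assert (cat.loc[planted["feature_id"]] == "cassette").sum() == 184


def test_shared_event_ids_appear_in_both_glial_tables():
    astro = default_config("astrocyte")
    ol = default_config("OL")
    ea, _, ta = generate_splicing_dataset(astro, 1)
    eo, _, to = generate_splicing_dataset(ol, 2)
    shared_a = {e for e in ea.df["event_id"] if e.startswith("SHGL")}
    shared_o = {e for e in eo.df["event_id"] if e.startswith("SHGL")}
    assert shared_a == shared_o and len(shared_a) == 48
    # shared events are planted disease events in both truths
    assert shared_a <= ta.features("splice_up", "splice_down")
    assert shared_o <= to.features("splice_up", "splice_down")


def test_planted_splice_effect_signs_match_observed_deltas():
    cfg = default_config("OL")
    events, sheet, truth = generate_splicing_dataset(cfg, 3)
    psi = per_replicate_psi(events)
    wt = sheet.select(genotype="WT", stage="differentiated")
    dm = sheet.select(genotype="DM", stage="differentiated")
    delta = psi[dm].mean(axis=1) - psi[wt].mean(axis=1)
    planted = truth.df[truth.df["label"].isin(["splice_up", "splice_down"])]
    observed = delta.loc[planted["feature_id"]].to_numpy()
    assert np.all(np.sign(observed) == np.sign(planted["effect"].to_numpy()))


# -- phospho ------------------------------------------------------------------

def test_exclusive_sites_are_exactly_genotype_partitioned():
    cfg = default_config("astrocyte")
    table, sheet, truth = generate_phospho_dataset(cfg, 2)
    wt = sheet.select(genotype="WT")
    dm = sheet.select(genotype="DM")
    mat = table.matrix()
    exclusive = truth.features("genotype_exclusive")
    for site in sorted(exclusive)[:50]:
        row = mat.loc[site]
        wt_present = row[wt].notna().sum()
        dm_present = row[dm].notna().sum()
        assert {wt_present, dm_present} == {0, len(wt)}


def test_astrocyte_default_plants_279_up_66_down():
    cfg = default_config("astrocyte")
    _, _, truth = generate_phospho_dataset(cfg, 1)
    assert len(truth.features("phospho_up")) == 279
    assert len(truth.features("phospho_down")) == 66


def test_zero_missingness_leaves_no_gaps_outside_exclusive_sites():
    cfg = null_config("OL", n_sites=200)
    cfg.phospho.missing_rate = 0.0
    table, _, _ = generate_phospho_dataset(cfg, 1)
    assert table.matrix().notna().all().all()


# -- foci ---------------------------------------------------------------------

def _bisect_zip_lambda(ratio: float) -> float:
    """Independent bisection for (1-exp(-lam))/lam = ratio."""
    lo, hi = 1e-9, 1e4
    for _ in range(200):
        mid = (lo + hi) / 2
        if (1 - math.exp(-mid)) / mid > ratio:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


@pytest.mark.parametrize("frac,mean", [(0.70, 2.4), (0.20, 1.4), (0.50, 2.5), (0.95, 6.0)])
def test_zip_solution_satisfies_both_constraints(frac, mean):
    pi, lam = solve_zip_parameters(frac, mean)
    assert abs((1 - pi) * lam - mean) < 1e-9
    assert abs((1 - pi) * (1 - math.exp(-lam)) - frac) < 1e-9
    assert abs(lam - _bisect_zip_lambda(frac / mean)) < 1e-6


def test_full_positivity_degenerates_to_plain_poisson():
    pi, lam = solve_zip_parameters(1.0, 6.0)
    assert pi == 0.0 and lam == 6.0


def test_infeasible_foci_parameters_raise():
    with pytest.raises(ConfigError):
        solve_zip_parameters(0.9, 0.5)  # fraction/mean > 1: no lambda fits


def test_wt_nuclei_carry_no_foci():
    table, _ = generate_foci_counts(default_config("neuron"), 1)
    wt = table.df[table.df["genotype"] == "WT"]
    assert (wt["foci_count"] == 0).all()


# -- default configurations mirror the published censuses ---------------------

def test_default_config_plants_printed_numbers():
    ol = default_config("OL")
    assert ol.expression.n_de == 85
    assert ol.expression.n_de_up == 2
    assert ol.expression.n_diff_genes == 8140
    assert sum(default_config("astrocyte").splicing.n_true.values()) == 264
    assert default_config("astrocyte").splicing.n_true["cassette"] == 184
    assert default_config("neuron").foci.mean_count == 2.4
    assert default_config("astrocyte").phospho.n_up == 279
    tr = default_config("astrocyte").splicing.trajectory
    assert tr.n_early_only + tr.n_both == 202
    assert tr.n_late_only + tr.n_both == 95


def test_unknown_cell_type_rejected():
    with pytest.raises(ConfigError):
        default_config("microglia")


def test_planted_counts_cannot_exceed_totals():
    cfg = null_config("OL", n_genes=10)
    cfg.expression.n_de_up = 20
    with pytest.raises(ConfigError):
        cfg.validate()
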