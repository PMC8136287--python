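"""Dual-rule phosphosite calling, direction census, ORA."""

import math

import numpy as np
import pandas as pd
import pytest

from gliadx.phospho import (
    census_direction,
    differential_phospho,
    ora,
    splicing_phospho_overlap,
)
from gliadx.tables import PhosphoSiteTable

from test_concordance import hypergeom_upper_tail_oracle

WT = [f"wt{i}" for i in range(4)]
DM = [f"dm{i}" for i in range(4)]


def _sites(rows: dict) -> PhosphoSiteTable:
    df = pd.DataFrame(
        {"site_id": list(rows), "protein_id": [s.split("_")[0] for s in rows]}
    )
    for j, s in enumerate(WT + DM):
        df[s] = [rows[site][j] for site in rows]
    return PhosphoSiteTable(df)


M = None  # missing shorthand


def test_exclusive_site_called_by_detection_rule():
    rows = {"P1_S1": [M, M, M, M, 9.0, 8.0, 8.5, 9.5]}
    rec = differential_phospho(_sites(rows), WT, DM)
    assert rec.loc[0, "status"] == "genotype_exclusive_DM"
    assert rec.loc[0, "direction"] == "up"
    assert rec.loc[0, "significant"]


def test_genotype_swap_mirrors_exclusive_statuses():
    rows = {
        "P1_S1": [M, M, M, M, 9.0, 8.0, 8.5, 9.5],
        "P2_S2": [7.0, 7.5, 8.0, 7.2, M, M, M, M],
    }
    fwd = differential_phospho(_sites(rows), WT, DM)
    rev = differential_phospho(_sites(rows), DM, WT)
    assert list(fwd["status"]) == ["genotype_exclusive_DM", "genotype_exclusive_WT"]
    assert list(rev["status"]) == ["genotype_exclusive_WT", "genotype_exclusive_DM"]
    assert list(rev["direction"]) == ["down", "up"]


def test_partial_missingness_never_triggers_exclusive_status():
    # 3 of 4 missing in WT is below the complete-partition bar
    rows = {"P1_S1": [M, M, M, 8.0, 9.0, 8.0, 8.5, 9.5]}
    rec = differential_phospho(_sites(rows), WT, DM)
    assert rec.loc[0, "status"] == "untestable"
    assert not rec.loc[0, "significant"]


def test_fold_change_gate_blocks_small_effects():
    rng = np.random.default_rng(0)
    base = rng.normal(1000.0, 5.0, 4)
    rows = {
        # ratio 1.25: clearly detectable but below the 1.4 gate
        "P1_S1": list(base) + list(base * 1.25),
        # ratio 1.6: passes both gates
        "P2_S2": list(base) + list(base * 1.6),
    }
    rec = differential_phospho(_sites(rows), WT, DM)
    assert rec.loc[0, "status"] == "not_significant"
    assert rec.loc[1, "status"] == "quantitative"
    assert rec.loc[1, "direction"] == "up"


def test_census_direction_totals_and_bias():
    rec = pd.DataFrame(
        {"site_id": [f"s{i}" for i in range(345)],
         "protein_id": "p",
         "significant": True,
         "direction": ["up"] * 279 + ["down"] * 66}
    )
    n_up, n_down, p = census_direction(rec)
    assert (n_up, n_down) == (279, 66)
    assert n_up + n_down == 345
    assert p < 0.001


def test_census_with_no_significant_sites_reports_na():
    rec = pd.DataFrame(
        {"site_id": ["s"], "protein_id": ["p"], "significant": [False],
         "direction": [""]}
    )
    assert census_direction(rec) == (0, 0, None)


def test_empty_group_rejected():
    rows = {"P1_S1": [1.0] * 8}
    with pytest.raises(ValueError):
        differential_phospho(_sites(rows), [], DM)


# -- cross-layer overlap ------------------------------------------------------

def test_overlap_disjoint_and_identical_sets():
    mapping = {f"P{i}": f"G{i}" for i in range(20)}
    universe = [f"G{i}" for i in range(20)]
    rep, _ = splicing_phospho_overlap(["P0", "P1"], ["G5", "G6"], mapping, universe)
    assert rep.n_overlap == 0 and rep.representation_factor == 0.0
    rep, _ = splicing_phospho_overlap(
        ["P0", "P1"], ["G0", "G1"], mapping, universe
    )
    assert rep.n_overlap == 2


def test_unmapped_proteins_counted_and_excluded():
    mapping = {"P0": "G0"}
    rep, n_unmapped = splicing_phospho_overlap(
        ["P0", "Pmystery"], ["G0"], mapping, ["G0", "G1"]
    )
    assert n_unmapped == 1
    assert rep.n_setA == 1


# -- over-representation ------------------------------------------------------

def test_ora_matches_hand_enumerated_hypergeometrics():
    universe = [f"g{i}" for i in range(20)]
    hits = universe[:5]
    annotation = {
        "identical": universe[:5],
        "half": universe[:10],
        "disjoint": universe[10:15],
        "broad": universe,
        "empty": [],
    }
    out = ora(hits, annotation, universe).set_index("term")
    assert "empty" not in out.index  # skipped with warning
    for term, members in annotation.items():
        if not members:
            continue
        k = len(set(hits) & set(members))
        expected_p = hypergeom_upper_tail_oracle(k, 20, len(members), 5)
        assert out.loc[term, "p"] == pytest.approx(expected_p, rel=1e-9)
    assert out.loc["disjoint", "n_overlap"] == 0
    # identical term: maximal RF for its size, smallest p among same-size terms
    assert out.loc["identical", "representation_factor"] == pytest.approx(4.0)
    assert out.loc["identical", "p"] == min(out.loc[t, "p"] for t in ("identical", "disjoint"))
    # BH across the four scored terms, hand-checked
    ps = out["p"].sort_values()
    qs = np.minimum.accumulate((ps.to_numpy() * 4 / np.arange(1, 5))[::-1])[::-1]
    np.testing.assert_allclose(
        out.loc[ps.index, "q"], np.minimum(qs, 1.0), rtol=1e-9
    )


def test_ora_hits_outside_universe_rejected():
    with pytest.raises(ValueError):
        ora(["alien"], {"t": ["a"]}, ["a", "b"])
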