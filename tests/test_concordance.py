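"""Overlap statistics, concordance classification, direction-bias test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gliadx.concordance import (
    classify_expression_concordance,
    classify_splicing_concordance,
    cross_celltype_overlap,
    direction_bias_test,
    overlap_test,
)


def hypergeom_upper_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by exact enumeration."""
    total = 0.0
    for j in range(k, min(K, n) + 1):
        if n - j > N - K:
            continue
        total += math.comb(K, j) * math.comb(N - K, n - j) / math.comb(N, n)
    return min(total, 1.0)


def test_overlap_example_matches_enumeration():
    U = [f"u{i}" for i in range(100)]
    A = U[:10]
    B = U[5:25]  # overlap with A: u5..u9 -> 5
    rep = overlap_test(A, B, U)
    assert rep.n_overlap == 5
    assert rep.expected_overlap == pytest.approx(2.0)
    assert rep.representation_factor == pytest.approx(2.5)
    assert rep.p_hypergeom == pytest.approx(
        hypergeom_upper_tail_oracle(5, 100, 20, 10), rel=1e-9
    )


def test_disjoint_sets_have_zero_rf_and_p_near_one():
    U = [f"u{i}" for i in range(50)]
    rep = overlap_test(U[:10], U[10:20], U)
    assert rep.n_overlap == 0
    assert rep.representation_factor == 0.0
    assert rep.p_hypergeom == pytest.approx(1.0)


def test_full_overlap_is_certain():
    U = [f"u{i}" for i in range(30)]
    rep = overlap_test(U, U, U)
    assert rep.representation_factor == pytest.approx(1.0)
    assert rep.p_hypergeom == pytest.approx(1.0)


def test_sets_must_be_subsets_of_universe():
    with pytest.raises(ValueError, match="stranger"):
        overlap_test(["stranger"], ["a"], ["a", "b"])
    with pytest.raises(ValueError, match="empty"):
        overlap_test([], [], [])


@settings(max_examples=250, derandomize=True, deadline=None)
@given(data=st.data(), N=st.integers(1, 40))
def test_hypergeometric_p_matches_enumeration(data, N):
    nA = data.draw(st.integers(0, N))
    nB = data.draw(st.integers(0, N))
    U = [f"u{i}" for i in range(N)]
    rng_a = data.draw(st.permutations(range(N)))
    A = [U[i] for i in rng_a[:nA]]
    rng_b = data.draw(st.permutations(range(N)))
    B = [U[i] for i in rng_b[:nB]]
    rep = overlap_test(A, B, U)
    assert rep.p_hypergeom == pytest.approx(
        hypergeom_upper_tail_oracle(rep.n_overlap, N, nB, nA), rel=1e-9, abs=1e-12
    )
    # representation-factor identity RF = k * N / (|A| |B|)
    if nA and nB:
        assert rep.representation_factor == pytest.approx(
            rep.n_overlap * N / (nA * nB), rel=1e-12
        )


def test_random_sets_have_unit_rf_on_average():
    rng = np.random.default_rng(0)
    U = [f"u{i}" for i in range(1000)]
    rfs = []
    for _ in range(20):
        A = rng.choice(U, 100, replace=False)
        B = rng.choice(U, 100, replace=False)
        rfs.append(overlap_test(A, B, U).representation_factor)
    assert 0.8 <= float(np.mean(rfs)) <= 1.2


# -- classification -----------------------------------------------------------

def _de(genes_lfc: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {"gene_id": list(genes_lfc), "log2fc": list(genes_lfc.values())}
    )


def _expr_catalog(dirs: dict) -> pd.DataFrame:
    return pd.DataFrame({"feature_id": list(dirs), "direction": list(dirs.values())})


def test_expression_concordance_classes():
    classes = classify_expression_concordance(
        _de({"a": -2.0, "b": -1.5, "c": 1.2, "d": 2.0, "e": -1.0}),
        _expr_catalog({"a": "up", "b": "down", "c": "up", "d": "down"}),
    )
    assert classes["a"] == "failed_activation"
    assert classes["b"] == "accentuated_down"
    assert classes["c"] == "accentuated_up"
    assert classes["d"] == "failed_repression"
    assert classes["e"] == "not_differentiation_regulated"


def _splice(records: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {"event_id": list(records), "delta_psi": list(records.values())}
    )


def _splice_catalog(deltas: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {"feature_id": list(deltas), "delta_psi_diff": list(deltas.values())}
    )


def test_splicing_concordance_classes():
    classes = classify_splicing_concordance(
        _splice({"x": -20.0, "y": 15.0, "z": -5.0}),
        _splice_catalog({"x": 30.0, "y": 30.0}),
    )
    assert classes["x"] == "immature_shift"   # disease opposes maturation
    assert classes["y"] == "mature_shift"
    assert classes["z"] == "not_differentiation_regulated"


def test_splicing_classifier_antisymmetric_under_sign_flip():
    rng = np.random.default_rng(2)
    events = {f"e{i}": float(rng.uniform(-40, 40)) for i in range(50)}
    catalog = _splice_catalog({f"e{i}": float(rng.choice([-30, 30])) for i in range(40)})
    fwd = classify_splicing_concordance(_splice(events), catalog)
    neg = classify_splicing_concordance(
        _splice({k: -v for k, v in events.items()}), catalog
    )
    swap = {"immature_shift": "mature_shift", "mature_shift": "immature_shift",
            "not_differentiation_regulated": "not_differentiation_regulated"}
    for ev in events:
        assert neg[ev] == swap[fwd[ev]]


# -- direction bias -----------------------------------------------------------

def test_direction_bias_phospho_census_is_significant():
    assert direction_bias_test(279, 66) < 0.001


def test_direction_bias_symmetric_counts():
    assert direction_bias_test(5, 5) == pytest.approx(1.0)


def test_direction_bias_one_sided_extreme():
    # closed form: both tails of 10/10 successes at p=0.5
    assert direction_bias_test(10, 0) == pytest.approx(2 * 0.5**10, rel=1e-12)


def test_direction_bias_empty_errors():
    with pytest.raises(ValueError):
        direction_bias_test(0, 0)


# -- cross cell type ----------------------------------------------------------

def test_pairwise_overlap_counts():
    sets = {"astro": {"a", "b", "c"}, "ol": {"b", "c", "d"}}
    unis = {"astro": {"a", "b", "c", "d", "e"}, "ol": {"a", "b", "c", "d", "e"}}
    out = cross_celltype_overlap(sets, unis)
    assert out.iloc[0]["n_overlap"] == 2


def test_four_disjoint_sets_overlap_zero():
    U = {f"u{i}" for i in range(40)}
    sets = {c: {f"u{10 * i + j}" for j in range(5)} for i, c in enumerate("abcd")}
    out = cross_celltype_overlap(sets, {c: U for c in sets})
    assert (out["n_overlap"] == 0).all()
    assert len(out) == 6  # all pairs


def test_single_set_rejected():
    with pytest.raises(ValueError):
        cross_celltype_overlap({"a": {"x"}}, {"a": {"x"}})
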