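"""Normalization and the Welch-t differential expression stage."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gliadx.expression import (
    apply_de_filter,
    differential_expression,
    normalize_counts,
)
from gliadx.tables import GeneCountTable


def _table(data: dict) -> GeneCountTable:
    n = len(next(iter(data.values())))
    return GeneCountTable(pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)], **data}))


def test_identical_samples_have_unit_size_factors():
    t = _table({"a": [10, 20, 40], "b": [10, 20, 40]})
    sf, _ = normalize_counts(t)
    assert np.allclose(sf, [1.0, 1.0])


def test_doubled_sample_gets_doubled_size_factor():
    # hand computation: ratios to the geometric mean are 1/sqrt(2) and sqrt(2)
    # for every gene, so the size-factor ratio is exactly 2
    t = _table({"a": [10, 20, 40], "b": [20, 40, 80]})
    sf, normalized = normalize_counts(t)
    assert sf["b"] / sf["a"] == pytest.approx(2.0, abs=1e-12)
    pd.testing.assert_series_equal(normalized["a"], normalized["b"], check_names=False)


def test_normalization_requires_a_fully_detected_gene():
    t = _table({"a": [0, 5], "b": [3, 0]})
    with pytest.raises(ValueError, match="filter"):
        normalize_counts(t)


def test_per_sample_scaling_does_not_change_calls():
    rng = np.random.default_rng(0)
    base = rng.poisson(200, size=(50, 8))
    samples = [f"s{i}" for i in range(8)]
    t1 = _table({s: base[:, i] for i, s in enumerate(samples)})
    scales = [1, 2, 3, 1, 5, 2, 1, 4]
    t2 = _table({s: base[:, i] * scales[i] for i, s in enumerate(samples)})
    g1, g2 = samples[:4], samples[4:]
    r1 = differential_expression(normalize_counts(t1)[1], g1, g2)
    r2 = differential_expression(normalize_counts(t2)[1], g1, g2)
    # identical calls: normalization removes the per-sample scales exactly up
    # to one global factor, whose interaction with the pseudocount perturbs
    # p in the fourth decimal at these depths
    np.testing.assert_allclose(r1["p"], r2["p"], rtol=5e-3)
    np.testing.assert_allclose(r1["log2fc"], r2["log2fc"], atol=5e-3)
    assert (apply_de_filter(r1)["gene_id"] == apply_de_filter(r2)["gene_id"]).all()


def test_welch_p_matches_hand_computed_statistic():
    """Fixed 4+4 toy: the p must equal the closed-form Welch tail value
    computed from first principles (statistic and Welch-Satterthwaite df)."""
    x1 = np.array([7.0, 7.5, 8.0, 8.5])
    x2 = np.array([9.0, 9.8, 10.4, 11.0])
    norm = pd.DataFrame(
        {f"a{i}": [2.0 ** x1[i] - 0.5] for i in range(4)}
        | {f"b{i}": [2.0 ** x2[i] - 0.5] for i in range(4)},
        index=["g0"],
    )
    rec = differential_expression(norm, [f"a{i}" for i in range(4)],
                                  [f"b{i}" for i in range(4)])
    v1, v2 = x1.var(ddof=1) / 4, x2.var(ddof=1) / 4
    t_stat = (x2.mean() - x1.mean()) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / 3 + v2**2 / 3)
    p_expected = 2 * stats.t.sf(abs(t_stat), df)
    assert rec.loc[0, "p"] == pytest.approx(p_expected, rel=1e-10)


def test_identical_groups_give_null_effect():
    norm = pd.DataFrame(
        {"a1": [100.0], "a2": [110.0], "b1": [100.0], "b2": [110.0]}, index=["g"]
    )
    rec = differential_expression(norm, ["a1", "a2"], ["b1", "b2"])
    assert rec.loc[0, "log2fc"] == 0.0
    assert rec.loc[0, "p"] > 0.9


def test_small_group_rejected():
    norm = pd.DataFrame({"a1": [1.0], "b1": [2.0], "b2": [3.0]}, index=["g"])
    with pytest.raises(ValueError, match=">= 2 samples"):
        differential_expression(norm, ["a1"], ["b1", "b2"])


@pytest.mark.parametrize(
    "fc,q,expected",
    [
        (1.4, 0.01, False),   # threshold is strict
        (3.0, 0.049, True),
        (0.5, 0.001, True),   # 2-fold down passes the absolute gate
        (2.0, 0.05, False),   # alpha is strict too
    ],
)
def test_de_filter_rule(fc, q, expected):
    rec = pd.DataFrame(
        {"gene_id": ["g"], "fold_change": [fc], "log2fc": [np.log2(fc)],
         "p": [q / 2], "q": [q], "testable": [True]}
    )
    out = apply_de_filter(rec)
    assert (len(out) == 1) is expected


def test_bh_q_values_are_valid_and_monotone():
    rng = np.random.default_rng(1)
    norm = pd.DataFrame(
        rng.poisson(100, size=(200, 8)).astype(float),
        index=[f"g{i}" for i in range(200)],
        columns=[f"s{i}" for i in range(8)],
    )
    rec = differential_expression(norm, [f"s{i}" for i in range(4)],
                                  [f"s{i}" for i in range(4, 8)])
    rec = rec.sort_values("p").reset_index(drop=True)
    q = rec["q"].to_numpy()
    p = rec["p"].to_numpy()
    assert np.all(q <= 1.0 + 1e-12)
    assert np.all(q >= p - 1e-12)
    assert np.all(np.diff(q) >= -1e-12)  # nondecreasing in p-rank


def test_all_zero_genes_excluded_from_bh_denominator():
    df = pd.DataFrame(
        {"a1": [0.0, 100, 50], "a2": [0.0, 90, 55], "b1": [0.0, 200, 52],
         "b2": [0.0, 210, 49]},
        index=["dead", "g1", "g2"],
    )
    rec = differential_expression(df, ["a1", "a2"], ["b1", "b2"])
    assert not rec.loc[rec["gene_id"] == "dead", "testable"].item()
    assert np.isnan(rec.loc[rec["gene_id"] == "dead", "q"].item())
    # BH over the 2 testable genes only
    tested = rec[rec["testable"]].sort_values("p")
    expected_q = np.minimum.accumulate(
        (tested["p"].to_numpy() * 2 / np.arange(1, 3))[::-1]
    )[::-1]
    np.testing.assert_allclose(tested["q"], np.minimum(expected_q, 1.0))
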