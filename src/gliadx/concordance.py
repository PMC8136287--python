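"""Overlap statistics and differentiation-concordance classification.

The central questions: do the disease-dysregulated features overlap the
WT differentiation program more than chance (hypergeometric enrichment,
representation factor), and in which direction — does disease oppose
the maturation change (failed activation, immature isoform shift) or
exaggerate it?
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats


@dataclass
class ConcordanceReport:
    """Overlap of two feature sets against an explicit background universe."""

    n_setA: int
    n_setB: int
    n_universe: int
    n_overlap: int
    expected_overlap: float
    representation_factor: float
    p_hypergeom: float
    class_counts: dict = field(default_factory=dict)
    p_direction_bias: float | None = None

    def to_dict(self) -> dict:
        out = {
            "n_setA": self.n_setA,
            "n_setB": self.n_setB,
            "n_universe": self.n_universe,
            "n_overlap": self.n_overlap,
            "expected_overlap": self.expected_overlap,
            "representation_factor": self.representation_factor,
            "p_hypergeom": self.p_hypergeom,
        }
        if self.class_counts:
            out["class_counts"] = dict(self.class_counts)
        if self.p_direction_bias is not None:
            out["p_direction_bias"] = self.p_direction_bias
        return out


def overlap_test(
    setA: Iterable[str], setB: Iterable[str], universe: Iterable[str]
) -> ConcordanceReport:
    """Upper-tail hypergeometric enrichment of |A intersect B|.

    The universe is a mandatory explicit argument (typically the features
    testable in BOTH comparisons); expected overlap is |A||B|/|U| and the
    representation factor is observed/expected.  p = P(X >= k) drawing
    |A| from the universe with |B| successes.
    """
    A, B, U = set(setA), set(setB), set(universe)
    if not U:
        raise ValueError("empty universe")
    stray = (A - U) | (B - U)
    if stray:
        raise ValueError(f"sets not contained in universe: {sorted(stray)[:5]}")
    k = len(A & B)
    expected = len(A) * len(B) / len(U)
    rf = k / expected if expected > 0 else float("nan")
    # X ~ Hypergeom(N=|U|, K=|B|, n=|A|); upper tail at k
    p = float(stats.hypergeom.sf(k - 1, len(U), len(B), len(A)))
    return ConcordanceReport(
        n_setA=len(A),
        n_setB=len(B),
        n_universe=len(U),
        n_overlap=k,
        expected_overlap=expected,
        representation_factor=rf,
        p_hypergeom=p,
    )


EXPRESSION_CLASSES = (
    "failed_activation",
    "failed_repression",
    "accentuated_up",
    "accentuated_down",
    "not_differentiation_regulated",
)


def classify_expression_concordance(
    disease: pd.DataFrame, catalog: pd.DataFrame
) -> pd.Series:
    """Concordance class per significant disease gene.

    ``failed_activation``: the catalog says the gene is activated with
    maturation but disease cells express it lower — the differentiation
    step did not complete.  ``accentuated_*``: disease moves the same
    way maturation does.  Genes absent from the catalog are
    ``not_differentiation_regulated``.
    """
    cat_dir = catalog.set_index("feature_id")["direction"]
    out = {}
    for _, row in disease.iterrows():
        gene = row["gene_id"]
        disease_up = row["log2fc"] > 0
        if gene not in cat_dir.index:
            out[gene] = "not_differentiation_regulated"
        elif cat_dir[gene] == "up":
            out[gene] = "accentuated_up" if disease_up else "failed_activation"
        else:
            out[gene] = "failed_repression" if disease_up else "accentuated_down"
    return pd.Series(out, name="concordance_class")


SPLICING_CLASSES = ("immature_shift", "mature_shift", "not_differentiation_regulated")


def classify_splicing_concordance(
    disease: pd.DataFrame, catalog: pd.DataFrame
) -> pd.Series:
    """Concordance class per significant disease splicing event.

    ``immature_shift``: the disease delta-PSI opposes the maturation
    delta, moving the isoform balance back toward the precursor state;
    ``mature_shift``: the signs agree.
    """
    cat_delta = catalog.set_index("feature_id")["delta_psi_diff"]
    out = {}
    for _, row in disease.iterrows():
        ev = row["event_id"]
        if ev not in cat_delta.index:
            out[ev] = "not_differentiation_regulated"
        elif row["delta_psi"] * cat_delta[ev] < 0:
            out[ev] = "immature_shift"
        else:
            out[ev] = "mature_shift"
    return pd.Series(out, name="concordance_class")


def direction_bias_test(n_class1: int, n_class2: int) -> float:
    """Two-sided exact binomial test of a 50:50 split between two classes.

    Used for e.g. hyper- vs hypo-phosphorylation or immature- vs
    mature-shift censuses; two-sided by summing outcome probabilities no
    larger than the observed one.
    """
    if n_class1 < 0 or n_class2 < 0:
        raise ValueError("counts must be nonnegative")
    n = n_class1 + n_class2
    if n == 0:
        raise ValueError("both class counts are zero")
    return float(stats.binomtest(n_class1, n, 0.5, alternative="two-sided").pvalue)


def cross_celltype_overlap(
    significant_sets: Mapping[str, Iterable[str]],
    universes: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Pairwise overlaps of significant-event sets across cell types.

    For each pair the enrichment is tested against the events testable
    in BOTH cell types; rows carry the pair, set sizes restricted to the
    shared universe, overlap, expected, representation factor and p.
    """
    names = list(significant_sets)
    if len(names) < 2:
        raise ValueError("need at least two cell types")
    rows = []
    for a, b in itertools.combinations(names, 2):
        U = set(universes[a]) & set(universes[b])
        A = set(significant_sets[a]) & U
        B = set(significant_sets[b]) & U
        if U:
            rep = overlap_test(A, B, U)
            rows.append(
                {
                    "cell_type_a": a,
                    "cell_type_b": b,
                    **rep.to_dict(),
                }
            )
        else:
            rows.append(
                {
                    "cell_type_a": a,
                    "cell_type_b": b,
                    "n_setA": len(A),
                    "n_setB": len(B),
                    "n_universe": 0,
                    "n_overlap": len(set(significant_sets[a]) & set(significant_sets[b])),
                    "expected_overlap": float("nan"),
                    "representation_factor": float("nan"),
                    "p_hypergeom": float("nan"),
                }
            )
    return pd.DataFrame(rows)
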