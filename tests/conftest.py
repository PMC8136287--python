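import numpy as np
import pandas as pd
import pytest

from gliadx.tables import (
    FociTable,
    GeneCountTable,
    PhosphoSiteTable,
    SampleSheet,
    SplicingEventTable,
)


@pytest.fixture
def sample_sheet() -> SampleSheet:
    rows = []
    for genotype in ("WT", "DM"):
        for r in (1, 2, 3, 4):
            rows.append(
                {
                    "sample_id": f"OL_{genotype}_differentiated_r{r}",
                    "genotype": genotype,
                    "cell_type": "OL",
                    "stage": "differentiated",
                    "replicate": r,
                }
            )
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture
def gene_counts(sample_sheet) -> GeneCountTable:
    rng = np.random.default_rng(0)
    samples = sample_sheet.sample_ids
    df = pd.DataFrame({"gene_id": [f"G{i}" for i in range(5)]})
    for s in samples:
        df[s] = rng.poisson(100, 5)
    return GeneCountTable(df)


def make_event_table(counts: dict[str, dict[str, tuple[int, int]]],
                     category: str = "cassette",
                     coords: bool = False) -> SplicingEventTable:
    """counts: event_id -> sample -> (inclusion, exclusion)."""
    rows = []
    for i, (event_id, per_sample) in enumerate(counts.items()):
        row = {"event_id": event_id, "gene_id": f"G_{event_id}", "category": category}
        if coords:
            row.update({"chrom": "chr1", "start": 100 * i, "end": 100 * i + 50, "strand": "+"})
        for s, (inc, exc) in per_sample.items():
            row[f"inc_{s}"] = inc
            row[f"exc_{s}"] = exc
        rows.append(row)
    return SplicingEventTable(pd.DataFrame(rows))


@pytest.fixture
def phospho_table(sample_sheet) -> PhosphoSiteTable:
    rng = np.random.default_rng(1)
    samples = sample_sheet.sample_ids
    df = pd.DataFrame(
        {"site_id": [f"P{i}_S{100 + i}" for i in range(6)],
         "protein_id": [f"P{i}" for i in range(6)]}
    )
    for s in samples:
        df[s] = np.exp2(rng.normal(20, 1, 6))
    df.loc[0, samples[0]] = np.nan  # one missing cell
    return PhosphoSiteTable(df)


@pytest.fixture
def foci_table() -> FociTable:
    rows = []
    for i, c in enumerate([0, 0, 3, 2, 5]):
        rows.append({"cell_id": f"astrocyte_DM_c{i}", "cell_type": "astrocyte",
                     "genotype": "DM", "foci_count": c})
    return FociTable(pd.DataFrame(rows))
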