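"""Materialize the default synthetic datasets for all four brain cell types.

Writes the full input tables (gene counts, splicing events, phosphosites,
foci, sample sheets, planted-truth labels) under scratch/data/<cell_type>/
— these are the inputs every later script recomputes from — and a small
inventory table under results/.

Run from the repository root:  python analysis/01_simulate_datasets.py
"""

from pathlib import Path

import pandas as pd

from gliadx import default_config, write_table
from gliadx.simulate import (
    generate_expression_dataset,
    generate_foci_counts,
    generate_phospho_dataset,
    generate_splicing_dataset,
)

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"

rows = []
for cell_type in ("neuron", "OPC", "OL", "astrocyte"):
    cfg = default_config(cell_type)
    out = DATA / cell_type
    counts, sheet, truth_e = generate_expression_dataset(cfg, SEED)
    write_table(counts, out / "gene_counts.tsv")
    write_table(sheet, out / "samples_expression.tsv")
    write_table(truth_e, out / "truth_expression.tsv")
    events, esheet, truth_s = generate_splicing_dataset(cfg, SEED)
    write_table(events, out / "splicing_events.tsv")
    write_table(esheet, out / "samples_splicing.tsv")
    write_table(truth_s, out / "truth_splicing.tsv")
    n_phospho = 0
    if cfg.phospho is not None:
        sites, psheet, truth_p = generate_phospho_dataset(cfg, SEED)
        write_table(sites, out / "phospho_sites.tsv")
        write_table(psheet, out / "samples_phospho.tsv")
        write_table(truth_p, out / "truth_phospho.tsv")
        n_phospho = len(sites.df)
    foci, truth_f = generate_foci_counts(cfg, SEED)
    write_table(foci, out / "foci_counts.tsv")
    rows.append(
        {
            "cell_type": cell_type,
            "n_genes": len(counts.df),
            "n_samples_expression": len(sheet.df),
            "n_events": len(events.df),
            "n_samples_splicing": len(esheet.df),
            "n_phosphosites": n_phospho,
            "n_nuclei": len(foci.df),
            "planted_de": cfg.expression.n_de,
            "planted_splice": sum(cfg.splicing.n_true.values()),
        }
    )

inventory = pd.DataFrame(rows)
RESULTS.mkdir(exist_ok=True)
inventory.to_csv(RESULTS / "01_dataset_inventory.tsv", sep="\t", index=False)
print("Default synthetic datasets written under", DATA)
print(inventory.to_string(index=False))
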