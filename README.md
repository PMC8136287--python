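# gliadx

Cell-type-resolved analysis of expression and splicing dysregulation in
glial models of myotonic dystrophy type 1 (DM1), with a planted-truth
simulator that makes every stage testable without any data download.

## The problem

DM1 is caused by an expanded CTG repeat in the *DMPK* 3'-UTR.  The
mutant CUG-repeat RNA accumulates in nuclear foci, sequesters MBNL
splicing regulators, and derails developmentally regulated alternative
splicing ("spliceopathy").  In primary brain cell cultures from a DM1
mouse model (the DM genotype here), glia are hit hardest: differentiated
oligodendrocytes (OL) fail to activate genes that normally switch on
during the OPC→OL transition, and both astrocytes and OL accumulate
splicing changes that revert exons to their precursor-stage isoforms.

`gliadx` implements that whole analytical arc as a reusable pipeline:

1. **Differential expression** — median-of-ratios normalization, Welch t
   on log2 counts, significant iff |fold change| > 1.4 (strict) and
   Benjamini-Hochberg q < 0.05.
2. **Differential splicing** — PSI = 100·inc/(inc+exc) per event
   (cassette, multi-exon, mutually exclusive, acceptor/donor switch);
   replicate counts pooled per genotype; two-sided Fisher exact test on
   the 2×2 inclusion/exclusion table; significant iff |ΔPSI| > 10 points
   and q < 0.05.
3. **Differentiation catalogs** — the same calls run between WT
   precursor and differentiated stages, with multi-stage trajectory
   union (|A∪B| = |A| + |B| − |A∩B|).
4. **Concordance** — hypergeometric overlap of disease calls with the
   catalogs (representation factor RF = observed/expected overlap,
   expected = |A||B|/|U|); per-feature classification into failed
   activation / accentuated (expression) or immature / mature isoform
   shifts (splicing); exact binomial direction-bias test.
5. **Phosphoproteomics** — a site is significant if detected in every
   replicate of one genotype and none of the other (genotype-exclusive),
   or by |FC| > 1.4 with q < 0.05; direction census and cross-layer
   overlap with misspliced genes; generic over-representation analysis.
6. **Foci quantitation** — per-nucleus foci counts summarized per cell
   type and compared by one-way ANOVA.

The **synthetic-data module** generates all inputs with the structure
the analyses assume — negative-binomial gene counts, binomial inclusion
counts given per-group PSI, Gaussian log-intensities with detection
dropout, zero-inflated Poisson foci counts — and plants labeled effects
whose default magnitudes mirror the published censuses (85 DE genes in
OL; 264 misspliced events in astrocytes, 184 cassette; 48 events shared
between the glia; 37 immature-shift OL events; 345 phosphosites, 279 up
vs 66 down), so recovery can be scored against ground truth.

## Worked example

```python
from gliadx import default_config
from gliadx.workflows import splicing_census

res = splicing_census(default_config("astrocyte"), seed=1)
print(res.n_significant)              # 271
print(res.extra["by_category"])       # {'cassette': 188, 'multi_exon': 42, ...}
print(res.extra["recovery"])          # {'sensitivity': 1.0, 'fdp': 0.026, ...}
```

This generates the default synthetic astrocyte dataset (10,000 events,
4 WT + 4 DM replicates at 100 informative reads per event), pools the
replicate counts, runs the Fisher test per event and applies the
|ΔPSI| > 10 / q < 0.05 filter: 271 events are called (264 planted, 7
false positives), 188 of them cassette exons — the astrocyte
spliceopathy census at this noise level.

The numbered scripts under `analysis/` walk the full study in order
(simulate → OL expression → splicing censuses → differentiation
concordance → phosphoproteome → foci), each printing its findings and
writing small tables under `results/`:

```bash
python analysis/03_splicing_census.py
# astro/OL shared events: 48 (RF 17.4, p = 7.21e-49)
# max overlap involving neurons/OPC: 0
```

A `gliadx` CLI exposes the same stages for file-based use
(`gliadx simulate|de|splice|catalog|concord|phospho|foci|report`, each
with `--seed`, `--out`, `--config`).

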