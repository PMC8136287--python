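# Methods

This note documents the statistical procedures implemented in `gliadx`,
the models behind the synthetic-data generators, the parameter defaults
and why they were chosen, and the known limits of what the synthetic
benchmarks demonstrate.

## Differential expression

Counts are normalized by median-of-ratios: for genes detected in every
sample, each sample's size factor is the median ratio of its count to
the gene's geometric mean across samples; normalized counts are raw
counts divided by the size factor.  If no gene is detected in all
samples the normalization refuses to run rather than silently using an
empty reference.

Testing is a two-sided Welch t-test per gene on log2(normalized + 0.5),
chosen over a negative-binomial GLM because the pipeline's scientific
content lies downstream of DE calling and the planted effects (4-fold)
are far from the regime where the test choice matters; the test sits
behind a single function and is swappable.  The pseudocount 0.5 avoids
log(0) and is negligible at the simulated depths.  Genes with zero
counts in every sample of both groups are excluded from testing and
from the BH denominator — untestable features would otherwise inflate
the correction.  Significance: max(FC, 1/FC) > 1.4 (strict inequality;
the gate applies to the raw, unshrunken fold change) and BH q < 0.05.

## Differential splicing

PSI = 100 × inclusion/(inclusion + exclusion), undefined (NaN, never 0)
when both counts are zero.  Replicate counts are pooled within each
genotype and a two-sided Fisher exact test (sum of table probabilities
≤ the observed table's) is run on [[inc₁, exc₁], [inc₂, exc₂]].  An
event is testable only with ≥ 10 pooled informative reads in *both*
groups (configurable; the upstream event-detection pipeline's internal
coverage filters are not published).  BH runs jointly over all testable
events across the five categories, one census per comparison.

Pooling trades replicate-level variance for power and is what a 2×2
Fisher construction implies; it treats reads as exchangeable across
replicates (pseudo-replication).  The per-replicate PSI matrix is also
exposed (`per_replicate_psi`) so the pooled calls can be inspected
against replicate scatter.  In the simulator the true PSI is constant
across replicates within a group, so the pooled test is exactly
calibrated there; on real data with replicate-level PSI variability the
pooled Fisher p is anti-conservative — a caveat inherited from the 2×2
design, not introduced by this implementation.

## Differentiation catalogs and concordance

Catalogs apply the same thresholds as the genotype comparisons
(FC > 1.4 / ΔPSI > 10 / q < 0.05 — no separate thresholds are published
for the differentiation lists) to WT precursor vs differentiated
samples.  For a three-stage trajectory, two screens (precursor→final
and intermediate→final) are merged by feature-id union; provenance
records the contributing stage pair(s), and a direction conflict on a
shared feature keeps the longer transition's direction but raises a
flag instead of resolving silently.

Overlap statistics: expected overlap |A||B|/|U|, representation factor
RF = observed/expected, and an upper-tail hypergeometric p (enrichment
only; depletion is out of scope).  The background universe is a
mandatory explicit argument — the convention here is the set of
features testable in *both* comparisons.  Published RF values are not
comparable across studies unless the background size is stated, which
is why the test suite checks the RF identity and its calibration on
random sets rather than any particular printed RF.

Concordance classes compare the disease direction with the catalog
direction: expression — failed_activation (catalog up, disease down),
failed_repression, accentuated_up/down, not_differentiation_regulated;
splicing — immature_shift when the disease ΔPSI opposes the maturation
ΔPSI (the isoform balance moves back toward the precursor state),
mature_shift when the signs agree.  The direction-bias test is an exact
two-sided binomial test against a 50:50 split; the published analyses
label the analogous test "Fisher's exact" without stating the second
margin, and the symmetric binomial is the defensible reading (it is
labeled as such in reports).

## Phosphoproteomics

Dual rule per site: (a) *genotype-exclusive* — detected in every
replicate of one genotype and in none of the other; significant by
rule, direction up for DM-exclusive; (b) *quantitative* — with ≥ 2
observed values per group, Welch t on log2 intensities, significant iff
|FC| > 1.4 and BH q < 0.05, with BH over the quantitative branch only.
The fold change is the ratio of arithmetic means of linear-scale
intensities (a geometric-mean option exists).  Sites that are neither
fully partitioned nor observed twice per group are untestable.  No
imputation is performed: under the exclusivity rule, missingness is the
signal, and imputing would destroy it.

## Synthetic-data generators

Gene counts: NB with variance μ + φμ², gene baselines log-normal
(median 250, σ_log 1.2), per-sample size factors log-normal (σ 0.15).
Planted genes (disease or differentiation-regulated) take baselines
log-uniform on [500, 5000] — detectable expression, mirroring the fact
that published DE lists concentrate above a base-mean floor.  Disease
effects are ±2 log2 units (4-fold) at the differentiated stage only
(precursor stages are unaffected, matching the near-silent precursor
comparisons); differentiation effects are ±2 log2 units between WT
stages.  The dispersion default is φ = 0.005 (CV ≈ 7% at high
expression).  This was set from a power analysis, not from a variance
survey: with Welch t at n = 4 and ~16,000 tests, the BH-adjusted
threshold sits near p ≈ 2×10⁻⁴ (t ≈ 7.6 at ~6 df), and the heavy t tail
means a 4-fold effect only clears it reliably when the per-replicate
log2 SD is ≲ 0.12.  φ = 0.005 puts per-gene power at ≈ 0.98–1.00, which
is the regime the planted-census benchmarks presuppose; inbred-mouse
primary cultures profiled in one batch plausibly sit near this
technical-replicate-like noise floor, but the benchmark should be read
as "recovery under the planted conditions", not as a claim about field
noise levels.

Splicing: per event and sample, an NB informative-read total (mean 100,
dispersion 0.05) and a binomial inclusion count at the group's true
PSI.  Planted effects are additive in PSI points (±30 by default) with
baselines placed so paths stay inside [1, 99]; truth labels therefore
carry the exact planted ΔPSI in points, the same scale the recovery
tolerance uses.  The three-stage astrocyte trajectory plants 202
early-transition and 95 late-maturation changes sharing 53: early-only
events finish their switch before the intermediate stage, late-only
events are transient (endpoints agree, the intermediate departs) so
they pass only the late screen, and shared events move monotonically
with a larger full-trajectory delta — the only single-threshold
structure consistent with those three counts.  Event identifiers live
in one genome-wide namespace; each cell type plants its disease events
in a disjoint index block, and the 48 astro/OL shared events use a
common `SHGL_*` namespace in both datasets, so cross-cell-type overlap
has a realistic ~10,000-event universe.

Phosphosites: Gaussian log2 intensities (baseline N(22, 2), residual SD
0.15 ≈ 11% CV, typical label-free replicate scatter), planted
quantitative shifts of ±1 log2 unit, genotype-exclusive sites fully
partitioned by construction, and stochastic dropout (rate 0.10) on null
sites only.  345 significant sites are distributed over 288 proteins
(57 proteins carry two sites); proteins are named `P_<gene>` in the
splicing gene namespace, and the first 27 significant proteins take the
gene ids of planted misspliced events, planting the cross-layer
overlap.

Foci: zero-inflated Poisson per DM nucleus.  Given a target positive
fraction f and mean m over *all* nuclei (the reading adopted for the
ambiguous published means), π and λ solve (1−π)(1−e^{−λ}) = f and
(1−π)λ = m; eliminating π leaves (1−e^{−λ})/λ = f/m, solved by
bracketed root finding, feasible iff f < m·(something ≤ 1) with the
implied occupancy ≤ 1.  f = 1 degenerates to a plain Poisson(m).  WT
nuclei are all zero.  Defaults: astrocyte (0.95, 6.0) — the positive
fraction is described only as "nearly all" and 0.95 is the chosen
reading — neuron (0.70, 2.4), OL (0.50, 2.5), OPC (0.20, 1.4), n = 500
nuclei per genotype.

### Values chosen where no number is printed

Non-cassette splicing category splits (astrocyte 40/20/10/10,
OL 12/7/9/8, neuron 3/2/1/1, OPC 3/2/2/1) sum to the printed totals but
the per-category values are graphical-only; they are config fields, not
constants.  Likewise: DE gene counts for neuron/OPC/astrocyte (6/3/12,
nominal small numbers), the OL differentiation splicing catalog size
(250), the astrocyte disease∩catalog direction split (31 immature / 15
mature — the smallest majority split whose binomial bias p lands near
the published 0.023), and the event universe (10,000 events across five
categories — a desk-scale stand-in for a genome-wide event catalog,
keeping a full four-cell-type analysis under a minute).  The OL
disease∩catalog split of 80 genes into 71 failed activations + 8
accentuating (1 up, 7 down) + 1 failed repression reconciles two
published statements ("71 of those 80", "the remaining eight
accentuated") that are off by one as printed.

## Numerical and tie-break choices

Strict inequalities at every gate (FC exactly 1.4, ΔPSI exactly 10, or
q exactly 0.05 do not pass).  Undefined PSI (0 inclusion + 0 exclusion)
propagates as NaN and such events are untestable, never imputed to 0.
Fisher two-sided p sums probabilities ≤ the observed table's (with a
1+1e-10 relative guard in the enumeration oracle against float ties).
The ZIP solver brackets λ in [1e-12, 1e6] with 1e-12 absolute
tolerance and raises a configuration error for infeasible
(fraction, mean) pairs rather than clamping.  All generator randomness
flows through one `numpy` Generator per call, seeded explicitly;
identical config + seed reproduces byte-identical TSV output.

## What the benchmarks do and do not show

Passing recovery tests shows the pipeline correctly inverts its own
generating model at the planted effect sizes and sample sizes — a
self-consistency and calibration check, deliberately at desk scale
(10,000 events vs a genome-wide catalog; one batch; no library-prep
artifacts).  They do not validate the biology of any real dataset: real
RNA-seq has correlated genes, batch structure, and dispersion that
varies with expression; real PSI varies between replicates (see the
pooling caveat); real phosphoproteomes have intensity-dependent
missingness on true sites too, which the exclusivity rule would then
misread — on real data the detection rule should be paired with a
presence-frequency sanity check.  One-way ANOVA on raw foci counts
mirrors the published analysis despite count non-normality;
Kruskal-Wallis is available (`method="kruskal"`), and a per-culture
aggregation would be the stricter unit of analysis where culture
identity is known.
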