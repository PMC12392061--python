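# Methods

## Data model

A Cq matrix holds one quantification cycle per (assay, sample).
Non-detection ("Undetermined", or a numeric reading above the 40-cycle
instrument ceiling) is kept **categorical** — stored as missing, never
imputed to a ceiling value — because imputing 40 would contaminate group
means and blur the detection logic the downstream rules depend on.  Samples
are annotated with donor, cell type ∈ {PSC, NSC, FPP} and compartment ∈
{IN, EV}; analysis groups are the (cell type, compartment) pairs.

## Detection and exclusivity

A reaction is *detected* iff its Cq is numeric and 15 ≤ Cq ≤ 30, inclusive
at both ends.  The inclusive-at-30 convention is the one that makes "Cq = 30
as a cut-off for detection" and "Cq > 30 is non-detected" simultaneously
true.  A group is *complete* for an assay iff all replicates are detected;
any failed read discards the assay from that group (its mean is undefined),
so reported group means always average exactly the full replicate set.

An assay is *exclusively expressed* in group A of a comparison iff every A
replicate has Cq < 28 and no B replicate is detected.  The criterion is
evaluated per replicate by default — the stricter, more reproducible reading
of a rule that could also be applied to group means; the group-mean variant
is available via `per_replicate=False` and is flagged in the call objects.
Assays detected between 28 and 30 cycles in one group and absent in the
other fall in a deliberate gap zone: expressed enough to be detected, not
enough to be called exclusive.

## Global-mean normalization

The normalizer set is the assays detected in all samples of the dataset
(computed once on the full design, jointly over IN and EV samples).  For
sample *j* with normalizer-mean Cq m<sub>j</sub>, expression is
expr(g, j) = m<sub>j</sub> − Cq(g, j): one unit is one Cq cycle = one log2
unit of abundance, larger means more abundant, and log2FC between groups is
mean(expr<sub>A</sub>) − mean(expr<sub>B</sub>).  The arithmetic mean of Cq
is used because Cq is already log-scale.  Per construction the procedure is
invariant to per-sample plate offsets and expr has exact zero mean over the
normalizer set in every sample.  Known limitation: the normalizer is a
compositional anchor — if a visible fraction of its members shifts with a
biological condition (e.g. many EV-loaded assays), that shift is partially
absorbed and contrasts are attenuated; with the handful of EV-loaded assays
typical of this design the attenuation is negligible.

## Moderated t and multiple testing

Each ordered two-group contrast is tested on assays complete in both groups
(n = 3 vs 3 by default, residual df d_g = 4), with pooled variance
s² = [(n_A−1)s²_A + (n_B−1)s²_B]/d_g.  The empirical-Bayes prior (d₀, s₀²)
is fitted by marginal moment matching under the scaled-F model
s² ~ s₀²·F(d_g, d₀): the mean and variance of log s² are closed forms in
digamma/trigamma, and d₀ solves a trigamma equation via Newton iteration on
the inverse trigamma.  When the observed spread of log s² does not exceed
its sampling noise, d₀ = ∞ and the prior is the plain average of the
variances (matching limma's `fitFDist` in both branches, which the test
suite verifies through Rscript).  The moderated statistic is

    s̃² = (d₀ s₀² + d_g s²) / (d₀ + d_g)
    t  = log2FC / sqrt(s̃² (1/n_A + 1/n_B)),   df = d₀ + d_g

with d₀ = 0 recovering the classical pooled t exactly (regression-tested at
1e-10).  One deliberate divergence from a full limma workflow: limma caps
the total df at the summed residual df of the fit; here df = d₀ + d_g as
defined, which only matters in the d₀ = ∞ branch and moves p-values by
≲2·10⁻³.  Contrasts are fitted pairwise (no global six-group design matrix
and no donor blocking): with three replicates per group this matches the
pairwise contrast tables the design reports while staying simple; donor
labels are kept in the annotations for future paired modeling.

Per contrast, p-values are BH-adjusted (step-up, implemented directly and
cross-checked against statsmodels) and the status call is joint: `up_A` iff
adjusted p ≤ 0.05 and log2FC ≥ log2 1.5 — the fold-change rule is applied on
the log scale as |log2FC| ≥ log2(1.5).  Exclusivity overrides any
statistical status and clears t/p, since such assays were never valid tests.
Assays testable in one comparison but incomplete in another are handled
independently per comparison.

## EV signatures

The nine comparisons of the design are three IN cell-type pairs, three EV
cell-type pairs and three EV-vs-IN contrasts within cell type.  From the
within-type contrasts, a miRNA is *EV-associated* in a type if it is
statistically up in EV (`up_A` in CT:EV vs CT:IN) **or** EV-exclusive; the
two evidence kinds are pooled because exclusivity is the categorical limit
of the same loading pattern.  Universal = associated in all three types
(the enrichment-only subset is reported separately), population-specific =
associated in exactly one, shared-neural = associated in NSC and FPP but not
PSC.  The shared-neural set has a second reading — up in both neural EV
populations *relative to PSC EVs* — exposed via
`shared_neural_definition="vs_psc_ev"`; the default is the EV-vs-IN reading
and every output records which was used.  miRNA names are canonicalized
(lowercase, optional "hsa-" prefix) with arm suffixes (-5p/-3p) preserved;
assay identifiers are otherwise taken verbatim with no miRBase version
remapping.

## ΔΔCt validation

Per sample, ΔCt references the arithmetic mean of the ACTB and GUSB Ct
values (equivalently the geometric mean of their linear quantities); ΔΔCt
subtracts the calibrator group's mean ΔCt, so the calibrator's geometric
mean fold change is exactly 1, and FC = 2^(−ΔΔCt).  The calibrator is the
second-listed group of a contrast (NSC when reporting FPP vs NSC), keeping
the reported orientation "target up in FPP".  Group differences are Welch
t-tests on log2 FC (no shared-SD assumption, each gene tested individually);
genes with zero variance in both groups and equal means get p = 1.
Family-wise correction across genes is Holm–Šídák step-down:
adj<sub>(i)</sub> = max<sub>j≤i</sub> [1 − (1 − p<sub>(j)</sub>)^(m−j+1)],
clipped at 1.  ANOVA-style multi-group validation is out of scope; only the
two-group path is implemented.

## Over-representation analysis

Predicted targets of a query miRNA set are pooled by set union from a
user-supplied miRNA→gene table (query miRNAs absent from the table warn,
they do not error).  Each pathway is scored with the one-sided
hypergeometric tail P(X ≥ k) for a universe of N genes, pathway size K,
query size n and overlap k, BH-adjusted across pathways.  The universe
defaults to all genes in the pathway table and is overridable; query genes
outside it are dropped with a warning.  No depletion test.  Target/pathway
databases are not bundled — mappings are plain TSV supplied by the user —
and an optional numeric `score` column can be thresholded (e.g. interaction
score > 0.95) before testing.

## Synthetic data generator

`generate_cq_dataset` emulates the profiled design: 754 assays × (3 cell
types × 2 compartments × 3 donors).  Per assay, a latent expression class
(expressed in both compartments / IN only / EV only / off) is drawn with
fractions 0.184 / 0.123 / 0.092, calibrated once so that per-compartment
detection sits near the study's 26%/24% and ~11.5% of assays are detected in
all 18 samples; expressed assays have baseline Cq ~ N(26, 3²), unexpressed
ones sit at N(36, 2²), above the window.  Noise is Gaussian on the Cq scale:
replicate noise sd 0.35 cycles, donor random intercepts sd 0.2 (mirroring
biological-replicate clustering without explicit pairing) and per-sample
plate offsets sd 0.5 (removed by normalization).  Dropout is
abundance-dependent: P(non-detected) = logistic((Cq − 30)/0.8), so
non-detection concentrates near the Cq 30 boundary.  Planted effects: 10% of
intracellularly expressed assays carry a cell-type effect with |log2FC| ~
U[0.6, 2.5]; 1% of assays are EV-enriched with an EV-vs-IN shift of
U[1.5, 3.5] cycles applied in all three cell types, restricted to abundant
baselines (≤ 25 cycles) because EV loading is only observable for cargo
whose cellular signal is itself reliably quantifiable; 1% are EV-exclusive
(EV baseline U[22, 25.5], intracellularly off).  EV loading is kept rare —
a handful of assays, as in the profiled study — which also keeps the
global-mean normalizer compositionally stable.  All draws come from one
seeded generator; identical configs are bitwise reproducible.

What the generator does **not** emulate: pre-amplification bias,
plate-position effects, amplification-efficiency differences between
assays, rRNA/tRNA-fragment contamination of EV RNA, and donor-by-assay
interaction beyond a shared intercept.  Passing tests on synthetic data
therefore demonstrate the correctness and calibration of the *pipeline*
under its assumed noise model, not robustness to those instrument artifacts.

`generate_validation_ct` emits ΔΔCt validation inputs: stable references
(ACTB at 20, GUSB at 22 cycles, sd 0.15), targets 5 cycles above the
per-sample reference mean with sd 0.2, shifted by −log2(FC) in the affected
group; with zero noise the pipeline recovers the planted fold change
exactly.

## Reference dataset for the worked examples

The original array exports are not publicly deposited, so the worked
examples run on a *synthetic* reference dataset
(`evmir.datasets.synthetic_reference_dataset`) that encodes the reported
group-level patterns: the named miRNA lists of the NSC/FPP contrasts (5 up +
2 exclusive + 1 down intracellularly; 11 + 16 in EVs, unnamed members filled
with labelled `sim-` placeholders), the universal and shared-neural EV
signatures, and the printed compartment Cq means of the EV-exclusive cargo
(miR-622, -639, -1300, -663b, -1290), embedded among 100 consistently
detected normalizer assays and ~600 unexpressed ones.  Replicates are the
group mean plus a centered ±0.05-cycle pattern that rotates across assays,
so group means are exact, variances are realistic, and every classification
is deterministic.  One encoded pattern deviates from its reported mean by
construction: a group printed as mean Cq 30 with all replicates non-detected
(> 30) is arithmetically impossible, so those replicates are placed just
above 30 (mean 30.2).

## Problem sizes and tolerances

The test suite and the acceptance script run at the study's native scale
(754 × 18) or smaller; the heaviest checks are a 200-repetition null
simulation at 2000 assays (empirical FDR, asserted ≤ nominal within two
Monte-Carlo standard errors), a 5000-assay hyperparameter-recovery
simulation (d₀ within 25%, s₀² within 10%), and a six-seed full-pipeline
recovery of planted universal-EV cargo (≥ 90% pooled).  Exact oracles are
asserted tight: classical-t equivalence at 1e-10, BH/Holm–Šídák hand values
at 1e-12, hypergeometric vs direct summation at relative 1e-12.  The whole
suite runs in well under a minute on one CPU.
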