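# Methods

## The sigmoid clone-growth model

A hematopoietic clone carrying a heterozygous autosomal driver occupies a
fraction 2·v of the stem-cell compartment when its variant allele frequency
is v, so a fully clonal compartment corresponds to VAF ½.  Clone growth is
modeled as logistic with that carrying capacity:

    v(t) = (1/2) · 1 / (1 + A e^(−s t))

with t in years, s the clonal fitness (/year) and A > 0 fixed by the
anchoring condition v(0) = v₀, giving A = 1/(2v₀) − 1.  The model is exactly
identified by two timepoints:

    s = ln[ (1/(2v₀) − 1) / (1/(2v₁) − 1) ] / Δt.

For v ≪ ½ this reduces to exponential growth, s ≈ ln(v₁/v₀)/Δt; near the
ceiling the logistic saturation dominates.  Three-timepoint cfDNA
trajectories are fit piecewise — one independent estimate per treatment
phase (chemotherapy, PARPi maintenance), each phase re-anchoring A at its
own starting VAF, so the fitted trajectory is continuous across the phase
boundary by construction.  Phase estimates are never averaged with the
overall two-timepoint (WB) estimate; they answer different questions and
are reported side by side.

**Identifiable domain and censoring.**  Endpoint VAFs are clamped into
[0.001, 0.499] before fitting.  The lower bound is the variant-calling
detection floor (0.1%); the upper bound keeps the estimate away from the
singularity at VAF ½, which real data can cross under loss of
heterozygosity — the model is silent there, so such estimates are flagged
`censored` rather than extrapolated.  The closed form inverts the forward
model exactly (machine precision; tested to 1e-9 relative error against an
independent Brent root-finder) *inside* this window; a trajectory that
decays below the floor is censored, and no inversion guarantee applies to
it.  Category boundaries s = ±0.25/yr are strict: exactly ±0.25 is
"stable".

## Classification cascade

Rules are applied per call, in order, with thresholds exactly as published:
retention requires a protein-altering effect (nonsynonymous, splice, and
the truncating classes) and ≥ 10 alternate consensus reads (inclusive);
germline is VAF > 45% (strict); SNP exclusion is VAF > 40% (strict) with a
dbSNP flag or gnomAD AF > 1% (strict), never applied below 40% VAF
regardless of annotation; recurrent driver hotspots (*DNMT3A* R882, *GNB1*
K57E, *JAK2* V617F, *SF3B1* K666/K700, *SRSF2* P95, *U2AF1* S34/Q157) are
exempt from SNP exclusion but not from the germline rule, and never rescue
a call failing the read-count floor.  Codon-level hotspot entries match any
substitution at the codon; the protein change is parsed from simple
substitution notation, and unparseable strings fall back to non-hotspot
with a warning.  The legacy symbol SFRS2 is canonicalized to SRSF2.
Patient CH status is ≥ 1 somatic CH-panel mutation at VAF ≥ 1%
(inclusive), evaluated on the baseline WB sample.

The read-count minimum is applied per sample (whether the published rule
pooled paired samples is not stated; per-sample is the conservative
reading).  Germline-range calls are routed onward to HRD classification,
not discarded.

## cfDNA origin attribution

The 5-fold rule is read as inclusive (cf/wb ≥ 5).  When WB is undetected
the 0.1% detection floor substitutes for the WB VAF — division-safe and
conservative toward the hematopoietic call (a cfDNA-only variant must reach
0.5% before it can be called tumor-shed).  Serial retention runs
independently per DNA source and keeps a variant if either source passes;
rescued sub-threshold timepoints take VAF 0.001 when residual alt reads
exist in the pileup, and timepoints with no evidence at all take the same
floor as a censoring convention for the fitness arithmetic but are flagged,
so downstream consumers can exclude them.

## Germline HRD

Pathogenicity databases enter as pre-annotated columns (ClinVar, ENIGMA,
expert review) — no live queries, for reproducibility.  BRCA1/2: any
database class of pathogenic/likely-pathogenic, or a deleterious effect
(splice, truncating indel, stopgain, startloss) with population AF < 1%.
Other HR-panel genes: the deleterious-and-rare arm only.  A missing
population AF is treated as rare and flagged (`af_assumed_rare`) — gnomAD
absence almost always means very rare, and the flag preserves
auditability.  The packaged 27-gene HR panel is an editable stand-in list;
any study-specific panel can be supplied as a one-symbol-per-line file.

## Single-cell clone inference

Clones are groups of cells with *identical* genotype vectors over the
somatic targets — the simplest reading of clone heatmaps, assumption-light
and exactly reproducible.  Cells missing a genotype at any target are left
unassigned rather than imputed; with allele-dropout (ADO) rate a, the
expected unassigned fraction is ~1 − (1 − a²)^m for m targets, and ADO also
miscalls het cells as hom at rate a(1 − a) per allele, which is why small
spurious "LOH" groups appear at realistic ADO — the ≥ 5-cell reporting
floor suppresses most of them.  QC requires ≥ 400 genotyped cells
(non-missing at ≥ 1 target).  Demultiplexing assigns each cell to the SNP
profile with maximal concordance over its non-missing SNP calls; cells
below 0.9 concordance or with a best-vs-second margin below 0.1 are dropped
as ambiguous (these thresholds are this package's choice; they mark
inter-sample doublets, whose merged profiles match both parents at ~75%).

**Exclusivity test.**  Truly exclusive clones still yield double-mutant
barcodes through doublets, at rate ≈ 2·d·f_a·f_b (two orderings of drawing
one cell from each clone).  The observed double-mutant count among cells
genotyped at both loci is compared to that background with a one-sided
binomial test at α = 0.05; "co-occurring" requires significant excess.  The
test is slightly conservative (the background uses observed mutant
fractions, which already include doublet inflation), so the false
co-occurrence rate on exclusive pairs sits below the nominal 5%
(simulation: ~1% across doublet rates 0–0.1), while nested subclones —
whose double-mutant fraction equals the subclone fraction — are detected
essentially always.

## Cohort statistics

Fisher tests use the probability-based two-sided definition (sum of the
probabilities of all tables with fixed margins no more likely than the
observed one), matching R's `fisher.test`; 2×2 tables go through scipy, and
r×c tables through full enumeration of the fixed-margin table space, which
is exact and fast for baseline-table totals (~10³ tables at n ≈ 100).
Wilcoxon rank-sum tests use the exact null for tie-free samples up to
n = 25 per group and the tie-corrected normal approximation otherwise;
degenerate inputs (identical samples) return p = 1.  Co-occurrence
restricts to patients with ≥ 2 mutations and the 5 most frequently mutated
genes (both configurable), with Benjamini–Hochberg FDR across the gene
pairs — BH is the standard default where the adjustment method is not
otherwise fixed.  Odds ratios are sample ORs; a zero cell reports OR = ∞
explicitly, and a zero margin reports p = 1 with a degenerate flag.

## The synthetic cohort generator

The generator is first-class, tested code.  It emulates the study design
the analysis assumes: three samples per patient (treatment start,
maintenance start, end of treatment; defaults 0 / 0.5 / 1.0 years,
approximating the reported median phase durations of just under six months
each), WB and cfDNA consensus depths of ~2000× / ~1500× (Poisson per
locus), CH prevalence 0.57, half the patients with tumor-derived cfDNA
variants.  CH clones draw a gene from a DDR-heavy frequency table and a
per-phase fitness from per-gene normal priors whose means encode the
therapy-selection pattern the analysis targets (chemotherapy ~1.9/yr for
*PPM1D* falling to ~0.4/yr under maintenance; *TP53* high in both phases;
DTA genes drifting near 0.1/yr); starting VAFs are log-uniform on
0.5–12%.  Observed reads are binomial at the sampled depth — the paper
states no explicit noise model for error-corrected VAFs, so binomial
counting noise on consensus reads is this package's assumption.  Tumor-shed
variants have true WB VAF exactly 0 and respond to chemotherapy (negative
phase-1 fitness prior); germline variants sit at true VAF 0.5; common-SNP
decoys are emitted at a mapping-biased 41–44.5% observed VAF with dbSNP
flags so the SNP-exclusion window is exercised; synonymous decoys exercise
the retention filter.  VAFs are fractions everywhere; percent thresholds
are converted exactly once at the configuration boundary.

What the generator does **not** emulate: clone–clone interference and
shared ancestry (clones grow independently), copy-number effects on VAF
(no LOH in bulk data), sequencing artifacts beyond binomial noise (no
position-specific error, no UMI-family-size effects), tumor-fraction
dynamics coupled to clinical response, and survival outcomes.  Passing
recovery tests therefore demonstrates correctness of the analysis logic
under the stated statistical assumptions, not robustness to every artifact
of real sequencing data.

## Problem sizes in the tests and acceptance script

Recovery checks use cohorts of 40–60 patients, 500-replicate fitness
recovery at depth 2000, 200-replicate exclusivity calibration at 1000
cells, and a 1000-triple inversion grid — sizes at which every reported
rate is stable to well within its asserted margin while the whole suite
runs in seconds.  The classification fixture is a 30-row hand-labelled
table covering every rule boundary (0.45/0.451, 0.40/0.401, 9/10 reads,
hotspot override, 0.9%/1.0% CH threshold).

## Known limitations

* Fitness estimation is closed-form and ignores read-count uncertainty; at
  small clone sizes the category assignment near |s| ≈ 0.25–0.5 is noisy
  (delta-method sd ≈ 0.2/yr at v₀ = 2%, depth 2000× and Δt = 1 yr).  A
  likelihood-based estimator would propagate depth but is out of scope.
* Exact-vector clone grouping fragments under high ADO; no imputation or
  denoising is attempted.
* The r×c Fisher enumeration is exponential in table size; it is intended
  for baseline tables (a few hundred subjects, ≤ ~4 levels), not large
  sparse tables.
* Germline calling trusts its annotation columns; variant effect
  prediction is out of scope.
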