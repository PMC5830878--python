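# Methods

## Variant model and filter cascade

A variant's identity is the tuple (chrom, pos, ref, alt); annotation fields
(gene, consequence, SIFT) never split identity, so the same site annotated
differently in two samples still matches. Positions are 1-based as in VCF;
all intervals in memory are 0-based half-open, converted at the boundary.

The somatic cascade is: control subtraction → dbSNP removal → coding-exon
restriction → evidence thresholds → cross-sample rescue. Each stage returns
a subset of its input, and the middle three stages commute (they are
independent per-variant predicates), which the suite verifies. Defaults:

| parameter | default | meaning |
|---|---|---|
| `min_af` | 0.05 | minimum observed allele fraction |
| `min_reads` | 10 | minimum variant-supporting reads |
| `reads_mode` | `supporting` | how `min_reads` is counted |
| `min_reads_af_analysis` | 5 | informativeness cutoff for the AF test |
| `rescue_min_reads` | 3 | cross-sample reads that rescue / flag a private variant |

"At least ten reads" is interpreted as ten *variant-supporting* reads — the
stricter and, for FFPE-derived libraries, more common convention — with
`reads_mode="total"` switching to a total-depth interpretation. The
cross-sample rescue replaces a manual alignment-viewer review with a
deterministic rule: a private variant with ≥ `rescue_min_reads` supporting
reads in the other tumor and none in the control is reclassified common (and
injected into the other sample's set with its cross-sample evidence); with
≥ `rescue_min_reads` control reads it is flagged as an artifact and removed.
`rescue_min_reads = 3` is a design choice, small enough to rescue a common
variant that randomly dipped below the 10-read threshold in one sample and
large enough that one or two stray reads do not.

## Allele-frequency comparison

Observed AFs are scaled by the pathologist-estimated tumor content,
`min(AF/t, 1)`: under a heterozygous-diploid model a variant carried by a
clonal fraction *c* of tumor cells in a sample of purity *t* has expected
AF `0.5·t·c`, so scaling removes *t* and leaves `0.5·c` — comparable across
samples of different purity. Per patient, scaled primary vs metastasis AFs
(variants with ≥ 5 supporting reads) are compared with a two-sided Welch
t-test; Welch because group sizes and variances differ systematically when
one lesion is more polyclonal. A patient is testable only if both groups
hold ≥ 5 informative variants (`min_informative`); untested patients are
reported with the reason rather than dropped. Benjamini–Hochberg correction
runs across the tested patients only, so `p_fdr ≥ p_raw` always. Degenerate
groups (zero pooled variance with equal means) are reported as t = 0,
p = 1. The suite calibrates the test under the null (rejection rate at
α = 0.05 inside the exact binomial 99% band over 1,000 replicates) and
checks > 95% power under a +0.3 mean shift at n = 20 per group.

## Coverage-depth CNV model

Each sample's per-bin counts are divided by the sample total, removing
library size; a reference panel (≥ 10 samples, enforced) gives the per-bin
expected fraction and its SD, absorbing capture-enrichment/GC/protocol bias
shared across samples. The SD is floored at `0.05 × expected_fraction` so a
degenerate (e.g. duplicated-sample) panel cannot yield unbounded z-scores;
5% is close to the Poisson coefficient of variation at the few-hundred-reads
-per-bin depths the model targets, so the floor does not mask real panel
variance.

Deviation and calling: `dev = observed/expected − 1`,
`z = (observed − expected)/sd`. A clonal integer copy number *k* at purity
*t* is expected at `(k/2 − 1)·t`. Tumor calling flags bins with |z| ≥ 2,
merges consecutive flagged bins per chromosome, and assigns the integer CN
(0–6, diploid excluded) nearest the segment's *mean* corrected deviation,
within an absolute tolerance of 0.1. Assigning CN at segment level rather
than per bin is deliberate: at ~500 reads/bin and t = 0.6 the per-bin
corrected-deviation noise SD is ≈ 0.1, so per-bin assignment against a ±0.1
band would misclassify roughly a third of genuinely duplicated bins, while
the segment mean is essentially noise-free; the z-flagging step remains
per-bin. Segments significant by z but concordant with no integer CN are
reported as `subclonal_or_impure` with copy number `ambiguous` — e.g. +20%
at 60% purity, which could be a duplication of the non-tumor compartment or
a subclonal duplication. Germline calling (controls) instead follows the
per-bin rule — flag iff |z| ≥ 2 *and* the bin's own deviation is concordant
— merging adjacent same-CN bins; isolated noise bins essentially never pass
the concordance test. Copy numbers above 6 map onto 6; the cap bounds the
search and high-level amplifications are rare in this entity.

Known limitation: fraction normalization makes deviations relative to the
sample mean, so a CNV covering a large share of the analysed territory
drags the total with it and attenuates its own (and inflates everyone
else's) deviation — a 10% territory gain at full purity reads ≈ +46%
rather than +50%, still inside the 0.1 tolerance, but a 40% territory gain
does not. The acceptance checks therefore use segments ≤ 10% of the binned
genome; real whole-chromosome events in an exome are comparably small
relative to the full target.

Control subtraction (`tumor − control` residual deviations, zeroing
|residual| < 0.20) and 5-Mb centered median smoothing are reporting-side
transforms; calling always uses unsmoothed, unsubtracted bins. Bins default
to 100 kb aggregated from exon targets by midpoint.

## Driver triage

Candidates are non-synonymous variants (missense, stop gained, frameshift,
in-frame, splice region) in a supplied census or prior-SI-NET gene list; no
gene data is bundled. Likely pathogenic: truncating consequence, or
SIFT ≤ 0.05 (splice-region variants carrying a SIFT score are treated
missense-like), or an in-frame indel without a SIFT score — the last rule an
explicit extension so such indels in listed genes are not dropped from the
pathogenic tier. Missense candidates without a SIFT score become VUS with a
warning. Recurrence counts distinct patients per gene (deduplicated within
patient) and reports genes hit in ≥ 2.

## Methylome

Analysis operates on a beta matrix (CpG × sample, values in [0, 1]) with
per-CpG gene, promoter (TSS-class) and SNP flags taken from the array
annotation; no de-novo promoter inference. SNP-flagged CpGs are removed
first. Gene-level calling is existential by default: a gene is
hyper(hypo)methylated if any ≥ `min_cpgs` (default 1) of its promoter CpGs
has delta beta strictly above 0.3 (below −0.3). A gene can appear in both
directions via different CpGs; both memberships are kept and same-direction
intersection defines the primary/metastasis overlap, with opposite-direction
genes reported separately as conflicts. The control-cohort check is
parametric: an alteration is `cohort_recurrent` if its same-direction delta
passes the threshold in more than `max_frequency` (default 0.05) of control
tumor/benign pairs, else `patient_specific`.

## Synthetic cohort

The generator's defaults are the emulated study conditions: tumor content
0.80 (primary) / 0.86 (metastasis) — the cohort means — mean depth 120,
somatic counts (10 common, 5 private-primary, 20 private-metastasis) giving
15/30 per sample within the observed 9–34 range, clonal fractions 1.0, and
a 50-variant dbSNP-annotated germline background (a chosen default; real
counts are orders of magnitude larger, but 50 suffices to exercise the
subtraction and dbSNP filters). Depth is Poisson (floor 1), supporting
reads binomial at the expected AF; a somatic variant enters a tumor's call
table only if ≥ 1 supporting read was drawn, while its read evidence at
every locus in every sample is recorded for the rescue step. Coverage
panels share a lognormal per-bin bias (σ = 0.3) across samples with
lognormal library-size variation (σ = 0.2) and Poisson counts; CNVs apply
at whole-bin granularity (> 50% overlap assigns a bin). Methylome baselines
are bimodal betas; dysregulated genes are drawn among genes with ≥ 2 usable
promoter CpGs and shifted by exactly ±`effect_delta` from baselines drawn
so the shift cannot clip (promoter hypermethylation starts from an
unmethylated baseline, as in real CpG-island promoters), with N(0, 0.03)
noise on every measured column; the primary/metastasis overlap is
`round(overlap_fraction · n_primary)` genes shifted in the same direction
in both lesions, so the recovered overlap fraction is exact by construction.

What the simulations do not model: FFPE deamination artifacts, mapping and
sequencing error, shared germline leakage past dbSNP, GC-dependent
coverage beyond a static bin bias, array batch effects, or replicate
variance. Passing recovery tests therefore demonstrates correctness of the
analysis logic under the stated noise model, not robustness to those
real-data failure modes.

## Problem sizes

The recovery suites run at deliberately modest scale: 100-replicate trio
recovery at depth 200, a 2,000-bin (100 kb) coverage genome with 20-Mb
segments at 500 reads/bin, 1,000-replicate AF-test calibration at n = 20
per group, and a 50,000-CpG methylome — sizes at which every stochastic
margin in the tests is already wide while the whole suite stays fast.
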