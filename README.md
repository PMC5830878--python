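# sinethet

A toolkit for analysing intratumoral heterogeneity between a primary tumor
and its metastasis from paired exome (and methylome) data, built around the
setting of small intestine neuroendocrine tumors (SI-NETs): mutationally
quiet neoplasms (< 1 mutation/Mb) in which the primary lesion and the liver
metastasis can share anywhere from 0% to almost all of their somatic
mutations. It is aimed at researchers who have per-sample variant calls,
capture coverage profiles, and array beta values for
primary/metastasis/control trios and want the downstream comparative
analysis — not at raw read processing.

## What it computes

**Somatic filtering.** Tumor call sets are filtered by control subtraction,
dbSNP removal, restriction to coding exons, and evidence thresholds
(AF ≥ 5% and ≥ 10 supporting reads). Variants private to one tumor are
re-examined in the read evidence of the other tumor and the control:
support in the other tumor reclassifies them as common, support in the
control flags an artifact.

**Heterogeneity.** Somatic variants are partitioned by identity tuple
(chrom, pos, ref, alt) into *common* (both lesions) and *private* sets with
per-sample percentages, mutation rates per Mb of target, and
pyrimidine-context substitution spectra. Observed allele frequencies are
scaled by tumor content, `AF_scaled = min(AF / purity, 1)`, so a clonal
heterozygous variant sits at 0.5 regardless of purity; scaled primary vs
metastasis AFs are compared per patient with a two-sided Welch t-test and
Benjamini–Hochberg FDR correction across patients.

**Coverage-depth CNV calling.** A panel of ≥ 10 reference exomes yields the
expected per-bin coverage fraction and its SD. A sample's per-bin deviation
is `observed/expected − 1`; a clonal copy-number-*k* segment at tumor
content *t* is expected at

    deviation = (k/2 − 1) · t

(+50% for a heterozygous duplication at full purity, −50% for a heterozygous
deletion, +30% for a duplication at 60% purity). Bins deviating by ≥ 2 SD
are flagged, merged, and each segment's purity-corrected mean deviation is
matched to the nearest biologically possible integer copy number (0–6);
significant segments matching no integer CN are reported as
`subclonal_or_impure`. Control tracks can be subtracted (keeping residuals
≥ 20%) and tracks median-smoothed over 5-Mb windows for reporting.

**Driver triage.** Non-synonymous variants in cancer-census or prior
SI-NET genes are classified *likely pathogenic* (nonsense, frameshift, or
SIFT ≤ 0.05) or *VUS*, plus cohort-level gene recurrence.

**Methylome overlap.** SNP-flagged CpGs are removed; per-CpG delta beta
(tumor − normal) is thresholded (|Δβ| > 0.3, strict) over promoter-associated
CpGs to produce hyper-/hypomethylated gene sets per lesion, which are
intersected by direction, annotated against a gene census, and checked
against a control cohort.

**Synthetic cohort.** `simulate_trio`, `simulate_coverage_panel` and
`simulate_methylome` generate all of the above inputs with known ground
truth (expected somatic AF = `0.5 · purity · clonal_fraction`, binomial
reads at Poisson depth; Poisson coverage with shared capture bias and
embedded CNV segments; bimodal betas with ±Δ promoter shifts), so the whole
pipeline is testable offline.

## Worked example

```sh
sinethet simulate --out-dir sim --seed 5            # trio + targets + truth
sinethet filter --primary sim/primary.vcf --metastasis sim/metastasis.vcf \
    --control sim/control.vcf --coding sim/targets.bed --out-dir filt
sinethet report --primary filt/primary.filtered.vcf \
    --metastasis filt/metastasis.filtered.vcf
```

prints

```
primary variants:       15
metastasis variants:    30
distinct somatic sites: 35
mutation rate per Mb:   primary 0.25, metastasis 0.50
common: 10 (67% of primary, 33% of metastasis); private primary 5, private metastasis 20
```

i.e. after the filter cascade the simulated patient carries 15 somatic
variants in the primary and 30 in the metastasis; 10 are common — 67% of the
primary's burden but only 33% of the metastasis's — matching the simulated
ground truth of 10 common, 5 private-primary and 20 private-metastasis
variants exactly. The rates per Mb refer to a 60-Mb exome target. The same
operations are available as library functions (`run_cascade`,
`partition_shared`, `compare_af`, `call_tumor`, `marked_promoter_genes`, …).

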