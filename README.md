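# lncrecur

Recurrent lncRNA deregulation analysis for matched multi-tissue cancer
cohorts.

Hepatocellular carcinoma (HCC) frequently invades the portal vein and
forms a portal-vein tumour thrombus (PVTT). Cohorts in which every
patient contributes three matched samples — adjacent normal liver,
primary tumour and PVTT — make it possible to ask, per patient, which
long noncoding RNAs (lncRNAs) change during tumorigenesis (tumour vs
normal) and which change further during intrahepatic metastasis (PVTT vs
tumour). `lncrecur` implements the full analysis chain for such designs:
lncRNA discovery from assembled transcript models, per-patient
differential expression with recurrence counting and a permutation FDR,
attribution of recurrent changes to copy-number and promoter-methylation
alterations, coding–noncoding co-expression networks with Markov
clustering, and clinical association (preranked enrichment, survival,
odds ratios, tumour subtypes). A synthetic-cohort generator with a
planted-truth ledger makes every stage testable without any external
download.

The package is aimed at computational biologists analysing matched
tumour designs, and at methodologists who need a transparent, fully
seeded re-implementation of this analysis style to benchmark against.

## The statistics at the core

**Discovery cascade.** Assembled candidate transcripts pass five filters
in order: (1) no exonic overlap (≥1 nt, same strand) with annotated
coding genes or ncRNAs; (2) summed exon length ≥ 200 bp and known
strand; (3) single-exon transcripts must lie > 2,000 bp from same-strand
annotated genes; (4) single-exon transcripts must reach FPKM ≥ 0.5 in at
least one sample; (5) no coding potential (CPC score ≤ 0 and COME score
≤ 0.5, with a longest-ORF fallback).

**Per-patient fold change (GFOLD-style).** For one patient and one
feature with counts *a*, *b* and library sizes *l_a*, *l_b*, posterior
rates are λ ~ Gamma(count + 1, 1) scaled by 1/*l*. The statistic is the
posterior *sc*-quantile (default 0.01) of log2(λ_b/λ_a) when the
posterior median is positive, the (1 − *sc*)-quantile when negative, and
0 when that credible bound crosses zero. |value| > 1 therefore means "a
2-fold change with posterior confidence 99%". A feature is *recurrently*
deregulated when called in the same direction in ≥ *r* patients (r = 8
of 20 for tumour vs normal, r = 4 for PVTT vs tumour); the FDR of each
recurrence level is estimated by drawing size-matched feature sets per
patient and re-counting recurrences over 10,000 permutations
(FDR(r) = mean null tail count / observed tail count).

**Cohort-level tests.** A paired Wilcoxon signed-rank test on
log2(FPKM + 1) and a patient-blocked negative-binomial Wald test on
counts (median-of-ratios size factors, method-of-moments dispersion,
effect = mean per-patient log2 ratio), each significant at
|log2FC| > 1 and Benjamini–Hochberg q < 0.05. Tumour-vs-normal recurrent
sets are the three-method intersection per direction; the PVTT contrast
uses the per-patient route alone, because replicate-based tests lose
power on heterogeneous metastatic samples.

**Drivers.** A GISTIC-style scan bins the genome, scores each bin by
frequency × amplitude of samples beyond ±0.3 log2 copy-ratio, and calls
regions against a circular-permutation null at BH q < 0.25; recurrent
features are CNV-driven when direction-consistent with an overlapping
region. Methylation-driven features have a promoter CpG (window:
2,000 bp upstream of the TSS) whose beta value anticorrelates with
expression (Pearson r < −0.3, most negative CpG retained) and is
differentially methylated between matched tumour and normal samples in
the consistent direction.

**Network.** After dropping the bottom 20% of features by maximal
expression, all-pairs Pearson correlations with Bonferroni-adjusted
p < 0.01 define edges; Markov clustering (inflation 2.4) partitions the
graph; cluster enrichment uses one-sided Fisher / hypergeometric tests.

**Clinical.** Signal-to-noise ((μ₁−μ₂)/(σ₁+σ₂)) preranked enrichment
with the weighted Kolmogorov–Smirnov running sum; Kaplan–Meier curves
with the log-rank test over a 5-year horizon; Woolf odds ratios with
Haldane correction; nearest-template subtype assignment (cosine
distance to S1/S2/S3 signature templates) and per-subclass Wilcoxon
rank-sum DE (q < 0.05, fold change > 2).

## Worked example

The whole pipeline runs from a single seeded command on the built-in
synthetic cohort (20 patients × 3 matched tissues, 1,900 features):

```bash
lncrecur run all --outdir run1 --seed 1
```

Selected numbers from the JSON reports this prints (seed 1):

```
discover:  n_discovered 800        # all 800 true lncRNAs; all 300 decoys removed
           snp_odds_ratio 3.51     # GWAS-SNP enrichment of lncRNA loci
           snp_odds_ratio_control 1.12
de:        tumour_vs_normal  n_up 38  n_down 37   (r_min 8)
           pvtt_vs_tumour    n_up 18  n_down 20   (r_min 4)
drivers:   n_regions 1             # the planted deletion, q < 0.25
           n_cnv_driven 9  n_methylation_driven 12
network:   n_nodes 1520  n_edges 1789  n_clusters_retained 4
clinical:  logrank_p 0.0007        # planted 2x hazard for marker-low patients
           subtype_counts {S1: 20, S2: 20, S3: 20}
```

Reading: the discovery cascade keeps exactly the planted true lncRNAs
and removes each decoy class at its designed filter; the recurrent sets
(75 tumorigenesis, 38 metastasis candidates) recover the planted
recurrent features at ~0.94 sensitivity with empirical FDR < 0.1; the
planted deletion is localised and its lncRNAs flagged CNV-driven; the
survival split on the planted marker separates the cohort at
log-rank p < 0.001.

Every stage is also callable as a library function; see
`lncrecur.recurrence`, `lncrecur.drivers`, `lncrecur.network`,
`lncrecur.clinical`, `lncrecur.synthetic`.

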