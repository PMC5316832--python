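# Methods

This note documents the models, parameters and design decisions behind
`lncrecur`, in the spirit of a statistical methods appendix. Everything
quantitative stated here is computed by the test suite or the acceptance
script; nothing is asserted that the code does not measure.

## Cohort model and coordinate conventions

The unit of analysis is a matched cohort: each patient contributes one
adjacent-normal, one primary-tumour and one PVTT sample. Contrasts are
within-patient (tumour vs normal; PVTT vs tumour), and a patient enters
a contrast only when both members exist and are usable; the generator
marks one patient's PVTT as unusable to mirror the realistic case of a
contaminated sample, so the metastasis contrast runs on 19 of 20
patients.

All internal genomic coordinates are 0-based half-open. GTF input
(1-based inclusive) converts at the parse boundary; BED and bedGraph are
native. The TSS of a minus-strand transcript is the genomic right edge
of its interval. Promoters are the 2,000 bp immediately upstream of the
TSS, clipped to chromosome bounds.

## Per-patient fold-change statistic

With counts *a*, *b* and library sizes *l_a*, *l_b*, the posterior rate
of each condition is Gamma(count + 1, 1)/*l* (a flat prior on the
Poisson rate). The reported value is the credible bound of
log2(λ_b/λ_a) nearest zero: the *sc*-quantile when the median is
positive, the (1 − *sc*)-quantile when negative, 0 when the bound
crosses zero. Quantiles are Monte-Carlo (default 10,000 draws, seeded);
the exact identity λ_b/(λ_a + λ_b) ~ Beta(b+1, a+1) gives a closed-form
oracle through `scipy.stats.beta.ppf`, used by the tests to verify the
Monte-Carlo path. The two conditions are canonically ordered before
drawing, so swapping them negates the value exactly with a shared seed.

This statistic deliberately models only counting noise, not biological
overdispersion — that is what the recurrence requirement across
patients is for. Under negative-binomial dispersion 0.1 the observed
per-pair log2-ratio noise is ~0.68 (log-gamma variance ψ′(10) × 2, in
log2 units), which caps single-pair detection of a 4-fold change at
P ≈ Φ((2 − 1.1)/0.68) ≈ 0.90 regardless of depth; recurrence across ≥ 8
patients restores near-perfect feature-level sensitivity.

## Recurrence permutation FDR

For each direction separately, each permutation draws, for patient *i*,
*k_i* features uniformly without replacement from the expressed lncRNA
universe (*k_i* = that patient's observed call count) and re-counts
recurrences. FDR(r) = mean null tail count / observed tail count,
capped at 1; a zero observed tail reports FDR 0 with a flag. The
Monte-Carlo estimate is validated against the exact Poisson-binomial
tail (p_i = k_i/N) on enumerable instances. The universe is the set of
discovered plus annotated lncRNAs with any expression in the cohort
(1,100 features at the default synthetic scale).

The operative recurrence thresholds are 8 of 20 (tumour) and 4
(PVTT). The selection rule that produced those constants — the smallest
r with permutation FDR < 0.05 — is implemented as
`fdr_thresholded_sets` and reported alongside; on the synthetic
conditions it selects r = 6 for the PVTT contrast because the
per-patient false-call density relative to a 1,100-feature universe
(~4%) is higher than in a genome-scale universe, and at that threshold
features planted at the 5-patient prevalence floor become structurally
undetectable. The pipeline therefore applies the standard constants
and reports the rule's choice for comparison.

## Cohort-level tests

The Wilcoxon route tests log2(FPKM + 1) pairs (signed-rank), reporting
the median per-patient log2 ratio; log-scale pairs make up- and
down-shifts symmetric. The negative-binomial Wald route normalises by
median-of-ratios size factors, estimates per-feature dispersion α by
method of moments from within-tissue variability (no shrinkage), and —
because the design is matched — blocks on patient: the effect is the
mean per-patient log2 ratio of normalised counts with a delta-method
standard error from Var(K) = μ + αμ². An unpaired group-means contrast
was rejected at design time: a feature 4-fold down in 12 of 20 patients
has a group-mean ratio of 0.55 (|log2FC| = 0.86), below the standard
|log2FC| > 1 rule, i.e. the unpaired estimate confounds prevalence with
effect size, while the blocked estimate (−1.2) does not. Significance
in both routes: |log2FC| > 1 and BH q < 0.05.

## Driver attribution

The copy-number scan bins the genome (pipeline default 50 kb), forms a
per-sample, per-bin length-weighted mean log2 copy ratio, and scores
G_amp(bin) = Σ over samples of the ratio where it exceeds +0.3 (G_del
analogously with −0.3). The null circularly rotates each sample's
genome-wide bin profile independently (2,000 rotations), preserving
within-sample segment structure; empirical p-values get BH correction
and maximal runs of q < 0.25 bins become regions. 2,000 rotations keep
the p-floor (1/(n+1)) fine enough for a single-bin region to clear BH
across ~600 bins; 50 kb bins keep edge-bin dilution of a ~200 kb
deletion below the ±0.3 call threshold. A recurrent feature is
CNV-driven only when its direction matches the region (down/deletion,
up/amplification).

Methylation attribution assigns promoter CpGs positionally, computes
Pearson r between FPKM and beta across all 60 samples per CpG, and
retains the most negative r ("highest correlation" is read as most
negative, since the downstream filter keeps r < −0.3 and a most-positive
reading could never pass). Because taking the minimum over ~Poisson(3)
CpGs at the nominal −0.3 cutoff has a ~3% per-feature null rate, the
pipeline applies a second criterion: the best CpG must be
differentially methylated between matched tumour and normal samples
(paired t-test, p < 0.05) in the direction consistent with the
expression change. The plain r-only rule is available by passing no
design.

## Co-expression network

Features in the bottom 20% by maximal expression are excluded (ties
broken by feature id, so the removed count is exact). Edges require
Bonferroni-adjusted Pearson p < 0.01, with p from the exact t transform
at n − 2 degrees of freedom and the multiplier equal to the number of
tested pairs. MCL runs on column-stochastic matrices built from edge
affinity −log10(p_adj) capped at 300 (the cap avoids infinities at
underflow; MCL needs a monotone small-p ⇒ strong-affinity transform),
with unit-or-larger self-loops, expansion/inflation iterations, pruning
below 1e−5, and idempotence tolerance 1e−8. Attractor-row supports
define clusters; overlapping supports merge. Retained clusters need
≥ 100 members on genome-scale data; synthetic runs use 10. The tests
compare the production implementation against an independent dense,
prune-free reference on all random graphs up to 8 nodes at inflations
1.5/2.4/4.0.

## Clinical associations

Preranked enrichment uses the classic weighted (weight 1) KS running
sum; p-values come from random same-size gene sets under the fixed
ranking, sign-matched. Phenotype permutation is possible only when the
full matrix is present, and gene-set permutation is the default for the
preranked mode. Survival uses the product-limit estimator and two-group
log-rank test (via lifelines), administratively censored at 1,825 days;
the marker split is lower tercile vs rest by default (matching a
51/100 split at n = 151), configurable. Odds ratios are Woolf estimates
with log-scale 95% CI and Haldane 0.5 correction on zero cells.
Nearest-template subtyping centres both the sample's signature-gene
vector and the ±1 templates gene-wise and assigns by cosine distance;
per-sample p-values come from gene-label permutations. Cosine distance
is the package's choice; the original tool family does not pin one in
a way that changes assignments on well-separated templates.

## The synthetic cohort

The generator emulates the processed shapes of a 20-patient matched
cohort on a 3 × 10 Mb genome: 500 coding genes, 300 annotated lncRNAs,
800 candidate lncRNAs and 300 filter decoys (five classes of 60, each
violating exactly one discovery filter), placed without overlap with
≥ 3 kb gaps.

Expression is negative-binomial (dispersion 0.1) around log-normal
baselines (median ~1,300–1,800 counts; the emulated study sequenced
~160 M reads per sample, and at shallower depth the credible-bound
margin of the per-patient statistic dominates detection), with a
per-(feature, patient) random effect (σ = 0.3 log) shared across the
patient's three tissues, a per-sample library factor (σ = 0.25 log),
and per-(module, patient) factors (σ = 0.8 log) for four planted
co-expression modules of 30 coding + 10 lncRNA members. FPKM is
count × 10⁹ / (exonic length × column total).

Planted truths: 40 up and 40 down tumour-contrast lncRNAs, each ±2 log2
in a per-feature random subset of 12–18 of 20 patients (a prevalence
*range*, mirroring the spread of recurrence levels in real matched
cohorts; planting every feature at the minimum would put every true
effect exactly at the |log2FC| = 1 detection boundary); 15 + 15 PVTT
features at 5–9 of 19 patients, shifted in the PVTT sample only;
tumour-contrast effects apply to tumour *and* PVTT samples so they
cancel in the metastasis contrast. Eight consecutive chr1 lncRNAs form
the CNV set: 12 carrier patients (penetrance 0.6) harbour a −0.8 ± 0.1
log2 deletion extending 25 kb past the outermost affected locus, and
those features are down exactly in the carriers. Ten non-CNV down
features are methylation-driven: one promoter CpG is hypermethylated
(+0.25 beta, noise σ = 0.13) in precisely the affected patients'
tumour/PVTT samples — the mechanistic direction of promoter silencing —
yielding realised expression–beta correlations of −0.5 ± 0.1. GWAS SNPs
are planted at 5× background density inside lncRNA loci. The survival
layer draws 150 subjects with exponential survival and hazard ratio 2
for the marker-low tercile, two clinical covariates with planted odds
ratios ~3 and one neutral covariate. Subtype templates are ±1 block
vectors over 30 signature genes; external samples scatter around their
subclass template (σ = 0.8).

Every generator is a pure function of (config, seed); a single global
seed fans out to stage seeds by stable hashing of stage names, so
adding a stage never perturbs another stage's randomness. The truth
ledger (JSON) is sufficient to score any stage without re-reading
generator internals.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: read-level artefacts (mapping bias, GC,
duplicates), isoform structure within genes, genuinely correlated
biological pathways beyond the planted modules, array probe chemistry
and batch effects, non-exponential survival, and a genome-scale
multiple-testing burden (the synthetic universe is 1,100 lncRNAs, not
~22,000). Conclusions about absolute FDR on real cohorts should not be
read off the synthetic numbers; the synthetic suite establishes
correctness of the machinery and its calibration under known truth.

## Problem sizes and determinism

Default analysis scale: 1,900 features × 60 samples; per-patient
statistics use 10,000 posterior draws; recurrence FDR 10,000
permutations; CNV null 2,000 rotations; network ~1,500 nodes. The
20-replicate null-calibration suites run on a reduced cohort (220
features, no planted effects, 2,000 posterior draws, 1,000
permutations) so the whole battery stays a few minutes on one CPU.
All Monte-Carlo paths take explicit seeds and identical inputs give
byte-identical outputs, including written artefacts.

## Known limitations

The NB Wald test uses method-of-moments dispersion without shrinkage,
so its q-values are anti-conservative for features with few effective
replicates; it is always used inside a three-method intersection.
The G-score scan is a deliberately simplified stand-in for segment-level
peak-calling algorithms: it reports contiguous significant bins, not
peel-off peaks, and will merge adjacent independent events. MCL on the
dense transition matrix is O(n³) per iteration and is intended for
graphs up to a few thousand nodes. The GFOLD-style statistic ignores
overdispersion by construction (see above). Interval queries are linear
scans per chromosome, adequate at these scales but not for genome-scale
annotation sets.
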