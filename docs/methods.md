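# Methods

This note documents the models, numerical choices and limitations behind
`methfidelity`, in the order data flows through the pipeline.

## Synthetic cohort model

The generator exists so that every downstream stage can be tested against
known ground truth. It emulates the features of Infinium-style array data
that the methods actually consume, and nothing more.

**Beta model.** Each probe draws a baseline beta from a three-component
mixture: an unmethylated mode Beta(5, 45) (mean 0.10), a methylated mode
Beta(38.25, 6.75) (mean 0.85), each with weight 0.45, and a uniform
mid-component with weight 0.10. This reproduces the bimodal beta
distribution of real arrays (≥ 60% of probe means fall in
[0, 0.2] ∪ [0.8, 1], an invariant the tests check). Per-sample,
per-probe noise is logit-normal with sd 0.3 on the logit scale — small in
absolute beta near the modes, larger mid-scale, as on real arrays.

**Class signatures and divergence.** Each histology class owns a disjoint
set of signature CpGs (default 60) pushed to a target level (alternating
0.85/0.10 across classes). Paired cultures are either *faithful* (full
class signature) or *unfaithful*: their class signature is attenuated to
30% and they acquire (i) the full signature of a designated attractor
class (default a meningioma-like control class, mirroring the empirical
observation that divergent cultures co-cluster around a distinct
methylation class) and (ii) a shared promoter-hypomethylation panel
(default 30 genes set to β = 0.07 at TSS200/TSS1500/1stExon probes).
Unfaithful status co-occurs with serum medium, late passage and 2D culture
by design, so stratified reports have signal to find.

**Intensities and CNV.** Beta is converted to channels through a single
total-intensity draw per probe × sample, T ~ lognormal(median 3000,
σ = 0.25); M = T·β, U = T·(1−β). This is the simplest model in which
copy number lives in M+U while methylation lives in the ratio, which is
exactly what the CNV method requires. A planted segment of `copies` copies
multiplies T by 1 + purity·(copies/2 − 1); tumor purity defaults to 1.0
(the factor floor is 0.025 so homozygous losses stay positive).
Copy-neutral controls can never carry a segment (enforced). The default
design gives each class's chromosome one 3-copy gain and one 1-copy loss,
each spanning ~30% of the chromosome's probes; a culture carries both, one
or none of its tissue's segments according to its designed CNV share
(*coincident* / *similar* / *different*), so all six fidelity conditions
are realized, four pairs each, in the default 24-pair cohort.

**Probe placement.** 30% of probes are grouped into CpG-island-like
clusters (15 probes over 1200 bp); the rest are scattered uniformly.
Island geometry matters: region callers aggregate dense runs and split at
gaps, so a manifest without islands cannot host a plantable DMR. Planted
DMRs sit on dense runs; before shifting the affected group by Δβ, the
region baseline of *all* samples is clipped into
[0.01 + max(0, −Δβ), 0.99 − max(0, Δβ)] so the planted difference is
achievable; truncation with a warning remains for infeasible targets.

**What the generator does not model:** probe chemistry (out-of-band
signal, dye bias), FFPE degradation, cell-composition mixtures, multi-gene
probes, sex-chromosome dosage. Passing tests therefore demonstrate that
the pipeline recovers the signals it models — not that it is robust to
artifacts it does not.

## Preprocessing

Probe filters run in a fixed order with first-match-exclusive reasons:
detection p > 0.01 in any sample (no sample-fraction is applied to this
rule — the conservative standard default), bead count < 3 in ≥ 5% of
samples, blacklist, sex chromosomes. Beta uses the standard Illumina
offset of 100; M-values clip beta to [1e-6, 1 − 1e-6].

**BMIQ.** Per sample, 3-state beta mixtures are fitted separately to
type I and type II probes by EM. The M-step uses weighted
method-of-moments beta updates (responsibility-weighted mean/variance
matched to Beta(a, b)); convergence is declared when the mean per-probe
log-likelihood changes by < 1e-4 (max 100 iterations), and a
non-converged sample passes through unchanged and is flagged in the log.
State boundaries on the value axis are the posterior-argmax crossings
searched outward from the component means (searching from the domain edges
is unstable when a fitted tail dominates a region with no data). The
unmethylated and methylated states map through CDF/inverse-CDF of the
fitted distributions (type II → type I); the hemimethylated state is
dilated linearly onto the interval between the two mapped outer states,
which keeps the whole map continuous and monotone; a final cumulative-max
pass absorbs inverse-CDF round-off. Type I probes are returned
bit-identical.

**Cohort QC.** The MDS screen takes the top-1000 most variable probes,
classical (Torgerson) MDS, and flags samples with robust z (median/MAD)
> 3 on either of the first two axes. This is an operational definition
tuned for technical outliers in a homogeneous cohort; on a strongly
clustered cohort it will flag small biological groups, and its output is a
list for review, not an automatic exclusion. The SVD scan mean-centers
probes, takes the top min(6, n−1) components and tests each against each
covariate (Kruskal–Wallis for categorical, Spearman for numeric),
reporting p-values with a significance mask at 0.01; constant covariates
are dropped with a warning.

## Embedding, clustering, validity

t-SNE follows the PCA-initialization protocol: PCA to 20 components, the
first two axes rescaled to sd 1e-4 as the initialization, Barnes–Hut
approximation with θ = 0.5, perplexity 15 (an error is raised when
perplexity ≥ (n−1)/3). The early-exaggeration iteration count (200) is
recorded in the embedding's hyperparameters; the scikit-learn backend
fixes the length of its exploration phase internally, so this parameter is
provenance rather than a control. HDBSCAN runs with
min_samples = min_cluster_size (= 4) and single-cluster selection
allowed; noise is relabeled 0 and clusters are renumbered 1..K by
decreasing size (cluster ids are a convention of this package, not
reproducible identifiers).

DBCV is implemented from its published definition: all-points core
distance with exponent d (= 2 here), mutual-reachability distances,
density sparseness = the largest internal edge of the in-cluster MST
(internal nodes have degree > 1), density separation = the minimum
mutual-reachability distance between internal nodes of different
clusters, validity V(C) = (sep − sparseness)/max(sep, sparseness), and
the overall index the size-weighted average with noise contributing
weight but zero validity. Clusters of identical points are handled by an
epsilon distance floor (1e-10) with a warning. For a lone cluster (no
other cluster to separate from) separation falls back to the diameter of
the full point set, so a single tight cluster still scores high; this
case is outside the published definition and is a documented choice.
Clusters with index > 0.25 are reported valid.

## CNV

The per-probe statistic regresses the sample's log2 total intensity on
the controls' mean log2 intensity (one regressor plus intercept — a
documented simplification of reference tools that fit combinations of
controls; validated on synthetic data) and median-centers the residuals,
making the profile invariant to global scaling of the sample. Zero-total
probes are excluded from the fit and imputed at the median. Binning is
greedy left-to-right per chromosome, closing a bin when both minima
(50 kb span, 15 probes) are met, merging the trailing remainder into the
last bin; undersized chromosomes yield one flagged bin excluded from
correlations. The bin statistic is the unshrunk mean of member probes.
Similarity is Pearson by default (Spearman available); tertile boundaries
are type-7 quantiles at 1/3 and 2/3 of the evaluated pairs' correlations,
with boundary ties going to the lower category, so categories partition
the pairs into sizes differing by ≤ 1. Alteration burden counts maximal
runs of consecutive bins with |log2R| strictly > 0.1 — runs, not bins,
and sign-agnostic within a run, following the region-count definition.
Group burdens are compared by the exact two-sided Wilcoxon rank-sum test
(the choice of test is this package's; all-tied groups return p = 1).

## DMRs

Per-CpG moderated t: pooled two-sample variance shrunk toward the global
mean variance with d0 = 4 pseudo-observations (d0 = 0 recovers the
ordinary pooled t exactly); p from t with df + d0 degrees of freedom.
Squared statistics are smoothed along each chromosome with a Gaussian
kernel of σ = λ/2 truncated at 3σ; under the null each t² is treated as
approximately χ²₁, so the smoothed statistic is referred to a
Satterthwaite scaled chi-square (c = Σw²/Σw, ν = (Σw)²/Σw²). This is an
architectural reimplementation of kernel-smoothed region calling, not a
port of any tool; its acceptance is planted-signal recovery. After BH
correction, significant CpGs (q < 0.05) group into regions split at gaps
> λ; regions keep min/max member positions as boundaries and need ≥ 7
significant CpGs. Δβ is computed on normalized beta (statistics are on
M-values) as the double average — over region probes, then test samples —
of the difference from the reference-group mean; it is exactly
antisymmetric under swapping the groups. Gene-level analyses default to
promoter-restricted DMRs (≥ 1 CpG in TSS200/TSS1500/1stExon; a flag
disables this, since the choice is ambiguous in practice), with
hypo/hyper sets at Δβ strictly beyond ∓0.10.

A note on operating characteristics: with a strong signal, kernel bleed
makes CpGs within ~2σ of a planted block significant; on island geometry
the > λ gap rule confines regions to the island, which is why recovery is
tested on island manifests (boundaries within ±2 CpGs in ≥ 18/20 seeds;
a 5-CpG island is never called; null runs average ≤ 2 spurious regions,
empirically ~0.1).

## Enrichment

The gene-level bias is the number of array CpGs annotated to the gene.
Each term's odds weight is the mean bias of its in-universe genes over
the mean bias of the rest; the p-value is the upper tail of the Wallenius
noncentral hypergeometric distribution (scipy's implementation) with that
odds, BH-corrected across terms. With uniform bias this reduces to the
central hypergeometric — the same tail Fisher ORA uses — to < 1e-6, and
with block-homogeneous bias it is the exact law of bias-weighted sampling
without replacement, which the tests verify against a 10,000-draw
permutation oracle. Redundancy reduction is greedy by ascending p (ties
by term id), dropping a term whose member-gene Jaccard similarity with an
already-kept term exceeds 0.3; this is a set-overlap surrogate for
ontology-graph semantic similarity, which is out of scope. The
multi-contrast intersection reports the genes common to all
hypomethylated lists plus a Venn-style membership table.

## Fidelity

Class scores are softmax-calibrated centroid correlations:
score_c ∝ exp(k·r_c) with sharpness k = 10, where r_c is the Pearson
correlation between the sample and the class-c centroid over an
informative probe subset (the pipeline uses the top-1000 most variable
probes across tumors; whole-array correlations are dominated by the
shared bimodal baseline and are uninformative). This is a transparent
surrogate for an externally trained classifier — raw-vs-calibrated score
distinctions are out of scope, and externally produced score tables can
be substituted. Categories: faithful at score ≥ 0.84, useful in
[0.3, 0.84), unfaithful below 0.3 — the published interval notation is
open at both ends, so the boundary convention (0.84 → faithful,
0.3 → useful) is this package's documented choice. DNAm status is
*maintained* only when the assigned class equals the histology label and
the category is not unfaithful. The six-condition code is the bijection
{(maintained, coincident): 1, (maintained, similar): 2,
(maintained, different): 3, (unfaithful, coincident): 4,
(unfaithful, similar): 5, (unfaithful, different): 6}.

The two-sided Fisher test uses the minimum-likelihood method (sum of
hypergeometric probabilities ≤ the observed table's) — results near small
printed p-values can differ from the doubling method, which is why the
choice is pinned here — and is verified against full-support enumeration
for every 2×2 table with N ≤ 30. The chi-square test is Pearson's without
continuity correction (Yates available by flag for 2×2). Stratified
reports give counts, whole-number percentages and condition distributions
per culture-metadata stratum, with Fisher (2×2) or chi-square otherwise
on faithful+useful vs unfaithful.

## Problem sizes and defaults

The default synthetic cohort is 8000 probes over four 10–20 Mb
chromosomes and 55 samples: 5 classes × 5 tumors (one class is the
attractor/control class and contributes no cultures), 24 paired cultures
(4 histologies × 6 conditions), 6 copy-neutral controls. These sizes keep
every planted signal estimable (≥ 2 samples per contrast group, ~500
bins, ~30 probes per signature) while a full pipeline run completes in
well under a minute; they are scaled-down study conditions, not tuning
knobs, and the acceptance script runs them unchanged.

## Known limitations

* The centroid surrogate is not a trained classifier; absolute score
  calibration differs from any external tool, only the downstream
  thresholds and taxonomy are shared.
* The CNV baseline is a one-regressor fit; shrinkage and multi-control
  combination fits are not implemented.
* DBCV for a single cluster uses a documented fallback separation.
* The MDS outlier rule over-flags on strongly clustered cohorts (see
  above).
* GO-graph semantics, KEGG topology, segmentation (CBS/HMM), focal
  amplification calling and sex-chromosome CNV are out of scope.
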