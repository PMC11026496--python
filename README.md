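# methfidelity

How faithful is a tumor-derived cell culture to the tumor it came from?
Methylation arrays answer this question twice over: the genome-wide DNA
methylation (DNAm) profile places a sample into a methylation class with a
calibrated score, and the combined probe intensities carry a copy-number
(CNV) profile. `methfidelity` implements that assessment as a reusable,
tested pipeline for Infinium-style array data — aimed at labs that bank
patient-derived brain-tumor cultures (gliomas, medulloblastoma, ependymoma)
and need to know, before running experiments, whether a culture still
represents its parental tumor.

## What it computes

Starting from per-probe methylated/unmethylated channel intensities
(M, U), detection p-values and bead counts:

1. **Preprocessing** — probe QC (detection p > 0.01; < 3 beads in ≥ 5% of
   samples; SNP/cross-reactive blacklist; X/Y probes), beta values
   β = M/(M+U+100), M-values log2(β/(1−β)), and BMIQ normalization
   (3-state beta-mixture EM per sample; type II probes quantile-mapped onto
   the type I scale, the hemimethylated state by dilation interpolation).
   Cohort QC: MDS outlier screen on the top-1000 most variable probes, and
   an SVD scan associating principal components with sample covariates.
2. **Embedding and clustering** — 20-component PCA-initialized Barnes–Hut
   t-SNE (perplexity 15, θ = 0.5), HDBSCAN with minimum cluster size 4
   (noise = cluster 0), and the density-based clustering validation (DBCV)
   index; clusters with DBCV > 0.25 are treated as valid.
3. **CNV** — per-probe log2R: the sample's log total intensity regressed on
   the mean of copy-neutral controls, residuals median-centered; genomic
   bins of ≥ 50 kb and ≥ 15 probes; cell-vs-tissue Pearson correlation of
   binned profiles, categorized by cohort tertiles
   (*different* / *similar* / *coincident*); alteration burden = number of
   runs of bins with |log2R| > 0.1.
4. **DMRs** — moderated t statistics on M-values, Gaussian-kernel smoothing
   along the genome (σ = λ/2, λ = 1000 bp) with Satterthwaite chi-square
   p-values, BH-FDR < 0.05, regions split at gaps > 1000 bp with ≥ 7 CpGs;
   per-region Δβ (double average of the test-vs-reference beta difference);
   promoter restriction (TSS200/TSS1500/1stExon); hypo/hyper split at
   |Δβ| > 0.10.
5. **Enrichment** — Wallenius noncentral hypergeometric test with per-gene
   CpG-count bias (odds = mean bias of term genes / mean bias of non-term
   genes), Fisher ORA, greedy Jaccard redundancy reduction, and the
   multi-contrast intersection of hypomethylated gene lists.
6. **Fidelity** — class scores (softmax-calibrated centroid correlations, a
   surrogate for an external classifier; external score tables can be
   supplied), categories *faithful* (score ≥ 0.84), *useful* (0.3–0.84),
   *unfaithful* (< 0.3); DNAm status (*maintained* = right class, usable
   score) crossed with CNV similarity gives the six-condition taxonomy
   (1 = maintained/coincident … 6 = unfaithful/different).

Because real cohorts of this kind are not redistributable, the package
ships a first-class synthetic cohort generator (`methfidelity.synthetic`)
with known ground truth: bimodal per-probe betas, class signatures, paired
cultures that drift toward an attractor class, planted DMRs and CNV
segments, copy-neutral controls, and planted QC failures.

## Worked example

```python
from methfidelity import pipeline

summary = pipeline.run_all("run", seed=1)
print(summary)
```

prints (seed 1, default 8000-probe / 55-sample cohort, 24 tumor–culture
pairs):

```
{'n_probes_retained': 7914, 'n_clusters': 6, 'n_valid_clusters': 6,
 'similarity_categories': {'coincident': 8, 'similar': 8, 'different': 8},
 'n_dmr_contrasts': 5,
 'conditions': {1: 4, 2: 4, 3: 4, 4: 4, 5: 4, 6: 4}}
```

Reading this: 7914 of 8000 probes survive QC; the t-SNE/HDBSCAN step finds
6 clusters, all DBCV-valid (tumor classes, the divergent-culture cluster,
controls); the 24 pairs split 8/8/8 across the CNV tertiles; 5 DMR
contrasts ran (the pooled divergent-vs-rest contrast plus one per
histology); and each of the six designed fidelity conditions is assigned
to exactly its 4 designed pairs. Per-stage tables (embedding coordinates,
bins, similarity calls, DMRs with Δβ, enrichment, fidelity records) are
written under `run/` as TSV/JSON. The same stages are available from the
shell:

```bash
methfidelity run-all --seed 1 --outdir run
methfidelity simulate --config config.yaml --seed 1 --outdir run
```

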