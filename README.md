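# mimqtl

Discovery and annotation of **miRNA–methylation Quantitative Trait Loci
(mimQTLs)** — miRNA–CpG pairs whose expression and DNA methylation are
consistently rank-correlated across two independent tumor cohorts — together
with sign-matrix clustering, microenvironment and genomic-context annotation,
and a per-tumor **Global Methylation Alteration (GMA)** score.

## The analysis

Given matched miRNA expression (log2) and CpG methylation (beta values in
[0, 1]) matrices for two cohorts:

1. **Preprocessing.** CpGs with > 50% missing values are removed, the rest
   imputed by k-nearest-neighbour rows (k = 10); CpGs are kept if their
   interquartile range exceeds 0.1 and miRNAs if detected in more than 10% of
   samples; feature spaces are intersected across cohorts.
2. **Screening.** Every miRNA–CpG pair is tested with Spearman's rank
   correlation (midranks; two-sided p from
   t = ρ·√((n−2)/(1−ρ²)) on n−2 df). Within each cohort, p-values are
   Bonferroni-adjusted over the m pairs tested.
3. **mimQTL calling.** A pair is a mimQTL iff p_adj < 0.05 in *both* cohorts
   with the same correlation sign. Each pair is flagged *in cis* (same
   chromosome, no distance cap) or *in trans*.
4. **Clustering.** mimQTLs are binarized into a CpG × miRNA sign matrix over
   {−1, 0, +1} and both axes are clustered hierarchically with correlation
   distance (1 − Pearson) and average linkage (UPGMA); trees are cut into 3
   miRNA and 2 CpG clusters by default.
5. **Annotation.** Each miRNA cluster is tested for enrichment of positive or
   negative correlations with lymphocyte infiltration, fibroblast
   infiltration and ESR1 expression (exact hypergeometric tails against the
   full miRNA background), and each miRNA is modelled as
   `expression ~ lymphocyte + fibroblast + ESR1` by OLS with 95% Wald
   intervals. CpG clusters are placed in genomic context: interval-set
   overlap (super-enhancers, TFBS with ±100 bp extension, chromatin states)
   with hypergeometric/Fisher enrichment, and chromatin-loop co-membership of
   cis pairs (CpG in one loop foot, miRNA precursor in the other) with a
   hypergeometric test against all same-chromosome background pairs.
6. **GMA score.** With per-CpG medians of a normal-tissue panel as reference,

   GMA_i = Σ_j | beta_{j,i} − median_j(normals) |

   summed over evaluated CpGs, and each miRNA cluster is tested for
   enrichment of positive/negative correlations between member expression
   and the GMA score.

Because real tumor cohorts are controlled-access, the package ships a
first-class synthetic-cohort generator: two cohorts share three latent
per-sample factors (lymphocyte infiltration L, fibroblast infiltration F, ER
signaling E) that drive planted miRNA clusters A/B/C and CpG clusters 1/2,
plus normal-tissue methylation, genomic coordinates, interval sets and loops
carrying planted enrichments, and a ground-truth ledger for recovery tests.
See `docs/methods.md` for the generative model and all defaults.

## Worked example

```bash
mimqtl run --seed 1 --outdir out/
```

runs the default-scale synthetic study (cohorts of 300 and 440 samples, 346
miRNAs, 2,000 CpGs) end to end and prints:

```
mimQTL run (seed 1)
========================================
total mimQTLs: 28362
unique miRNAs: 119; unique CpGs: 560
sign: 87.86% negative (88% rounded), 12.14% positive
cohort1: 28363 / 618994 significant (4.5821%, rounded 4.58%)
cohort2: 28408 / 618994 significant (4.5894%, rounded 4.59%)
cluster A: 9971 pairs (35.16%, rounded 35%)
cluster B: 11100 pairs (39.14%, rounded 39%)
cluster C: 7291 pairs (25.71%, rounded 26%)
in cis: 5683 (20.04%, rounded 20.0%)
```

Reading this: 28,362 miRNA–CpG pairs were significant with concordant sign
in both cohorts, involving 119 miRNAs and 560 CpGs; most correlations are
negative (low methylation with high expression); the three miRNA clusters
partition the pairs, and a fifth of pairs lie on the same chromosome. The
run directory holds every stage artifact (filtered matrices, the mimQTL
table, sign matrix, cluster assignments, GMA scores, `manifest.json` and
`report.txt`); against the generator's ledger this run recovers 99.8% of
planted pairs and both cluster assignments exactly (adjusted Rand index 1.0,
reported under `truth_recovery` in the manifest).

The same stages are available individually (`mimqtl simulate | preprocess |
discover | cluster | annotate | context | gma | report`), and everything is
importable as a library (`mimqtl.spearman_screen`, `mimqtl.call_mimqtls`,
`mimqtl.gma.gma_scores`, ...).

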