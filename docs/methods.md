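# Methods

## Statistical model and procedure

### Screening and calling

Associations are screened with Spearman's rank correlation, computed as the
Pearson correlation of midranks so that ties are handled by average ranks.
Two-sided p-values use the t approximation `t = rho * sqrt((n-2)/(1-rho^2))`
on `n − 2` degrees of freedom — the same approximation R's `cor.test` falls
back to in the presence of ties; a unit test checks it against the exact
permutation distribution at n = 8 (agreement within 0.02). An exact
permutation p-value is deliberately not used at genome scale.

Multiplicity is controlled per cohort by Bonferroni over the test family
m = the number of pairs actually tested in that cohort — pairs with
defined correlation (no zero-variance feature) and at least 8 pairwise
complete samples. The family size is logged explicitly because, with
filters applied per cohort before intersection, it is a run-dependent
quantity. A pair is a mimQTL iff `p_adj < alpha` (strictly) in both cohorts
and the two correlation coefficients share a sign. Both thresholds
(IQR > 0.1, detected fraction > 10%) are strict inequalities.

Cis/trans is chromosome identity only, with no distance cap; features
without coordinates are flagged `unknown` and excluded from cis summaries.

### Sign-matrix clustering

mimQTLs are encoded in a CpG × miRNA matrix over {−1, 0, +1} (0 = not
significant; only features with ≥ 1 nonzero entry enter). Both axes are
clustered with correlation distance `d = 1 − Pearson` (computed on the full
sign vectors, zeros included) and average linkage (UPGMA, via
`scipy.cluster.hierarchy`). The correlation flavour is Pearson — the common
heatmap default. Constant rows have undefined correlation and are assigned
distance 1 to every other row (logged). The correlation distance is a
dissimilarity, not a metric (triangle inequality can fail); this is
documented, not asserted. Trees are cut into exactly k clusters (defaults:
3 miRNA, 2 CpG; k is a config parameter — automated model selection is out
of scope) and aliased by decreasing size: A/B/C for miRNAs, 1/2 for CpGs.
Because size ranking is arbitrary relative to any planted identity,
recovery metrics first match discovered aliases to planted labels by
majority overlap.

### Enrichment statistics

Cluster-versus-covariate enrichment uses exact hypergeometric tails:
members n drawn from background N with K flagged, observed x, reporting
`P[X ≥ x]` (over) and `P[X ≤ x]` (under) plus fold = (x/n)/(K/N). The
flagging rule for "positively correlated" is `rho > 0 and p < 0.05`
(configurable); the source analyses leave this rule implicit, so it is
logged prominently. Region-set enrichment builds the 2×2 in-cluster ×
in-region table and reports both the hypergeometric upper tail and Fisher's
exact two-sided p; batch results are BH-adjusted. Loop enrichment counts a
pair once regardless of how many loops link it, against the background of
all same-chromosome miRNA–CpG pairs of the annotated universe.

Group comparisons: Wilcoxon rank-sum for two groups (exact enumeration when
both n ≤ 10 and no ties, else normal approximation with continuity
correction; the branch taken is logged), Kruskal–Wallis for three or more,
BH correction for batches.

The per-miRNA microenvironment model is a Gaussian identity-link GLM
(ordinary least squares) of expression on lymphocyte score, fibroblast
score and ESR1 expression, with Wald t p-values and 95% confidence
intervals `estimate ± t_{0.975, n−4} · SE`. Predictors are not standardized
by default. GLMs are fitted per cohort and reported side by side rather
than pooled.

### GMA score

`GMA_i = Σ_j |beta_{j,i} − median_j(normals)|` over CpGs non-missing in
both the tumor and the reference (the per-CpG median of ≥ 2 normal
samples). The sum is unnormalized by design; `n_cpgs_used` is reported per
tumor and an optional mean-normalized variant is available for unequal
missingness. The default scoring universe is the post-filter CpG
intersection ("processed data"); scoring over all shared CpGs is a switch.

## Preprocessing conventions

Order of operations: remove CpGs with > 50% missing → kNN imputation →
IQR filter → detection filter → cross-cohort intersection. Whether IQR is
computed before or after imputation is not fixed by the source material;
here it is after (imputation precedes every downstream statistic).
Quantiles use linear interpolation (R type 7 / numpy default) — borderline
rows near the 0.1 cutoff are quantile-method-sensitive, so the method is
fixed and logged. Imputation replaces each missing cell with the mean of
the k = 10 nearest feature rows (RMS distance over shared non-missing
columns) observed at that sample, falling back to the row mean when fewer
than k usable neighbours exist. The detection floor is the cohort's common
minimum value when it carries ≥ 5% of the probability mass (the
floored-array convention), can be supplied explicitly, and defaults to
"everything detected" when no mass point exists.

## Synthetic study design

The generator emulates the *statistical assumptions* of the analysis, not
array physics. Per sample, three latent factors: L, F ~ N(0, 1)
(lymphocyte, fibroblast) and ER signaling `E = 2.0·1[ER+] + N(0, 0.6²)`,
with P(ER+) = 0.75. E is deliberately asymmetric — near zero in
ER-negative tumors, shifted up in ER-positive ones — so that ER-positive
tumors deviate more from normal methylation and the GMA score is positively
coupled to E with a signed statistic, and so both ER-status group tests and
ESR1-correlation analyses are exercised. Observed covariates (infiltration
scores, ESR1 expression) are the factors plus N(0, 0.3²) noise.

Expression: `x = mu + B·(L,F,E) + N(0, 0.8²)` on the log2 scale with
mu ~ U(2, 10); values below the 5% matrix quantile are set to that common
floor. Methylation: `beta = invlogit(b + G·(L,F,E) + N(0, 0.6²))` with
baselines b ~ U(−2, 2) (planted CpGs U(−1, 1)); the logit link keeps betas
in (0, 1) with realistic boundary compression and, being monotone,
preserves every rank correlation. Normals are `invlogit(b + N(0, 0.15²))`
with no factor loadings. Cohort 2 shares all loadings but has independent
samples and noise, and its expression gets a global affine perturbation
(×1.25 + 0.3) to verify that results rest on ranks.

Planted structure (defaults: cohorts of 300/440 samples, 346 miRNAs of
which clusters A/B/C have 23/59/37 members, 2,000 CpGs of which clusters
1/2 have 300/260; all loading magnitudes ~ U(0.85, 1.15)):

* miRNA cluster A loads +L, B loads +F, C loads +E;
* CpG cluster 1 loads −E, and half of it additionally +L — those shared
  CpGs correlate negatively with cluster C and positively with cluster A,
  reproducing the shared-CpG, opposite-sign overlap between the ER and
  immune axes;
* CpG cluster 2 loads negatively on the microenvironment axes, split into
  L-only (35%), F-only (35%) and L+F (30%) subgroups. The mixed subgroup
  makes the cluster cohere at a 2-cut while clusters A and B keep distinct
  CpG repertoires — with a single homogeneous block, cluster-B sign
  profiles would be affine copies of cluster-A profiles and no correlation
  metric could separate the two, defeating the generator's purpose as a
  recovery benchmark.

Every planted pair shares exactly one factor, so its expected sign is the
product of the two loading signs; at the defaults the population rank
correlations of planted pairs are ≈ 0.5–0.7, comfortably above the
dual-cohort Bonferroni detection threshold (|rho| ≈ 0.25–0.30 at these
sample sizes), which is what makes ≥ 90% planted-pair sensitivity a fair
expectation at n ≥ 300 but *not* at substantially smaller n (the reduced
fixtures used for fast wiring tests assert looser bounds for exactly this
reason).

Annotations place features uniformly over 5 chromosomes of 10 Mb, so ~20%
of planted pairs are cis by construction. 40% of cluster-1 CpGs (vs 10% of
others) sit inside the "SE" and "TFBS" interval sets; 30% of planted cis
pairs get a loop with one foot over the CpG (±1 kb) and one over the
precursor, plus 50 decoy loops; loop pairs whose feet would overlap are
skipped rather than shifted.

What the generator does **not** emulate: probe-type and color-channel
bias, batch effects, copy-number or genotype structure, spatially
correlated methylation, realistic miRNA count distributions, or
missing-at-random patterns (matrices are complete by default; missingness
paths are exercised with explicit fixtures). Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
stated model, not robustness to array artefacts.

## Numerical choices

* Bonferroni: `p_adj = min(1, p·m)`; `|rho| = 1` maps to p = 0 exactly.
* The vectorized screen requires complete matrices; inputs with missing
  values take a pairwise-complete per-pair path intended for small inputs
  (the pipeline imputes first).
* Distances: correlation distance clipped to [0, 2]; UPGMA merge order on
  ≤ 7 points is verified against exhaustive brute force.
* Tie-breaks: cluster aliasing breaks size ties by first appearance;
  `p_adj < alpha` is strict, so no tie-break is needed at the threshold.
* Degenerate inputs raise rather than guess: empty feature intersection,
  empty mimQTL table, constant covariate, rank-deficient GLM design,
  single-row distance matrix, < 2 normals.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; normals and annotations use derived seed
  streams so each artifact is reproducible independently.

## Problem sizes used in the shipped checks

Recovery checks run the full default-scale study (300/440 samples,
346 miRNAs, 2,000 CpGs) over several seeds; null-calibration checks use
200 replicates of a reduced all-null study (60/60 samples, 25 miRNAs,
60 CpGs) — the family-wise error guarantee of Bonferroni is
scale-invariant, so the reduced size is a choice of economy, not of
necessity. Oracle-equivalence checks use ≤ 20-feature instances where
exhaustive enumeration is feasible.

## Known limitations

* The asymptotic Spearman p-value is anti-conservative for very small n;
  the screen excludes pairs with n < 8 and the package is intended for
  cohort-scale n.
* k in the tree cut is user-chosen; the dendrogram inspection that guided
  the original choice is not automated.
* Loop "found in a foot" uses any-overlap (≥ 1 bp) for the precursor by
  default; a strict-containment switch exists. Containment semantics for
  long precursors spanning a foot boundary are convention, not fact.
* Genome builds are the caller's responsibility; coordinates must arrive
  on one build (chromosome names are normalized, positions are not lifted).
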