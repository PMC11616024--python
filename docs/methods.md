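# Methods

## Problem and model

`methylmark` implements a discovery-and-evaluation pipeline for
tissue-specific DNA-methylation diagnostic markers, with colon cancer as the
target tissue. The data object is a beta-value matrix: CpG sites in rows,
samples in columns, each entry β = M/(M+U) ∈ [0, 1] from a methylation
array, with "NA" for missing entries. Markers are discovered by a
three-stage cascade and then validated as features of a logistic diagnostic
classifier.

### Selection cascade

1. **Hypermethylation screen.** Within the candidate genes (an
   `eligible_gene` flag in the site annotation — candidate-gene derivation
   is upstream of this package), each site is compared between the tumor and
   normal samples of a paired colon training cohort with a two-sided
   Wilcoxon rank-sum test. A site is called hypermethylated when its
   Benjamini–Hochberg q ≤ `q_max` (default 0.05) **and** its mean
   difference Δβ = mean(tumor) − mean(normal) ≥ `delta_min` (default 0.2).
   The q-and-Δβ rule is this package's screening criterion; both thresholds
   are exposed in `CascadeParams`.
2. **Normal-background filter.** A surviving site is removed if its mean β
   is *higher than* `tau_bg` (default 0.1, strict inequality; a mean of
   exactly 0.1 is retained) in **any** reference cohort: the training
   normals, every normal-tissue cohort, and every blood cohort. Sites
   already methylated in healthy tissue or blood cannot give a specific
   blood- or tissue-based test.
3. **Pan-cancer specificity filter.** A site is removed if its mean β
   exceeds `tau_spec` (default 0.1) in the tumor samples of **any** other
   (non-colorectal) cancer type. Only other-type *tumor* samples
   participate; the rule is deliberately symmetric with stage 2 and
   distribution-free of the other types' normals.

Every stage records (n_in, n_removed, survivors); the invariants
n_in − n_removed = n_out and survivor nesting are asserted on every run.

### Rank-sum engine

When the smaller group has ≤ 10 samples the two-sided p-value is exact: ties
receive midranks, the midranks are doubled to integers, and the full
permutation distribution of the group rank-sum over all C(n, n₁) equally
likely assignments is built by a count-polynomial dynamic program (identical
to literal enumeration, which is the test oracle, but tractable when the
other group is large). Two-sided means P(|W − E W| ≥ |w_obs − E W|). For
larger groups a normal approximation with midranks, tie-corrected variance
and a 0.5 continuity correction is used; at the 10/12 boundary the two
routes agree to ~0.01.

### Diagnostic model

Logistic regression on the selected markers' β values (an M-value option,
log2(β/(1−β)) with β clipped to [0.01, 0.99], is provided since the feature
scale is a free choice). The fit maximizes the Bernoulli log-likelihood
minus (λ/2)‖coef‖² — the intercept is unpenalized — by Newton/IRLS with
step halving, so the penalized objective is non-increasing at every step;
convergence when the largest parameter change is below 1e-8, capped at 200
iterations. The ridge default λ = 1e-3 exists because well-separated
markers make the classes linearly separable, where the unpenalized MLE
diverges (an unpenalized fit on separable data raises an error advising
λ > 0). Missing marker values are imputed with training-cohort means, which
are stored in the serialized model. Discrimination is the Mann–Whitney AUC
(ties credited 0.5), equal to the probability that a random tumor sample
outranks a random normal sample; class calls for sensitivity/specificity
and misclassification profiling use a fixed p ≥ 0.5 threshold
(configurable).

### Specificity evaluation

For each non-colorectal cancer type (reference labels NORMAL_TISSUE and
BLOOD, and the colorectal labels COAD/READ, are excluded — READ is treated
as a transfer target, not an "other" tumor), `misclassification_profile`
reports the percentage of in-scope samples (tumor, normal, or both) the
model calls colon cancer, plus the (min, max, median) over types; a type
with zero in-scope samples is reported with n = 0 and excluded from the
summary. `compare_marker_sets` fits one model per named marker set under
identical training and reports per-cohort AUC plus tumor- and normal-scope
profiles side by side. Published comparison panels are configuration inputs
(id lists), never embedded.

### Descriptive statistics

* **Neighbor co-methylation:** Pearson r (Spearman optional) between each
  anchor and every annotated site within 2000 bp on the same chromosome,
  boundary inclusive (|Δpos| ≤ window; "within" is read inclusively),
  over samples complete in both sites; fewer than 3 complete pairs → NA.
* **Cluster separation:** average-linkage agglomerative clustering
  (Euclidean distance on the selected sites' β values, per-site mean
  imputation), tree cut at k = 2, scored as the adjusted Rand index against
  tumor/normal labels. Average linkage + Euclidean is the common heatmap
  convention; the claim being checked is a two-group separation, hence
  k = 2.
* **Subgroup tests:** per-site rank-sum (same engine as the screen) between
  any two disjoint sample selections (CIMP-H vs CIMP-L tumors; stage-I
  tumors vs normals), BH-corrected across the tested sites.

## Synthetic studies

Real inputs for this design are multi-cohort array compendia that cannot be
bundled; `synthetic_data` generates studies with the same structure and
known ground truth, and is itself a tested, first-class module.

**Layout.** Defaults mirror the study design the cascade targets: a paired
COAD training cohort of 38 tumor + 38 normal; five COAD validation cohorts
totaling 230 tumor / 212 normal (46/43, 46/43, 46/42, 46/42, 46/42); one
43-sample normal-tissue and one 184-sample blood reference cohort; one READ
transfer cohort (40 tumor / 20 normal — the rectal cohort's size is not
specified by the design, this is a desk-scale choice); and 28 other-tumor
cohorts (standard TCGA abbreviations), 20 tumor + 10 normal each. Total:
200 sites × 1645 samples with the default site counts below.

**Site classes and marginals.** Each site belongs to one planted class with
Beta marginals per context (colon tumor / other tumor / normal tissue /
blood). Defaults use three shapes — high Beta(6, 2) (mean 0.75), low
Beta(1, 20) (mean 0.048), background Beta(2, 6) (mean 0.25):

| class (default count) | colon tumor | other tumor | normal | blood |
|---|---|---|---|---|
| specific (3) | high | low | low | low |
| pancancer (5) | high | high | low | low |
| background (30) | high | background | background | background |
| neutral (162) | low | low | low | low |

The counts and shapes are calibration choices (no effect-size or variance
estimates exist to copy); they are set so each class exercises exactly one
cascade stage: neutral falls at the screen, background at the background
filter (mean 0.25 > 0.1 in references), pancancer at the specificity
filter, and specific survives. READ samples draw from the colon-tumor
context, so the transfer evaluation has signal. `eligible_gene` is true
for all specific/pancancer sites and a random half of the rest.

**Dependence.** Sites sit on one pseudo-chromosome at 500 bp spacing (so a
2000 bp window spans four neighbors per side); strand is ignored (β is
strand-symmetric after bisulfite aggregation). Consecutive blocks of
`block_size` = 5 sites share a standard-normal factor: z = √ρ·g_block +
√(1−ρ)·e, mapped through Φ and each site's Beta quantile function (Gaussian
copula). Latent within-block correlation is exactly ρ (default 0.7);
β-scale Pearson correlation is mildly attenuated by the non-linear quantile
maps (~0.65–0.68 observed at ρ = 0.7), which stays within the ±0.1
calibration band the tests check at n ≥ 300.

**Subgroups.** Half of colorectal tumors (deterministic interleaving) are
labeled CIMP-H and receive +0.2 β on the specific sites, clamped to [0, 1]
— a pure location shift, chosen because only the direction of the CIMP
effect is specified by the target design. Stage labels I–IV round-robin
across colorectal tumors; normals carry stage/CIMP "NA".

**What the generator does not emulate:** array chemistry (type I/II probe
bias), batch effects, copy-number confounding, missing values (tests inject
those by hand), realistic LD-like decay of co-methylation with distance
(correlation is block-constant), and biological heterogeneity of the
"other 28" types (they share one context). Passing tests therefore show the
pipeline's logic and statistics are correct under the assumed generative
structure, not that the defaults' effect sizes match any real cohort.

## Numerical and edge-case choices

* Beta values are written with fixed 6-decimal formatting; write→read→write
  is byte-identical.
* A site whose missing fraction exceeds `missing_max` (default 0.2) in
  either group is excluded from the screen with a warning; a candidate with
  zero usable values in some cohort is excluded by the filters with a
  warning.
* Exact-test tie comparison uses a 1e-9 slack when counting equally extreme
  rank sums.
* Copula quantiles are clipped to [1e-12, 1 − 1e-12] before inversion.
* ARI of a degenerate single-cluster split is 0 by chance correction; the
  2-cut of an all-identical sample set returns 0 against mixed labels.
* The AUC denominator is n_tumor × n_normal; both classes are required.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run entirely on generated data:
100 default-layout studies for marker recovery, 50 for clustering
separation, one 500+500-sample single-cohort study for moment/correlation
calibration, 1000 small random instances for AUC oracle agreement, and full
enumeration oracles up to group sizes 7. These sizes are the package's
verification defaults; all scale linearly if enlarged.

## Known limitations

* The screen criterion (rank-sum + BH + Δβ) is one reasonable DMP
  convention; count-matched alternatives (e.g. limma on M-values) are not
  implemented.
* No DMR/region-level calling; CIMP labels are inputs, not inferred.
* No cross-validation over marker subsets, no DeLong confidence intervals
  for AUC, no calibration curves.
* The specificity filter compares means only; a per-type rank-sum mode was
  considered and deliberately omitted to keep the filter independent of
  other-type normal availability.
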