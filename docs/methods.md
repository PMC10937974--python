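# Methods

## The problem

Metastatic tumors — in the extreme, cancers of unknown primary — often cannot
be assigned a tissue of origin or a histologic lineage from morphology alone.
This package implements a transcriptome-only workflow that classifies a single
tumor RNA-expression profile along two independent axes: anatomical **site of
origin** (up to 22 organ classes) and histologic **lineage** (8 classes:
adenocarcinoma, squamous cell carcinoma, sarcoma, melanoma, glioma, germ cell
tumor, lymphoid/myeloid neoplasm, neuroepithelial cancer). Because the two
models are trained independently, the lineage probability vector carries
information beyond the class call: its maximum — the **differentiation
score** — quantifies how strongly a sample resembles any single lineage
program, and degrades continuously as a tumor de-differentiates. That single
scalar supports zero-shot detection of de-differentiated disease and
survival stratification without any additional training.

## Single-sample normalization

Public expression cohorts arrive on incompatible per-sample scales (RSEM,
FPKM/RPKM, TPM, CPM, TMM, microarray intensities). Rather than batch-correct
across cohorts, every sample is normalized *alone*:

1. fit the Yeo-Johnson power parameter λ by maximizing the Gaussian profile
   log-likelihood (including the Jacobian term) of the sample's non-missing
   values, with bounded scalar optimization over λ ∈ [−5, 5] to 1e-4;
2. apply the transform (using numerically stable `expm1`/`log1p` forms, so the
   λ→0 and λ→2 branch points are continuous to machine precision);
3. z-score the transformed values within the sample.

The within-sample z-scoring step is this package's own addition: the power
transform alone leaves samples on λ-dependent scales, and putting every
sample on a common (0, 1) scale is what makes tree thresholds learned on one
platform transferable to another. Missing values are excluded from the λ fit
and the moments and propagate to the output; filling them is the predictor's
job. Gene-wise z-scored input (negative values with near-zero per-gene
means) defeats per-sample normalization and triggers a warning.

## Models

Both classifiers are XGBoost multiclass ensembles with the soft-probability
objective, depth 6, learning rate 0.3, no subsampling, and single-thread
deterministic training; the **only tuned hyperparameter is the number of
boosting rounds**, chosen by 5-fold stratified cross-validation (default grid
25–800, ties to the smaller count). The site model additionally receives a
binary sex flag (female 0, male 1, unknown → native missing-branch
handling); the lineage model sees genes only. The two models are fit from
disjoint seed streams, so any change confined to one label axis leaves the
other model's predictions bit-identical.

Training genes are filtered by completeness (no missing values) and by
median expression (the lowest ⌊10%⌋ of medians dropped; ties broken
lexicographically by gene id). Features are then ranked by total split gain,
models are retrained on top-k features over a k-grid with a frozen fold
partition, and the final k is the smallest whose mean CV accuracy falls
within the 95% Student-t confidence interval (df = 4, over the five fold
accuracies) of the best k's mean — a parsimony rule that trades a
statistically invisible accuracy loss for a much smaller model. The CI
interpretation over fold accuracies is a declared choice; a binomial CI on
pooled predictions would be the main alternative.

At prediction time genes are matched by symbol; model genes absent from the
sample become missing and are imputed by k-nearest neighbors (k = 5) against
the normalized training panel. Distance is Euclidean over the features
non-missing in the query, divided by the square root of the number used so
queries with different missingness are comparable; distance ties break by
reference sample id; the imputed value is the unweighted mean over the k
neighbors. Sex is never imputed. Class calls are the probability argmax,
with exact ties going to the alphabetically first class. Per-class feature
attributions use the ensemble's additive TreeSHAP decomposition
(attributions plus bias reproduce each sample's class margin exactly),
reduced by the median over samples.

## Derived scores and evaluation

- **Differentiation score** = max lineage probability, in (0, 1].
- **Adeno−SCC delta** = P(adenocarcinoma) − P(SCC), in [−1, 1].
- **Named lineage scores** (e.g. the sarcoma score) support zero-shot
  scoring of tumor types absent from training.
- **ROC optimal cut**: candidate thresholds at midpoints of consecutive
  distinct scores (plus ±∞); the chosen cut minimizes the Euclidean distance
  to the (sensitivity 1, specificity 1) corner, ties resolved toward higher
  specificity then lower threshold; "high" group = score ≥ threshold.

Evaluation uses overall accuracy, one-vs-all macro sensitivity/specificity
(classes absent from the truth excluded from the macro mean), the Hand-Till
multiclass M statistic (mean of all pairwise one-vs-one rank AUCs, midrank
ties), binary Mann-Whitney AUC, and accuracy stratified at a 0.99 confidence
threshold (an empty stratum reports accuracy as undefined, never 0).

Survival analysis censors administratively at 60 months (records at exactly
the horizon keep their event status; the rule is idempotent), uses the
two-group log-rank test with Kaplan-Meier medians and curves, and
univariable Cox proportional-hazards fits with Efron tie handling, reported
as HR = exp(β) with a 95% Wald interval. With the differentiation score
(scale [0, 1]) as covariate, HR < 1 means higher differentiation confers
lower hazard.

## The synthetic cohort generator

The generator is first-class, tested code: it defines the study conditions
under which every downstream claim is verified. Log-scale expression for
sample s at gene g is

    log x_gs = mu_g + site effect + lineage effect + sex effect + N(0, sd)

with baseline mu_g ~ N(2, 1) (positive, right-skewed linear-scale values
resembling normalized RNA-seq), disjoint marker blocks per site, lineage and
sex, marker effect 2.0 natural-log units, and noise sd 1.0. The standard
design fully crosses 12 sites with 4 lineages (100 samples/cell for
training, 30/cell held out, 500 genes, 6 markers per class, 5 male-only sex
genes). Platform distortions emulate heterogeneous normalization schemes:
per-sample scaling, log1p, library-size rescaling (all rank-preserving
within a sample), and gene-subset dropout producing missing values. Purity
admixture and de-differentiation are linear-scale convex mixtures, the
latter toward the **anaplastic background** — the unweighted mean of the
lineage archetype profiles, class-neutral by construction. The
normal-tissue contamination profile is the marker-free baseline, a free
design choice. Survival times are exponential with hazard
`baseline_rate * exp(beta * (1 − differentiation))` plus independent
exponential censoring.

What the generator does **not** emulate: real gene-gene correlation,
isoform structure, batch-specific chemistry, class imbalance, or realistic
class overlap. Passing tests therefore demonstrate that the machinery
recovers the structure it assumes at desk scale — not that real-data
accuracies would be reproduced.

## Problem sizes and numerical choices

Tests and the acceptance script run the standard cohort at 4,800 training /
1,440 held-out samples x 500 genes with 60 boosting rounds fixed (the CV
tuning path is exercised separately on small cohorts); the feature-curve
replication uses a scaled-down standard design (10 samples/cell, 150 genes)
over 10 seeds; survival simulations use n = 500 (effect recovery, 20–50
seeds) and n = 200 (null calibration, 200–500 seeds). Probability vectors
sum to 1 within 1e-6 (float32 softmax); normalized samples have mean 0 and
sd 1 within 1e-8; oracle comparisons (Hand-Till, kNN imputation, ROC cut)
are exact.

## Known limitations

- The differentiation score saturates near 1 for well-classified samples,
  so mild de-differentiation admixtures (α ≤ 0.5) are only weakly separable
  from unmixed samples under the standard noise level; strong admixture
  (α ≥ 0.75) separates cleanly. This mirrors the score's intended use as a
  detector of overt de-differentiation.
- Probabilities are raw softmax outputs; no calibration post-processing is
  applied.
- The per-sample λ MLE for half-negative inputs is not 0 even when the
  positive part is exactly lognormal, because the Yeo-Johnson negative
  branch is polynomial rather than logarithmic.
- No cross-sample normalization, batch diagnostics, multivariable survival
  models, or DNA-feature models.
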