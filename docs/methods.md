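# Methods

## Problem and model

High-dimensional multi-omics cancer cohorts pair tens of thousands of
molecular features (copy-number values, CpG beta values, expression levels)
with a few hundred clinically annotated samples.  This package compresses
such data into a small set of latent features (LFs) with a variational
autoencoder and uses those LFs for three downstream analyses: cancer /
subtype clustering and classification, survival subgrouping, and mapping
latent factors back to candidate biomarker features.

The generative model is the standard VAE: each sample x ∈ R^d is assumed
drawn from p_θ(x|z) with z ∈ R^p, p ≪ d, and an approximate posterior
q_φ(z|x) = N(μ(x), diag σ²(x)) is learned by an encoder.  Sampling uses the
reparameterization z = μ + σ ⊙ ε, ε ~ N(0, I).  Two objectives are
implemented:

* **ELBO** (`loss_kind="elbo"`): reconstruction (binary cross-entropy, all
  inputs being min-max normalized into [0, 1]) plus the closed-form KL
  divergence `0.5 Σ (μ² + σ² − 1 − ln σ²)` to the standard-normal prior.
* **MMD** (`loss_kind="mmd"`): reconstruction (squared error in the same
  block structure) plus the kernel maximum mean discrepancy between the
  encoded batch and a fresh prior sample, estimated by the biased
  V-statistic with a Gaussian kernel k(z, z′) = exp(−‖z−z′‖²/(2σ_k²)).
  The MMD variant avoids the over-regularization of the KL term, which can
  render latent codes uninformative.

Reconstruction is block-structured: the methylation block's term is the
per-chromosome loss averaged over the M chromosome branches; every other
omics block contributes its own term.  Cross-entropy / squared error are
summed over features and averaged over the batch — a fixed reduction
convention so loss values are comparable across runs.  The full objective is

    L_total = α (L_recon + L_reg) + β L_cl

with α = 1 by default and β = 0 (unsupervised) or β > 0, which attaches a
softmax classifier head (p → p/2 → n_classes) to the sampled z and adds its
cross-entropy.  The classifier reads the sampled z during training (a mild
regularizer) and the posterior mean μ at inference, for determinism.

## Architecture

Every omics block has its own encoder branch: input → 2048 → 1024 for CNV /
expression blocks; the methylation block is split by chromosome, each
chromosome's probes encoded into a 256-wide vector (intra-chromosome
structure), concatenated and projected to the common 1024-wide vector
(inter-chromosome structure).  Per-block vectors are concatenated and fused
to 512 units feeding the two p-wide heads (μ and log-variance;
σ = exp(0.5·logvar) guarantees positivity).  The decoder mirrors the
encoder exactly and ends in sigmoids, so reconstructions always lie in
(0, 1).  Every hidden dense block is Linear → batch-norm → ReLU.
Mono-omics inputs pass through the same 512-wide fusion layer as
multi-omics inputs, keeping the architecture uniform across omic counts.

The neural stack is implemented on a small reverse-mode automatic
differentiation engine over numpy (`autodiff.py`); gradients of the full
objective are exact, which the test suite verifies against central finite
differences at 1e−4 relative error.  Weights use fan-in scaled uniform
initialization from a seeded generator; training is Adam at learning rate
1e−3, batch size 32, default 250 epochs with optional early stopping
(patience 20 on total loss).  Identical seeds give bit-identical training
histories.

Key tunables: `latent_dim` p (typical sizes are 32/64/128; any positive
p < d is accepted), `alpha`/`beta` loss weights, `mmd_kernel_bandwidth`
(default σ_k = √(p/2), with a median-heuristic `"auto"` option; the prior
batch matches the data batch size and is redrawn every step).

## Preprocessing

Xena-dialect genomicMatrix TSVs (features in rows) are transposed to the
samples × features orientation internally.  The pipeline order is fixed:

1. **Intersect** blocks to the samples present in every block, sorted
   lexicographically for determinism.
2. **Clean**: drop features that are entirely missing or identically zero.
3. **Min-max normalize** per feature into [0, 1]; constant features map to
   0 rather than NaN.  Parameters are stored for the inverse transform.
   Normalization is computed once on the full matrix before any modeling
   split — the preprocessing stage precedes any modeling split in this
   workflow, with the usual caveat that downstream cross-validation metrics
   inherit a small optimistic bias from the shared scaling.
4. **Concatenate** normalized blocks into the integrated samples × D matrix
   with per-column provenance, so the matrix can be split back bit-exactly.

Binary class imbalance is addressed with Borderline-SMOTE-SVM: an RBF
support-vector classifier locates the borderline region, minority-class
support vectors act as seeds, and synthetic samples are uniform linear
interpolations between a seed and one of its k = 5 nearest minority
neighbors.  Interpolation-only synthesis keeps every synthetic point on a
segment between two original minority points, a property the tests check
directly.  The target minority count is explicit (count or final-share
ratio) rather than inherited from library defaults.

## Downstream evaluation

*Embeddings*: the first k = 2 or 3 LFs verbatim (any k would do; the first
are a deterministic choice), PCA / t-SNE baselines on raw features, and
t-SNE on the full LF matrix.  t-SNE perplexity defaults to 30, clipped to
(n−1)/3 for small cohorts.  Cluster purity runs seeded k-means (10
restarts) and matches clusters to labels by the Hungarian assignment, so
the score is invariant to cluster relabeling and rigid rotations.

*Classification*: stratified seeded 5-fold CV.  The ANN classifier mirrors
the supervised head (input → half-width hidden → softmax), trained with
Adam 1e−3 for up to 500 epochs with patience-50 early stopping on strict
training-loss improvement — 200 epochs at this learning rate demonstrably
under-converges on small LF inputs.  The SVM comparison classifier is a
grid-tuned RBF SVC.  Metrics are accuracy (%), macro precision / recall /
f1 (macro for robustness to class imbalance), and the confusion matrix
summed over held-out folds.

*Survival*: (i) one Cox proportional-hazards fit (lifelines, Efron ties)
per LF; LFs with likelihood-ratio p < 0.05 — equivalent to the score /
log-rank test for a single covariate — are the clinically relevant LFs
(CRLFs).  The 128 per-LF tests are deliberately not multiplicity-corrected,
matching the screening character of the step; a Benjamini–Hochberg option
exists but is off by default.  If fewer than 2 CRLFs survive, clustering
falls back to all LFs with a warning.  (ii) K is chosen by majority vote
over five internal validity indices (silhouette, Calinski–Harabasz,
Davies–Bouldin, Dunn, gap statistic) on seeded k-means fits over K = 2..6,
ties broken toward smaller K; subgroups are inferred by seeded k-means and
renumbered by decreasing size.  (iii) A stratified 60/40 split; an RBF SVM
grid-tuned by 5-fold CV on the training part predicts subgroup labels for
the held-out samples.  Multivariate Cox models (clinical = age + stage +
grade; combined = clinical + subgroup) are compared by Harrell's C-index
(risk ties 0.5), the IPCW Brier score (censoring distribution by
Kaplan–Meier, evaluated on a decile grid of observed test times up to the
last event, trapezoid-integrated), and the Kaplan–Meier log-rank test
between predicted subgroups.  Stage and grade enter as ordinal integers.

*Biomarkers*: each (CRLF, feature) pair gets a univariate OLS fit on
standardized variables — the standardized slope is the Pearson correlation
— with the slope-test p-value.  Features with |r| ≥ 0.3 and p < 0.05 for at
least one CRLF are retained (the 0.3 default reflects that the observed
±0.5 ceiling of the linear mapping describes its range, not a filter;
both thresholds are configurable), then ordered by average-linkage
hierarchical clustering for the signed, zero-centered heatmap.

## Synthetic data

The generator plants known structure so every stage is testable without
downloads.  Each sample carries a true latent vector in R^q (default
q = 8); class means sit at scaled simplex vertices with a configurable
pairwise separation; per-sample noise is standard normal.  Every block is a
linear factor model (loadings drawn once per seed, scaled by 1/√q) plus
Gaussian noise; methylation additionally passes through a logistic link
into (0, 1) and assigns probes to contiguous chromosome chunks; CNV /
expression blocks stay unbounded to exercise min-max normalization.
Survival times follow a Weibull proportional-hazards model (default scale
1500 days, shape 1.2 — a realistic advanced-cancer scale) with linear
predictor `true_latents · hazard_coefficients`; independent exponential
censoring is calibrated by bisection on the drawn sample to a requested
rate.  Age is truncated normal (60 ± 10, clipped to 30–90); stage and
grade are ordinal draws weighted toward late stage / high grade, matching
an advanced-disease cohort; both are independent of risk unless the
confounding flag is set.

The generator emulates the statistical shape of the data — bounded beta
values grouped by chromosome, unbounded continuous blocks, class imbalance,
censored proportional-hazards outcomes — but deliberately not real-data
marginals, batch effects, platform artifacts or non-linear
feature–latent maps.  Passing tests therefore demonstrate that the
implementation recovers structure the model family can represent; they do
not certify performance on real cohorts.

## Benchmark study conditions

The recovery benchmarks (`omicsvae.benchmarks`) fix the following sizes,
chosen to keep a full run in the minutes range on a single CPU:

* *Subtype recovery*: n = 400, four equal classes, three blocks of 1,000
  features (methylation over 10 chromosomes), p = 16, 100 epochs, hidden
  widths scaled to 256/128 (chromosome branches 32, fusion 64).  "High
  separation" is defined as pairwise class-mean distance 6 in latent units
  — Bayes accuracy ≈ 99.9% — so the ≥ 90% cross-validated bar measures the
  method, not planted class overlap.  Cross-validation retrains the joint
  model (encoder + decoder + classifier head) per fold on the 80% training
  portion and scores the held-out 20% with the classifier head; extracting
  LFs from a model supervised on all labels and cross-validating only a
  downstream classifier would leak label information (a zero-separation
  cohort scores far above chance under that protocol).
* *Cox coefficient recovery*: n = 500, planted log-hazard slope 1.0 on one
  latent, ~20% censoring.
* *Survival subgrouping*: n = 300, two latent classes at separation 2
  carrying a log-hazard difference of ln 3 (hazard ratio 3), 30%
  censoring, three blocks of 300 features, unsupervised MMD-VAE (p = 16,
  40 epochs), repeated over 10 seeds.  A seed succeeds when the test-set
  log-rank p < 0.05 and the combined Cox model's test C-index exceeds the
  clinical-only one.

## Numerical choices and degenerate inputs

* Constant features normalize to 0; constant LFs are flagged and excluded
  from Cox screening rather than failing the run.
* Non-converging per-LF Cox fits are flagged and excluded; multivariate
  fits drop constant covariates with a warning and carry a tiny ridge
  penalty (1e−6) for stability.
* BCE clamps reconstructions to [1e−12, 1−1e−12] before the logarithms.
* Batch-norm falls back to running statistics for batches of one sample;
  trailing single-sample minibatches are skipped during training.
* MMD of a batch against itself is exactly zero (terms cancel in floating
  point); the V-statistic estimator is nonnegative by construction.
* If the subgroup SVM predicts a single class for the whole test split,
  the log-rank comparison is reported as statistic 0, p = 1 instead of
  failing.
* All randomness flows from explicit seeds; the pipeline derives per-stage
  seeds from the single global seed via `SeedSequence((seed, stage_index))`.

## Known limitations

* The linear CRLF → feature mapping only surfaces linear associations; it
  is a screening device, not an attribution method.
* Min-max normalization before splitting leaks scale information into CV
  folds (kept for fidelity to the fixed preprocessing order).
* The per-LF screening p-values are uncorrected by design; treat CRLF
  counts as descriptive.
* The synthetic generator's linear factor structure favors the model
  family; real multi-omics data are noisier and non-linear.
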