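# omicsvae

VAE and MMD-VAE latent representations for integrated multi-omics cancer
analysis: Xena-style preprocessing, supervised or unsupervised latent-feature
learning with per-omics / per-chromosome encoder branches, clustering and
classification evaluation, Cox/Kaplan–Meier survival subgrouping, and
latent-factor biomarker mapping — with a synthetic-data generator so the
entire workflow runs and is tested without any download.

## Who this is for

Computational biologists integrating bulk multi-omics cohorts (copy-number,
DNA methylation, expression arrays, RNA-seq) where feature counts dwarf
sample counts (e.g. 72,885 features for 292 samples after tri-omics
concatenation) and a compressed, task-aware representation is needed before
clustering, classification or survival modeling.

## The model

Each sample x ∈ R^d is modeled as generated from a latent vector z ∈ R^p
(p ≪ d) with approximate posterior q_φ(z|x) = N(μ(x), diag σ²(x)) and the
reparameterization z = μ + σ ⊙ ε.  Two objectives share one architecture:

* **VAE** — reconstruction (binary cross-entropy) + KL(q_φ(z|x) ‖ N(0, I)),
  with the closed form ½ Σ (μ² + σ² − 1 − ln σ²);
* **MMD-VAE** — reconstruction (squared error) + MMD(q_φ(z|x) ‖ N(0, I)),
  the kernel V-statistic with Gaussian kernel exp(−‖z−z′‖²/(2σ_k²)).

Each omics block has its own encoder branch (input → 2048 → 1024); the
methylation block is split per chromosome into 256-wide branches before a
shared 1024-wide projection; branches fuse into a 512-wide layer feeding
the μ and log σ² heads.  The decoder mirrors the encoder with sigmoid
outputs.  Supervision attaches a softmax head (p → p/2 → classes) on z, and
the total loss is α(L_recon + L_reg) + β L_cl (β = 0 unsupervised).  The
neural stack runs on a small numpy reverse-mode autodiff engine whose
gradients are finite-difference-verified in the tests.

Downstream, latent features (LFs) drive 2-D/3-D embeddings (first-k LFs,
PCA/t-SNE baselines, t-SNE on LFs), 5-fold cross-validated ANN/SVM
classification, and a three-step survival pipeline: univariate Cox
screening of clinically relevant LFs (p < 0.05), K-means subgrouping
(K by majority vote of validity indices), SVM transfer to a held-out 40%,
evaluated by Harrell's C-index, IPCW Brier score and log-rank tests.
Clinically relevant LFs are finally mapped back to input features by
per-feature linear fits (standardized slope = Pearson r) and a clustered
correlation heatmap.

## Worked example

Run the whole workflow on a synthetic 4-class cohort (n = 200, three
100-feature blocks, one hazard-linked latent factor, 30% censoring):

```python
from omicsvae.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    outdir="demo_run", seed=7,
    stages=["simulate", "preprocess", "train", "embed",
            "classify", "survival", "biomarkers"],
    simulate={"n_samples": 200, "latent_dim_true": 6, "n_classes": 4,
              "class_proportions": [0.25, 0.25, 0.25, 0.25],
              "class_separation": 5.0,
              "block_specs": [
                  {"modality": "cnv", "n_features": 100},
                  {"modality": "mrna", "n_features": 100},
                  {"modality": "methylation", "n_features": 100,
                   "n_chromosomes": 5}],
              "survival": {"hazard_coefficients": [1, 0, 0, 0, 0, 0],
                           "censoring_rate": 0.3}},
    model={"latent_dim": 8, "hidden_widths": [64, 32], "chromosome_width": 16,
           "fused_width": 16, "loss_kind": "mmd", "beta": 1.0, "epochs": 30,
           "early_stopping_patience": None},
    evaluation={"folds": 5, "first_k": 2})
manifest = run_pipeline(cfg)
```

The run takes ~20 s and writes, among other artifacts,
`demo_run/classification_report.json`:

```
accuracy 97.0 ± 1.87 %   precision 0.971   recall 0.969   f1 0.968
cluster purity (first 2 LFs, k-means vs true subtypes): 0.885
```

— the supervised MMD-VAE latent space separates the four planted subtypes
almost perfectly — and `demo_run/survival_metrics.json`:

```
n_crlf 7                      (LFs passing univariate Cox screening)
cindex_clinical_test  0.511   brier_clinical_test  0.223
cindex_combined_test  0.713   brier_combined_test  0.192
logrank_p_test        1.4e-11
```

The clinical covariates alone are uninformative (C ≈ 0.5, as planted);
adding the inferred subgroup lifts the test C-index to 0.71 and the
predicted subgroups differ sharply in survival (log-rank p ≈ 1e−11),
recovering the hazard-linked latent factor end to end.

The same stages are available as CLI subcommands
(`omicsvae simulate|preprocess|train|embed|classify|survival|biomarkers`)
and as `omicsvae run-all --config run.yaml`.

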