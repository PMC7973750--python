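"""Reference study conditions for end-to-end recovery benchmarks.

These functions define the synthetic cohorts and scaled model sizes used to
demonstrate that the full method recovers planted structure: a 4-class
subtype cohort (n = 400, three blocks of 1,000 features, 16 latent
features, 100 epochs), a univariate Cox coefficient-recovery cohort
(n = 500, planted log-hazard 1.0, ~20% censoring) and a two-subgroup
survival cohort (n = 300, hazard ratio 3 between subgroups).  Hidden widths
are scaled to the feature counts (256/128 per block, 32-wide chromosome
branches, 64-wide fusion) so a full run stays in the minutes range on one
CPU.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional

import numpy as np

from . import classify, io, models, survival, synthetic

__all__ = [
    "integration_dimensions", "rebalance_arithmetic", "subtype_recovery",
    "cox_coefficient_recovery", "survival_pipeline_study",
]

# Feature counts of the TCGA ovarian-cancer (OV) assay platforms on UCSC Xena.
PLATFORM_FEATURES = {
    "cnv": 24_776,
    "mrna": 12_043,
    "rnaseq": 20_530,
    "methylation": 27_579,
}


def _schema_block(modality: str, n_features: int, n_samples: int = 2) -> io.OmicsBlock:
    """A placeholder block carrying only the platform's feature dimension."""
    rng = np.random.default_rng(0)
    prefix = "cg" if modality == "methylation" else f"{modality}_"
    return io.OmicsBlock(
        modality=modality,
        values=rng.uniform(0, 1, (n_samples, n_features)),
        sample_ids=[f"S{i}" for i in range(n_samples)],
        feature_ids=[f"{prefix}{j:07d}" for j in range(n_features)],
        normalized=True,
    )


def integration_dimensions() -> Dict[str, int]:
    """Integrated feature dimension D for the di- and tri-omics combinations."""
    combos = {
        "methylation_mrna": ["methylation", "mrna"],
        "cnv_methylation_rnaseq": ["cnv", "methylation", "rnaseq"],
        "cnv_methylation_mrna": ["cnv", "methylation", "mrna"],
    }
    out = {}
    for name, modalities in combos.items():
        blocks = [_schema_block(m, PLATFORM_FEATURES[m]) for m in modalities]
        ds = io.MultiOmicsDataset(blocks)
        out[name] = io.concatenate_blocks(ds).n_features
    return out


def rebalance_arithmetic(seed: int = 0, n_majority: int = 603,
                         n_minority: int = 10, target: int = 283) -> Dict[str, float]:
    """Oversample a 2-class cohort and report the resulting sample arithmetic."""
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n_majority, 10)),
                   rng.normal(2.5, 1, (n_minority, 10))])
    y = np.array([1] * n_majority + [0] * n_minority)
    X2, y2 = io.rebalance_borderline_smote_svm(X, y, target, seed=seed)
    n_min = int(np.sum(y2 == 0))
    return {
        "total_samples": len(y2),
        "minority_count": n_min,
        "minority_percent": round(100.0 * n_min / len(y2), 2),
    }


def _scaled_model_spec(loss_kind: str, beta: float, n_classes: Optional[int],
                       epochs: int, seed: int) -> models.ModelSpec:
    return models.ModelSpec(
        latent_dim=16, hidden_widths=(256, 128), chromosome_width=32,
        fused_width=64, loss_kind=loss_kind, beta=beta, n_classes=n_classes,
        epochs=epochs, batch_size=32, seed=seed, early_stopping_patience=None)


def _three_block_spec(n_samples, n_features, n_classes, proportions, separation,
                      survival_spec, seed) -> synthetic.SyntheticSpec:
    return synthetic.SyntheticSpec(
        n_samples=n_samples, latent_dim_true=8, n_classes=n_classes,
        class_proportions=proportions,
        block_specs=[
            synthetic.BlockSpec("cnv", n_features),
            synthetic.BlockSpec("mrna", n_features),
            synthetic.BlockSpec("methylation", n_features, n_chromosomes=10),
        ],
        class_separation=separation,
        survival=survival_spec or synthetic.SurvivalSpec(),
        seed=seed)


def _normalized_dataset(spec: synthetic.SyntheticSpec):
    dataset, truth = synthetic.generate_multiomics(spec)
    blocks = [io.minmax_normalize(b) for b in dataset.blocks]
    return io.MultiOmicsDataset(blocks, labels=dataset.labels,
                                clinical=dataset.clinical), truth


def subtype_recovery(seed: int = 0, separation: float = 6.0,
                     epochs: int = 100, folds: int = 5) -> Dict[str, float]:
    """Supervised MMD-VAE on a 4-class cohort; fold-wise joint-model CV accuracy.

    n = 400 samples, three blocks of 1,000 features each, 16 latent features.
    In every fold the joint model (encoder + decoder + classifier head) is
    trained on the 80% training portion only and the held-out 20% is scored
    by the classifier head, so no held-out label ever influences the latent
    space.  High separation should give >= 90% accuracy; zero separation,
    chance.
    """
    from sklearn.model_selection import StratifiedKFold

    spec = _three_block_spec(400, 1000, 4, (0.25,) * 4, separation, None, seed)
    ds, _ = _normalized_dataset(spec)
    arrays = ds.block_arrays()
    labels = ds.labels.to_numpy()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_acc = []
    first_cl = last_cl = None
    for fold, (tr, te) in enumerate(skf.split(arrays[0], labels)):
        mspec = _scaled_model_spec("mmd", beta=1.0, n_classes=4, epochs=epochs,
                                   seed=seed + fold)
        model = models.build_model(mspec, ds.schemas())
        models.train(model, [a[tr] for a in arrays], labels=labels[tr])
        pred = models.predict_classes(model, [a[te] for a in arrays])
        fold_acc.append(100.0 * float(np.mean(pred == labels[te])))
        if fold == 0:
            first_cl = model.history[0].classification
            last_cl = model.history[-1].classification
    return {
        "cv_accuracy_percent": float(np.mean(fold_acc)),
        "cv_accuracy_sd": float(np.std(fold_acc)),
        "final_classification_loss": last_cl,
        "first_classification_loss": first_cl,
    }


def cox_coefficient_recovery(seed: int = 0, n: int = 500,
                             true_coef: float = 1.0) -> Dict[str, float]:
    """Fit a univariate Cox model on a latent with planted log-hazard slope.

    Weibull event times, ~20% censoring; returns the estimated coefficient
    for the hazard-linked latent.
    """
    coefs = np.zeros(8)
    coefs[0] = true_coef
    spec = synthetic.SyntheticSpec(
        n_samples=n, latent_dim_true=8, n_classes=2, class_proportions=(0.5, 0.5),
        block_specs=[synthetic.BlockSpec("cnv", 10)], class_separation=0.0,
        survival=synthetic.SurvivalSpec(hazard_coefficients=coefs,
                                        censoring_rate=0.2),
        seed=seed)
    _, truth = synthetic.generate_multiomics(spec)
    table = synthetic.generate_survival(truth, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel = survival.cox_univariate_per_lf(truth.true_latents, table)
    return {"estimated_coefficient": float(sel.coefficients[0]),
            "true_coefficient": true_coef,
            "p_value": float(sel.p_values[0])}


def survival_pipeline_study(seeds=range(10), hazard_ratio: float = 3.0,
                            n: int = 300, epochs: int = 40) -> Dict[str, object]:
    """Full pipeline on planted survival subgroups, repeated across seeds.

    Two latent-space classes (separation 2) carry a log-hazard difference of
    ln(hazard_ratio); the unsupervised MMD-VAE is trained, LFs screened,
    subgroups clustered and transferred by SVM.  A seed 'succeeds' when the
    test-set KM log-rank p < 0.05 and the combined Cox model's test C-index
    exceeds the clinical-only one.
    """
    c = np.log(hazard_ratio) / (2.0 * np.sqrt(2.0))
    coefs = np.zeros(8)
    coefs[0], coefs[1] = c, -c
    results: List[Dict[str, float]] = []
    for seed in seeds:
        spec = synthetic.SyntheticSpec(
            n_samples=n, latent_dim_true=8, n_classes=2,
            class_proportions=(0.5, 0.5),
            block_specs=[
                synthetic.BlockSpec("cnv", 300),
                synthetic.BlockSpec("mrna", 300),
                synthetic.BlockSpec("methylation", 300, n_chromosomes=5),
            ],
            class_separation=2.0,
            survival=synthetic.SurvivalSpec(hazard_coefficients=coefs,
                                            censoring_rate=0.3),
            seed=seed)
        ds, _ = _normalized_dataset(spec)
        mspec = _scaled_model_spec("mmd", beta=0.0, n_classes=None,
                                   epochs=epochs, seed=seed)
        # Survival cohorts use smaller blocks; scale the widths down with them.
        mspec.hidden_widths, mspec.chromosome_width, mspec.fused_width = (128, 64), 16, 32
        model = models.build_model(mspec, ds.schemas())
        models.train(model, ds.block_arrays())
        lfs = models.extract_latent(model, ds.block_arrays())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = survival.run_survival_pipeline(lfs, ds.clinical, seed=seed, K=2)
        m = res.metrics
        results.append({
            "seed": seed,
            "logrank_p_test": m["logrank_p_test"],
            "cindex_combined_test": m["cindex_combined_test"],
            "cindex_clinical_test": m["cindex_clinical_test"],
            "brier_combined_test": m["brier_combined_test"],
            "success": bool(m["logrank_p_test"] < 0.05
                            and m["cindex_combined_test"] > m["cindex_clinical_test"]),
        })
    wins = sum(r["success"] for r in results)
    return {"per_seed": results, "successes": wins, "n_seeds": len(results)}
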