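"""Synthetic multi-omics generator with planted latent structure.

The generator emulates the statistical shape of TCGA-style multi-omics cohorts: each sample
carries a low-dimensional true latent vector whose class-dependent mean sits
at a scaled simplex vertex; every omics block is a linear factor model
(block loadings drawn once per seed) plus Gaussian noise.  Methylation
values pass through a logistic link so they land in (0, 1) like CpG beta
values, and probes are assigned to chromosomes; CNV / expression blocks stay
unbounded to exercise min-max normalization.  Survival times follow a
Weibull proportional-hazards model whose linear predictor is
``true_latents @ hazard_coefficients``, with independent censoring
calibrated to a requested rate.  Clinical covariates (age, ordinal stage and
grade) are independent of risk unless confounding is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import MultiOmicsDataset, OmicsBlock, ProbeMap
from .survival import SurvivalTable

__all__ = ["BlockSpec", "SurvivalSpec", "SyntheticSpec", "GroundTruth",
           "generate_multiomics", "generate_survival", "write_dataset"]


@dataclass
class BlockSpec:
    modality: str  # cnv | mrna | rnaseq | methylation
    n_features: int
    noise_sd: float = 0.5
    n_chromosomes: int = 0  # methylation only


@dataclass
class SurvivalSpec:
    baseline_scale: float = 1500.0  # days; Weibull scale lambda
    baseline_shape: float = 1.2  # Weibull shape k
    hazard_coefficients: Optional[np.ndarray] = None  # over true latent factors
    censoring_rate: float = 0.3
    confound_clinical: bool = False


@dataclass
class SyntheticSpec:
    """Full description of one synthetic cohort."""

    n_samples: int = 400
    latent_dim_true: int = 8
    n_classes: int = 4
    class_proportions: Tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    block_specs: List[BlockSpec] = field(default_factory=lambda: [
        BlockSpec("cnv", 1000, noise_sd=0.5),
        BlockSpec("mrna", 1000, noise_sd=0.5),
        BlockSpec("methylation", 1000, noise_sd=0.5, n_chromosomes=10),
    ])
    class_separation: float = 4.0
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 0:
            raise ValueError("n_samples must be nonnegative")
        if self.latent_dim_true < 1:
            raise ValueError("latent_dim_true must be positive")
        if self.n_classes not in (2, 4):
            raise ValueError("n_classes must be 2 or 4")
        if len(self.class_proportions) != self.n_classes:
            raise ValueError("class_proportions length must equal n_classes")
        if not np.isclose(sum(self.class_proportions), 1.0):
            raise ValueError("class_proportions must sum to 1")
        if self.class_separation < 0:
            raise ValueError("class_separation must be nonnegative")
        if not (0 <= self.survival.censoring_rate < 1):
            raise ValueError("censoring_rate must lie in [0, 1)")
        for b in self.block_specs:
            if b.modality == "methylation":
                if b.n_chromosomes < 1:
                    raise ValueError("methylation block requires n_chromosomes >= 1")
                if b.n_features < b.n_chromosomes:
                    raise ValueError("n_features must be >= n_chromosomes for methylation")
            if b.noise_sd < 0:
                raise ValueError("noise_sd must be nonnegative")


@dataclass
class GroundTruth:
    true_latents: np.ndarray  # n x latent_dim_true
    class_labels: np.ndarray  # n
    risk_scores: np.ndarray  # n; linear predictor of the hazard
    subgroup_labels: Optional[np.ndarray] = None  # n, when survival is planted


def _class_means(n_classes: int, latent_dim: int, separation: float) -> np.ndarray:
    """Class means at scaled simplex vertices in true latent space.

    Vertices are the first n_classes coordinate directions, centered and
    scaled so adjacent means sit `separation` apart.
    """
    if latent_dim < n_classes:
        raise ValueError("latent_dim_true must be >= n_classes for simplex placement")
    vertices = np.eye(n_classes, latent_dim)
    vertices -= vertices.mean(axis=0)
    # Distance between any two distinct vertices of eye() is sqrt(2).
    return vertices * (separation / np.sqrt(2.0))


def generate_multiomics(spec: SyntheticSpec) -> Tuple[MultiOmicsDataset, GroundTruth]:
    """Generate the dataset and its ground truth; bit-identical per seed."""
    rng = np.random.default_rng(spec.seed)
    n, q = spec.n_samples, spec.latent_dim_true
    labels = rng.choice(spec.n_classes, size=n, p=np.asarray(spec.class_proportions))
    means = _class_means(spec.n_classes, q, spec.class_separation)
    latents = means[labels] + rng.standard_normal((n, q))

    sample_ids = [f"SYN-{i:04d}" for i in range(n)]
    blocks = []
    for b_idx, bspec in enumerate(spec.block_specs):
        loadings = rng.standard_normal((bspec.n_features, q)) / np.sqrt(q)
        signal = latents @ loadings.T
        noise = rng.standard_normal((n, bspec.n_features)) * bspec.noise_sd
        raw = signal + noise
        if bspec.modality == "methylation":
            values = 1.0 / (1.0 + np.exp(-raw))
            feature_ids = [f"cg{b_idx}{j:07d}" for j in range(bspec.n_features)]
            # Contiguous chromosome chunks spread over n_chromosomes.
            bounds = np.linspace(0, bspec.n_features, bspec.n_chromosomes + 1).astype(int)
            chromosome_of = {}
            for c in range(bspec.n_chromosomes):
                for j in range(bounds[c], bounds[c + 1]):
                    chromosome_of[feature_ids[j]] = f"chr{c + 1}"
            unit = "beta value"
        else:
            offset = {"mrna": 6.0, "rnaseq": 8.0, "cnv": 0.0}[bspec.modality]
            values = raw + offset
            feature_ids = [f"{bspec.modality}_gene_{j:05d}" for j in range(bspec.n_features)]
            chromosome_of = None
            unit = {"mrna": "log2(affy RMA)", "rnaseq": "log2(norm_count+1)",
                    "cnv": "gistic2 copy number"}[bspec.modality]
        blocks.append(OmicsBlock(
            modality=bspec.modality, values=values, sample_ids=sample_ids,
            feature_ids=feature_ids, unit=unit, chromosome_of=chromosome_of))

    coefs = spec.survival.hazard_coefficients
    if coefs is None:
        coefs = np.zeros(q)
    coefs = np.asarray(coefs, float)
    if coefs.shape != (q,):
        raise ValueError(
            f"hazard_coefficients length {coefs.shape} must match latent_dim_true {q}")
    risk = latents @ coefs if n else np.zeros(0)
    subgroups = None
    if np.any(coefs != 0) and n:
        subgroups = (risk >= np.median(risk)).astype(int)

    label_series = pd.Series(labels, index=sample_ids, name="label")
    truth = GroundTruth(true_latents=latents, class_labels=labels,
                        risk_scores=risk, subgroup_labels=subgroups)
    dataset = MultiOmicsDataset(blocks, labels=label_series)
    dataset.clinical = generate_survival(truth, spec, sample_ids=sample_ids)
    return dataset, truth


def generate_survival(truth: GroundTruth, spec: SyntheticSpec,
                      sample_ids: Optional[Sequence[str]] = None) -> SurvivalTable:
    """Weibull proportional-hazards event times with calibrated censoring.

    T = lambda * (-ln U * exp(-risk))^(1/k); an independent exponential
    censoring time is scaled (by bisection on the drawn sample) so the
    realized censoring fraction approximates ``censoring_rate``.
    """
    sspec = spec.survival
    coefs = sspec.hazard_coefficients
    if coefs is not None and np.asarray(coefs).shape != (spec.latent_dim_true,):
        raise ValueError("hazard_coefficients length must equal latent_dim_true")
    n = len(truth.risk_scores)
    rng = np.random.default_rng(spec.seed + 10_000)
    if sample_ids is None:
        sample_ids = [f"SYN-{i:04d}" for i in range(n)]
    lam, shape = sspec.baseline_scale, sspec.baseline_shape
    u = rng.uniform(size=n)
    event_times = lam * (-np.log(u) * np.exp(-truth.risk_scores)) ** (1.0 / shape)

    if sspec.censoring_rate > 0 and n:
        v = rng.uniform(size=n)
        base = -np.log(v)

        def censored_frac(scale):
            return np.mean(scale * base < event_times)

        lo, hi = 1e-6, 1e12
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if censored_frac(mid) > sspec.censoring_rate:
                lo = mid
            else:
                hi = mid
        censor_times = np.sqrt(lo * hi) * base
    else:
        censor_times = np.full(n, np.inf)

    observed = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    observed = np.maximum(observed, 1e-3)  # os_time must stay positive

    age = np.clip(rng.normal(60, 10, size=n), 30, 90)
    if sspec.confound_clinical and n:
        p_late = 1.0 / (1.0 + np.exp(-truth.risk_scores))
        stage = 1 + rng.binomial(3, p_late)
    else:
        stage = rng.choice([1, 2, 3, 4], size=n, p=[0.05, 0.10, 0.55, 0.30])
    grade = rng.choice([1, 2, 3], size=n, p=[0.05, 0.25, 0.70])

    df = pd.DataFrame({
        "sample_id": list(sample_ids),
        "os_time": observed,
        "os_event": event,
        "age": np.round(age, 1),
        "stage": stage,
        "grade": grade,
    })
    if truth.subgroup_labels is not None:
        df["subtype"] = truth.class_labels
    return SurvivalTable(df)


def write_dataset(dataset: MultiOmicsDataset, outdir) -> dict:
    """Write blocks as Xena genomicMatrix TSVs plus probe-map and clinical TSVs."""
    from pathlib import Path

    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for block in dataset.blocks:
        p = outdir / f"{block.modality}.genomicMatrix.tsv"
        _io.write_genomic_matrix(block, p)
        paths[block.modality] = str(p)
        if block.modality == "methylation" and block.chromosome_of:
            pm = outdir / "probe_map.tsv"
            _io.write_probe_map(ProbeMap(dict(block.chromosome_of)), pm)
            paths["probe_map"] = str(pm)
    if dataset.clinical is not None:
        cp = outdir / "clinical.tsv"
        _io.write_clinical(dataset.clinical, cp)
        paths["clinical"] = str(cp)
    if dataset.labels is not None:
        lp = outdir / "labels.tsv"
        dataset.labels.rename_axis("sample_id").to_csv(lp, sep="\t")
        paths["labels"] = str(lp)
    return paths
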