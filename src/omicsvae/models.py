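"""Multi-branch VAE / MMD-VAE with an optional supervised classifier head.

Architecture
------------
Each omics block gets its own encoder branch.  Non-methylation blocks pass
through two dense blocks (default widths 2048 then 1024).  The methylation
block is split by chromosome: each chromosome's probes are encoded into a
256-wide vector (capturing intra-chromosome structure), the branch outputs
are concatenated and projected to the common 1024-wide per-block vector
(inter-chromosome structure).  All per-block vectors are concatenated and
fused into a 512-wide layer feeding two heads of width p: the posterior mean
mu and the log-variance (sigma = exp(0.5 * logvar)).  The decoder mirrors
the encoder exactly, ending in sigmoids so reconstructions lie in (0, 1).
Every hidden dense block carries batch normalization and ReLU.

The classifier head (built only when beta > 0) is p -> p/2 -> n_classes with
softmax, consuming the sampled z during training and mu at inference.

Training minimizes alpha * (reconstruction + regularizer) + beta * CE with
Adam; the regularizer is the closed-form KL (loss_kind="elbo") or the kernel
MMD between the encoded batch and a fresh standard-normal sample
(loss_kind="mmd").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .autodiff import Tensor, concat
from .nn import Adam, DenseBlock, Linear, Module
from . import losses
from .losses import LossBreakdown

__all__ = [
    "ModelSpec", "BlockSchema", "LatentCodes", "TrainedModel",
    "build_model", "reparameterize", "train", "extract_latent",
]


@dataclass
class ModelSpec:
    """Hyperparameters of the model and its training loop.

    latent_dim is the number of latent features (LFs) p; typical sizes are
    32/64/128 but any positive value below the input dimension is valid.
    beta = 0 trains unsupervised (no classifier head is constructed);
    beta > 0 adds the softmax classifier on z.
    """

    latent_dim: int = 128
    hidden_widths: Tuple[int, int] = (2048, 1024)
    chromosome_width: int = 256
    fused_width: int = 512
    loss_kind: str = "elbo"  # "elbo" | "mmd"
    alpha: float = 1.0
    beta: float = 0.0
    mmd_bandwidth: Union[float, str] = "default"  # positive float | "auto" | "default"
    n_classes: Optional[int] = None
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 250
    early_stopping_patience: Optional[int] = 20
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")
        if self.loss_kind not in ("elbo", "mmd"):
            raise ValueError(f"loss_kind must be 'elbo' or 'mmd', got {self.loss_kind!r}")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.beta > 0 and not self.n_classes:
            raise ValueError("supervised model (beta > 0) requires n_classes")

    def resolve_bandwidth(self, z: np.ndarray = None, w: np.ndarray = None) -> float:
        if self.mmd_bandwidth == "default":
            return float(np.sqrt(self.latent_dim / 2.0))
        if self.mmd_bandwidth == "auto":
            return losses.median_heuristic_bandwidth(z, w)
        return float(self.mmd_bandwidth)


@dataclass
class BlockSchema:
    """Shape of one omics block as the model sees it.

    For methylation, ``chromosomes`` lists (label, column index array) pairs
    in deterministic order; other modalities leave it None.
    """

    modality: str
    n_features: int
    chromosomes: Optional[List[Tuple[str, List[int]]]] = None

    @property
    def is_methylation(self) -> bool:
        return self.modality == "methylation"


@dataclass
class LatentCodes:
    """Per-sample posterior mean, scale and sampled latent vectors."""

    mu: np.ndarray
    sigma: np.ndarray
    z: np.ndarray
    epsilon: np.ndarray

    def __post_init__(self):
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")


def reparameterize(mu, sigma, epsilon):
    """z = mu + sigma * epsilon, differentiable in mu and sigma."""
    sig_data = sigma.data if isinstance(sigma, Tensor) else np.asarray(sigma)
    if np.any(sig_data <= 0):
        raise ValueError("sigma must be strictly positive")
    eps = epsilon if isinstance(epsilon, Tensor) else np.asarray(epsilon, dtype=float)
    return mu + sigma * eps


class _EncoderBranch(Module):
    def __init__(self, schema: BlockSchema, spec: ModelSpec, rng):
        h1, h2 = spec.hidden_widths
        self.schema = schema
        if schema.is_methylation:
            self.chrom_blocks = [
                DenseBlock(len(cols), spec.chromosome_width, rng)
                for _, cols in schema.chromosomes
            ]
            self.merge = DenseBlock(len(self.chrom_blocks) * spec.chromosome_width, h2, rng)
        else:
            self.first = DenseBlock(schema.n_features, h1, rng)
            self.second = DenseBlock(h1, h2, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if self.schema.is_methylation:
            parts = [blk(x[:, cols]) for blk, (_, cols) in
                     zip(self.chrom_blocks, self.schema.chromosomes)]
            return self.merge(concat(parts, axis=1))
        return self.second(self.first(x))


class _DecoderBranch(Module):
    def __init__(self, schema: BlockSchema, spec: ModelSpec, rng):
        h1, h2 = spec.hidden_widths
        self.schema = schema
        if schema.is_methylation:
            self.expand = DenseBlock(h2, len(schema.chromosomes) * spec.chromosome_width, rng)
            self.chrom_width = spec.chromosome_width
            self.chrom_outs = [
                Linear(spec.chromosome_width, len(cols), rng)
                for _, cols in schema.chromosomes
            ]
        else:
            self.first = DenseBlock(h2, h1, rng)
            self.out = Linear(h1, schema.n_features, rng)

    def __call__(self, h: Tensor):
        """Returns the reconstruction: a list per chromosome for methylation,
        otherwise a single tensor; all sigmoid-activated."""
        if self.schema.is_methylation:
            expanded = self.expand(h)
            outs = []
            for i, lin in enumerate(self.chrom_outs):
                lo, hi = i * self.chrom_width, (i + 1) * self.chrom_width
                outs.append(lin(expanded[:, lo:hi]).sigmoid())
            return outs
        return self.out(self.first(h)).sigmoid()


class MultiOmicsVAE(Module):
    def __init__(self, spec: ModelSpec, schemas: Sequence[BlockSchema]):
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        self.schemas = list(schemas)
        total_d = sum(s.n_features for s in self.schemas)
        if spec.latent_dim >= total_d:
            raise ValueError(
                f"latent_dim {spec.latent_dim} must be smaller than the "
                f"total input dimension {total_d}"
            )
        for s in self.schemas:
            if s.is_methylation and not s.chromosomes:
                raise ValueError("methylation block requires a chromosome partition")
        h2 = spec.hidden_widths[1]
        self.enc_branches = [_EncoderBranch(s, spec, rng) for s in self.schemas]
        self.fuse = DenseBlock(len(self.schemas) * h2, spec.fused_width, rng)
        self.mu_head = Linear(spec.fused_width, spec.latent_dim, rng)
        self.logvar_head = Linear(spec.fused_width, spec.latent_dim, rng)
        self.defuse = DenseBlock(spec.latent_dim, spec.fused_width, rng)
        self.split = DenseBlock(spec.fused_width, len(self.schemas) * h2, rng)
        self.dec_branches = [_DecoderBranch(s, spec, rng) for s in self.schemas]
        if spec.beta > 0:
            half = max(spec.latent_dim // 2, 1)
            self.cls_hidden = DenseBlock(spec.latent_dim, half, rng)
            self.cls_out = Linear(half, spec.n_classes, rng)
        else:
            self.cls_hidden = self.cls_out = None

    # -- forward pieces ----------------------------------------------------

    def encode(self, x_blocks: Sequence[Tensor]):
        per_block = [branch(x) for branch, x in zip(self.enc_branches, x_blocks)]
        fused = self.fuse(concat(per_block, axis=1))
        mu = self.mu_head(fused)
        logvar = self.logvar_head(fused)
        sigma = (0.5 * logvar).exp()
        return mu, sigma

    def decode(self, z: Tensor):
        h2 = self.spec.hidden_widths[1]
        hidden = self.split(self.defuse(z))
        recons = []
        for i, branch in enumerate(self.dec_branches):
            recons.append(branch(hidden[:, i * h2:(i + 1) * h2]))
        return recons

    def classify_logits(self, z: Tensor) -> Tensor:
        if self.cls_out is None:
            raise ValueError("model was built without a classifier head (beta = 0)")
        return self.cls_out(self.cls_hidden(z))

    def describe_architecture(self) -> dict:
        """Layer widths per component, for inspection and logging."""
        h1, h2 = self.spec.hidden_widths
        blocks = {}
        for s in self.schemas:
            if s.is_methylation:
                blocks[s.modality] = {
                    "branches": len(s.chromosomes),
                    "branch_width": self.spec.chromosome_width,
                    "widths": [s.n_features, self.spec.chromosome_width, h2],
                }
            else:
                blocks[s.modality] = {"widths": [s.n_features, h1, h2]}
        desc = {
            "blocks": blocks,
            "fused_width": self.spec.fused_width,
            "latent_dim": self.spec.latent_dim,
        }
        if self.cls_out is not None:
            desc["classifier"] = [
                self.spec.latent_dim,
                max(self.spec.latent_dim // 2, 1),
                self.spec.n_classes,
            ]
        return desc


@dataclass
class TrainedModel:
    """A built (possibly trained) model with its spec, schema and history."""

    spec: ModelSpec
    schemas: List[BlockSchema]
    network: MultiOmicsVAE
    history: List[LossBreakdown] = field(default_factory=list)

    def describe_architecture(self) -> dict:
        return self.network.describe_architecture()

    def save(self, path: str) -> None:
        """Checkpoint: spec/schema/history as JSON plus parameter arrays."""
        meta = {
            "spec": asdict(self.spec),
            "schemas": [
                {"modality": s.modality, "n_features": s.n_features,
                 "chromosomes": s.chromosomes}
                for s in self.schemas
            ],
            "history": [asdict(h) for h in self.history],
        }
        params = {f"p{i}": p.data for i, p in enumerate(self.network.parameters())}
        for i, bn in enumerate(self.network.batch_norms()):
            params[f"bn{i}_mean"] = bn.running_mean
            params[f"bn{i}_var"] = bn.running_var
        np.savez(path, meta=json.dumps(meta), **params)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        archive = np.load(path if str(path).endswith(".npz") else f"{path}.npz",
                          allow_pickle=False)
        meta = json.loads(str(archive["meta"]))
        spec = ModelSpec(**{**meta["spec"],
                            "hidden_widths": tuple(meta["spec"]["hidden_widths"])})
        schemas = [
            BlockSchema(s["modality"], s["n_features"],
                        [(c, list(cols)) for c, cols in s["chromosomes"]]
                        if s["chromosomes"] else None)
            for s in meta["schemas"]
        ]
        model = cls(spec, schemas, MultiOmicsVAE(spec, schemas),
                    [LossBreakdown(**h) for h in meta["history"]])
        for i, p in enumerate(model.network.parameters()):
            p.data[...] = archive[f"p{i}"]
        for i, bn in enumerate(model.network.batch_norms()):
            bn.running_mean[...] = archive[f"bn{i}_mean"]
            bn.running_var[...] = archive[f"bn{i}_var"]
        model.network.eval()
        return model


def build_model(spec: ModelSpec, schemas: Sequence[BlockSchema]) -> TrainedModel:
    """Construct an untrained model for the given dataset schema."""
    return TrainedModel(spec=spec, schemas=list(schemas),
                        network=MultiOmicsVAE(spec, schemas))


def _split_blocks(X_blocks: Sequence[np.ndarray], idx: np.ndarray):
    return [Tensor(b[idx]) for b in X_blocks]


def _batch_loss(net: MultiOmicsVAE, xb: List[Tensor], labels_b, spec: ModelSpec,
                rng: np.random.Generator):
    n = xb[0].shape[0]
    mu, sigma = net.encode(xb)
    eps = rng.standard_normal((n, spec.latent_dim))
    z = reparameterize(mu, sigma, eps)
    recons = net.decode(z)
    meth_pairs, other_pairs = [], []
    for schema, x, xr in zip(net.schemas, xb, recons):
        if schema.is_methylation:
            for (_, cols), chrom_recon in zip(schema.chromosomes, xr):
                meth_pairs.append((x[:, cols], chrom_recon))
        else:
            other_pairs.append((x, xr))
    recon_meth, recon_other = losses.reconstruction_loss(
        meth_pairs, other_pairs, spec.loss_kind)
    if spec.loss_kind == "elbo":
        reg = losses.kl_divergence(mu, sigma)
    else:
        prior = rng.standard_normal((n, spec.latent_dim))
        bw = spec.resolve_bandwidth(z.data, prior)
        reg = losses.mmd(z, Tensor(prior), bandwidth=bw)
    if spec.beta > 0:
        logits = net.classify_logits(z)
        cl = losses.softmax_cross_entropy(logits, labels_b)
    else:
        cl = 0.0
    return losses.total_loss(recon_meth, recon_other, reg, cl,
                             alpha=spec.alpha, beta=spec.beta)


def train(model: TrainedModel, X_blocks: Sequence[np.ndarray],
          labels: Optional[np.ndarray] = None, verbose: bool = False) -> TrainedModel:
    """Minibatch Adam training; appends one LossBreakdown per epoch.

    X_blocks are the normalized samples x features matrices in schema order.
    Supervised training (beta > 0) requires an integer label per sample.
    Deterministic for a fixed ModelSpec.seed.
    """
    spec = model.spec
    net = model.network
    n = X_blocks[0].shape[0]
    for schema, X in zip(model.schemas, X_blocks):
        if X.shape != (n, schema.n_features):
            raise ValueError(
                f"block {schema.modality}: expected shape {(n, schema.n_features)}, "
                f"got {X.shape}")
    if spec.beta > 0:
        if labels is None or len(labels) != n:
            raise ValueError("supervised training (beta > 0) requires one label per sample")
        labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(spec.seed + 1)
    opt = Adam(net.parameters(), lr=spec.learning_rate)
    best, patience_left = np.inf, spec.early_stopping_patience
    net.train()
    for epoch in range(spec.epochs):
        perm = rng.permutation(n)
        sums = np.zeros(4)  # recon_meth, recon_other_total, reg, cl
        other_sums = None
        n_batches = 0
        for start in range(0, n, spec.batch_size):
            idx = perm[start:start + spec.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs >= 2 samples
            xb = _split_blocks(X_blocks, idx)
            lb = labels[idx] if spec.beta > 0 else None
            loss, breakdown = _batch_loss(net, xb, lb, spec, rng)
            if not np.isfinite(breakdown.total):
                parts = {"recon_methylation": breakdown.recon_methylation,
                         "recon_other": breakdown.recon_other,
                         "regularizer": breakdown.regularizer,
                         "classification": breakdown.classification}
                bad = [k for k, v in parts.items()
                       if not np.all(np.isfinite(np.atleast_1d(v)))]
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: offending component(s) {bad}")
            net.zero_grad()
            loss.backward()
            opt.step()
            sums += [breakdown.recon_methylation, sum(breakdown.recon_other),
                     breakdown.regularizer, breakdown.classification]
            if other_sums is None:
                other_sums = np.array(breakdown.recon_other, dtype=float)
            else:
                other_sums += breakdown.recon_other
            n_batches += 1
        epoch_other = list(other_sums / n_batches) if other_sums is not None else []
        epoch_lb = LossBreakdown(
            recon_methylation=sums[0] / n_batches,
            recon_other=epoch_other,
            regularizer=sums[2] / n_batches,
            classification=sums[3] / n_batches,
            total=spec.alpha * (sums[0] + sums[1] + sums[2]) / n_batches
            + spec.beta * sums[3] / n_batches,
        )
        model.history.append(epoch_lb)
        if verbose:
            print(f"epoch {epoch + 1}/{spec.epochs}: total={epoch_lb.total:.4f} "
                  f"recon_meth={epoch_lb.recon_methylation:.4f} "
                  f"recon_other={epoch_lb.recon_other} reg={epoch_lb.regularizer:.4f} "
                  f"cl={epoch_lb.classification:.4f}")
        if spec.early_stopping_patience is not None:
            if epoch_lb.total < best - 1e-6:
                best, patience_left = epoch_lb.total, spec.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    net.eval()
    return model


def encode_dataset(model: TrainedModel, X_blocks: Sequence[np.ndarray],
                   seed: Optional[int] = None) -> LatentCodes:
    """Full-dataset posterior parameters and one sampled z (inference mode)."""
    _check_schema(model, X_blocks)
    net = model.network
    net.eval()
    mu, sigma = net.encode([Tensor(b) for b in X_blocks])
    rng = np.random.default_rng(model.spec.seed if seed is None else seed)
    eps = rng.standard_normal(mu.shape)
    z = mu.data + sigma.data * eps
    return LatentCodes(mu=mu.data, sigma=sigma.data, z=z, epsilon=eps)


def _check_schema(model: TrainedModel, X_blocks: Sequence[np.ndarray]):
    if len(X_blocks) != len(model.schemas):
        raise ValueError(
            f"schema mismatch: model has {len(model.schemas)} blocks, "
            f"input has {len(X_blocks)}")
    bad = [s.modality for s, X in zip(model.schemas, X_blocks)
           if X.shape[1] != s.n_features]
    if bad:
        raise ValueError(f"schema mismatch in block(s): {bad}")


def extract_latent(model: TrainedModel, X_blocks: Sequence[np.ndarray],
                   use_mean: bool = True, seed: Optional[int] = None) -> np.ndarray:
    """The samples x p latent-feature (LF) matrix all downstream stages consume."""
    codes = encode_dataset(model, X_blocks, seed=seed)
    return codes.mu if use_mean else codes.z


def predict_classes(model: TrainedModel, X_blocks: Sequence[np.ndarray]) -> np.ndarray:
    """Classifier-head predictions from the posterior mean (inference mode)."""
    _check_schema(model, X_blocks)
    net = model.network
    net.eval()
    mu, _ = net.encode([Tensor(b) for b in X_blocks])
    logits = net.classify_logits(mu)
    return np.argmax(logits.data, axis=1)
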