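"""Objective functions for the VAE and MMD-VAE.

The total objective is

    L_total = alpha * (L_recon + L_reg) + beta * L_cl

where L_recon is block-structured reconstruction error (binary cross-entropy
for the ELBO variant, squared error for the MMD variant; the methylation
block's term is averaged over its chromosome branches), L_reg is either the
closed-form KL divergence to the standard normal prior or the kernel MMD
between the encoded batch and a prior sample, and L_cl is softmax
cross-entropy of the classifier head (beta = 0 disables supervision).

All functions accept either plain numpy arrays (returning floats) or autodiff
tensors (returning differentiable scalars).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Union

import numpy as np

from .autodiff import Tensor

ArrayLike = Union[np.ndarray, Tensor, float]

_EPS = 1e-12


@dataclass
class LossBreakdown:
    """Per-component values of the training objective for one batch/epoch."""

    recon_methylation: float = 0.0
    recon_other: List[float] = field(default_factory=list)
    regularizer: float = 0.0
    classification: float = 0.0
    total: float = 0.0

    @property
    def recon_total(self) -> float:
        return self.recon_methylation + float(sum(self.recon_other))


def _as_tensor(x: ArrayLike) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _maybe_float(x: Tensor, want_float: bool):
    return float(x.data) if want_float else x


def kl_divergence(mu: ArrayLike, sigma: ArrayLike) -> ArrayLike:
    """KL( N(mu, diag(sigma^2)) || N(0, I) ), averaged over the batch.

    Closed form per sample: 0.5 * sum_i (mu_i^2 + sigma_i^2 - 1 - ln sigma_i^2).
    """
    want_float = not isinstance(mu, Tensor) and not isinstance(sigma, Tensor)
    mu_t, sigma_t = _as_tensor(mu), _as_tensor(sigma)
    if np.any(sigma_t.data <= 0):
        raise ValueError("sigma must be strictly positive")
    if mu_t.ndim == 1:
        mu_t, sigma_t = mu_t.reshape(1, -1), sigma_t.reshape(1, -1)
    var = sigma_t**2
    per_sample = 0.5 * (mu_t**2 + var - 1.0 - var.log()).sum(axis=1)
    return _maybe_float(per_sample.mean(), want_float)


def _pairwise_sq_dists(a: Tensor, b: Tensor) -> Tensor:
    aa = (a**2).sum(axis=1, keepdims=True)  # (n, 1)
    bb = (b**2).sum(axis=1, keepdims=True).T  # (1, m)
    return aa + bb - 2.0 * (a @ b.T)


def mmd(z_batch: ArrayLike, prior_batch: ArrayLike, bandwidth: float = 1.0) -> ArrayLike:
    """Biased (V-statistic) maximum mean discrepancy with a Gaussian kernel.

    MMD^2 = mean k(z, z') + mean k(w, w') - 2 mean k(z, w), with
    k(z, z') = exp(-||z - z'||^2 / (2 * bandwidth^2)).  Nonnegative by
    construction and exactly zero for identical batches.
    """
    want_float = not isinstance(z_batch, Tensor) and not isinstance(prior_batch, Tensor)
    z, w = _as_tensor(z_batch), _as_tensor(prior_batch)
    if z.ndim == 1:
        z = z.reshape(-1, 1)
    if w.ndim == 1:
        w = w.reshape(-1, 1)
    if z.shape[0] == 0 or w.shape[0] == 0:
        raise ValueError("mmd requires nonempty batches")
    if z.shape[1] != w.shape[1]:
        raise ValueError(
            f"dimension mismatch: z has {z.shape[1]} columns, prior has {w.shape[1]}"
        )
    gamma = 1.0 / (2.0 * bandwidth**2)
    k_zz = (_pairwise_sq_dists(z, z) * (-gamma)).exp().mean()
    k_ww = (_pairwise_sq_dists(w, w) * (-gamma)).exp().mean()
    k_zw = (_pairwise_sq_dists(z, w) * (-gamma)).exp().mean()
    out = k_zz + k_ww - 2.0 * k_zw
    return _maybe_float(out, want_float)


def median_heuristic_bandwidth(z: np.ndarray, w: np.ndarray) -> float:
    """Median pairwise distance between the two batches (the 'auto' bandwidth)."""
    d2 = _pairwise_sq_dists(Tensor(z), Tensor(w)).data
    med = float(np.median(np.sqrt(np.maximum(d2, 0.0))))
    return med if med > 0 else 1.0


def binary_cross_entropy(x: ArrayLike, x_recon: ArrayLike) -> ArrayLike:
    """BCE -(x ln x' + (1-x) ln(1-x')), summed over features, batch-averaged.

    Minimized (not zero) at x' = x; scalar BCE(0.5, 0.5) = ln 2.
    """
    want_float = not isinstance(x, Tensor) and not isinstance(x_recon, Tensor)
    xt, rt = _as_tensor(x), _as_tensor(x_recon)
    if np.any(xt.data < 0) or np.any(xt.data > 1):
        raise ValueError("binary cross-entropy requires targets in [0, 1]")
    if xt.ndim < 2:
        xt, rt = xt.reshape(1, -1), rt.reshape(1, -1)
    # Clamp the reconstruction away from {0, 1} for the logs.
    r = Tensor(np.clip(rt.data, _EPS, 1 - _EPS), _parents=(rt,),
               _backward=lambda g: ((rt, g),)) if rt.requires_grad else \
        Tensor(np.clip(rt.data, _EPS, 1 - _EPS))
    per_sample = -(xt * r.log() + (1.0 - xt) * (1.0 - r).log()).sum(axis=1)
    return _maybe_float(per_sample.mean(), want_float)


def squared_error(x: ArrayLike, x_recon: ArrayLike) -> ArrayLike:
    """Squared error summed over features, averaged over the batch."""
    want_float = not isinstance(x, Tensor) and not isinstance(x_recon, Tensor)
    xt, rt = _as_tensor(x), _as_tensor(x_recon)
    if xt.ndim < 2:
        xt, rt = xt.reshape(1, -1), rt.reshape(1, -1)
    per_sample = ((xt - rt) ** 2).sum(axis=1)
    return _maybe_float(per_sample.mean(), want_float)


def reconstruction_loss(
    methylation_pairs: Sequence,  # [(x_chrom, x'_chrom), ...] one per chromosome
    other_pairs: Sequence,  # [(x_block, x'_block), ...]
    loss_kind: str,
):
    """Block-structured reconstruction term.

    Returns ``(recon_methylation, [recon_other...])`` where the methylation
    term is the per-chromosome loss averaged over the M chromosome branches
    (zero when no methylation block is present) and each other block
    contributes its own term.
    """
    if loss_kind not in ("elbo", "mmd"):
        raise ValueError(f"unknown loss_kind {loss_kind!r}")
    per_term = binary_cross_entropy if loss_kind == "elbo" else squared_error
    meth_terms = [per_term(x, xr) for x, xr in methylation_pairs]
    if meth_terms:
        m = len(meth_terms)
        recon_meth = meth_terms[0]
        for t in meth_terms[1:]:
            recon_meth = recon_meth + t
        recon_meth = recon_meth * (1.0 / m) if isinstance(recon_meth, Tensor) else recon_meth / m
    else:
        recon_meth = 0.0
    recon_other = [per_term(x, xr) for x, xr in other_pairs]
    return recon_meth, recon_other


def softmax_cross_entropy(logits: ArrayLike, labels: np.ndarray) -> ArrayLike:
    """Mean cross-entropy of integer labels against softmax(logits)."""
    want_float = not isinstance(logits, Tensor)
    lt = _as_tensor(logits)
    labels = np.asarray(labels, dtype=int)
    n = lt.shape[0]
    lse = lt.logsumexp(axis=1)  # (n,)
    picked = lt[np.arange(n), labels]  # (n,)
    return _maybe_float((lse - picked).mean(), want_float)


def total_loss(recon_meth, recon_other, regularizer, classification,
               alpha: float = 1.0, beta: float = 0.0):
    """Compose L_total = alpha * (recon + regularizer) + beta * classification."""
    if alpha < 0 or beta < 0:
        raise ValueError("loss weights must be nonnegative")
    recon = recon_meth
    for t in recon_other:
        recon = recon + t
    total = alpha * (recon + regularizer)
    if beta > 0:
        total = total + beta * classification
    breakdown = LossBreakdown(
        recon_methylation=float(getattr(recon_meth, "data", recon_meth)),
        recon_other=[float(getattr(t, "data", t)) for t in recon_other],
        regularizer=float(getattr(regularizer, "data", regularizer)),
        classification=float(getattr(classification, "data", classification)),
        total=float(getattr(total, "data", total)),
    )
    return total, breakdown
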