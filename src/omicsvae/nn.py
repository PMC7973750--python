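"""Neural-network layers and the Adam optimizer on top of :mod:`omicsvae.autodiff`.

Fully connected blocks follow the convention used throughout the model
architecture: Linear -> batch normalization -> ReLU on hidden layers, with
the output nonlinearity (sigmoid / softmax) applied by the caller.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Parameter", "Linear", "BatchNorm1d", "DenseBlock", "Adam"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def parameters(self):
        out = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def batch_norms(self):
        """All BatchNorm1d submodules in deterministic (parameter) order."""
        out = []
        for v in vars(self).values():
            if isinstance(v, BatchNorm1d):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.batch_norms())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.batch_norms())
        return out

    def train(self):
        self._set_mode(True)

    def eval(self):
        self._set_mode(False)

    def _set_mode(self, training: bool):
        for v in vars(self).values():
            if isinstance(v, Module):
                v._set_mode(training)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item._set_mode(training)
        if hasattr(self, "training"):
            self.training = training


class Linear(Module):
    """Affine map with fan-in scaled uniform initialization (seeded)."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(in_features, out_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=(out_features,)))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    """Batch normalization with running statistics for inference mode."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered**2).mean(axis=0, keepdims=True)
            xhat = centered / (var + self.eps).sqrt()
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            n = x.shape[0]
            unbiased = var.data.ravel() * n / max(n - 1, 1)
            self.running_var = (1 - m) * self.running_var + m * unbiased
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta


class DenseBlock(Module):
    """Linear -> BatchNorm -> ReLU, the repeated unit of encoder and decoder."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 batch_norm: bool = True):
        self.linear = Linear(in_features, out_features, rng)
        self.bn = BatchNorm1d(out_features) if batch_norm else None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.linear(x)
        if self.bn is not None:
            h = self.bn(h)
        return h.relu()


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
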