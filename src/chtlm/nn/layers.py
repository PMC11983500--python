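"""Layers and modules built on the autodiff core: Conv2d, BatchNorm2d, Linear,
plus a tiny Module base class with parameter traversal and train/eval modes."""

from __future__ import annotations

import numpy as np

from .core import Tensor, conv2d, relu, sigmoid

__all__ = ["Module", "Conv2d", "BatchNorm2d", "Linear", "SGD"]


class Module:
    """Base class: recursive parameter discovery and training-mode switching."""

    def __init__(self):
        self.training = True

    @staticmethod
    def _walk(name, val):
        """Yield (name, Tensor|Module) pairs, recursing through nested
        lists/tuples (e.g. stages of blocks)."""
        if isinstance(val, (Tensor, Module)):
            yield name, val
        elif isinstance(val, (list, tuple)):
            for i, item in enumerate(val):
                yield from Module._walk(f"{name}.{i}", item)

    def named_parameters(self, prefix=""):
        """All parameter tensors (including frozen ones); SGD filters trainables."""
        for attr, val in vars(self).items():
            for name, obj in Module._walk(f"{prefix}{attr}", val):
                if isinstance(obj, Tensor):
                    yield name, obj
                else:
                    yield from obj.named_parameters(prefix=f"{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for attr, val in vars(self).items():
            for _, obj in Module._walk(attr, val):
                if isinstance(obj, Module):
                    yield from obj.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def freeze(self):
        """Make all parameters constants (no gradients)."""
        for p in self.parameters():
            p.requires_grad = False
        return self

    def state_arrays(self) -> dict:
        """Flat dict of all parameter arrays plus buffers, for persistence/hashing."""
        out = {name: p.data for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                out[f"__bn{i}.running_mean"] = m.running_mean
                out[f"__bn{i}.running_var"] = m.running_var
        return out

    def all_tensors(self):
        """Every parameter Tensor, whether or not it requires grad."""
        for _, p in self.named_parameters():
            yield p


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1, padding=0,
                 bias=True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = in_channels * k * k
        std = np.sqrt(2.0 / fan_in)  # He initialization for ReLU networks
        self.weight = Tensor(
            rng.normal(0.0, std, size=(out_channels, in_channels, k, k)).astype(np.float32),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel; running stats for eval."""

    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(num_features, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self.eps, self.momentum = eps, momentum

    def __call__(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(C)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(C)
            xhat = xc * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean.reshape(1, C, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, C, 1, 1)
            xhat = (x - mu) * (1.0 / sd)
        return xhat * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)


class Linear(Module):
    def __init__(self, in_features, out_features, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(1.0 / in_features)
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(in_features, out_features)).astype(np.float32),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr=0.01, momentum=0.9, weight_decay=0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
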