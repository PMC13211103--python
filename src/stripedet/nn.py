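"""Layers and optimizers on top of the autodiff core."""

from __future__ import annotations

import math

import numpy as np

from ._tensor import Tensor, conv2d, matmul, relu


class Module:
    """Base class: parameter discovery by attribute walk."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=key + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{key}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch on keys: {sorted(missing)}")
        for k, v in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            v.data[...] = arr

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = math.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel, stride: int = 1,
                 padding=None, bias: bool = True, rng=None):
        if isinstance(kernel, int):
            kernel = (kernel, kernel)
        kh, kw = kernel
        if padding is None:
            padding = (kh // 2, kw // 2)
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = padding
        self.weight = _he_init(rng, (out_ch, in_ch, kh, kw), in_ch * kh * kw)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng=None):
        rng = rng or np.random.default_rng(0)
        self.weight = _he_init(rng, (in_features, out_features), in_features)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def __call__(self, x):
        out = matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class ConvBnAct(Module):
    """Conv + ReLU (no batch-norm; tiny models train fine without it here)."""

    def __init__(self, in_ch, out_ch, kernel=3, stride=1, rng=None):
        self.conv = Conv2d(in_ch, out_ch, kernel, stride=stride, rng=rng)

    def __call__(self, x):
        return relu(self.conv(x))


class SGD:
    """SGD with classical momentum and decoupled-style weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, buf in zip(self.params, self._buf):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            buf *= self.momentum
            buf += g
            p.data -= self.lr * buf


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr(base_lr: float, step: int, total_steps: int,
              min_ratio: float = 0.01) -> float:
    """Cosine annealing from base_lr down to min_ratio * base_lr."""
    if total_steps <= 1:
        return base_lr
    frac = min(step, total_steps - 1) / (total_steps - 1)
    return base_lr * (min_ratio + (1 - min_ratio) * 0.5 * (1 + math.cos(math.pi * frac)))
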