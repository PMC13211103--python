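"""Multi-scale stripe local spatial attention (MS-LSAM).

The block refines a pyramid feature map in two multiplicative stages:

1. a channel gate — shared two-layer 1x1-conv MLP applied to global
   average- and max-pooled channel descriptors, summed and squashed;
2. a spatial gate built from *strip* convolutions: the channel-refined map
   is compressed to a 2-channel spatial descriptor (channel mean and max),
   convolved with horizontal 1xk and vertical kx1 kernels at three lengths
   (7, 11, 21 by default), each orientation pair fused by elementwise
   maximum, the three scales averaged, and squashed by a sigmoid.

Long thin targets excite the strip kernels along their axis far more than
square kernels can, which is the point: the gate concentrates on elongated
structures.  The three pre-sigmoid per-length responses are concatenated
into a strip stack S (B x 3 x H x W) and kept for the reconstruction loss.

A square-kernel ablation gate (3x3, CBAM-style spatial branch) and a
uniform gate (constant 0.5) live here too; they share the channel branch
and serve as controls in the edge-concentration experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .nn import Conv2d, Module

__all__ = ["MslsamParams", "MslsamOutput", "MsLsam", "build_attention"]


def _open_unit(gate):
    """Numerical guard: sigmoid is strictly inside (0,1) but float64
    rounds saturated logits onto the boundary; clamp back inside."""
    return T.clip(gate, 1e-12, 1.0 - 1e-12)


@dataclass(frozen=True)
class MslsamParams:
    channels: int = 96
    reduction: int = 16
    kernel_lengths: tuple = (7, 11, 21)
    strip_bias: bool = True
    spatial_kind: str = "strip"   # strip | square | uniform

    def __post_init__(self):
        if self.channels % self.reduction != 0:
            raise ValueError("reduction must divide channels")
        ks = self.kernel_lengths
        if list(ks) != sorted(ks) or len(set(ks)) != len(ks):
            raise ValueError("kernel_lengths must be strictly increasing")
        if any(k % 2 == 0 for k in ks):
            raise ValueError("kernel_lengths must all be odd")
        if self.spatial_kind not in ("strip", "square", "uniform"):
            raise ValueError(f"unknown spatial_kind {self.spatial_kind!r}")


@dataclass
class MslsamOutput:
    refined: Tensor        # x'' — same shape as the input
    channel_gate: Tensor   # B x C x 1 x 1, in (0,1)
    spatial_gate: Tensor   # B x 1 x H x W, in (0,1)
    strip_stack: Tensor    # S: B x 3 x H x W, pre-sigmoid strip responses


class MsLsam(Module):
    def __init__(self, params: MslsamParams = MslsamParams(), rng=None):
        rng = rng or np.random.default_rng(0)
        self.params = params
        c, r = params.channels, params.reduction
        # shared MLP for both pooled descriptors
        self.mlp1 = Conv2d(c, c // r, 1, rng=rng)
        self.mlp2 = Conv2d(c // r, c, 1, rng=rng)
        self.strip_h = []
        self.strip_v = []
        if params.spatial_kind == "strip":
            for k in params.kernel_lengths:
                self.strip_h.append(Conv2d(2, 1, (1, k), padding=(0, k // 2),
                                           bias=params.strip_bias, rng=rng))
                self.strip_v.append(Conv2d(2, 1, (k, 1), padding=(k // 2, 0),
                                           bias=params.strip_bias, rng=rng))
                self._window_init(self.strip_h[-1], rng)
                self._window_init(self.strip_v[-1], rng)
        elif params.spatial_kind == "square":
            self.square = Conv2d(2, 1, 3, bias=params.strip_bias, rng=rng)
            self._window_init(self.square, rng)

    @staticmethod
    def _window_init(conv, rng):
        """Structured start for every spatial-gate convolution: an
        averaging window over the channel-max descriptor plus small noise.

        All scales then begin sign-aligned and object-positive, so the
        averaged multi-scale response is meaningful from the first step;
        with generic random signs the scales start mutually cancelling,
        which short training runs cannot always repair.  Applied
        identically to the strip and square variants.
        """
        w = conv.weight.data
        w[...] = rng.normal(0.0, 0.01, size=w.shape)
        w[0, 1] += 1.0 / (w.shape[2] * w.shape[3])
        if conv.bias is not None:
            conv.bias.data[...] = 0.0

    # -- stage 1: channel gate ------------------------------------------
    def channel_gate(self, x: Tensor):
        x = T.as_tensor(x)
        if x.shape[1] != self.params.channels:
            raise ValueError(
                f"expected {self.params.channels} channels, got {x.shape[1]}")
        avg = x.mean(axis=(2, 3), keepdims=True)
        mx = x.max(axis=(2, 3), keepdims=True)
        gate = _open_unit(T.sigmoid(self._mlp(avg) + self._mlp(mx)))
        return x * gate, gate

    def _mlp(self, v: Tensor) -> Tensor:
        return self.mlp2(T.relu(self.mlp1(v)))

    # -- stage 2: spatial gate ------------------------------------------
    @staticmethod
    def spatial_descriptor(xp: Tensor) -> Tensor:
        """2-channel map: per-pixel channel mean and channel max."""
        xp = T.as_tensor(xp)
        return T.concat([xp.mean(axis=1, keepdims=True),
                         xp.max(axis=1, keepdims=True)], axis=1)

    def strip_response(self, fs: Tensor, k: int) -> Tensor:
        """A(k): elementwise max of horizontal and vertical strip convs."""
        if k % 2 == 0:
            raise ValueError("strip kernel length must be odd")
        try:
            idx = self.params.kernel_lengths.index(k)
        except ValueError:
            raise ValueError(f"{k} not in kernel_lengths") from None
        fs = T.as_tensor(fs)
        return T.maximum(self.strip_h[idx](fs), self.strip_v[idx](fs))

    def spatial_gate(self, xp: Tensor):
        """Returns (gate, strip stack S); S holds the pre-sigmoid A(k)."""
        xp = T.as_tensor(xp)
        fs = self.spatial_descriptor(xp)
        B, _, H, W = xp.shape
        kind = self.params.spatial_kind
        if kind == "strip":
            responses = [self.strip_response(fs, k)
                         for k in self.params.kernel_lengths]
            stack = T.concat(responses, axis=1)
            fused = stack.mean(axis=1, keepdims=True)
            gate = _open_unit(T.sigmoid(fused))
        elif kind == "square":
            resp = self.square(fs)
            stack = T.concat([resp, resp, resp], axis=1)
            gate = _open_unit(T.sigmoid(resp))
        else:  # uniform control: constant gate, zero stack
            gate = Tensor(np.full((B, 1, H, W), 0.5))
            stack = Tensor(np.zeros((B, 3, H, W)))
        return gate, stack

    def forward(self, x: Tensor) -> MslsamOutput:
        xp, cgate = self.channel_gate(x)
        sgate, stack = self.spatial_gate(xp)
        return MslsamOutput(refined=xp * sgate, channel_gate=cgate,
                            spatial_gate=sgate, strip_stack=stack)

    __call__ = forward


def build_attention(channels: int, kind: str, kernel_lengths=(7, 11, 21),
                    reduction: int = 16, rng=None) -> MsLsam:
    return MsLsam(MslsamParams(channels=channels, reduction=reduction,
                               kernel_lengths=tuple(kernel_lengths),
                               spatial_kind=kind), rng=rng)
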