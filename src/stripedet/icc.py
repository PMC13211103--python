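"""Dual-level RoI contrastive regularization (ICC).

For every annotated object in a pair of augmented views, a fixed-size
patch is RoI-aligned from the two intermediate pyramid levels (strides 16
and 32), pooled to a 96-vector, and the two levels averaged.  Two MLP
projection heads with identical architecture but separate weights map the
fused vector to unit-norm 128-d embeddings:

* the *instance* head, trained with a supervised contrastive loss whose
  labels are instance ids — the two views of the same object are mutual
  positives (temperature 0.07, selective matching);
* the *class* head, trained with the same loss over class labels, pulling
  same-class objects together more loosely (temperature 0.15).

The combined objective is  L_ICC = w_inst * L_inst + w_cls * L_cls  with
default weights 0.05 and 0.3.

The supervised contrastive loss here excludes the anchor's self-similarity
from the denominator and skips anchors without positives; the variant that
keeps the self term is available via ``include_self=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .nn import Linear, Module

__all__ = ["IccConfig", "ProjectionHead", "IccModule", "roi_fuse",
           "supcon_loss"]


@dataclass(frozen=True)
class IccConfig:
    roi_output: int = 7
    embed_dim: int = 128
    hidden_dim: int = 256
    feature_dim: int = 96
    tau_inst: float = 0.07
    tau_cls: float = 0.15
    w_inst: float = 0.05
    w_cls: float = 0.3
    include_self: bool = False

    def __post_init__(self):
        if self.tau_inst <= 0 or self.tau_cls <= 0:
            raise ValueError("temperatures must be positive")
        if self.w_inst < 0 or self.w_cls < 0:
            raise ValueError("loss weights must be non-negative")


def _rois_array(boxes, batch_idx=None) -> np.ndarray:
    """Normalize box input to an (N,5) array of (batch, x1, y1, x2, y2)."""
    rows = []
    for i, b in enumerate(boxes):
        if hasattr(b, "x1"):
            coords = (b.x1, b.y1, b.x2, b.y2)
        else:
            coords = tuple(b)
        bi = 0 if batch_idx is None else batch_idx[i]
        rows.append((bi,) + coords)
    arr = np.asarray(rows, dtype=np.float64).reshape(-1, 5)
    if np.any(arr[:, 3] <= arr[:, 1]) or np.any(arr[:, 4] <= arr[:, 2]):
        raise ValueError("degenerate RoI (zero area)")
    return arr


def roi_fuse(f3: Tensor, f4: Tensor, boxes, batch_idx=None,
             roi_output: int = 7) -> Tensor:
    """Average of the pooled RoI patches from the two pyramid levels.

    f3, f4: stride-16 and stride-32 levels, equal channel count.
    Returns (N, C) feature vectors: each RoI patch is RoI-aligned to
    roi_output^2 bins, globally average-pooled, and the two levels averaged.
    """
    f3, f4 = T.as_tensor(f3), T.as_tensor(f4)
    if f3.shape[1] != f4.shape[1]:
        raise ValueError("pyramid levels must share channel count")
    rois = _rois_array(boxes, batch_idx)
    v3 = T.roi_align(f3, rois, roi_output).mean(axis=(2, 3))
    v4 = T.roi_align(f4, rois, roi_output).mean(axis=(2, 3))
    return (v3 + v4) * 0.5


class ProjectionHead(Module):
    """FC(96->256) + ReLU + FC(256->128) + l2 normalization."""

    def __init__(self, cfg: IccConfig = IccConfig(), rng=None):
        rng = rng or np.random.default_rng(0)
        self.fc1 = Linear(cfg.feature_dim, cfg.hidden_dim, rng=rng)
        self.fc2 = Linear(cfg.hidden_dim, cfg.embed_dim, rng=rng)

    def __call__(self, v: Tensor) -> Tensor:
        v = T.as_tensor(v)
        if v.ndim == 1:
            v = v.reshape(1, -1)
        z = self.fc2(T.relu(self.fc1(v)))
        norm = (T.tsum(z * z, axis=1, keepdims=True) + 1e-12) ** 0.5
        return z / norm


def supcon_loss(Z, labels, tau: float, include_self: bool = False) -> Tensor:
    """Supervised contrastive loss over unit-norm embeddings.

    Per anchor i with positives P(i) = {j != i : label_j == label_i}:
    -log( sum_{j in P(i)} exp(z_i.z_j / tau) / sum_{k != i} exp(z_i.z_k / tau) ),
    averaged over anchors with non-empty P(i); anchors without positives
    are skipped, and the loss is 0 when no anchor contributes.  With
    ``include_self`` the denominator runs over all k including the anchor.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    if not isinstance(Z, Tensor):
        Z = Tensor(np.stack([np.asarray(z, dtype=np.float64) for z in Z]))
    n = Z.shape[0]
    if n < 2:
        raise ValueError("need at least two embeddings")
    labels = np.asarray(labels)
    if labels.shape[0] != n:
        raise ValueError("labels length mismatch")

    sim = T.matmul(Z, T.transpose(Z, (1, 0))) * (1.0 / tau)
    # constant row-shift for numerical stability; cancels exactly in the ratio
    shift = sim.data.max(axis=1, keepdims=True)
    E = T.exp(sim - Tensor(shift))

    eye = np.eye(n)
    pos_mask = (labels[:, None] == labels[None, :]).astype(np.float64) * (1 - eye)
    den_mask = np.ones((n, n)) if include_self else (1 - eye)

    contributing = np.nonzero(pos_mask.sum(axis=1) > 0)[0]
    if contributing.size == 0:
        return Tensor(0.0)
    pos_sum = T.tsum(E * Tensor(pos_mask), axis=1)
    den_sum = T.tsum(E * Tensor(den_mask), axis=1)
    per_anchor = T.log(den_sum[contributing]) - T.log(pos_sum[contributing])
    return per_anchor.mean()


class IccModule(Module):
    """Holds the two projection heads and composes the full objective."""

    def __init__(self, cfg: IccConfig = IccConfig(), rng=None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.head_inst = ProjectionHead(cfg, rng=rng)
        self.head_cls = ProjectionHead(cfg, rng=rng)

    def embed(self, f3, f4, boxes, batch_idx=None):
        v = roi_fuse(f3, f4, boxes, batch_idx, roi_output=self.cfg.roi_output)
        return self.head_inst(v), self.head_cls(v)

    def loss(self, feats1, feats2, boxes1, boxes2,
             batch_idx1=None, batch_idx2=None):
        """L_ICC and its two branches for a pair of augmented views.

        feats1/feats2: (F3, F4) tuples of stride-16/32 refined levels from
        each view's forward pass; boxes1/boxes2 share instance ids.
        Returns (L_ICC, L_inst, L_cls) as scalar Tensors.
        """
        if len(boxes1) == 0 or len(boxes2) == 0:
            zero = Tensor(0.0)
            return zero, zero, zero
        zi1, zc1 = self.embed(*feats1, boxes1, batch_idx1)
        zi2, zc2 = self.embed(*feats2, boxes2, batch_idx2)
        inst_labels = np.concatenate([[b.instance_id for b in boxes1],
                                      [b.instance_id for b in boxes2]])
        cls_labels = np.concatenate([[b.label for b in boxes1],
                                     [b.label for b in boxes2]])
        z_inst = T.concat([zi1, zi2], axis=0)
        z_cls = T.concat([zc1, zc2], axis=0)
        l_inst = supcon_loss(z_inst, inst_labels, self.cfg.tau_inst,
                             include_self=self.cfg.include_self)
        l_cls = supcon_loss(z_cls, cls_labels, self.cfg.tau_cls,
                            include_self=self.cfg.include_self)
        l_icc = self.cfg.w_inst * l_inst + self.cfg.w_cls * l_cls
        return l_icc, l_inst, l_cls
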