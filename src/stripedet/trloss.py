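"""Topology reconstruction loss (TR-Loss) on the strip-response stacks.

Occlusion removes part of an elongated object's response.  TR-Loss
simulates that during training: for each ground-truth box, the box is
projected onto its assigned pyramid level, the 3-channel strip-response
crop is taken, a rectangular mask (25% of the crop's height and width,
minimum 2 pixels per side, uniformly placed, shared across channels) is
"occluded" by replacing the masked values with each channel's mean over
the visible positions, and the squared deviation from the original crop,
averaged over all 3*h*w entries, is penalized.  The batch loss is the mean
over accepted RoIs and zero when there are none.  It is a training-only
term and is dropped at inference.

The fill is a differentiable function of the visible responses, so
gradients flow through both the crop and the reconstruction; pass
``detach_target=True`` to stop gradients through the fill.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._tensor import Tensor

__all__ = ["TrConfig", "project_box", "assign_level", "sample_mask",
           "reconstruct", "tr_loss"]


@dataclass(frozen=True)
class TrConfig:
    mask_ratio: float = 0.25
    min_mask_px: int = 2
    min_roi_px: int = 4
    w_tr: float = 0.1
    detach_target: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.mask_ratio < 1.0:
            raise ValueError("mask_ratio must lie in (0,1)")
        if self.min_mask_px < 1:
            raise ValueError("min_mask_px must be >= 1")


def project_box(box, stride: int, extent=None):
    """Project a pixel box onto a feature grid: divide by stride, floor the
    top-left, ceil the bottom-right, clip to the level extent.

    extent: (width, height) of the feature map, optional.  Returns the
    integer feature-space box, or None when clipping empties it (the RoI is
    dropped, not fatal).
    """
    x1, y1, x2, y2 = box
    fx1 = math.floor(x1 / stride)
    fy1 = math.floor(y1 / stride)
    fx2 = math.ceil(x2 / stride)
    fy2 = math.ceil(y2 / stride)
    if extent is not None:
        w, h = extent
        fx1, fy1 = max(fx1, 0), max(fy1, 0)
        fx2, fy2 = min(fx2, w), min(fy2, h)
    if fx2 <= fx1 or fy2 <= fy1:
        return None
    return (fx1, fy1, fx2, fy2)


def assign_level(box, strides=(8, 16, 32, 64)) -> int:
    """Closest stride-to-scale match: minimize |log2(scale / (8*stride))|
    where scale = sqrt(box area); ties go to the smaller stride."""
    x1, y1, x2, y2 = box
    scale = math.sqrt(max((x2 - x1) * (y2 - y1), 1e-12))
    dists = [abs(math.log2(scale / (8.0 * s))) for s in strides]
    return int(np.argmin(dists))


def accepts_roi(fbox, min_roi_px: int = 4) -> bool:
    """Minimum feature-size rule: for elongated targets it is enough that
    either side of the projected box reaches the threshold."""
    x1, y1, x2, y2 = fbox
    return max(x2 - x1, y2 - y1) >= min_roi_px


def _mask_side(full: int, cfg: TrConfig) -> int:
    want = math.floor(cfg.mask_ratio * full + 0.5)  # round half up
    return min(full, max(cfg.min_mask_px, want))


def sample_mask(h: int, w: int, cfg: TrConfig, rng) -> np.ndarray:
    """One solid rectangle, 25%-with-min-2 per side, uniform placement."""
    mh = _mask_side(h, cfg)
    mw = _mask_side(w, cfg)
    y0 = int(rng.integers(0, h - mh + 1))
    x0 = int(rng.integers(0, w - mw + 1))
    mask = np.zeros((h, w), dtype=bool)
    mask[y0:y0 + mh, x0:x0 + mw] = True
    return mask


def reconstruct(s_roi, mask: np.ndarray, detach_target: bool = False):
    """Fill masked positions with each channel's visible mean.

    s_roi: (3, h, w) Tensor or array; mask: (h, w) boolean.  Returns the
    reconstructed (3, h, w) Tensor, or None when nothing is visible (the
    RoI is then excluded from the loss).
    """
    s_roi = T.as_tensor(s_roi)
    vis = (~mask).astype(np.float64)
    n_vis = vis.sum()
    if n_vis == 0:
        return None
    src = s_roi.detach() if detach_target else s_roi
    fill = T.tsum(src * Tensor(vis), axis=(1, 2), keepdims=True) * (1.0 / n_vis)
    return s_roi * Tensor(vis) + fill * Tensor(mask.astype(np.float64))


def tr_loss(strip_stacks, gt_boxes, cfg: TrConfig, rng,
            strides=(8, 16, 32, 64)):
    """Mean reconstruction error over all accepted RoIs in a batch.

    strip_stacks: per-level list of (B, 3, H, W) strip-stack Tensors from
    one forward pass; gt_boxes: per-image lists of pixel boxes on the
    network input.  Returns a scalar Tensor (0 when no RoI is accepted).
    """
    terms = []
    for b, boxes in enumerate(gt_boxes):
        for box in boxes:
            lvl = assign_level(box, strides)
            stack = strip_stacks[lvl]
            H, W = stack.shape[2], stack.shape[3]
            fbox = project_box(box, strides[lvl], extent=(W, H))
            if fbox is None or not accepts_roi(fbox, cfg.min_roi_px):
                continue
            x1, y1, x2, y2 = fbox
            crop = stack[b, :, y1:y2, x1:x2]
            mask = sample_mask(y2 - y1, x2 - x1, cfg, rng)
            if mask.all():
                continue  # whole RoI masked: no visible statistics
            recon = reconstruct(crop, mask, detach_target=cfg.detach_target)
            if recon is None:
                continue
            diff = recon - crop
            terms.append((diff * diff).mean())
    if not terms:
        return Tensor(0.0)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))
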