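"""Reproducible study protocols built from the package's pieces.

Two scaled-down experiments mirror the headline qualitative findings on
synthetic scenes sized for a single CPU:

* ``run_ecs_comparison`` — train the tiny detector twice under identical
  seeds, once with the stripe spatial gate and once with a 3x3
  square-kernel gate, then compare the mean Edge Concentration Score per
  aspect-ratio bucket on held-out scenes.  Stripe attention should
  concentrate more on elongated-object boundaries (buckets G3/G4).  A
  uniform-gate control (constant attention) pins the metric's null value
  at exactly 1.
* ``run_overfit`` — capacity and wiring sanity: the tiny model should
  overfit four fixed scenes to perfect AP@50, and enabling the
  contrastive and reconstruction objectives should leave every logged
  component finite while detection loss still falls.

Problem sizes (128x128 scenes, a few hundred optimization steps, Adam)
are the package's CPU-scale protocol; see docs/methods.md.
"""

from __future__ import annotations

import math
import tempfile
from pathlib import Path

import numpy as np

from ._tensor import Tensor, no_grad
from .detector import ModelConfig, build_model, image_to_input, predict, train
from .icc import supcon_loss
from .metrics import ar_bucket, ecs, map_suite
from .synthetic import SceneSpec, generate_dataset
from .trloss import TrConfig, assign_level, reconstruct, sample_mask
from .detector import load_voc_dataset, total_loss

__all__ = ["analytic_loss_values", "mask_statistics", "run_ecs_comparison",
           "run_overfit", "tiny_model_config", "training_scene_spec"]


def tiny_model_config(spatial_kind: str = "strip") -> ModelConfig:
    """CPU-scale configuration used by the experiment protocols."""
    return ModelConfig(spatial_kind=spatial_kind, backbone_width=12,
                       head_width=32, score_thr=0.5)


def training_scene_spec(image_size: int = 128, seed: int = 0,
                        ar_range=(1.0, 12.0)) -> SceneSpec:
    """Scene family spanning aspect-ratio buckets G1-G4 with moderate
    occlusion and clutter."""
    return SceneSpec(image_size=image_size, n_objects=(2, 4),
                     ar_range=ar_range, curvature_range=(0.0, 15.0),
                     occlusion_fraction_range=(0.0, 0.35),
                     clutter_level=0.5, seed=seed,
                     length_frac_range=(0.25, 0.55))


# ------------------------------------------------------------- analytic

def analytic_loss_values() -> dict:
    """Closed-form fixtures evaluated through the package's loss code."""
    e1 = np.zeros(128)
    e1[0] = 1.0
    e2 = np.zeros(128)
    e2[1] = 1.0
    orth = supcon_loss([e1, e1, e2], [0, 0, 1], tau=1.0).item()
    same = supcon_loss([e1, e1, e1], [0, 0, 1], tau=1.0).item()

    crop = np.ones((3, 4, 4))
    mask = np.zeros((4, 4), dtype=bool)
    mask[1:3, 1:3] = True
    crop[:, mask] = 5.0
    recon = reconstruct(Tensor(crop), mask)
    diff = recon - Tensor(crop)
    tr_value = (diff * diff).mean().item()

    total = total_loss(Tensor(1.0), Tensor(1.0), Tensor(1.0), Tensor(1.0),
                       ModelConfig()).item()
    return {"supcon_orthogonal_pair": orth, "supcon_identical": same,
            "tr_worked_example": tr_value, "total_loss_ones": total}


def mask_statistics(seed: int = 0, n_draws: int = 10_000) -> dict:
    """Mask sizing rule on enumerated RoI shapes + placement uniformity.

    Returns the worst absolute deviation of the mask side from the
    25%-with-min-2 rule (0 when exact) and the chi-square p-value for
    uniform placement of the 2x2 mask over an 8x8 RoI.
    """
    from scipy import stats

    cfg = TrConfig()
    rng = np.random.default_rng(seed)
    worst = 0
    for h in range(2, 33):
        mask = sample_mask(h, h, cfg, rng)
        side = int(mask.sum(axis=0).max())
        expected = min(h, max(cfg.min_mask_px, math.floor(0.25 * h + 0.5)))
        worst = max(worst, abs(side - expected))

    counts = np.zeros((7, 7))
    for _ in range(n_draws):
        mask = sample_mask(8, 8, cfg, rng)
        ys, xs = np.nonzero(mask)
        counts[ys.min(), xs.min()] += 1
    chi2_p = float(stats.chisquare(counts.ravel()).pvalue)
    return {"mask_rule_worst_deviation": worst, "placement_chi2_p": chi2_p}


# ------------------------------------------------------------- training

def _gate_maps(model, image: np.ndarray):
    with no_grad():
        out = model(image_to_input(image))
    return [g.data[0, 0] for g in out.gates]


def _bucket_ecs(model, scenes, strides) -> dict:
    acc = {b: [] for b in ("G1", "G2", "G3", "G4")}
    for scene in scenes:
        maps = _gate_maps(model, scene.image)
        for box in scene.boxes:
            lvl = assign_level(box, strides)
            per_box, _ = ecs(maps[lvl], [box], strides[lvl])
            if per_box[0] is not None:
                acc[ar_bucket(box)].append(per_box[0])
    return {b: (float(np.mean(v)) if v else None) for b, v in acc.items()}


def run_ecs_comparison(seed: int = 0, n_train: int = 200, n_val: int = 40,
                       image_size: int = 256, epochs: int = 16,
                       batch_size: int = 8, lr: float = 3e-3,
                       work_dir=None) -> dict:
    """Train stripe vs square spatial gates under identical seeds and
    score boundary concentration per aspect-ratio bucket on held-out
    scenes.  Returns per-variant bucket-mean ECS dictionaries."""
    if work_dir is None:
        work_dir = tempfile.mkdtemp(prefix="stripedet_ecs_")
    work_dir = Path(work_dir)
    spec = training_scene_spec(image_size=image_size, seed=seed)
    n_total = n_train + n_val
    generate_dataset(spec, n_total, work_dir / "data",
                     train_frac=n_train / n_total)
    val_scenes = load_voc_dataset(work_dir / "data", "val")

    results = {}
    for kind in ("strip", "square"):
        cfg = tiny_model_config(spatial_kind=kind)
        model, _, log = train(work_dir / "data", cfg, seed=seed,
                              epochs=epochs, batch_size=batch_size,
                              use_icc=False, use_tr=True,
                              optimizer="adam", lr=lr)
        results[kind] = _bucket_ecs(model, val_scenes, cfg.strides)
        results[f"{kind}_final_loss"] = log[-1]["L_total"]
    uniform_cfg = tiny_model_config(spatial_kind="uniform")
    uniform_model = build_model(uniform_cfg, seed=seed)
    results["uniform"] = _bucket_ecs(uniform_model, val_scenes,
                                     uniform_cfg.strides)
    return results


def run_overfit(seed: int = 0, steps: int = 500, image_size: int = 128,
                lr: float = 3e-3, icc_steps: int = 60, work_dir=None) -> dict:
    """Overfit four fixed scenes; then a short run with the auxiliary
    objectives switched on."""
    if work_dir is None:
        work_dir = tempfile.mkdtemp(prefix="stripedet_overfit_")
    work_dir = Path(work_dir)
    spec = SceneSpec(image_size=image_size, n_objects=(2, 3),
                     ar_range=(2.0, 7.0), curvature_range=(0.0, 10.0),
                     occlusion_fraction_range=(0.0, 0.15),
                     clutter_level=0.4, seed=seed,
                     length_frac_range=(0.3, 0.5))
    generate_dataset(spec, 4, work_dir / "data", train_frac=1.0)
    scenes = load_voc_dataset(work_dir / "data", "train")

    cfg = tiny_model_config("strip")
    model, _, log = train(work_dir / "data", cfg, seed=seed, epochs=steps,
                          batch_size=4, use_icc=False, use_tr=False,
                          optimizer="adam", lr=lr)
    dets = [predict(model, s.image, score_thr=0.5, nms_iou=0.5)
            for s in scenes]
    gts = [(s.boxes, s.labels) for s in scenes]
    report = map_suite(dets, gts, cfg.num_classes)

    aux_model, _, aux_log = train(work_dir / "data", cfg, seed=seed,
                                  epochs=icc_steps, batch_size=4,
                                  use_icc=True, use_tr=True,
                                  optimizer="adam", lr=lr)
    components = [v for entry in aux_log for v in entry.values()]
    det_first = aux_log[0]["L_cls"] + aux_log[0]["L_loc"]
    det_last = aux_log[-1]["L_cls"] + aux_log[-1]["L_loc"]
    return {
        "ap50": report.ap50,
        "map": report.map,
        "plain_final_loss": log[-1]["L_total"],
        "aux_components_finite": bool(np.all(np.isfinite(components))),
        "aux_det_loss_first": det_first,
        "aux_det_loss_last": det_last,
    }
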