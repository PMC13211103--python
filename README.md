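# stripedet

A detection toolkit for **elongated, occlusion-prone plant organs** —
think slender fruit (aspect ratios of 5:1 to 10:1) photographed in
cluttered field canopies, partially hidden behind leaves.  Standard
detectors built on square convolutions blur the long, parallel boundary
cues such objects depend on; occlusion fragments the visible evidence;
and large within-class shape variation scatters the feature space.  The
package implements three mechanisms that target those failure modes,
wired into a small anchor-free detector, together with the evaluation
machinery needed to measure their effect — all exercisable end-to-end on
built-in synthetic field scenes, so no external dataset is required.

## The core mechanisms

**Multi-scale stripe spatial attention (MS-LSAM).**  Each pyramid level
(strides 8/16/32/64, 96 channels) is refined by a channel gate

M_CA(x) = σ(MLP(F_avg) + MLP(F_max)),  x′ = x ⊙ M_CA(x)

followed by a spatial gate built from *strip* convolutions on the
2-channel descriptor F_s (channel mean ‖ channel max): horizontal 1×k and
vertical k×1 kernels for k ∈ {7, 11, 21}, fused per scale by elementwise
maximum A(k) = max(A_h(k), A_v(k)), averaged across scales, and squashed:
x″ = x′ ⊙ σ(mean_k A(k)).  The pre-sigmoid responses are kept as a
3-channel strip stack S for the reconstruction loss.

**Dual-level RoI contrastive regularization (ICC).**  Every annotated box
in two independently augmented views is RoI-aligned on the stride-16/32
levels, pooled, level-averaged (F = (F⁽³⁾+F⁽⁴⁾)/2), and projected by two
MLP heads to unit-norm 128-d embeddings.  A supervised contrastive loss
ties the two views of each instance together (τ_inst = 0.07) and pulls
same-class objects into a looser cluster (τ_cls = 0.15):
L_ICC = 0.05·L_inst + 0.3·L_cls.

**Topology reconstruction loss (TR-Loss).**  For each ground-truth RoI on
the strip stack, a rectangular mask (25% of each side, min 2 px) is
filled with the channel-wise mean of the visible area and the squared
deviation from the original response is penalized — synthetic occlusion
in feature space.  The total objective is

L_total = L_cls + L_loc + 0.35·L_ICC + 0.1·L_TR.

**Evaluation.**  COCO-style AP (mAP@[.50:.95], AP@50, AP@75, AP@S/M/L),
aspect-ratio buckets G1 (<2.5), G2 ([2.5,5)), G3 ([5,8)), G4 (≥8), and
the **Edge Concentration Score**: ECS = μ_E/μ_G, the mean attention on a
3-pixel strip inside each box edge over the whole-map mean; ECS > 1 means
boundary-concentrated attention.

## Worked example

```python
from stripedet import SceneSpec, generate_dataset
from stripedet.experiments import tiny_model_config
from stripedet.detector import train, predict, load_voc_dataset
from stripedet.metrics import map_suite

spec = SceneSpec(image_size=128, n_objects=(2, 3), ar_range=(2.0, 7.0),
                 curvature_range=(0.0, 10.0),
                 occlusion_fraction_range=(0.0, 0.15),
                 clutter_level=0.4, seed=1, length_frac_range=(0.3, 0.5))
generate_dataset(spec, 4, "demo_data", train_frac=1.0)

cfg = tiny_model_config("strip")
model, icc, log = train("demo_data", cfg, seed=0, epochs=500, batch_size=4,
                        use_icc=False, use_tr=True, optimizer="adam", lr=3e-3)
scenes = load_voc_dataset("demo_data", "train")
dets = [predict(model, s.image, score_thr=0.5) for s in scenes]
rep = map_suite(dets, [(s.boxes, s.labels) for s in scenes], cfg.num_classes)
print(f"epoch {log[-1]['epoch']}: L_total={log[-1]['L_total']:.3f}")
print(f"AP@50={rep.ap50:.3f}")
```

prints (seeds as above, about two minutes on one CPU):

```
epoch 499: L_total=0.015
AP@50=1.000
```

i.e. after 500 optimization steps the tiny model re-detects its four
training scenes perfectly at IoU 0.5 — the wiring (pyramid, attention,
head, decoding, NMS, evaluation) is consistent end to end.

The same functionality is available from the shell:

```bash
stripedet synth --out data --n 200 --seed 7
stripedet train --data data --seed 0 --epochs 10 --out ckpt.npz
stripedet eval  --ckpt ckpt.npz --data data --report report.json
stripedet ecs   --ckpt ckpt.npz --data data
```

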