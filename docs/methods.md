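# Methods

This note documents the models, the synthetic-scene design, the numerical
choices and the scaled-down study protocol behind `stripedet`.  Nothing
here states an empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

Elongated plant organs (slender fruit with aspect ratios commonly 5:1 to
10:1) are hard for standard detectors for three related reasons: square
convolutional receptive fields mix the thin object with surrounding
clutter; partial occlusion by foliage fragments the visible evidence while
the annotation still covers the whole instance; and strong within-class
shape variation (length, thickness, curvature) scatters same-class
features.  The package implements one mechanism per failure mode and a
measurement suite for each claim.

## Components

### Stripe spatial attention (MS-LSAM)

Input: a pyramid level x ∈ R^(B×96×H×W).  Stage one is a channel gate:
global average- and max-pooled descriptors pass through a *shared*
two-layer 1×1-conv MLP (reduction r = 16, ReLU between), are summed and
squashed by a sigmoid; x′ = x ⊙ gate.  Stage two compresses x′ to a
2-channel spatial descriptor (channel mean, channel max) and applies
horizontal 1×k and vertical k×1 strip convolutions for k ∈ {7, 11, 21}
(2 input channels → 1 output each).  Per scale the two orientations fuse
by elementwise maximum; the three scales are averaged and squashed; the
refined output is x″ = x′ ⊙ gate.  The pre-sigmoid per-scale responses
are concatenated into the strip stack S ∈ R^(B×3×H×W) and retained.

Choices the design leaves open, resolved as follows:

- **Padding**: zero padding, k//2 along the kernel's long axis only, so
  every A(k) keeps the level's full H×W.  On the stride-64 level of a
  640 input (10×10) the 21-tap kernel necessarily truncates at the
  borders; accepted.
- **Strip biases**: on by default (`MslsamParams.strip_bias`).
- **Structured initialization of the spatial-gate convolutions**: each
  starts as an averaging window over the channel-max descriptor (weight
  1/k per tap on that channel, zero bias, small noise).  All scales then
  begin sign-aligned and object-positive; with generic random signs the
  three averaged scales start mutually cancelling, a symmetry accident
  that short training runs on one CPU cannot reliably repair.  The same
  rule applies to the square-kernel control, so comparisons between the
  two spatial branches stay fair.
- **S stores pre-sigmoid fused responses**, not gated features: the
  reconstruction loss needs unsquashed channel statistics.
- A 3×3 square-kernel spatial gate (`spatial_kind="square"`) and a
  constant gate (`"uniform"`, exactly 0.5 everywhere) share the channel
  branch and serve as experimental controls.

### RoI contrastive regularization (ICC)

For each annotated object in two independently augmented views of the
same image, features are RoI-aligned (7×7 bins, one bilinear sample per
bin centre, half-pixel convention, clamped borders) from the stride-16
and stride-32 refined levels, average-pooled to 96-vectors and
level-averaged.  Two projection heads (96→256→128, ReLU, l2
normalization; identical architecture, separate weights) produce
instance and class embeddings.  Both branches use the supervised
contrastive loss; labels are instance ids (τ = 0.07) and class ids
(τ = 0.15); the combination is L_ICC = 0.05·L_inst + 0.3·L_cls.

The loss excludes the anchor's self term from the denominator and skips
anchors with no positives (mean over contributing anchors, 0 when none);
the literal variant with the self term kept is available via
`include_self=True`.  Embeddings come from post-attention refined
features.  RoIs are ground-truth boxes, never predicted proposals.

### Reconstruction loss (TR-Loss)

Each ground-truth box is assigned to the pyramid level minimizing
|log2(scale/(8·stride))| with scale = sqrt(area) — i.e. the level where
the box spans roughly 8 feature pixels — ties to the smaller stride.  The
box is projected by floor/ceil division and accepted when *either*
projected side reaches 4 feature pixels (elongated boxes are thin by
nature).  A rectangular mask of 25% of each crop side (round half up,
minimum 2 px, clamped to the crop) is placed uniformly; masked positions
of the 3-channel strip crop are replaced by each channel's mean over the
visible positions; the loss is the mean squared deviation over all 3·h·w
entries, averaged over accepted RoIs, 0 when none.  Gradients flow
through both the crop and the fill (`detach_target=False` by default).
Fully-masked crops (possible only for 2×2 RoIs) are excluded.

### Detector and total objective

The backbone/neck/head are deliberately plain carriers honoring the
pyramid contract — strides 8/16/32/64, all levels 96 channels (80², 40²,
20², 10² on a 640 input): a strided 3×3-conv backbone, 1×1 laterals with
top-down nearest-neighbour addition, and a shared head (3×3 conv tower,
1×1 classification and box-distance branches).  Each ground truth trains
the cell containing its centre on its assigned level; classification is a
sigmoid focal loss (α 0.25, γ 2, normalized by positive count),
localization an IoU loss on exp-decoded left/top/right/bottom distances.
L_total = L_cls + L_loc + 0.35·L_ICC + 0.1·L_TR.  The auxiliary terms are
training-only; inference decodes, thresholds and applies greedy per-class
NMS.  A non-finite loss component aborts the step with diagnostics.
All differentiable code runs on the package's own float64 reverse-mode
autodiff core (`stripedet._tensor`); no external deep-learning framework
is used.

Training defaults mirror common practice for this detector family (SGD,
momentum 0.937, weight decay 5e-4, cosine schedule to 1% of the base
rate); the learning rate is deliberately config-exposed.  The scaled-down
experiment protocols use Adam at 3e-3, which converges far faster at
tiny-model scale on CPU.

## Synthetic scenes

`SceneSpec` renders seeded field scenes: capsules (rectangles with
semicircular caps, optionally bent along a circular arc) with controlled
aspect ratio, drawn over a cluttered green background, then partially
covered by leaf-hued occluder ellipses until a target coverage fraction
is reached.  Key design points:

- **Boxes annotate the pre-occlusion extent** (the whole fruit, not the
  visible fragment) and are tight bounding boxes of the rendered mask;
  per-object visibility fractions are recorded.
- **Axis-aligned midlines** (horizontal or vertical): the annotated-box
  aspect ratio then tracks the sampled capsule aspect ratio, so bucket
  membership (G1–G4) is controllable from the spec.  Rotated rendering
  would decouple box AR from object AR.
- **Appearance ambiguity**: background leaf-blob density scales with
  image area, and scenes contain unannotated broad (AR ≲ 1.8) distractor
  masses rendered with the same green palettes and shading as the
  targets.  Local colour therefore does not separate target from
  background — elongation does — which is the field condition the
  scenes are meant to emulate.  Class 2 is red and remains locally
  distinctive, as ripe fruit is.
- Coordinates are 0-based half-open throughout; the VOC 1-based closed
  convention exists only at the XML boundary.
- Everything (pixels and XML bytes) is a pure function of
  (spec, n_images).

What the scenes do *not* model: photorealistic texture, wrinkles,
specular highlights, 3-D canopy geometry, perspective, or realistic
occluder shape statistics.  Passing tests on these scenes demonstrates
that the mechanisms behave as designed under controlled geometry and
appearance ambiguity — not field-level accuracy.

## Scaled-down study protocol

Sized for a single CPU; chosen once as the package's protocol.

- **Edge-concentration comparison** (`run_ecs_comparison`): 240 scenes at
  256×256 spanning G1–G4 (AR 1–12, curvature 0–15°, occlusion 0–35%,
  clutter 0.5); 200 train / 40 held out.  Two identically seeded
  trainings — stripe gate vs 3×3 square gate — for 16 epochs, batch 8,
  Adam 3e-3, detection + TR losses.  Mean ECS per bucket is computed on
  the held-out scenes, each ground truth scored on the spatial gate of
  its assigned level; the uniform-gate control pins the null at exactly 1.
  Expected outcome: the square gate's concentration degrades toward the
  high-AR buckets while the stripe gate's holds or rises, leaving the
  stripe gate ahead in G3/G4.
- **Capacity sanity** (`run_overfit`): four 128×128 scenes, 500 steps of
  plain detection training (Adam 3e-3) must reach AP@50 = 1.0 on those
  scenes; a further short run with ICC and TR enabled must keep every
  logged component finite with the detection loss still decreasing.
- Attention-oracle checks run on 2×96×12×12 inputs (100 draws), the
  evaluation-suite cross-check on 25 random small fixtures, RoI fusion
  against direct bilinear sampling on 20 fixtures.

## Numerical notes

- All tensors are float64; the attention oracle comparisons use absolute
  tolerances (1e-5 attention, 1e-4 RoI fusion, 1e-9 evaluation suite).
- Gates are clamped to [1e-12, 1-1e-12] after the sigmoid: the function
  is strictly inside (0,1) but float64 rounds saturated logits onto the
  boundary.
- l2 normalization guards with eps = 1e-12; focal-loss logs add the same
  epsilon; logits are clipped to ±30 before the sigmoid inside losses.
- The supervised contrastive loss subtracts each anchor's row maximum
  before exponentiation; the shift cancels exactly in the ratio.

## Evaluation conventions

- AP: COCO-style — greedy highest-score-first matching, each ground
  truth matched at most once, 101-point interpolated PR area; mAP
  averages classes and IoU thresholds 0.50:0.05:0.95; classes absent
  from the ground truth are excluded from the mean; AP is undefined
  (excluded), not zero, when a selection contains no ground truth.
- Size and bucket breakdowns use ignore semantics (out-of-selection
  ground truths ignored; detections matching only ignored ground truths,
  or themselves out of selection while unmatched, are not false
  positives).
- ECS: boxes project to the map grid with the same floor/ceil rule as
  the reconstruction loss; the strip E lies *inside* the box edges
  (3 map pixels wide, corners counted once); ECS = μ_E/μ_G.  Instance
  mean, not image mean, aggregates a bucket.
- Aspect ratio is long side / short side of the annotated box.

## Known limitations

- The autodiff core is eager and unoptimized; training beyond tiny
  models/resolutions is slow by design.
- The center-cell assignment gives each object a single positive cell;
  crowded scenes with coincident centres on one level drop a target.
- The ECS comparison is a trend check on synthetic scenes at small map
  resolutions (32² and below), where long strip kernels smear responses
  over a large fraction of the map; absolute ECS values are not
  comparable to full-scale results.
- Curvature handling stops at circular-arc bending; strongly articulated
  shapes are out of scope.
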