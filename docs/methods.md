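# Methods

`pestlite` implements a lightweight one-stage detector for greenhouse pest
and disease imagery, built around three architectural ideas — cross-scale
lite attention (CSLA), block-level substitution distillation (BLSD) and a
small-object enhancement branch (SOEB) — together with the surrounding
toolchain: a box-aware augmentation suite, a synthetic scene generator, a
COCO-style metric suite and a MAC-counting profiler.  This note records the
model as implemented, the defaults and why they hold, and what the desk-
scale experiments do and do not establish.

## Numerical core

No GPU framework is assumed: the networks run on a compact reverse-mode
autodiff engine over float64 numpy arrays (`pestlite.nn`).  Convolution is
im2col + matmul with full gradient support for strides, padding, groups
(hence depthwise) and per-sample dynamic kernels.  Float64 everywhere makes
every forward and training run bitwise reproducible from its seed; the
engine is deliberately small and is validated against finite differences
in the test suite.

## Backbone

A four-stage feature extractor at strides {4, 8, 16, 32} with channel
profile {64, 96, 128, 192} over (2, 2, 6, 2) = 12 blocks.  Stages 1–3 use
convolutional mixing blocks (LayerNorm → depthwise 3×3 → pointwise expand
×2 → GELU → pointwise project, residual); the two stride-32 blocks are full
pre-norm transformer blocks (4-head self-attention + MLP ×4), where the
400-token grid at 640² input makes dense attention affordable.  The stem is
a full 3×3 stride-2 convolution to 24 channels followed by a
depthwise-separable stride-2 step to 64.  A stride-32 "semantic top"
(1×1 to 504 channels + one FFN block) supplies a global context vector and
image-level class logits.  The distillation student is the same structure
at half width, {32, 48, 64, 96}.

Every width scales jointly through `width_ratio`; the shipped default
(ratio 1) is the calibrated deployed profile, and desk-scale experiments
use ratio 0.25.

### Width/depth calibration

The block internals, per-stage depths, stem, head and semantic-top widths
are free knobs; they were fixed once by calibrating the profiler's counts
of the assembled model at 640×640 against the published complexity figures
for this architecture class: 5.6 G FLOPs / 3.2 M params at CSLA ratio 4 and
SOEB kernels {3,5,7}; 6.8 and 4.9 G FLOPs at ratios 2 and 16; 2.8 M params
at kernel set {3}.  The shipped defaults reproduce all five to ≈1%
(5.629 G, 3.172 M, 6.780 G, 4.930 G, 2.831 M), and the unconstrained
interior points land on the same curve (ratio 8 → 5.148 G; kernels {3,5} →
2.95 M, {5,7,9} → 3.50 M).  `scripts/acceptance.py` recomputes these from
scratch.

## Cross-scale lite attention (CSLA)

Each pyramid level ℓ ∈ {(4, 64), (8, 96), (16, 128)} carries a stack of
four CSLA blocks applied residually (Y = X + f(X)).  Inside a block:

1. LayerNorm + local depthwise 3×3 encoding;
2. compact projections Q = XW_Q, K = XW_K, V = XW_V with
   C′ = C / ratio (ratio ∈ {2, 4, 8, 16}, default 4);
3. attention over average-pooled token sets at scales s ∈ {1, 2, 4}, each
   restored by nearest upsampling and averaged;
4. a pointwise projection back to C channels, zero-initialized so every
   block starts as the exact identity — deep stacks are stable by
   construction, and the attention path grows only where it reduces loss.

The score path is rank-constrained.  In production the N×N score matrix is
never materialized: learned rank-r factor maps (r = C′/2) with a softplus
feature transform give a linear-attention normalization at Θ(HW·r) cost.
An explicit mode materializes softmax attention for analysis and refuses
token counts above a threshold, which the tests use to verify the
Eckart–Young bracket: the truncated-SVD error is at most the singular tail
Σ_{i>r} σ_i and at most any learned factorization's error.  The per-scale
key dimension is d_s = C′; the three levels do not share weights.

## Block-level substitution distillation (BLSD)

A frozen teacher and the half-width student share the 12-block layout at
identical resolutions, so alignment is purely channel-wise:

* **Alignment**: T̂_i = S_i M_i with a trainable M_i ∈ R^{C′_i×C_i};
  the loss is the squared substitution error ‖T_i − T̂_i‖².  Losses are
  computed on a fixed 10×10 pooled descriptor grid per block, which makes
  the distillation cost independent of input resolution (and is why the
  training-graph overhead stays near 3% of backbone FLOPs at 640² rather
  than growing with the feature maps).
* **Substitution**: early in training the input of block k is the convex
  mix Z_k = α_k·T_{k−1} + (1−α_k)·S_{k−1}; teacher features are adapted to
  student width by a frozen parameter-free grouped-mean projection (rows
  orthogonal, cost O(C·HW)).  The energy identity
  ‖Z_k − S_{k−1}‖ = α_k‖T_{k−1} − S_{k−1}‖ holds algebraically.  α_k is a
  scheduled upper bound (linear decay to zero at half of training) times a
  learnable per-block sigmoid gate; only the top-4 blocks by running
  alignment loss are eligible per step.  Stage-entry blocks are never
  substituted (their predecessor lives at a different stride).
* **Substitution blocks**: a bias-free Linear(C′→4C′)–GELU–Linear(4C′→C)
  path with scale-shift modulation renders student descriptors in teacher
  width (parameter count exactly C′·4C′ + 4C′·C); its stride-4 output is
  the distilled guidance injected into the SOEB fusion (μ-term) while
  training.

Teacher involvement is treated throughout as an early-training device, and
three details matter in practice.  The per-block squared errors are
normalized by the teacher descriptor's energy (scale-free relative errors
of order one — raw MSEs over 12 blocks would otherwise swamp the detection
loss).  The alignment weight and the distilled μ-guidance both decay on
the same linear schedule as the substitution bound, so by mid-training the
dynamics — and crucially the head's stride-4 input — are identical to an
undistilled run; injecting μ·D_blk without the fade leaves a train/inference
feature mismatch that measurably costs small-object accuracy.  The gate
logits are differentiable through the mixed forward (init −2), so a
substitution that raises the loss closes its own gate.

None of these modules exist in the inference graph; the profiler asserts
the deployed model is bit-identical in cost to a never-distilled one.

At desk scale the teacher is a double-width model trained on the same
synthetic scenes (by default for the same number of epochs as the main
run; it can also be supplied pre-trained or left random — the alignment
mechanics and all invariants are teacher-agnostic, though the benefit of
distillation tracks teacher quality).

## Small-object enhancement branch (SOEB)

A stride-1 branch on the raw stride-4 backbone feature (64 ch at ratio 1):
1×1 group convolution (4 groups) to 48 channels; a low-rank token
projection Z = XW₁W₂ with r = C/8 (rank 6 at 48 channels); a bank of
context-conditioned depthwise kernels, one per kernel size k ∈ {3, 5, 7};
a 3×3 stride-1 average-pooling path; a learnable scalar gate α (sigmoid,
init 0.5) mixing Σ_k D_k(Z)·α + P(Z)·(1−α); then a pointwise
channel-reorganization chain 48→64→80→96 (GELU) and a final 1×1 to 128.

The per-kernel depthwise weights are generated from a 96-d global context
vector (pooled from the stride-16 attention output through a linear
adapter) by a bias-free linear map, plus a fixed identity-kernel offset.
Each branch therefore costs 96·k²·48 parameters — receptive-field size
genuinely costs capacity, which is what makes the kernel-set axis a real
parameter dial ({3} → 2.83 M, {3,5,7} → 3.17 M, {5,7,9} → 3.50 M total) —
while the per-pixel cost stays that of a depthwise convolution.  This
context-generated form is also the concrete realization of "attention
guidance injected into the branch's modulation": the attention stack
decides what the high-resolution kernels look for.

A parameter-free residual completes the branch: the input channels are
tiled up to the output width and added with a learnable scalar gain, so
the branch refines rather than replaces the shallow feature and the
stride-4 gradient path stays open from the first step (without this the
extra depth slows early convergence enough to erase the branch's benefit
at desk scale).  Guidance fusion: U = E + η·G_cs + μ·D_blk with learnable
scalars (init 0.1), G_cs the stride-8 attention output upsampled and
1×1-adapted, and the μ-term present only while distilling (faded with the
substitution schedule, see above).  The head's stride-4 input
is U; with SOEB disabled it is the (attention-recalibrated) backbone
feature.

## Detection head, losses, training

Anchor-free decoupled head on strides {4, 8, 16}: per-level 1×1 stems to a
shared width (64), one depthwise-separable tower conv per branch,
classification (focal prior bias −3), box regression as exp-scaled
left/top/right/bottom distances with a per-level learnable scale, and
centerness.  Ground truth is assigned by regression range ((0,32), (32,64),
(64,∞) px) with center sampling (radius 1.5 strides); 5–20 px pests land
on stride 4.  Loss = focal(α 0.25, γ 2) + 2·CIoU + centerness BCE,
normalized by positive count, plus 0.2 × an image-level multi-label BCE on
the semantic-top logits (this image-level reading is also what defines
accuracy for a detector: an image is flagged as containing a class when a
detection clears the presence threshold, the only form with a defined true
negative).

Training: AdamW (weight decay 0.01), initial lr 1e-3 with cosine annealing
to zero and a 2-epoch linear warmup, global gradient-norm clipping at 5
(without it a minority of seeds collapse from early focal/CIoU gradient
spikes), batch 32, stratified 7:2:1 split, optional 5-fold
cross-validation.  Splits stratify on each image's rarest present class
(multi-label scenes; minority classes keep their own stratum) with
largest-remainder allocation, exact to ±1 per stratum.  A single master
seed fans out to separate streams for data, split, init, batch order and
augmentation; additionally every module draws its weights from its own
(seed, module) stream, so toggling one module in an ablation leaves all
other weights bit-identical — ablation rows are paired comparisons, not
independent re-rolls.  The published epoch budget is not stated in the
sources this design follows; the default is 24 epochs, and the distillation
term enters with weight 0.5.

## Augmentation

Color jitter (brightness/contrast/saturation/hue via a YIQ chroma
rotation; neutral parameters are the bitwise identity), cutout (boxes
covered > 90% dropped), crop–resize (boxes keeping < 25% of their area
dropped) — the principal scale amplifier for 5–20 px pests — mosaic
(four sources resized to the target size, anchored about a random center
in the central 50% of a double canvas, center-cropped back), mixup
(λ ~ Beta(1,1); annotations are the union with per-box weights), and
small-object copy–paste (donors ≤ 20 px max dimension, N ∈ [1,5] pastes,
scale ∈ [0.8, 1.25], accepted only when IoU with every existing box is
≤ 0.2, composited with a 1-px feathered edge — occluding rather than
additive, since additive compositing corrupts pixel ranges).  Every
operator is bit-reproducible from its generator and preserves box validity
under arbitrary composition (property-tested).

## Synthetic scenes

The generator emulates the statistical structure of greenhouse imagery:
layered leaf-ellipse clutter with a low-frequency illumination field,
specular streaks and local vapor blur as nuisance; two micro-pest classes
(dark beetle-like, bright whitefly-like) with max box dimension log-uniform
on [5, 20] px and an irregular multi-lobe lesion class on [20, 80] px;
class imbalance 0.45/0.30/0.25; Poisson object counts (rate 5 by default,
4 in the benchmark preset); objects are rescaled so the rendered tight box
matches the drawn size and placed with pairwise IoU ≤ 0.3.  Easy/hard
presets differ only in nuisance levels, and a fixed trained model scores
monotonically worse from easy to hard.  What it does **not** emulate:
real pest morphology and pose, occlusion by foliage geometry, camera noise
and compression, and realistic class taxonomies — so green tests establish
mechanism correctness and directional behaviour, not field accuracy.

## Desk-scale benchmark sizes

CPU-budget choices, stated once: the ablation/benchmark preset trains a
quarter-width model (CSLA stack depth 2) on 96×96 scenes (80 train /
48 val), 32 epochs, batch 8, lr 2e-3, no augmentation, 3 paired seeds,
reporting medians; the distillation rows share one half-width teacher
trained for the same 32 epochs on the same scenes.  At this scale absolute mAP values are
small and noisy; only directional orderings (with pairing, medians) are
meaningful, which is exactly what the acceptance experiment asserts.

## Profiler

FLOPs are multiply-accumulates counted by instrumenting the conv/matmul
kernels during a real forward pass, so the report reflects the executed
graph exactly; G FLOPs = MACs/1e9 (the convention under which the
calibration lands on the published 5–7 G regime for nano detectors at
640²).  Pooling, normalization and activations are not MAC-bearing, per
common profiler convention.  The textbook single-layer formula that omits
the input-channel factor is provided as `simplified_layer_flops` for
comparison; all reported numbers use the standard count
C_in·C_out·H·W·K²/groups.

## Known limitations

* Pure-numpy training is ~10³ slower than GPU frameworks; the package is
  a reference implementation and desk-scale testbed, not a production
  trainer.
* The linear-attention production path and the explicit softmax path are
  mathematically different normalizations of the same scores; the low-rank
  error bracket is verified on explicit scores, while production uses the
  factorized form throughout.
* Image-level accuracy depends on the presence threshold (default 0.5);
  detection precision/recall/F1 are reported at confidence 0.25, IoU 0.5.
* The synthetic benchmark's absolute metric levels say nothing about real
  greenhouse data (see above); only calibrated counts and directional
  orderings transfer.
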