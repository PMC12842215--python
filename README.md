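# pestlite

Lightweight small-object detection for greenhouse pest and disease
imagery. Micro-pests (whiteflies, aphids, thrips) occupy 5–20 pixels at a
640×640 input and sit on cluttered leaf backgrounds with specular
highlights and vapor blur; detecting them on edge hardware demands models
in the few-G-FLOPs / few-M-params class. `pestlite` implements and tests a
complete stack for this regime:

* a four-stage **mobile-transformer backbone** (strides {4,8,16,32},
  channels {64,96,128,192}, 12 blocks; half-width student {32,48,64,96});
* **CSLA** — cross-scale lite attention: compact Q/K/V projections
  (C′ = C/ratio), attention over pooled token sets at scales s ∈ {1,2,4},
  and a rank-r factorized score path (A ≈ UVᵀ, r ≪ N) that reduces cost
  from O((HW)²) to O(HW·r), fused residually (Y = X + f(X));
* **BLSD** — block-level substitution distillation: per-block linear
  alignment T̂ᵢ = SᵢMᵢ with loss ‖Tᵢ − T̂ᵢ‖², a gated substitution path
  Z_k = α_k T_{k−1} + (1−α_k) S_{k−1} whose schedule drives α_k → 0, and
  expansion-4 substitution blocks (params C′·4C′ + 4C′·C) — all train-only,
  zero inference cost;
* **SOEB** — a stride-1 small-object branch on the stride-4 feature:
  group-conv compression to 48 channels, low-rank projection (r = C/8),
  context-conditioned depthwise kernels for k ∈ {3,5,7}, a gated pooled
  path, and guidance fusion U = E + η·G_cs + μ·D_blk;
* the greenhouse **augmentation suite** (color jitter, cutout,
  crop–resize, mosaic, mixup with λ ~ Beta(α,α), small-object copy–paste),
  all bounding-box-aware and seed-reproducible;
* an anchor-free decoupled **detection head** (strides {4,8,16}), focal +
  CIoU + centerness losses, AdamW/cosine training, stratified 7:2:1
  splits and 5-fold cross-validation;
* **COCO-style metrics** (mAP@50, mAP@50:95, mAP-small/recall-small at the
  20-px threshold, precision/recall/F1, image-level accuracy) and a
  MAC-counting **profiler** with per-module breakdowns;
* a seeded **synthetic greenhouse scene generator** so everything is
  exercisable end-to-end without any dataset download.

Everything runs on a compact float64 numpy autodiff core (`pestlite.nn`)
— no GPU framework required, and every run is bitwise reproducible from
its seed.

## Worked example

```bash
python examples/profile_architecture.py
```

prints the per-module profile of the default model and the two sensitivity
axes:

```
module              GFLOPs      params
backbone             2.654     1446912
csla                 0.990      138880
head                 0.593       32774
soeb                 0.947      412324
top                  0.445     1116363
...
default model: 5.629 G FLOPs, 3.172 M params

CSLA compression ratio sweep (larger ratio -> cheaper attention):
  ratio  2: 6.780 G FLOPs
  ratio  4: 5.629 G FLOPs
  ratio  8: 5.148 G FLOPs
  ratio 16: 4.930 G FLOPs

SOEB kernel-set sweep (larger kernels -> more generator params):
  kernels [3]: 2.831 M params
  kernels [3, 5]: 2.946 M params
  kernels [3, 5, 7]: 3.172 M params
  kernels [5, 7, 9]: 3.504 M params
```

The FLOPs numbers are MACs/1e9 for one 640×640 forward pass; the
compression ratio trades attention cost against accuracy, and the kernel
set sizes the small-object branch's context-generated receptive fields.
`examples/train_and_evaluate.py` trains a quarter-width model on synthetic
96×96 scenes in about a minute and prints the metric suite;
`examples/distillation_demo.py` shows the distillation mechanics and its
FLOPs overhead; `examples/generate_and_augment.py` renders scenes and runs
the augmentation pipeline.

There is also a thin CLI over the same API:

```bash
pestlite generate-data --out data/ --n 600
pestlite train --config run.yaml
pestlite profile --config run.yaml --input 640
pestlite ablate --config run.yaml
pestlite sensitivity --axis csla.compression_ratio --values '[2,4,8,16]'
```

Exit codes: 0 ok, 2 config error, 3 data error, 4 training divergence.

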