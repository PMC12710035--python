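# Methods

podkit models the architecture family behind real-time prototype-mask
instance segmentation of soybean pods in field imagery, together with the
surrounding pipeline: harvesting usable frames from handheld field video by
no-reference image quality assessment (NR-IQA), converting polygon labels to
masks and back, evaluating instance masks with mAP, and generating synthetic
pod scenes so that every stage is testable without field data.

## The architecture family and its accounting

The base network is a nano-scale CSP backbone with a three-level feature
pyramid (taps P3/P4/P5 at strides 8/16/32), decoupled box/class heads, a
mask-coefficient head, and a prototype branch ("Protonet") that emits k
prototype planes (k = 32 by default).  An instance mask is
`sigmoid(Σ_j c_j · P_j)` for that instance's k coefficients, cropped to its
box.  Two modifications are modelled:

* **Hierarchical prototype aggregation (HPA).**  Instead of feeding the
  prototype branch P3 alone, each pyramid scale contributes a fixed share of
  its input channels — c3 from P3, c4 from P4 (upsampled ×2), c5 from P5
  (upsampled ×4) — with c3 + c4 + c5 = k enforced by construction
  (default split 24/6/2).  Three upsampling variants exist: cascaded
  transposed conv, parallel transposed conv (the default), and parallel
  nearest interpolation.
* **U-shaped prototype decoder with EMA.**  The prototype branch is rebuilt
  as a small U: a 3×3 conv at 1/8 scale, a pooled dip to 1/16, two ×2 rises
  (transposed conv or parameter-free nearest) with an additive skip, a 3×3
  conv at 1/4 scale and a 1×1 head — so prototypes are emitted at 1/4 of the
  input resolution.  An efficient multiscale attention (EMA) block follows
  each prototype-branch convolution.  In the composed model the P4
  aggregation path enters the decoder at its native 1/16 scale through a 1×1
  projection and rises by nearest interpolation: transposed convolutions do
  the learnable upsampling on the encoder side (the P5 path), interpolation
  on the decoder side.

Graphs are symbolic DAGs of primitive layers with closed-form parameter
costs; `instantiate_parameters` allocates every tensor a layer implies and
serves as an independent counting oracle (the two totals are asserted equal
in tests and in `scripts/acceptance.py`).

**Counting conventions.**  Parameter totals use the *fused* convention:
batch-norm is folded into the preceding convolution, so a normalised conv
costs `cin·cout·k²/groups + cout`.  This convention reproduces the published
reference totals for this model family exactly (e.g. 3,404,320 parameters
for the stock 80-class segmentation nano model).  Totals in millions are
*floored* at three decimals (`format_millions`), which is how such tables
are conventionally printed from raw counts.  FLOPs are 2 × multiply–
accumulates of conv/transposed-conv/linear layers at the stated input size;
a transposed conv is costed as its equivalent dense convolution over the
zero-inserted input (`k²·cin/groups` MACs per output element), matching
mainstream profilers; nearest upsampling, pooling and concatenation cost
nothing.  Under these conventions the single-class baseline at 640 input
costs 3.258 M parameters and 12.0 GFLOPs, the HPA variant with split 24/6/2
costs 3.586 M, and the composed model 3.537 M / 12.4 GFLOPs.

**Geometry choices the literature leaves open.**  The exact transposed-conv
geometry of the aggregation paths is not published; podkit fixes it by
reconciliation against the published parameter totals: the P5 path is
convT(256→256, 2×2 stride 2) then convT(256→48, 2×2 stride 2) then a 1×1
projection to c5; the P4 path convT(128→64, 2×2 stride 2) then 1×1 to c4;
P3 projects 1×1 to c3.  Projecting each scale down *before* upsampling
would be far cheaper (~3 k added parameters) but contradicts the published
totals by ~0.3 M, so it was rejected.  Two reconciliations fail and are
knowingly left unmatched: the k = 64 ablation row (published 3.487 M /
13.2 GFLOPs; every natural geometry searched gives 3.481 M / 13.0) and the
nearest-upsampling U-decoder row (we count 3,241,811, which floors to 3.241
against a published 3.242 — a print-rounding hair).  Our realization of the
standalone HPA variant also costs 13.6 GFLOPs where 13.2 is published;
parameter totals, not FLOPs, were the binding surface for these rows.

**Other pinned conventions.**  The prototype-trunk width follows
`min(64, 2k)` across the prototype-count ablations; the coefficient-head
width is `max(16, k)`.  EMA uses channel-to-batch grouping with group count
32 (the published module's default factor); per group it holds a per-channel
group-norm affine, a 1×1 branch and a 3×3 branch, with cross-spatial fusion
(each branch's pooled, channel-softmaxed descriptor weights the other
branch's map) and a sigmoid gate.  The 3×3 branch uses edge-replicate
padding so that a spatially constant input yields a spatially constant
output — attention degenerates gracefully on flat regions.

## Mask evaluation

Assembly, cropping and binarisation are as above, with a strict `> 0.5`
binarisation.  Postprocessing keeps predictions with confidence ≥ 0.3 and
applies greedy box-IoU NMS at 0.5 (the standard inference settings for this
task).  TP/FP/FN matching is greedy, one-to-one, by **mask** IoU in
descending confidence order (box IoU appears only inside NMS); confidence
ties break by input index and IoU ties by truth index.  AP is the 101-point
interpolated area under the confidence-ranked PR curve (an all-point variant
is available); mAP@50 is AP at IoU 0.5 and mAP@50–95 the mean over IoU
0.50:0.05:0.95.  Empty-vs-empty mask IoU is defined as 1.0, a degenerate
case real data never meets.  Predictions and ground truth interchange as
COCO-style JSON with polygon or uncompressed RLE segmentations.

## Frame harvesting and quality indicators

Video decomposes to one frame per interval (default 1 s) starting at t = 0;
the final sample is kept only if its frame exists.  Clips may be in-memory
stacks, directories of PNG frames with a `clip.json` frame rate, or any
container imageio can read.  Four indicators are computed on 8-bit
grayscale (BT.601 luma):

| indicator | definition | range | constant image |
|---|---|---|---|
| clarity | variance of the 4-neighbour Laplacian response | ≥ 0 | 0 |
| edge sharpness | mean Tenengrad (squared Sobel magnitude) | ≥ 0 | 0 |
| entropy | Shannon entropy of the 256-bin histogram (bits) | [0, 8] | 0 |
| GLCM energy | Σ p² of the symmetric normalized co-occurrence matrix, 32 gray levels, offsets (0,1) and (1,0) averaged | (0, 1] | 1 |

These concrete formulas are this package's stand-ins for unpublished
definitions; all are configurable, all are invariant to image flips, and
clarity/sharpness decrease monotonically under Gaussian blur of a fixed
scene (tested on generated fixtures).  Filtering is two-staged: loose bounds
over all frames, then per-subset tuned bounds (keyed by clip id, with a
`default` fallback), each rejection logged with the failing indicator(s).
Because published absolute thresholds do not exist, the shipped default is
dataset-relative: keep frames above the 5th percentile of each indicator.

## Dataset utilities

Labels are one polygon per line with normalized coordinates (a second,
COCO-style JSON dialect is provided).  All geometry uses one convention:
0-based pixels, x right / y down, half-open boxes, even-odd fill over pixel
centers at (col + 0.5, row + 0.5) — an axis-aligned rectangle
[x1, x2) × [y1, y2) rasterises to exactly (x2−x1)(y2−y1) pixels.  Masks
trace back to polygons via 0.5-level contours; multi-part masks keep
multiple rings under one instance (the line dialect, which has no multi-part
concept, writes one line per ring).  Splits are seed-stable uniform
partitions (default sizes 406/47/35 over 488 ids).  Statistics cover
per-image instance counts, instance pixel areas and a G×G (default 64)
histogram of normalized box centers whose total equals the instance count.
Augmentations are flips, quarter-turn rotations and window crops; masks
transform with the image and instances reduced below 3 pixels are dropped.

## Synthetic scenes

Scenes emulate side-view imaging of a plant row against a light backdrop:
pods are filled rotated ellipses (default full axes 26–42 × 10–16 px on a
256² canvas, ~24 per scene) with mildly perturbed boundaries, clustered
around vertical stem lines; occluders are thin "stem" bands and broad
"leaf" blobs drawn over the pods.  Ground truth stores the **visible**
(post-occlusion) mask of each pod, matching how field annotations are drawn.
Clips render one wide static scene and crop a laterally translating window
with optional per-frame jitter and a per-frame blur schedule.  All
randomness flows through `numpy.random.default_rng(seed)`, so scenes and
clips are bitwise reproducible across platforms.  The generator is a
deliberate cartoon: it captures density, occlusion, blur and backdrop
contrast, but not colour statistics, lighting, or real plant structure —
passing tests demonstrate pipeline correctness, not field-data performance.

The "easy" configuration (64² canvas, three large pairwise-disjoint
unoccluded pods, low noise) defines the separable regime for end-to-end
smoke training.

## Toy trainer

`train_toy` is a hand-differentiated NumPy realization of the
prototype-coefficient family, small enough to train on one CPU core in
seconds: three stride-2 3×3 convs to an 8×8 cell grid; 1×1 objectness, box
and 8-coefficient heads per cell; a prototype branch from the 16² feature
map producing 8 planes at 1/4 input resolution.  Each instance claims the
cell holding its box centre (larger instance wins collisions).  The loss is
a standard composite — weighted BCE objectness, squared-error box regression
(sigmoid-encoded centre offsets, log sizes), and per-instance BCE between
the assembled mask and the 16² downsampled truth — optimised with Adam
(lr 3e-3, batch 8, 600 steps by default; chosen once for stable convergence
on easy scenes).  Training augmentation applies random flips, quarter
rotations and translate-crops.  Evaluation decodes cells above confidence
0.3, assembles masks through the same `mask_eval` machinery used everywhere
else, applies NMS at IoU 0.5 and reports precision/recall/mAP.  Determinism
is exact for a fixed seed.  On 32 easy scenes the held-out mAP@50 typically
exceeds 0.9; the trainer makes no claim about full-scale recipes, and
problem sizes (64² scenes, 600 steps) are the package's own choice of a
desk-scale experiment.

Checkpoints are plain `.npz` arrays.

## Known limitations

* Ablation-table layer *counts* are not modelled (published counts disagree
  for identical models, so the counting convention is unknowable).
* The cascaded and interpolation HPA variants and their compositions are
  functional but their published parameter totals are not reconciled (the
  published table prints identical totals for structurally different
  geometries).
* FLOPs of the standalone HPA and U-decoder ablations deviate from the
  published column (13.6 vs 13.2; 12.2 vs 15.6; 11.1 vs 11.5) under the
  geometry that reconciles the parameter totals.
* The evaluator's AP interpolation (101-point) and mask-IoU matching are
  this package's documented choices; published work rarely states them.
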