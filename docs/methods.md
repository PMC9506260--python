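# Methods

## Problem and pipeline

In vivo reflectance confocal microscopy (RCM) produces horizontal
grayscale optical sections of skin at cellular resolution. Basal cell
carcinoma (BCC) appears in such sections as compact bright tumor
aggregates ("bright tumor island" cores) with elevated local reflectance,
often demarcated from the surrounding speckle-textured stroma by a dark
peripheral fissure. The package segments such regions with a two-stage
approach: a 256×256 patch classifier is trained on crops labeled by a
strict-majority rule, then converted into a fully-convolutional dense
predictor that scores whole slices; the resulting probability heatmap is
smoothed, thresholded and morphologically opened into a binary mask, and
evaluated at pixel, stack (scan site) and case (patient) level under
grouped cross-validation.

## Synthetic data generator

The clinical scans behind the original study are not deposited, so the
generator emulates their *appearance statistics* — the features the
classifier actually keys on — rather than confocal physics:

- **Stroma**: a base gray level of 90 (8-bit scale) modulated by a smooth
  Gaussian random field (amplitude 12%, correlation length 60 px),
  mimicking slowly varying illumination and tissue density.
- **Speckle**: multiplicative Gamma noise with mean 1 and shape 8
  (intensity CV ≈ 35%), blurred with σ = 1 px to give it the short-range
  correlation of a coherent imaging system. A Gamma multiplicative model
  is the standard texture model for coherent imagery; the choice of
  shape sets how grainy slices look.
- **Tumor islands**: ellipses with semi-axes drawn uniformly from
  110–230 px. At the instrument's ~0.5 µm/px sampling this spans
  ~55–115 µm, typical of basaloid island cross-sections. Island texture
  is the stroma texture multiplied by (1 + contrast); the default
  contrast 0.8 makes islands distinctly brighter without saturating.
  Each island is ringed by a dark fissure (width 6 px, attenuation ×0.45).
  Islands are placed fully inside the frame and non-overlapping by
  rejection sampling (an island that cannot be placed in 200 tries is
  dropped), which keeps the realized lesion-pixel fraction close to the
  analytic expectation n·π·E[a]·E[b]/(H·W); the test suite asserts
  agreement within ±20%.
- **Masks** cover island interiors only — the fissure and stroma are
  healthy — matching expert annotation of the compact clusters
  themselves. An optional multi-criterion mask assigns each island one
  of five annotation-criterion palette indices, but every downstream
  stage collapses masks to binary.
- **Grouping**: slices are organized as cases × stacks × slices with
  defaults 14 × 3 × 10, the scale of the clinical dataset (14 cases,
  37 stacks, 385 slices). Per-slice seeds are spawned from the master
  seed keyed on (case, stack, slice), so any slice is regenerable in
  isolation and the whole dataset is a pure function of the parameters.

What the generator does **not** emulate: cell-level morphology (nuclear
polarization, palisades), depth sectioning and point-spread optics,
annotation noise, and the heterogeneity of real BCC subtypes. Passing
synthetic benchmarks therefore demonstrates that the pipeline's
machinery is correct and can recover lesions whose statistical signature
it was trained on — not that it reaches any particular accuracy on
clinical scans.

## Patch extraction and augmentation

Slices are tiled on a regular grid; a patch is malignant iff strictly
more than 50% of its area is annotated (a tie stays healthy). The
default stride of 106 px gives an 8×8 grid (64 patches) per 1000×1000
slice, reproducing the study's bookkeeping of ~63.5 patches per slice
(24,448 patches from 385 slices); the stride is configurable since the
original tiling is not recorded. Training augmentation follows the
stated recipe — rotation ±30°, zoom 80–120%, horizontal flip at p=0.5 —
with rotation and zoom composed into a single bilinear resampling with
reflection fill (no flat borders, one interpolation pass). Augmentation
is resampled per epoch and never touches labels.

## Classifier

The backbone keeps the MobileNet-v1 skeleton — a strided stem plus 13
depthwise-separable stages with stride schedule 1,2,1,2,1,2,1×5,2,1
(total stride 32 including the stem) and the standard channel schedule
under a width multiplier (0.5 ⇒ 512 final channels, matching the
full-scale model; the desk-test width 1/64 ends at 16 channels) — with
one deliberate geometric change: **every convolution's kernel size
equals its stride**. Downsampling stages use 2×2 kernels on
non-overlapping tiles; stride-1 stages are 1×1. Each cell of the final
feature grid is then a function of exactly its own aligned 32×32 input
block. This is what makes the dense expansion *exactly* equivalent to
sliding-window patch inference: with spatially overlapping kernels and
shape-preserving padding, a patch forward pass pads at the window border
while the full-image pass sees real context there, so the two can never
agree to high precision. The trade-off is a smaller receptive field per
grid cell; for texture/contrast discrimination this costs little, and it
buys a provable equivalence between the two inference modes.

Every conv is followed by batch normalization and ReLU (as in the
reference architecture); in inference mode batch norm is a fixed
per-channel affine map, so it preserves block alignment. Because the
momentum-averaged batch-norm statistics lag the rapidly changing weights
of a short training run, training ends with one calibration sweep over
the clean training patches that re-estimates the running statistics
under the final weights (the standard re-estimation used with weight
averaging); without it, inference-mode predictions can diverge from what
was learned.

The head is global average pooling over the 8×8 grid followed by a
2-way fully connected softmax. Training uses Adam with plain 2-class
cross-entropy (no class weighting, no schedule, no early stopping); the
full-scale recipe is learning rate 1e-5 for 20 epochs. Model, layers,
backprop and Adam are implemented directly on NumPy in float64 (default)
or float32 (≈6× faster at desk scale, statistically equivalent); all
initialization and batching is driven by explicit seeds, and a
finite-difference check of every parameter's gradient is part of the
development protocol.

## Dense expansion

To score a whole slice: mirror-pad 1000→1024 (24 px total, split 12 per
side, symmetric reflection in which the edge pixel participates —
padded row *i* equals original row 11−*i*), run the backbone to the
32×32×C grid, average-pool with a stride-1 shape-preserving kernel,
apply a 1×1 convolution whose two filters carry the transplanted
fully-connected weights, softmax, and upsample ×32 (bilinear by default
for smooth heatmaps; nearest available for exactness tests). The padding
split is chosen so 1024/32 gives exactly the 32×32 grid.

The default pooling kernel is 7, the full-scale configuration; kernel 8
covers exactly one 256-px patch footprint and makes dense grid cell
(i+4, j+4) equal the patch classifier's output on sliding window (i, j)
— the brute-force sliding-window oracle and this alignment are part of
the public API, and the equivalence is asserted to 1e-5 (it holds to
~1e-16 in float64). Kernel 7 differs from the patch model's 8×8 global
pool by one row/column and is therefore a near- but not bit-exact
variant; both are supported.

Heatmaps are evaluated on the padded 1024×1024 canvas against masks
padded with the same mirror geometry (matching the full-scale
evaluation); cropping back to 1000×1000 is available by flag. Linear
upsampling applies identical weights per channel, so per-pixel channel
sums stay at 1; the implementation renormalizes after interpolation to
keep the invariant tight against float error.

## Postprocessing

smooth → binarize → erode → dilate, in that order. Gaussian σ defaults
to 2 px — enough to soften the 32→1024 upsampling block structure
without erasing lesion-scale features; the σ is not recorded in the
original description, so it is configurable. Channel-wise smoothing uses
a reflective boundary and renormalizes each pixel's channel pair to
sum 1. Thresholding keeps a pixel at probability exactly 0.5 (everything
not below the threshold maps to 1). The structuring element, also
unrecorded, defaults to the 3×3 square with one erosion and one dilation
— the minimal opening that removes isolated pixels; erosion-then-
dilation is anti-extensive and idempotent, which the tests assert.

## Metrics and cross-validation

Pixel metrics: sensitivity TP/(TP+FN), specificity TN/(TN+FP), and the
row-normalized confusion matrix [[TN,FP],[FN,TP]]/row-sums. (The
specificity definition follows the prose "proportion of healthy pixels
correctly predicted" and the published matrix, which it reproduces
exactly: 233,794,335/(233,794,335+40,618,083) = 0.852.) Ratios with an
empty class are reported as NaN with an explicit `undefined` flag, never
silently as 0 or 1.

The stack criterion — "40% of the lesions found correctly in at least
three slices" — is operationalized as per-slice lesion-pixel recall
≥ 0.40 (inclusive) in ≥ 3 slices; "lesion" is not defined instance-wise
in the source, and slice-level recall is the reading that needs no
instance matching. Lesion-free slices are excluded as non-evaluable, and
a stack with no lesion slices is flagged non-evaluable rather than
counted as a miss. A case is detected when any evaluable stack is.

Cross-validation groups by case, the only leakage-safe unit for
patient-wise data: no slice of a validation case ever contributes a
training patch. Fold assignment is a seeded permutation split into k
near-equal parts, independent of input order. Pooling sums the per-fold
confusion counts into a single matrix (the convention behind the
published pooled matrix of 382M pixels) rather than averaging per-fold
ratios; per-fold seeds are spawned deterministically from the master
seed.

## The scaled-down benchmark

Full-scale conditions (512-channel backbone, 24k patches, 20 epochs,
k=14) are far beyond a single-CPU run, so the package defines one
reference experiment (`rcmseg.experiments.scaled_cv_benchmark`), used by
both the test suite and `scripts/acceptance.py`:

- 6 cases × 2 stacks × 4 slices of 1000×1000 px at the default lesion
  contrast 0.8;
- patch stride 186 (5×5 grid, 25 patches/slice; 1000 training patches
  per fold);
- tiny-width backbone (width 1/64, 16 final channels), float32;
- leave-one-case-out (k = 6), 5 epochs per fold, batches of 16, Adam at
  2e-3. The full-scale schedule performs ~15k updates; this run performs
  ~315, so the step size is raised accordingly and small batches double
  the update count. Augmentation is off: at this scale the model
  underfits rather than overfits, and the zoom transform changes a
  patch's visible lesion area while the label stays fixed, injecting
  label noise near the 50% boundary that ~300 updates cannot average
  out;
- default expansion (pool kernel 7, bilinear ×32) and postprocessing,
  evaluation on the padded canvas.

The run takes ~8 minutes on one CPU and is deterministic given its
seed. Typical pooled results across seeds: pixel sensitivity ~0.55–0.72,
specificity ~0.98–1.00, stack detection 67–100%, case detection
67–100%. Sensitivity sits well below specificity for a structural
reason shared with the full-scale study: the dense grid scores each
pixel by a 256-px window around it, so predicted regions shrink toward
lesion cores and boundary pixels are missed.

## Numerical and degenerate-input conventions

- Probabilities are softmax-normalized at every stage; heatmap channel
  sums are kept at 1 (±1e-6).
- The strict-majority patch label uses a strict inequality; the
  postprocessing threshold and the lesion-recall criterion are
  inclusive. All three tie-breaks follow the stated rules verbatim.
- Masks are validated to be strictly {0,1}; non-binary inputs raise.
- A training set without both classes raises (cross-entropy is
  degenerate for evaluation); inside cross-validation the failing fold
  is identified in the error.
- Images divisibility: mirror padding checks that the padded size is
  divisible by the total stride and suggests a pad when it is not.
- Checkpoints store parameters, batch-norm running statistics and the
  architecture spec in a single NPZ archive.

## Known limitations

- The 32-px dense grid bounds localization: lesions much smaller than a
  patch cannot be recovered, and boundary precision is ~half a window.
- The block-aligned backbone trades receptive-field overlap for exact
  expansion equivalence; architectures with overlapping kernels would
  need an approximate-equivalence tolerance instead.
- Synthetic results do not transfer to clinical RCM accuracy claims
  (see the generator section); the published clinical operating point
  (0.46/0.85) enters only through its arithmetic, which the metric
  formulas reproduce from the published tallies.
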