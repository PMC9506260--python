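"""Fully-convolutional expansion of the patch classifier into a dense
per-pixel predictor.

A trained patch classifier scores one 256x256 crop at a time.  To score a
whole 1000x1000 slice, its head is convolutionalized: the backbone runs on
the mirror-padded 1024x1024 canvas producing a 32x32 feature grid, a
stride-1 shape-preserving average pooling replaces the patch model's
global pool, the 2-way fully connected layer becomes a 1x1 convolution
carrying the transplanted weights, and softmax plus x32 upsampling yield a
1024x1024x2 probability heatmap.

Because the backbone's receptive fields tile the input in aligned 32x32
blocks (see :mod:`rcmseg.classifier`), pooling the dense grid with a
kernel equal to the patch feature-grid size (8) reproduces sliding-window
patch inference exactly; :func:`sliding_window_oracle` is the brute-force
reference for that equivalence.  The default pool kernel is 7, the
slightly asymmetric variant used at full scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from . import nn
from .classifier import PatchModel, predict_patch

__all__ = [
    "ExpansionConfig",
    "DenseModel",
    "Heatmap",
    "mirror_pad",
    "expand",
    "predict_heatmap",
    "sliding_window_oracle",
    "oracle_grid_offset",
]


@dataclass(frozen=True)
class ExpansionConfig:
    """Geometry of the dense expansion.

    ``avgpool_kernel`` 7 is the full-scale default; 8 makes the dense grid
    agree exactly with patch predictions (the pooled window then covers
    precisely one 256-px patch footprint).  ``mirror_pad_total`` of 24
    brings 1000-px slices to the 1024-px canvas divisible by the stride.
    """

    avgpool_kernel: int = 7
    avgpool_stride: int = 1
    padding_mode: str = "same"
    upsample_factor: int = 32
    upsample_method: str = "bilinear"
    mirror_pad_total: int = 24
    evaluate_on_padded_canvas: bool = True

    def __post_init__(self) -> None:
        if self.avgpool_kernel < 1:
            raise ValueError("avgpool_kernel must be >= 1")
        if self.avgpool_stride != 1:
            raise ValueError("only stride-1 shape-preserving pooling is supported")
        if self.mirror_pad_total % 2:
            raise ValueError("mirror_pad_total must split evenly across sides")
        if self.upsample_method not in ("bilinear", "nearest"):
            raise ValueError("upsample_method must be 'bilinear' or 'nearest'")

    @property
    def pad_per_side(self) -> int:
        return self.mirror_pad_total // 2


@dataclass
class Heatmap:
    """Per-pixel class probabilities on the padded canvas, plus the crop
    geometry mapping back to the original slice."""

    probabilities: np.ndarray  # (Hp, Wp, 2), channels (healthy, malignant)
    pad_per_side: int
    original_shape: tuple[int, int]

    def crop(self) -> np.ndarray:
        """Probabilities restricted to the original (unpadded) slice."""
        p = self.pad_per_side
        h, w = self.original_shape
        return self.probabilities[p:p + h, p:p + w]

    @property
    def malignant(self) -> np.ndarray:
        return self.probabilities[..., 1]


def mirror_pad(image: np.ndarray, cfg: ExpansionConfig = ExpansionConfig()
               ) -> np.ndarray:
    """Symmetric-reflection pad by ``mirror_pad_total``, split per side.

    With the default 24-px total a 1000x1000 slice becomes 1024x1024.
    Symmetric reflection: for a per-side pad of 12, padded row i (< 12)
    equals original row 11 - i; the edge pixel participates in its mirror.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    f = cfg.upsample_factor
    if (h + cfg.mirror_pad_total) % f or (w + cfg.mirror_pad_total) % f:
        need_h = (-h) % f
        need_w = (-w) % f
        raise ValueError(
            f"shape {h}x{w} plus pad {cfg.mirror_pad_total} is not divisible by "
            f"{f}; suggested mirror_pad_total: {max(need_h, need_w)} "
            f"(or that plus a multiple of {f})")
    p = cfg.pad_per_side
    pad = ((p, p), (p, p)) + ((0, 0),) * (image.ndim - 2)
    return np.pad(image, pad, mode="symmetric")


class DenseModel:
    """Expanded predictor sharing the source classifier's backbone.

    The 1x1 convolution's filter for class k carries, at channel c, the
    fully connected weight from pooled feature c to class k; biases are
    transplanted likewise.  The backbone layers are the same objects as
    the source model's, so their weights are bit-identical by construction.
    """

    def __init__(self, source: PatchModel, cfg: ExpansionConfig) -> None:
        self.source = source
        self.cfg = cfg
        self.conv_w = source.head.params["w"].copy()  # (C, 2)
        self.conv_b = source.head.params["b"].copy()

    def predict_grid(self, slice_image: np.ndarray) -> np.ndarray:
        """Pre-upsample softmax grid (Hg, Wg, 2) for a padded-input slice."""
        padded = mirror_pad(slice_image, self.cfg)
        feats = self.source.features(padded[None, :, :, None])[0]
        k = self.cfg.avgpool_kernel
        pooled = ndimage.uniform_filter(feats, size=(k, k, 1), mode="reflect")
        logits = pooled @ self.conv_w + self.conv_b
        return nn.softmax(logits)


def expand(model: PatchModel, cfg: ExpansionConfig = ExpansionConfig()
           ) -> DenseModel:
    """Convolutionalize a trained patch classifier."""
    if not model.trained:
        raise RuntimeError("expand() requires a trained patch classifier")
    c = model.spec.final_channels
    if model.head.params["w"].shape != (c, 2):
        raise ValueError(
            f"head weight shape {model.head.params['w'].shape} does not match "
            f"backbone output channels {c}")
    return DenseModel(model, cfg)


def _upsample(grid: np.ndarray, factor: int, method: str) -> np.ndarray:
    if method == "nearest":
        return np.repeat(np.repeat(grid, factor, axis=0), factor, axis=1)
    hg, wg, c = grid.shape
    return resize(grid, (hg * factor, wg * factor, c), order=1,
                  mode="edge", anti_aliasing=False, preserve_range=True)


def predict_heatmap(dense: DenseModel, slice_image: np.ndarray) -> Heatmap:
    """Full-slice heatmap: mirror pad -> backbone -> pool -> 1x1 conv ->
    softmax -> x-factor upsample."""
    slice_image = np.asarray(slice_image)
    grid = dense.predict_grid(slice_image)
    probs = _upsample(grid, dense.cfg.upsample_factor, dense.cfg.upsample_method)
    # Linear interpolation applies identical weights per channel, so pixel
    # sums stay 1 up to float error; renormalize to keep the invariant tight.
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum(axis=-1, keepdims=True)
    return Heatmap(probabilities=probs, pad_per_side=dense.cfg.pad_per_side,
                   original_shape=(slice_image.shape[0], slice_image.shape[1]))


def oracle_grid_offset(cfg: ExpansionConfig) -> int:
    """Dense-grid index shift aligning sliding windows with pooled cells.

    Window i of the stride-32 sliding window covers grid cells
    [i, i + 8); the stride-1 pooled cell r covers [r - k//2, r - k//2 + k).
    With kernel 8 these coincide at r = i + 4.
    """
    return cfg.avgpool_kernel // 2


def sliding_window_oracle(model: PatchModel, slice_image: np.ndarray,
                          stride: int = 32,
                          cfg: ExpansionConfig = ExpansionConfig()) -> np.ndarray:
    """Brute-force reference: the patch classifier applied to every
    256x256 window of the padded slice at the given stride.

    Returns an (n, n, 2) probability grid; window (i, j) aligns with dense
    pre-upsample cell (i + off, j + off) where off =
    :func:`oracle_grid_offset` — exact for pool kernel 8.
    """
    padded = mirror_pad(np.asarray(slice_image), cfg)
    ps = model.patch_size
    h, w = padded.shape
    rows = range(0, h - ps + 1, stride)
    cols = range(0, w - ps + 1, stride)
    windows = [padded[r:r + ps, c:c + ps] for r in rows for c in cols]
    chunks = [predict_patch(model, np.stack(windows[i:i + 32]).astype(np.float64))
              for i in range(0, len(windows), 32)]
    probs = np.concatenate(chunks, axis=0)
    return probs.reshape(len(rows), len(cols), 2)
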