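"""Tiling of RCM slices into labeled 256 x 256 patches, and training-time
augmentation.

A patch is labeled malignant only when strictly more than half of its area
is annotated as cancer — the strict-majority rule under which the patch
classifier is trained.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .synthetic import AnnotatedSlice

__all__ = [
    "PatchLabel",
    "PatchRule",
    "AugmentConfig",
    "LabeledPatch",
    "label_patch",
    "tile_slice",
    "grid_offsets",
    "augment",
    "augment_draw",
    "apply_augment",
]


class PatchLabel(IntEnum):
    HEALTHY = 0
    MALIGNANT = 1


@dataclass(frozen=True)
class PatchRule:
    """Patch geometry and the strict-majority labeling threshold.

    The default stride of 106 px lays an 8 x 8 grid over a 1000 x 1000
    slice (~64 patches per slice).
    """

    patch_size: int = 256
    malignant_fraction_threshold: float = 0.5
    stride: int = 106

    def __post_init__(self) -> None:
        if not 0 < self.malignant_fraction_threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")


@dataclass(frozen=True)
class AugmentConfig:
    """Training augmentation: rotation, zoom and horizontal flip."""

    rotation_deg: float = 30.0          # symmetric range +/- rotation_deg
    zoom: tuple[float, float] = (0.8, 1.2)
    horizontal_flip_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.zoom[0] <= 0 or self.zoom[1] < self.zoom[0]:
            raise ValueError("zoom range must be positive and ordered")
        if self.rotation_deg < 0:
            raise ValueError("rotation_deg must be >= 0")


@dataclass(frozen=True)
class LabeledPatch:
    pixels: np.ndarray  # (patch_size, patch_size)
    label: PatchLabel
    origin: tuple[str, str, int, int, int]  # case, stack, slice, row, col


def label_patch(mask_patch: np.ndarray, rule: PatchRule = PatchRule()) -> PatchLabel:
    """Strict-majority label: malignant iff mask fraction strictly exceeds
    the threshold (a patch at exactly 50% stays healthy)."""
    if mask_patch.shape != (rule.patch_size, rule.patch_size):
        raise ValueError(
            f"mask patch shape {mask_patch.shape} != "
            f"({rule.patch_size}, {rule.patch_size})")
    if not np.isin(mask_patch, (0, 1)).all():
        raise ValueError("mask patch must be binary {0,1}")
    frac = float(np.count_nonzero(mask_patch)) / mask_patch.size
    return (PatchLabel.MALIGNANT if frac > rule.malignant_fraction_threshold
            else PatchLabel.HEALTHY)


def grid_offsets(length: int, patch_size: int, stride: int) -> np.ndarray:
    """Offsets of a regular tiling grid; count = floor((L-P)/stride)+1."""
    if length < patch_size:
        raise ValueError(f"extent {length} smaller than patch size {patch_size}")
    return np.arange(0, length - patch_size + 1, stride)


def tile_slice(sl: AnnotatedSlice, rule: PatchRule = PatchRule()) -> list[LabeledPatch]:
    """Tile a slice on a regular grid, labeling each patch from its mask."""
    ps = rule.patch_size
    rows = grid_offsets(sl.image.shape[0], ps, rule.stride)
    cols = grid_offsets(sl.image.shape[1], ps, rule.stride)
    out = []
    for r in rows:
        for c in cols:
            out.append(LabeledPatch(
                pixels=sl.image[r:r + ps, c:c + ps],
                label=label_patch(sl.mask[r:r + ps, c:c + ps], rule),
                origin=(sl.case_id, sl.stack_id, sl.slice_index, int(r), int(c)),
            ))
    return out


def augment_draw(cfg: AugmentConfig, rng: np.random.Generator
                 ) -> tuple[float, float, bool]:
    """Sample one (rotation_deg, zoom, flip) augmentation triple."""
    angle = float(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
    zoom = float(rng.uniform(*cfg.zoom))
    flip = bool(rng.random() < cfg.horizontal_flip_prob)
    return angle, zoom, flip


def apply_augment(pixels: np.ndarray, angle: float, zoom: float, flip: bool
                  ) -> np.ndarray:
    """Apply one augmentation triple; reflection fill, output shape preserved.

    Rotation and zoom about the patch center are composed into a single
    bilinear resampling (one interpolation, not two).  The identity triple
    (0, 1.0, False) returns the pixels bit-unchanged.
    """
    dtype = pixels.dtype
    x = pixels
    if flip:
        x = x[:, ::-1]
    if angle != 0.0 or zoom != 1.0:
        x = x.astype(np.float64)
        theta = np.deg2rad(angle)
        # Inverse map: out = zoom * R(theta) @ (in - c) + c, so
        # in = (R(-theta)/zoom) @ (out - c) + c.
        rot = np.array([[np.cos(theta), np.sin(theta)],
                        [-np.sin(theta), np.cos(theta)]])
        matrix = rot / zoom
        c = (np.array(x.shape, float) - 1.0) / 2.0
        offset = c - matrix @ c
        x = ndimage.affine_transform(x, matrix, offset=offset, order=1,
                                     mode="reflect")
        if np.issubdtype(dtype, np.integer):
            x = np.clip(np.rint(x), 0, 255)
    return np.ascontiguousarray(x.astype(dtype))


def augment(patch: LabeledPatch, cfg: AugmentConfig,
            rng: np.random.Generator) -> LabeledPatch:
    """Randomly augmented copy of a patch; the label is never touched."""
    angle, zoom, flip = augment_draw(cfg, rng)
    return LabeledPatch(
        pixels=apply_augment(patch.pixels, angle, zoom, flip),
        label=patch.label,
        origin=patch.origin,
    )
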