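"""Synthetic reflectance confocal microscopy (RCM) slice generator.

Real in vivo RCM of basal cell carcinoma shows bright tumor islands —
compact cellular aggregates with elevated local reflectance — embedded in
speckle-textured stroma and often demarcated by a dark peripheral fissure.
This module emulates those appearance statistics (not cell-level anatomy):
each slice is a smooth stromal background carrying multiplicative
Gamma-distributed speckle, with elliptical tumor islands whose texture is
contrast-shifted upward and ringed by a darker band.  Ground-truth masks
mark the island interiors only, mirroring expert annotation of the compact
clusters rather than the surrounding stroma.

Slices are grouped into stacks (one scan site) and cases (one patient), the
grouping the cross-validation runner stratifies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "GeneratorParams",
    "AnnotatedSlice",
    "Stack",
    "slice_rng",
    "generate_slice",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

# Gray level of healthy stroma on the 8-bit scale, and the multiplicative
# attenuation inside the dark peripheral fissure.
STROMA_LEVEL = 90.0
FISSURE_FACTOR = 0.45
# Amplitude and correlation length (px) of the smooth background modulation.
BACKGROUND_AMPLITUDE = 0.12
BACKGROUND_SCALE_PX = 60.0
# Spatial correlation (px) imposed on the speckle field.
SPECKLE_BLUR_PX = 1.0

N_CRITERIA = 5  # annotation criteria available for the multi-criterion mask


@dataclass(frozen=True)
class GeneratorParams:
    """Conditions of a synthetic RCM study.

    Sizes are in pixels on the native 1000 x 1000 grid (at the instrument's
    ~0.5 um/px sampling a 1000-px field is ~0.5 mm of skin).
    ``lesion_axis_px`` bounds the tumor-island semi-axes: 110-230 px
    (~55-115 um) spans typical basaloid island cross-sections.
    ``lesion_contrast`` is the fractional reflectance elevation of island
    texture over stroma; ``speckle_shape`` is the Gamma shape of the
    mean-one multiplicative speckle (shape 8 gives ~35% intensity CV,
    coherent-imaging-like texture).
    """

    image_height: int = 1000
    image_width: int = 1000
    n_lesions_per_slice: tuple[int, int] = (1, 3)
    lesion_axis_px: tuple[float, float] = (110.0, 230.0)
    lesion_contrast: float = 0.8
    fissure_width_px: float = 6.0
    speckle_shape: float = 8.0
    slices_per_stack: int = 10
    stacks_per_case: int = 3
    n_cases: int = 14
    seed: int = 0
    multi_criterion: bool = False

    def validate(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        lo, hi = self.n_lesions_per_slice
        if lo < 0 or hi < lo:
            raise ValueError("invalid n_lesions_per_slice range")
        alo, ahi = self.lesion_axis_px
        if alo <= 0 or ahi < alo:
            raise ValueError("lesion_axis_px must be a positive range")
        if self.lesion_contrast < 0:
            raise ValueError("lesion_contrast must be >= 0")
        if self.fissure_width_px < 0:
            raise ValueError("fissure_width_px must be >= 0")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be > 0")
        if min(self.slices_per_stack, self.stacks_per_case, self.n_cases) < 1:
            raise ValueError("dataset counts must be >= 1")
        margin = 2 * (ahi + self.fissure_width_px)
        if hi > 0 and margin >= min(self.image_height, self.image_width):
            raise ValueError(
                f"largest lesion (diameter+fissure {margin:.0f}px) does not fit "
                f"inside a {self.image_height}x{self.image_width} image"
            )

    def expected_lesion_fraction(self) -> float:
        """Analytic expectation of the per-slice lesion-pixel fraction.

        Mean ellipse area pi*E[a]*E[b] with independent uniform semi-axes,
        times the mean lesion count, over the image area.  Holds when
        islands are placed without overlap (which the generator enforces).
        """
        alo, ahi = self.lesion_axis_px
        mean_axis = 0.5 * (alo + ahi)
        mean_n = 0.5 * sum(self.n_lesions_per_slice)
        return mean_n * math.pi * mean_axis**2 / (self.image_height * self.image_width)


@dataclass
class AnnotatedSlice:
    """One RCM image with its pixel-aligned lesion annotation."""

    image: np.ndarray          # (H, W) uint8
    mask: np.ndarray           # (H, W) uint8 in {0, 1}; 1 = malignant
    case_id: str
    stack_id: str
    slice_index: int
    criterion_mask: np.ndarray | None = None  # optional palette 0..5

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be binary {0,1}")


@dataclass
class Stack:
    """Ordered slices from one scan site of one case."""

    slices: list[AnnotatedSlice]

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("stack must be non-empty")
        ids = {(s.case_id, s.stack_id) for s in self.slices}
        if len(ids) != 1:
            raise ValueError("slices of a stack must share case_id and stack_id")
        idx = [s.slice_index for s in self.slices]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("slice_index must be strictly increasing")

    @property
    def case_id(self) -> str:
        return self.slices[0].case_id

    @property
    def stack_id(self) -> str:
        return self.slices[0].stack_id


def slice_rng(params: GeneratorParams, case: int, stack: int, slice_index: int
              ) -> np.random.Generator:
    """Deterministic per-slice generator so any slice is regenerable alone."""
    seq = np.random.SeedSequence(params.seed, spawn_key=(case, stack, slice_index))
    return np.random.default_rng(seq)


def _ellipse_fields(shape: tuple[int, int], cx: float, cy: float, a: float, b: float,
                    theta: float, fissure: float) -> tuple[np.ndarray, np.ndarray]:
    """Boolean interior and fissure-band fields of a rotated ellipse.

    Computed only on the bounding box for speed.
    """
    h, w = shape
    r_out = max(a, b) + fissure + 1.0
    y0, y1 = max(0, int(cy - r_out)), min(h, int(cy + r_out) + 1)
    x0, x1 = max(0, int(cx - r_out)), min(w, int(cx + r_out) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inner = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    outer = (u / (a + fissure)) ** 2 + (v / (b + fissure)) ** 2 <= 1.0
    interior = np.zeros(shape, bool)
    band = np.zeros(shape, bool)
    interior[y0:y1, x0:x1] = inner
    band[y0:y1, x0:x1] = outer & ~inner
    return interior, band


def generate_slice(params: GeneratorParams, rng: np.random.Generator,
                   case_id: str = "case00", stack_id: str = "stack0",
                   slice_index: int = 0) -> AnnotatedSlice:
    """Render one synthetic RCM slice with its ground-truth mask.

    Deterministic given ``rng``'s state.  Islands are placed fully inside
    the frame and non-overlapping (rejection sampling); an island that
    cannot be placed after many tries is dropped.
    """
    params.validate()
    h, w = params.image_height, params.image_width

    # Smooth stromal background modulation.
    noise = rng.standard_normal((h, w))
    smooth = ndimage.gaussian_filter(noise, BACKGROUND_SCALE_PX, mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth /= sd
    base = STROMA_LEVEL * (1.0 + BACKGROUND_AMPLITUDE * smooth)

    # Tumor islands: contrast-shifted interior, dark fissure ring.
    n_lo, n_hi = params.n_lesions_per_slice
    n_lesions = int(rng.integers(n_lo, n_hi + 1))
    mask = np.zeros((h, w), np.uint8)
    crit_mask = np.zeros((h, w), np.uint8) if params.multi_criterion else None
    gain = np.ones((h, w))
    placed: list[tuple[float, float, float]] = []
    fis = params.fissure_width_px
    for _ in range(n_lesions):
        for _attempt in range(200):
            a = rng.uniform(*params.lesion_axis_px)
            b = rng.uniform(*params.lesion_axis_px)
            theta = rng.uniform(0.0, math.pi)
            r = max(a, b) + fis + 2.0
            cx = rng.uniform(r, w - r)
            cy = rng.uniform(r, h - r)
            if all((cx - px) ** 2 + (cy - py) ** 2 > (r + pr) ** 2
                   for px, py, pr in placed):
                placed.append((cx, cy, r))
                interior, band = _ellipse_fields((h, w), cx, cy, a, b, theta, fis)
                gain[interior] = 1.0 + params.lesion_contrast
                gain[band] = FISSURE_FACTOR
                mask[interior] = 1
                if crit_mask is not None:
                    crit_mask[interior] = 1 + int(rng.integers(0, N_CRITERIA))
                break

    # Multiplicative mean-one Gamma speckle with short-range correlation.
    speckle = rng.gamma(params.speckle_shape, 1.0 / params.speckle_shape, (h, w))
    speckle = ndimage.gaussian_filter(speckle, SPECKLE_BLUR_PX, mode="reflect")
    image = base * gain * speckle
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return AnnotatedSlice(image, mask, case_id, stack_id, slice_index,
                          criterion_mask=crit_mask)


def generate_dataset(params: GeneratorParams) -> list[Stack]:
    """Generate ``n_cases * stacks_per_case`` stacks, grouped by case.

    Per-slice seeds are spawned from the master seed, so any slice can be
    regenerated in isolation with :func:`slice_rng`.
    """
    params.validate()
    stacks: list[Stack] = []
    for c in range(params.n_cases):
        case_id = f"case{c:02d}"
        for s in range(params.stacks_per_case):
            stack_id = f"stack{s}"
            slices = [
                generate_slice(params, slice_rng(params, c, s, z),
                               case_id=case_id, stack_id=stack_id, slice_index=z)
                for z in range(params.slices_per_stack)
            ]
            stacks.append(Stack(slices))
    return stacks


_PALETTE = [0, 0, 0, 255, 0, 0, 0, 255, 0, 0, 0, 255,
            255, 255, 0, 255, 0, 255, 0, 255, 255]


def write_dataset(stacks: list[Stack], out_dir: str | Path) -> list[Path]:
    """Write slices as grayscale PNG and masks as paletted PNG.

    Files are named ``{case}_{stack}_{slice:03d}.png`` and
    ``..._mask.png`` (palette index 0 = background, 1 = lesion, 2-6 =
    per-criterion labels when a multi-criterion mask is present).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for stack in stacks:
        for s in stack.slices:
            stem = f"{s.case_id}_{s.stack_id}_{s.slice_index:03d}"
            img_path = out / f"{stem}.png"
            Image.fromarray(s.image, mode="L").save(img_path)
            m = s.criterion_mask if s.criterion_mask is not None else s.mask
            pm = Image.fromarray(m.astype(np.uint8), mode="P")
            pm.putpalette(_PALETTE + [0] * (768 - len(_PALETTE)))
            mask_path = out / f"{stem}_mask.png"
            pm.save(mask_path)
            written += [img_path, mask_path]
    return written


def read_dataset(in_dir: str | Path) -> list[Stack]:
    """Load a directory written by :func:`write_dataset` back into stacks."""
    in_dir = Path(in_dir)
    by_stack: dict[tuple[str, str], list[AnnotatedSlice]] = {}
    for img_path in sorted(in_dir.glob("*.png")):
        if img_path.stem.endswith("_mask"):
            continue
        case_id, stack_id, idx = img_path.stem.rsplit("_", 2)
        raw = np.asarray(Image.open(in_dir / f"{img_path.stem}_mask.png"))
        sl = AnnotatedSlice(
            image=np.asarray(Image.open(img_path).convert("L")),
            mask=(raw > 0).astype(np.uint8),
            case_id=case_id, stack_id=stack_id, slice_index=int(idx),
            criterion_mask=raw.astype(np.uint8) if raw.max() > 1 else None,
        )
        by_stack.setdefault((case_id, stack_id), []).append(sl)
    return [Stack(sorted(sls, key=lambda s: s.slice_index))
            for _, sls in sorted(by_stack.items())]
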