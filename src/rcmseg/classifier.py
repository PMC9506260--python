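"""Depthwise-separable patch classifier and its training loop.

The backbone follows the MobileNet-v1 stage plan — a strided stem followed
by 13 depthwise-separable stages whose strides multiply to 32, with a
width multiplier (0.5 gives the 512 final channels of the full-scale
model) — but every convolution's kernel size equals its stride.
Downsampling stages therefore use 2x2 kernels on non-overlapping tiles and
stride-1 stages are 1x1.  The receptive field of each cell in the final
feature grid is exactly its own aligned 32x32 input block, which is what
lets the dense expansion (:mod:`rcmseg.dense`) reproduce sliding-window
patch inference exactly instead of only approximately.

A 256x256 patch yields an 8x8 feature grid; global average pooling and a
2-way fully connected softmax head produce the (healthy, malignant)
probability pair.  The whole model runs on the NumPy core in
:mod:`rcmseg.nn`; training uses Adam with cross-entropy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .patches import AugmentConfig, LabeledPatch, apply_augment, augment_draw

__all__ = [
    "BackboneSpec",
    "TrainConfig",
    "PatchModel",
    "build_model",
    "train",
    "predict_patch",
    "save_model",
    "load_model",
]

# MobileNet-v1 stage plan at width 1.0: (out_channels, stride) after a
# 32-channel stride-2 stem.
_MOBILENET_STEM = (32, 2)
_MOBILENET_BLOCKS = (
    (64, 1), (128, 2), (128, 1), (256, 2), (256, 1), (512, 2),
    (512, 1), (512, 1), (512, 1), (512, 1), (512, 1), (1024, 2), (1024, 1),
)


@dataclass(frozen=True)
class BackboneSpec:
    """Backbone stage plan; strides (stem included) must multiply to 32."""

    stem_channels: int = 16
    stem_stride: int = 2
    block_pattern: tuple[tuple[int, int], ...] = tuple(
        (max(2, c // 2), s) for c, s in _MOBILENET_BLOCKS)
    total_stride: int = 32

    def __post_init__(self) -> None:
        prod = self.stem_stride * math.prod(s for _, s in self.block_pattern)
        if prod != self.total_stride:
            raise ValueError(
                f"stage strides multiply to {prod}, expected {self.total_stride}")
        if any(c < 1 for c, _ in self.block_pattern):
            raise ValueError("channel counts must be positive")

    @property
    def final_channels(self) -> int:
        return self.block_pattern[-1][0]

    @classmethod
    def mobilenet(cls, width: float = 0.5) -> "BackboneSpec":
        """Width-scaled MobileNet-v1 plan; width=0.5 ends at 512 channels."""
        scale = lambda c: max(2, round(c * width))
        return cls(stem_channels=scale(_MOBILENET_STEM[0]),
                   stem_stride=_MOBILENET_STEM[1],
                   block_pattern=tuple((scale(c), s) for c, s in _MOBILENET_BLOCKS))

    @classmethod
    def tiny(cls) -> "BackboneSpec":
        """Desk-test width (final feature depth 16)."""
        return cls.mobilenet(width=1.0 / 64.0)


@dataclass(frozen=True)
class TrainConfig:
    """Training recipe; defaults are the full-scale settings (Adam at
    1e-5 for 20 epochs, plain 2-class cross-entropy)."""

    learning_rate: float = 1e-5
    epochs: int = 20
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class PatchModel:
    """Separable-conv backbone + global-average-pool softmax head."""

    def __init__(self, spec: BackboneSpec, seed: int, patch_size: int = 256,
                 dtype=np.float64) -> None:
        if patch_size % spec.total_stride:
            raise ValueError("patch_size must be divisible by total_stride")
        self.spec = spec
        self.seed = seed
        self.patch_size = patch_size
        self.dtype = np.dtype(dtype)
        self.trained = False
        rng = np.random.default_rng(seed)
        # conv -> batch norm -> ReLU throughout, as in the reference
        # depthwise-separable architecture.
        layers: list[nn.Layer] = [
            nn.Rescale(),
            nn.BlockConv(spec.stem_stride, 1, spec.stem_channels, rng, dtype),
            nn.BatchNorm(spec.stem_channels, dtype),
            nn.ReLU(),
        ]
        c_in = spec.stem_channels
        for c_out, stride in spec.block_pattern:
            layers += [
                nn.DepthwiseBlockConv(stride, c_in, rng, dtype),
                nn.BatchNorm(c_in, dtype),
                nn.ReLU(),
                nn.PointwiseConv(c_in, c_out, rng, dtype),
                nn.BatchNorm(c_out, dtype),
                nn.ReLU(),
            ]
            c_in = c_out
        self.backbone = nn.Sequential(layers)
        self.pool = nn.GlobalAvgPool()
        self.head = nn.PointwiseConv(spec.final_channels, 2, rng, dtype)

    # -- forward passes -------------------------------------------------
    def features(self, x: np.ndarray) -> np.ndarray:
        """Backbone feature grid for an (B, H, W, 1) input; spatial dims
        must be divisible by the total stride."""
        return self.backbone.forward(np.asarray(x, self.dtype))

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        return self.head.forward(self.pool.forward(self.features(x)))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward_logits(x))

    # -- bookkeeping -----------------------------------------------------
    def named_params(self) -> list[tuple[str, nn.Layer, str]]:
        out = self.backbone.named_params()
        for name in self.head.params:
            out.append((f"head.{name}", self.head, name))
        return out

    def param_arrays(self) -> dict[str, np.ndarray]:
        return {key: layer.params[name] for key, layer, name in self.named_params()}

    def buffer_arrays(self) -> dict[str, np.ndarray]:
        """Non-trainable state (batch-norm running statistics)."""
        out = {}
        for i, layer in enumerate(self.backbone.layers):
            if isinstance(layer, nn.BatchNorm):
                out[f"{i}.running_mean"] = layer.running_mean
                out[f"{i}.running_var"] = layer.running_var
        return out


def build_model(spec: BackboneSpec, seed: int = 0, patch_size: int = 256,
                dtype=np.float64) -> PatchModel:
    """Untrained model with deterministic He initialization given seed.

    ``dtype`` float64 (default) for bit-tight checks; float32 trains
    noticeably faster at equal statistical behavior.
    """
    return PatchModel(spec, seed, patch_size, dtype)


def _as_batch(patch: np.ndarray, patch_size: int) -> tuple[np.ndarray, bool]:
    x = np.asarray(patch)
    single = False
    if x.ndim == 2:
        x = x[None, :, :, None]
        single = True
    elif x.ndim == 3:
        if x.shape == (patch_size, patch_size, 1):
            x = x[None]
            single = True
        else:  # (B, H, W)
            x = x[..., None]
    elif x.ndim != 4:
        raise ValueError(f"cannot interpret input of ndim {x.ndim} as patches")
    if x.shape[1:3] != (patch_size, patch_size):
        raise ValueError(
            f"patch spatial shape {x.shape[1:3]} != ({patch_size}, {patch_size})")
    return x, single


def predict_patch(model: PatchModel, patch: np.ndarray) -> np.ndarray:
    """(p_healthy, p_malignant) for one patch, or an (B, 2) array for a
    batch.  Probabilities are softmax-normalized; inference is pure."""
    if not model.trained:
        raise RuntimeError("model has not been trained; call train() first")
    x, single = _as_batch(patch, model.patch_size)
    probs = model.predict_proba(x)
    return probs[0] if single else probs


def train(model: PatchModel, patches: list[LabeledPatch], cfg: TrainConfig,
          aug: AugmentConfig | None = None) -> tuple[PatchModel, list[dict]]:
    """Train in place with Adam + cross-entropy; returns the model and a
    per-epoch log of mean loss and training accuracy.

    Augmentation, when given, is resampled on the fly each epoch.  A
    single-class patch set is rejected.
    """
    labels = np.array([int(p.label) for p in patches])
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires at least one patch of each class")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(cfg.learning_rate)
    named = model.named_params()
    n = len(patches)
    log: list[dict] = []
    model.backbone.set_training(True)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            imgs = []
            for i in idx:
                px = patches[i].pixels
                if aug is not None:
                    px = apply_augment(px, *augment_draw(aug, rng))
                imgs.append(px)
            x = np.stack(imgs).astype(model.dtype)[..., None]
            y = labels[idx]
            probs = nn.softmax(model.forward_logits(x))
            loss, dlogits = nn.cross_entropy(probs, y)
            g = model.head.backward(dlogits)
            g = model.pool.backward(g)
            model.backbone.backward(g)
            opt.step(named)
            losses.append(loss * len(idx))
            correct += int((probs.argmax(axis=1) == y).sum())
        log.append({"epoch": epoch, "loss": sum(losses) / n, "accuracy": correct / n})
    # Batch-norm statistics tracked by a momentum average lag behind the
    # final weights; re-estimate them with one sweep over the (clean)
    # training patches so inference normalization matches what was learned.
    for layer in model.backbone.layers:
        if isinstance(layer, nn.BatchNorm):
            layer.start_calibration()
    for start in range(0, n, max(cfg.batch_size, 64)):
        idx = np.arange(start, min(start + max(cfg.batch_size, 64), n))
        x = np.stack([patches[i].pixels for i in idx]).astype(model.dtype)[..., None]
        model.backbone.forward(x)
    for layer in model.backbone.layers:
        if isinstance(layer, nn.BatchNorm):
            layer.calibrating = False
    model.backbone.set_training(False)
    model.trained = True
    return model, log


def training_log_to_csv(log: list[dict], path) -> None:
    import pandas as pd

    pd.DataFrame(log).to_csv(path, index=False)


def save_model(model: PatchModel, path) -> None:
    """Checkpoint: parameter arrays plus the spec, as a single NPZ."""
    meta = {
        "stem_channels": model.spec.stem_channels,
        "stem_stride": model.spec.stem_stride,
        "block_pattern": [list(bs) for bs in model.spec.block_pattern],
        "total_stride": model.spec.total_stride,
        "seed": model.seed,
        "patch_size": model.patch_size,
        "trained": model.trained,
        "dtype": model.dtype.name,
    }
    arrays = {k.replace(".", "__"): v for k, v in model.param_arrays().items()}
    arrays.update({f"buf__{k.replace('.', '__')}": v
                   for k, v in model.buffer_arrays().items()})
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_model(path) -> PatchModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    spec = BackboneSpec(
        stem_channels=meta["stem_channels"], stem_stride=meta["stem_stride"],
        block_pattern=tuple(tuple(bs) for bs in meta["block_pattern"]),
        total_stride=meta["total_stride"])
    model = PatchModel(spec, meta["seed"], meta["patch_size"],
                       dtype=np.dtype(meta.get("dtype", "float64")))
    for key, layer, name in model.named_params():
        layer.params[name][...] = data[key.replace(".", "__")]
    for i, layer in enumerate(model.backbone.layers):
        if isinstance(layer, nn.BatchNorm):
            layer.running_mean[...] = data[f"buf__{i}__running_mean"]
            layer.running_var[...] = data[f"buf__{i}__running_var"]
    model.trained = bool(meta["trained"])
    return model
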