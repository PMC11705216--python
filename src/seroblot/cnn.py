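"""Strip-image CNN classification: preprocessing, the experimentally
specified architecture, data augmentation, and holdout training.

Image treatments: color (HxWx3), grayscale (HxWx1), and a compact Fourier
descriptor (per-row DFT magnitudes of the lowest 15 frequency bins,
log-compressed and min-max scaled, giving an Hx15x1 raster).  The study used
256x256 inputs; the edge size is a parameter so desk-scale runs can use
smaller rasters.

The experimental architecture is three conv blocks of 20/40/80 filters
(kernel size from {3, 7, 9}, same-size padding, batch norm + ReLU), 2x2 max
pooling after the first two blocks, a fully connected classification layer
and softmax.  Augmentation tops each class up to 250 images with random
affine transforms (rotation 10-30 deg, translation 0.1-0.3 of the side,
scale 0.5-1) or a kernel-7 Gaussian blur.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import AffineTransform, resize, warp

from . import nn
from .metrics import (ExperimentResult, HoldoutConfig, MetricsReport,
                      confusion, holdout_split, metrics_from_confusion)
from .profiles import to_grayscale
from .synth import StripImage, to_color

__all__ = [
    "KERNEL_SIZES",
    "IMAGE_MODES",
    "ConvBlock",
    "ArchitectureSpec",
    "TrainConfig",
    "AugmentConfig",
    "preprocess_image",
    "build_ecnn",
    "build_network",
    "augment_dataset",
    "train_and_evaluate",
    "prepare_tensors",
]

KERNEL_SIZES = (3, 7, 9)
IMAGE_MODES = ("color", "gray", "fourier")


@dataclass(frozen=True)
class ConvBlock:
    filters: int
    kernel: int
    padding_same: bool = True
    batch_norm: bool = True
    activation: str = "relu"
    pool: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.filters < 1:
            raise ValueError("filters must be positive")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of a small CNN (decoded genomes included)."""

    input_shape: tuple[int, int, int]  # (rows, cols, planes)
    conv_blocks: tuple[ConvBlock, ...]
    dense_blocks: tuple[int, ...]
    n_classes: int
    notes: str = ""

    def __post_init__(self) -> None:
        if len(self.conv_blocks) < 1:
            raise ValueError("need at least one conv block")
        if self.n_classes < 2:
            raise ValueError("need at least two output classes")
        if any(n < 1 for n in self.dense_blocks):
            raise ValueError("dense widths must be positive")
        h, w = self.input_shape[0], self.input_shape[1]
        for blk in self.conv_blocks:
            if blk.pool is not None:
                h, w = h // blk.pool[0], w // blk.pool[1]
                if h < 1 or w < 1:
                    raise ValueError("input too small for the configured pools")

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @staticmethod
    def from_yaml(path: str | Path) -> "ArchitectureSpec":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["conv_blocks"] = tuple(
            ConvBlock(**{**b, "pool": tuple(b["pool"]) if b["pool"] else None})
            for b in raw["conv_blocks"]
        )
        raw["dense_blocks"] = tuple(raw["dense_blocks"])
        raw["input_shape"] = tuple(raw["input_shape"])
        return ArchitectureSpec(**raw)


@dataclass(frozen=True)
class TrainConfig:
    """Epochs per treatment follow the study: 20 for color/gray inputs,
    70 for the Fourier descriptors, 10 for neuroevolution fitness."""

    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class AugmentConfig:
    target_per_class: int = 250
    rotation_deg: tuple[float, float] = (10.0, 30.0)
    translation_frac: tuple[float, float] = (0.1, 0.3)
    scale: tuple[float, float] = (0.5, 1.0)
    blur_kernel: int = 7
    seed: int = 0


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi - lo == 0:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def preprocess_image(
    strip: StripImage,
    mode: str,
    size: int = 256,
    n_descriptors: int = 15,
) -> np.ndarray:
    """Tensor-shaped raster for one strip, values in [0, 1].

    ``color`` -> (size, size, 3); ``gray`` -> (size, size, 1);
    ``fourier`` -> (size, n_descriptors, 1) built by resizing to a square
    grayscale raster, taking the per-row DFT magnitude of the lowest
    ``n_descriptors`` non-negative frequency bins (DC included), log(1+.)
    compression, and min-max scaling.
    """
    if mode not in IMAGE_MODES:
        raise ValueError(f"unknown image mode {mode!r}")
    if mode == "color":
        px = to_color(strip).pixels / 255.0
        return resize(px, (size, size, 3), anti_aliasing=True).astype(np.float32)
    gray = to_grayscale(strip.pixels) / 255.0
    gray = resize(gray, (size, size), anti_aliasing=True)
    if mode == "gray":
        return gray[:, :, None].astype(np.float32)
    spectrum = np.abs(np.fft.rfft(gray, axis=1))[:, :n_descriptors]
    return _minmax(np.log1p(spectrum))[:, :, None].astype(np.float32)


def build_ecnn(
    kernel: int,
    n_classes: int,
    input_shape: tuple[int, int, int] = (256, 256, 1),
) -> ArchitectureSpec:
    """The experimentally specified architecture.

    Conv filters 20/40/80, all at the requested kernel size, batch norm +
    ReLU per block, 2x2 pooling after blocks 1 and 2 only, then the fully
    connected softmax classifier.  Narrow inputs (e.g. the 15-column Fourier
    raster) pool along the row axis only, keeping the stack shape-safe.
    """
    if kernel not in KERNEL_SIZES:
        raise ValueError(f"kernel must be one of {KERNEL_SIZES}")
    rows, cols = input_shape[0], input_shape[1]
    if rows < 4:
        raise ValueError("input rows too small for two 2x2 pools")
    pool_w = 2 if cols >= 32 else 1
    if pool_w == 1 and cols < 1:
        raise ValueError("input columns must be positive")
    pool = (2, pool_w)
    blocks = (
        ConvBlock(20, kernel, pool=pool),
        ConvBlock(40, kernel, pool=pool),
        ConvBlock(80, kernel, pool=None),
    )
    return ArchitectureSpec(input_shape, blocks, (), n_classes, notes="ecnn")


def build_network(spec: ArchitectureSpec, rng: np.random.Generator) -> nn.Network:
    """Materialize an :class:`ArchitectureSpec` as a trainable network."""
    layers: list[nn.Layer] = []
    rows, cols, planes = spec.input_shape
    ch = planes
    for blk in spec.conv_blocks:
        layers.append(nn.Conv2D(ch, blk.filters, blk.kernel, rng))
        if blk.batch_norm:
            layers.append(nn.BatchNorm2D(blk.filters))
        layers.append(nn.ReLU())
        if blk.pool is not None:
            layers.append(nn.MaxPool2D(blk.pool))
            rows, cols = rows // blk.pool[0], cols // blk.pool[1]
        ch = blk.filters
    layers.append(nn.Flatten())
    width = ch * rows * cols
    for neurons in spec.dense_blocks:
        layers.append(nn.Dense(width, neurons, rng))
        layers.append(nn.ReLU())
        width = neurons
    layers.append(nn.Dense(width, spec.n_classes, rng))
    return nn.Network(layers)


def _affine_about_center(shape, rotation=0.0, translation=(0.0, 0.0), scale=1.0):
    h, w = shape[:2]
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    t = (AffineTransform(translation=center)
         + AffineTransform(rotation=rotation, scale=(scale, scale))
         + AffineTransform(translation=-center))
    return AffineTransform(matrix=t.params) + AffineTransform(translation=translation)


def _gauss_blur(px: np.ndarray, kernel: int) -> np.ndarray:
    # separable Gaussian with the requested odd kernel size (sigma = radius/3)
    radius = kernel // 2
    sigma = max(radius / 3.0, 1e-6)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-(x**2) / (2 * sigma**2))
    k /= k.sum()

    def conv_axis(img, axis):
        pad = [(0, 0)] * img.ndim
        pad[axis] = (radius, radius)
        padded = np.pad(img, pad, mode="edge")
        return np.apply_along_axis(
            lambda v: np.convolve(v, k, mode="valid"), axis, padded
        )

    return conv_axis(conv_axis(px, 0), 1)


def _transform_strip(strip: StripImage, rng: np.random.Generator,
                     cfg: AugmentConfig, new_id: str) -> StripImage:
    px = strip.pixels / 255.0
    kind = rng.integers(0, 4)
    if kind == 0:  # rotation, random sign
        angle = np.deg2rad(rng.uniform(*cfg.rotation_deg)) * rng.choice([-1.0, 1.0])
        tform = _affine_about_center(px.shape, rotation=angle)
        out = warp(px, tform.inverse, mode="edge", preserve_range=True)
    elif kind == 1:  # translation as a fraction of each side, random sign
        h, w = px.shape[:2]
        fy = rng.uniform(*cfg.translation_frac) * rng.choice([-1.0, 1.0])
        fx = rng.uniform(*cfg.translation_frac) * rng.choice([-1.0, 1.0])
        tform = AffineTransform(translation=(fx * w, fy * h))
        out = warp(px, tform.inverse, mode="edge", preserve_range=True)
    elif kind == 2:  # scale about the center
        s = rng.uniform(*cfg.scale)
        tform = _affine_about_center(px.shape, scale=s)
        out = warp(px, tform.inverse, mode="edge", preserve_range=True)
    else:  # Gaussian blur, fixed kernel
        out = _gauss_blur(px, cfg.blur_kernel)
    return StripImage(np.clip(out * 255.0, 0.0, 255.0), strip.label, new_id)


def augment_dataset(strips: list[StripImage],
                    config: AugmentConfig | None = None) -> list[StripImage]:
    """Top each class up to ``target_per_class`` images.

    Originals are retained untouched; each synthetic image is one original
    put through one randomly chosen transform and keeps its source's label.
    Deterministic under the config seed.
    """
    config = config or AugmentConfig()
    by_class: dict[str, list[StripImage]] = {}
    for s in strips:
        by_class.setdefault(s.label, []).append(s)
    for label, group in by_class.items():
        if len(group) > config.target_per_class:
            raise ValueError(
                f"class {label!r} has {len(group)} originals, above the "
                f"target {config.target_per_class}"
            )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA06]))
    out: list[StripImage] = []
    for label in sorted(by_class, key=str):
        group = by_class[label]
        out.extend(group)
        for i in range(config.target_per_class - len(group)):
            src = group[int(rng.integers(0, len(group)))]
            out.append(
                _transform_strip(src, rng, config,
                                 new_id=f"{src.patient_id}_aug{i + 1:03d}")
            )
    return out


def prepare_tensors(strips: list[StripImage], mode: str, size: int = 256,
                    n_descriptors: int = 15) -> tuple[np.ndarray, list[str]]:
    """Stack preprocessed strips into an NCHW float32 tensor plus labels."""
    rasters = [preprocess_image(s, mode, size, n_descriptors) for s in strips]
    x = np.stack(rasters).transpose(0, 3, 1, 2).astype(np.float32)
    return x, [s.label for s in strips]


def _fit_predict(spec, x_train, y_train, x_test, class_list, train_cfg, run):
    rng = np.random.default_rng(
        np.random.SeedSequence([train_cfg.seed, run, 0xEC])
    )
    net = build_network(spec, rng)
    try:
        nn.train_network(net, x_train, y_train, train_cfg.epochs, rng,
                         batch_size=train_cfg.batch_size,
                         lr=train_cfg.learning_rate)
    except nn.TrainingFailure as exc:
        raise nn.TrainingFailure(f"run {run}: {exc}") from exc
    return [class_list[i] for i in net.predict(x_test)]


def train_and_evaluate(
    spec: ArchitectureSpec,
    dataset: tuple[np.ndarray, list[str]],
    train_cfg: TrainConfig,
    holdout_cfg: HoldoutConfig,
    aggregation: str = "micro_ovr",
    positive_class: str | None = None,
) -> ExperimentResult:
    """Repeated-holdout training of one architecture.

    Each run reinitializes the network from a run-derived seed, minimizes
    cross-entropy for the configured epochs, and scores the test split.
    """
    x, labels = dataset
    class_list = sorted(set(labels), key=str)
    if len(class_list) > spec.n_classes:
        raise ValueError("dataset has more classes than the architecture output")
    y = np.array([class_list.index(lab) for lab in labels])
    per_run: list[MetricsReport] = []
    confusions = []
    for run in range(holdout_cfg.n_runs):
        tr, te = holdout_split(labels, holdout_cfg, run)
        pred = _fit_predict(spec, x[tr], y[tr], x[te], class_list, train_cfg, run)
        cm = confusion([labels[i] for i in te], pred)
        per_run.append(metrics_from_confusion(cm, aggregation, positive_class))
        confusions.append(cm)
    mean = MetricsReport(
        *(float(np.mean([getattr(r, f) for r in per_run]))
          for f in ("accuracy", "precision", "sensitivity", "specificity")),
        aggregation=aggregation,
    )
    fingerprint = hashlib.md5(
        json.dumps([str(spec), str(train_cfg), str(holdout_cfg)]).encode()
    ).hexdigest()[:12]
    return ExperimentResult(per_run, mean, fingerprint, confusions)
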