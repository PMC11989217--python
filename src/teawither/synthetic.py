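"""Synthetic withering-leaf image generator.

Emulates the structure of an hourly withering series for Jin Guan Yin fresh
leaves: 13 consecutive time-point classes whose moisture (wet basis) falls
from about 0.78 to about 0.49 while the leaf colour darkens from fresh green
toward dark olive, the leaf outline shrinks, and the surface texture
coarsens. The generator is purely phenomenological — any renderer satisfying
the monotone colour/area contracts would do — but it is deterministic under a
single seed, so every downstream stage (augmentation, features, training,
confidence-weighted moisture) is testable without any study data.

Each image is a ragged-edged superellipse leaf on a neutral grey background,
with a central vein, low-frequency blotch texture whose amplitude grows as
the leaf dries, and additive Gaussian pixel noise.
"""

from __future__ import annotations

import csv
import uuid
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "TRAINING_MOISTURE_LABELS",
    "HELD_OUT_MOISTURE",
    "DEFAULT_HELD_OUT_CLASSES",
    "thirteen_point_labels",
    "Provenance",
    "ImageSample",
    "SyntheticConfig",
    "generate_dataset",
    "make_withering_leaves",
    "holdout_split",
    "write_dataset",
]

#: Moisture labels (wet basis) of the ten trained withering time points.
TRAINING_MOISTURE_LABELS: tuple[float, ...] = (
    0.7843, 0.7714, 0.763, 0.7501, 0.699, 0.6654, 0.6372, 0.5671, 0.5177, 0.4863,
)

#: Measured moisture of the three time points customarily held out as an
#: external test set; each lies between its neighbouring trained labels.
HELD_OUT_MOISTURE: dict[int, float] = {1: 0.7799, 5: 0.7231, 9: 0.597}

DEFAULT_HELD_OUT_CLASSES: tuple[int, ...] = (1, 5, 9)


def thirteen_point_labels() -> tuple[float, ...]:
    """The full 13-point trajectory: trained labels with the three external
    time points inserted at indices 1, 5 and 9 (strictly decreasing)."""
    labels = list(TRAINING_MOISTURE_LABELS)
    out: list[float] = []
    for idx in range(13):
        if idx in HELD_OUT_MOISTURE:
            out.append(HELD_OUT_MOISTURE[idx])
        else:
            out.append(labels.pop(0))
    return tuple(out)


class Provenance(str, Enum):
    SYNTHETIC = "synthetic"
    AUGMENTED = "augmented"
    EXTERNAL = "external"


@dataclass
class ImageSample:
    """One RGB leaf image with its withering class and moisture label."""

    pixels: np.ndarray  # H x W x 3, uint8
    class_index: int
    moisture: float
    provenance: Provenance = Provenance.SYNTHETIC

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.pixels.size == 0:
            raise ValueError("empty image")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values outside [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if not 0.0 < self.moisture < 1.0:
            raise ValueError("moisture must be a fraction in (0, 1)")


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate the 13-time-point study layout.

    darkening_gain and shrink_gain are unitless couplings between dryness
    (normalized water loss) and, respectively, interior colour darkening and
    leaf-mask area shrinkage. noise_sd is the additive pixel-noise standard
    deviation in 8-bit intensity units.
    """

    n_classes: int = 13
    moisture_labels: tuple[float, ...] | None = None
    images_per_class: int = 10
    image_size: int = 64
    seed: int = 0
    noise_sd: float = 8.0
    darkening_gain: float = 1.0
    shrink_gain: float = 1.0

    def __post_init__(self):
        if self.moisture_labels is None:
            self.moisture_labels = self._default_labels()
        self.moisture_labels = tuple(float(m) for m in self.moisture_labels)
        if self.n_classes != len(self.moisture_labels):
            raise ValueError(
                f"n_classes={self.n_classes} but {len(self.moisture_labels)} labels"
            )
        if any(not 0.0 < m < 1.0 for m in self.moisture_labels):
            raise ValueError("moisture labels must lie in (0, 1)")
        diffs = np.diff(self.moisture_labels)
        if not np.all(diffs < 0):
            raise ValueError("moisture labels must be strictly decreasing")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.images_per_class < 1:
            raise ValueError("images_per_class must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def _default_labels(self) -> tuple[float, ...]:
        if self.n_classes == 13:
            return thirteen_point_labels()
        if self.n_classes == 10:
            return TRAINING_MOISTURE_LABELS
        # otherwise spread linearly over the same moisture range
        return tuple(
            float(m) for m in np.linspace(0.7843, 0.4863, self.n_classes)
        )


# colour anchors (RGB, 8-bit): fresh green leaf -> withered dark olive
_FRESH_RGB = np.array([74.0, 148.0, 58.0])
_DRY_RGB = np.array([96.0, 84.0, 38.0])
# moisture range used to normalize dryness; slightly wider than the labels
_M_WET, _M_DRY = 0.80, 0.45


def _dryness(moisture: float) -> float:
    return float(np.clip((_M_WET - moisture) / (_M_WET - _M_DRY), 0.0, 1.0))


def _leaf_mask(size: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Ragged superellipse leaf mask; ``scale`` shrinks the axes."""
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    a = 0.44 * size * scale  # semi-axis along x (leaf length)
    b = 0.30 * size * scale  # semi-axis along y (leaf width)
    theta = np.arctan2(yy - cy, xx - cx)
    # smooth angular raggedness from a few random harmonics
    edge = np.zeros_like(theta)
    for harmonic in (3, 5, 8):
        amp = rng.normal(0.0, 0.02)
        phase = rng.uniform(0, 2 * np.pi)
        edge += amp * np.sin(harmonic * theta + phase)
    r = ((np.abs(xx - cx) / a) ** 2.4 + (np.abs(yy - cy) / b) ** 2.4) ** (1 / 2.4)
    return r <= 1.0 + edge


def _blotch_texture(size: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency multiplicative blotches; coarser texture as leaves dry."""
    coarse = rng.normal(0.0, 1.0, size=(8, 8))
    tex = np.kron(coarse, np.ones((size // 8 + 1, size // 8 + 1)))[:size, :size]
    return 1.0 + amplitude * tex


def _render_leaf(cfg: SyntheticConfig, moisture: float,
                 rng: np.random.Generator) -> np.ndarray:
    size = cfg.image_size
    d = _dryness(moisture)
    scale = 1.0 - 0.25 * cfg.shrink_gain * d  # deterministic per class
    mask = _leaf_mask(size, scale, rng)
    base = _FRESH_RGB + cfg.darkening_gain * d * (_DRY_RGB - _FRESH_RGB)
    base = base + rng.normal(0.0, 1.0, size=3)  # small per-image colour jitter
    # dark neutral background (withering-trough cloth): keeps both the
    # darkening and the shrinkage effect pushing first-order gray statistics
    # the same way as moisture falls
    img = np.full((size, size, 3), 48.0)
    img += rng.normal(0.0, 2.0, size=img.shape)  # background grain
    tex = _blotch_texture(size, 0.04 + 0.10 * d, rng)
    leaf = base[None, None, :] * tex[:, :, None]
    # central vein: a brighter stripe along the long axis
    yy = np.abs(np.arange(size) - (size - 1) / 2.0)
    vein = 1.0 + 0.10 * np.exp(-(yy / (0.02 * size + 1.0)) ** 2)
    leaf = leaf * vein[:, None, None]
    img[mask] = leaf[mask]
    img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_dataset(cfg: SyntheticConfig) -> list[ImageSample]:
    """Render ``n_classes * images_per_class`` seeded leaf images.

    Deterministic: identical configs yield byte-identical pixel arrays. Class
    means of the interior green channel decrease strictly with class index
    (darkening with water loss) and mask area shrinks monotonically.
    """
    rng = np.random.default_rng(cfg.seed)
    samples: list[ImageSample] = []
    for class_index, moisture in enumerate(cfg.moisture_labels):
        for _ in range(cfg.images_per_class):
            pixels = _render_leaf(cfg, moisture, rng)
            samples.append(
                ImageSample(pixels, class_index, moisture, Provenance.SYNTHETIC)
            )
    return samples


def make_withering_leaves(
    n_classes: int = 13,
    images_per_class: int = 10,
    image_size: int = 64,
    seed: int = 0,
    **kwargs,
):
    """Convenience maker: returns (X, y, moisture) arrays.

    X is (n, H, W, 3) uint8, y the class indices, moisture the per-sample
    wet-basis labels.
    """
    cfg = SyntheticConfig(
        n_classes=n_classes,
        images_per_class=images_per_class,
        image_size=image_size,
        seed=seed,
        **kwargs,
    )
    samples = generate_dataset(cfg)
    X = np.stack([s.pixels for s in samples])
    y = np.array([s.class_index for s in samples])
    m = np.array([s.moisture for s in samples])
    return X, y, m


def holdout_split(
    samples: list[ImageSample], held_classes
) -> tuple[list[ImageSample], list[ImageSample]]:
    """Partition samples into (train, external) by whole withering classes."""
    held = set(int(c) for c in held_classes)
    present = {s.class_index for s in samples}
    unknown = held - present
    if unknown:
        raise ValueError(f"unknown class indices in holdout: {sorted(unknown)}")
    train = [s for s in samples if s.class_index not in held]
    external = [s for s in samples if s.class_index in held]
    return train, external


def write_dataset(samples: list[ImageSample], root) -> Path:
    """Write a class-per-directory PNG tree plus labels.csv."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    labels: dict[int, float] = {}
    for sample in samples:
        class_dir = root / str(sample.class_index)
        class_dir.mkdir(exist_ok=True)
        Image.fromarray(sample.pixels).save(class_dir / f"{uuid.uuid4().hex}.png")
        labels[sample.class_index] = sample.moisture
    with open(root / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class_index", "moisture"])
        for idx in sorted(labels):
            writer.writerow([idx, labels[idx]])
    return root
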