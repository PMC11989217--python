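"""Dataset loading, train/validation splitting and image augmentation.

Datasets live on disk as class-per-directory PNG/JPEG trees with a
``labels.csv`` mapping class index to wet-basis moisture, the same layout
the synthetic generator writes, so real and synthetic data flow through one
path.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize, rotate as _sk_rotate

from .synthetic import ImageSample, Provenance

__all__ = [
    "DatasetManifest",
    "load_manifest",
    "load_samples",
    "split_train_validation",
    "augment",
    "augment_dataset",
]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass
class DatasetManifest:
    root: Path
    classes: tuple[int, ...]
    files: dict[int, tuple[Path, ...]]
    labels: dict[int, float]

    @property
    def n_images(self) -> int:
        return sum(len(v) for v in self.files.values())

    def all_files(self) -> list[tuple[Path, int]]:
        return [(f, c) for c in self.classes for f in self.files[c]]


def load_manifest(root) -> DatasetManifest:
    """Scan a class-per-directory tree and its labels.csv."""
    root = Path(root)
    labels_path = root / "labels.csv"
    if not labels_path.exists():
        raise FileNotFoundError(f"no labels.csv under {root}")
    labels: dict[int, float] = {}
    with open(labels_path) as fh:
        for row in csv.DictReader(fh):
            labels[int(row["class_index"])] = float(row["moisture"])
    files: dict[int, tuple[Path, ...]] = {}
    for class_dir in sorted((p for p in root.iterdir() if p.is_dir()),
                            key=lambda p: int(p.name)):
        idx = int(class_dir.name)
        found = tuple(
            sorted(p for p in class_dir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        )
        if not found:
            raise ValueError(f"class directory {class_dir} holds no images")
        if idx not in labels:
            raise ValueError(f"class {idx} missing from labels.csv")
        files[idx] = found
    if not files:
        raise ValueError(f"no class directories under {root}")
    return DatasetManifest(root, tuple(sorted(files)), files, labels)


def load_samples(manifest: DatasetManifest, size: int | None = None) -> list[ImageSample]:
    """Decode every image in the manifest (optionally resized to size x size)."""
    samples = []
    for path, class_index in manifest.all_files():
        img = Image.open(path).convert("RGB")
        if size is not None:
            img = img.resize((size, size), Image.BILINEAR)
        samples.append(
            ImageSample(
                np.asarray(img, dtype=np.uint8),
                class_index,
                manifest.labels[class_index],
                Provenance.EXTERNAL,
            )
        )
    return samples


def split_train_validation(items, ratio_train: float = 0.9, seed: int = 0,
                           stratify: bool = False):
    """Seeded disjoint/exhaustive split; validation takes the floor of the
    validation share of the whole pool (556 items at 0.9 -> 501/55).

    ``items`` may be a list (of samples, paths, anything) or a
    DatasetManifest; manifests split over their image files and return two
    manifests. With ``stratify`` the floor rule applies per class instead.
    """
    if not 0.0 < ratio_train < 1.0:
        raise ValueError("ratio_train must lie strictly between 0 and 1")

    if isinstance(items, DatasetManifest):
        pairs = items.all_files()
        if stratify:
            tr, va = _split_stratified(pairs, ratio_train, seed)
        else:
            tr, va = split_train_validation(pairs, ratio_train, seed)
        return (_manifest_from_pairs(items, tr), _manifest_from_pairs(items, va))

    items = list(items)
    if not items:
        raise ValueError("cannot split an empty pool")
    if stratify:
        key = lambda it: it.class_index  # noqa: E731 - samples only
        groups: dict = {}
        for it in items:
            groups.setdefault(key(it), []).append(it)
        train, val = [], []
        for g, (cls, members) in enumerate(sorted(groups.items())):
            t, v = split_train_validation(members, ratio_train, seed + g)
            train += t
            val += v
        return train, val
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n_val = math.floor((1.0 - ratio_train) * len(items) + 1e-9)
    val_idx = set(order[:n_val].tolist())
    train = [it for i, it in enumerate(items) if i not in val_idx]
    val = [it for i, it in enumerate(items) if i in val_idx]
    return train, val


def _split_stratified(pairs, ratio_train, seed):
    groups: dict[int, list] = {}
    for path, cls in pairs:
        groups.setdefault(cls, []).append((path, cls))
    train, val = [], []
    for g, (cls, members) in enumerate(sorted(groups.items())):
        t, v = split_train_validation(members, ratio_train, seed + g)
        train += t
        val += v
    return train, val


def _manifest_from_pairs(src: DatasetManifest, pairs) -> DatasetManifest:
    files: dict[int, list[Path]] = {}
    for path, cls in pairs:
        files.setdefault(cls, []).append(path)
    classes = tuple(sorted(files))
    return DatasetManifest(
        src.root,
        classes,
        {c: tuple(files[c]) for c in classes},
        {c: src.labels[c] for c in classes},
    )


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------
def _resize_uint8(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if img.shape[:2] == shape:
        return img.astype(np.uint8)
    out = _sk_resize(img.astype(np.float64), shape, order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def _apply_op(pixels: np.ndarray, op: dict, rng: np.random.Generator) -> np.ndarray:
    kind = op["kind"]
    h, w = pixels.shape[:2]
    if kind == "flip":
        direction = op.get("direction", "horizontal")
        axis = 1 if direction == "horizontal" else 0
        return np.flip(pixels, axis=axis)
    if kind == "rotate":
        angle = op.get("angle")
        if angle is None:
            angle = float(rng.uniform(-30.0, 30.0))
        angle = float(angle) % 360.0
        if angle % 90.0 == 0.0:
            # exact index permutation for right-angle rotations
            return np.rot90(pixels, k=int(angle // 90))
        out = _sk_rotate(pixels.astype(np.float64), angle, resize=True, order=1,
                         mode="edge", preserve_range=True)
        return np.clip(np.round(out), 0, 255).astype(np.uint8)
    if kind == "crop":
        frac = op.get("fraction")
        if frac is None:
            frac = float(rng.uniform(0.7, 0.95))
        if not 0.0 < frac <= 1.0:
            raise ValueError("crop fraction must lie in (0, 1]")
        ch, cw = max(1, round(frac * h)), max(1, round(frac * w))
        if ch > h or cw > w:
            raise ValueError("crop window larger than image")
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        return pixels[top : top + ch, left : left + cw]
    if kind == "brightness":
        factor = op.get("factor")
        if factor is None:
            factor = float(rng.uniform(0.7, 1.3))
        if factor <= 0:
            raise ValueError("brightness factor must be positive")
        out = pixels.astype(np.float64) * factor
        return np.clip(np.round(out), 0, 255).astype(np.uint8)
    raise ValueError(f"unknown augmentation op {kind!r}")


def augment(sample: ImageSample, ops, seed: int = 0,
            out_size: tuple[int, int] | None = None) -> list[ImageSample]:
    """Apply each requested op independently to one sample.

    Ops are dicts like ``{"kind": "flip", "direction": "horizontal"}``,
    ``{"kind": "rotate", "angle": 90}``, ``{"kind": "crop", "fraction": 0.8}``
    or ``{"kind": "brightness", "factor": 1.2}``; unspecified parameters are
    drawn from the seeded stream. Outputs are resized back to ``out_size``
    (default: the input's resolution), inherit class and moisture labels and
    are marked augmented.
    """
    ops = [{"kind": op} if isinstance(op, str) else dict(op) for op in ops]
    if not ops:
        raise ValueError("at least one augmentation op required")
    shape = out_size or sample.pixels.shape[:2]
    rng = np.random.default_rng(seed)
    out = []
    for op in ops:
        pixels = _apply_op(sample.pixels, op, rng)
        out.append(
            ImageSample(
                _resize_uint8(pixels, tuple(shape)),
                sample.class_index,
                sample.moisture,
                Provenance.AUGMENTED,
            )
        )
    return out


def augment_dataset(samples, per_image: int = 3, seed: int = 0,
                    out_size: tuple[int, int] | None = None) -> list[ImageSample]:
    """Random crop/rotate/flip/brightness expansion: ``per_image`` augmented
    copies per input (originals are kept by the caller if wanted)."""
    rng = np.random.default_rng(seed)
    kinds = ("crop", "rotate", "flip", "brightness")
    out: list[ImageSample] = []
    for sample in samples:
        for _ in range(per_image):
            kind = kinds[int(rng.integers(0, len(kinds)))]
            op: dict = {"kind": kind}
            if kind == "flip":
                op["direction"] = "horizontal" if rng.random() < 0.5 else "vertical"
            out += augment(sample, [op], seed=int(rng.integers(0, 2**31 - 1)),
                           out_size=out_size)
    return out
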