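"""Contracts of the synthetic withering-series generator."""

import numpy as np
import pytest

from teawither import (
    HELD_OUT_MOISTURE,
    TRAINING_MOISTURE_LABELS,
    ImageSample,
    SyntheticConfig,
    generate_dataset,
    holdout_split,
    thirteen_point_labels,
    write_dataset,
)
from teawither.dataio import load_manifest, load_samples


def test_thirteen_point_trajectory_is_strictly_decreasing():
    labels = thirteen_point_labels()
    assert len(labels) == 13
    assert all(a > b for a, b in zip(labels, labels[1:]))
    # held-out positions carry the external time-point moistures, the rest
    # the ten trained labels in order
    assert all(labels[i] == HELD_OUT_MOISTURE[i] for i in (1, 5, 9))
    kept = [labels[i] for i in range(13) if i not in HELD_OUT_MOISTURE]
    assert tuple(kept) == TRAINING_MOISTURE_LABELS


def test_sample_counts_and_label_fidelity():
    cfg = SyntheticConfig(n_classes=13, images_per_class=10, image_size=32, seed=1)
    samples = generate_dataset(cfg)
    assert len(samples) == 130
    per_class = {}
    for s in samples:
        per_class.setdefault(s.class_index, []).append(s)
        assert s.moisture == cfg.moisture_labels[s.class_index]
        assert s.pixels.dtype == np.uint8
        assert s.pixels.shape == (32, 32, 3)
    assert all(len(v) == 10 for v in per_class.values())


def test_seeded_determinism_is_byte_identical():
    cfg = dict(n_classes=5, images_per_class=3, image_size=32, seed=42)
    a = generate_dataset(SyntheticConfig(**cfg))
    b = generate_dataset(SyntheticConfig(**cfg))
    for sa, sb in zip(a, b):
        assert np.array_equal(sa.pixels, sb.pixels)
    c = generate_dataset(SyntheticConfig(**{**cfg, "seed": 43}))
    assert any(not np.array_equal(sa.pixels, sc.pixels) for sa, sc in zip(a, c))


def _leafish_mask(pixels):
    # background is neutral grey (R~G~B); leaf interior is green-dominant
    p = pixels.astype(int)
    return (p[:, :, 1] - p[:, :, 0] > 15) | (p[:, :, 1] - p[:, :, 2] > 40)


def test_green_intensity_monotone_in_moisture(small_dataset):
    """Class-mean interior green channel strictly decreases with class index,
    checked against an independent per-pixel loop oracle."""
    _, samples = small_dataset
    class_means = []
    for c in sorted({s.class_index for s in samples}):
        greens = []
        for s in (s for s in samples if s.class_index == c):
            mask = _leafish_mask(s.pixels)
            total = n = 0
            for i in range(s.pixels.shape[0]):  # explicit pixel loop oracle
                for j in range(s.pixels.shape[1]):
                    if mask[i, j]:
                        total += int(s.pixels[i, j, 1])
                        n += 1
            greens.append(total / n)
            # oracle agrees with the vectorized mean
            assert abs(greens[-1] - s.pixels[:, :, 1][mask].mean()) < 1e-9
        class_means.append(np.mean(greens))
    diffs = np.diff(class_means)
    assert np.all(diffs < 0)


def test_leaf_area_shrinks_with_class_index(small_dataset):
    _, samples = small_dataset
    areas = []
    for c in sorted({s.class_index for s in samples}):
        areas.append(
            np.mean([_leafish_mask(s.pixels).sum() for s in samples
                     if s.class_index == c])
        )
    assert np.all(np.diff(areas) <= 0)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"image_size": 16},
        {"images_per_class": 0},
        {"n_classes": 3, "moisture_labels": (0.7, 0.7, 0.6)},  # not strict
        {"n_classes": 3, "moisture_labels": (0.7, 0.8, 0.6)},  # not decreasing
        {"n_classes": 2, "moisture_labels": (1.2, 0.6)},  # out of (0,1)
        {"n_classes": 4, "moisture_labels": (0.7, 0.6)},  # count mismatch
        {"noise_sd": -1.0},
    ],
)
def test_invalid_configs_raise(kwargs):
    with pytest.raises(ValueError):
        SyntheticConfig(**kwargs)


def test_holdout_split_external_categories():
    cfg = SyntheticConfig(n_classes=13, images_per_class=2, image_size=32, seed=0)
    samples = generate_dataset(cfg)
    train, ext = holdout_split(samples, (1, 5, 9))
    assert {s.class_index for s in ext} == {1, 5, 9}
    assert len({s.class_index for s in train}) == 10
    ids = {id(s) for s in train} & {id(s) for s in ext}
    assert not ids


def test_holdout_split_edge_cases():
    cfg = SyntheticConfig(n_classes=3, images_per_class=5, image_size=32, seed=0,
                          moisture_labels=(0.7, 0.6, 0.5))
    samples = generate_dataset(cfg)
    train, ext = holdout_split(samples, ())
    assert len(train) == 15 and ext == []
    train, ext = holdout_split(samples, {0})
    # set-difference oracle: 1 of 3 classes of 5 images held out
    assert len(ext) == 5 and len(train) == 10
    assert all(s.class_index == 0 for s in ext)
    with pytest.raises(ValueError):
        holdout_split(samples, {7})


def test_written_tree_roundtrips(tmp_path):
    cfg = SyntheticConfig(n_classes=3, images_per_class=2, image_size=32, seed=5,
                          moisture_labels=(0.75, 0.65, 0.55))
    samples = generate_dataset(cfg)
    root = write_dataset(samples, tmp_path / "ds")
    manifest = load_manifest(root)
    assert manifest.classes == (0, 1, 2)
    assert manifest.n_images == 6
    assert manifest.labels == {0: 0.75, 1: 0.65, 2: 0.55}
    loaded = load_samples(manifest)
    # PNG is lossless: the multiset of pixel arrays matches exactly
    originals = sorted(s.pixels.tobytes() for s in samples)
    recovered = sorted(s.pixels.tobytes() for s in loaded)
    assert originals == recovered


def test_image_sample_validation():
    with pytest.raises(ValueError):
        ImageSample(np.zeros((4, 4), dtype=np.uint8), 0, 0.5)
    with pytest.raises(ValueError):
        ImageSample(np.full((4, 4, 3), 300.0), 0, 0.5)
    with pytest.raises(ValueError):
        ImageSample(np.zeros((4, 4, 3), dtype=np.uint8), 0, 1.5)
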