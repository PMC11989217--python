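"""First-order colour and texture descriptors of a leaf image.

The fifteen features are the classical inputs of chemometric moisture
models for tea imagery: nine colour metrics (channel means, colour angle of
the mean colour vector, mean saturation and luminance, super-green index
2G - R - B, red/green ratio, mean hue) and six grayscale-histogram texture
statistics (mean, standard deviation, smoothness, third moment, uniformity,
entropy). All are orderless image statistics, hence invariant to flips.

Definitions follow the standard first-order formulations: grayscale is the
ITU-R BT.601 luma; smoothness is R = 1 - 1/(1 + sigma^2) with sigma measured
on [0,1]-normalized gray; the third moment is sum((z - m)^3 p(z)) on
normalized gray; uniformity sum(p^2) and entropy -sum(p log2 p) use a
256-bin histogram; hue/saturation/value come from the HSV transform of the
[0,1] RGB channels; the colour angle is the hue (in degrees) of the mean
(R, G, B) vector, distinct from the mean per-pixel hue.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from skimage.color import rgb2hsv
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic import ImageSample

__all__ = ["FeatureVector", "FEATURE_NAMES", "extract_features", "ColorTextureFeaturizer"]


@dataclass(frozen=True)
class FeatureVector:
    mean_R: float
    mean_G: float
    mean_B: float
    color_angle: float
    mean_saturation: float
    mean_luminance: float
    super_green: float
    rg_ratio: float
    mean_hue: float
    gray_mean: float
    gray_sd: float
    smoothness: float
    third_moment: float
    uniformity: float
    entropy: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])


FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in fields(FeatureVector))


def extract_features(sample) -> FeatureVector:
    """Compute all fifteen descriptors of one RGB image.

    Accepts an ImageSample or an H x W x 3 array in [0, 255]. On an all-black
    image the red/green ratio is undefined and reported as NaN.
    """
    pixels = sample.pixels if isinstance(sample, ImageSample) else np.asarray(sample)
    if pixels.ndim != 3 or pixels.shape[2] != 3 or pixels.size == 0:
        raise ValueError("expected a non-empty H x W x 3 image")
    rgb = pixels.astype(np.float64)

    mean_rgb = rgb.reshape(-1, 3).mean(axis=0)
    mean_R, mean_G, mean_B = (float(v) for v in mean_rgb)

    # colour angle: hue of the mean colour vector, degrees in [0, 360)
    color_angle = float(
        rgb2hsv(np.clip(mean_rgb, 0, 255).reshape(1, 1, 3) / 255.0)[0, 0, 0] * 360.0
    )

    hsv = rgb2hsv(rgb / 255.0)
    mean_hue = float(hsv[..., 0].mean() * 360.0)
    mean_saturation = float(hsv[..., 1].mean())
    mean_luminance = float(hsv[..., 2].mean())

    super_green = 2.0 * mean_G - mean_R - mean_B
    rg_ratio = mean_R / mean_G if mean_G > 0 else float("nan")

    gray = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    gray_mean = float(gray.mean())
    gray_sd = float(gray.std())  # population SD: 0 for a constant image

    z = gray.ravel() / 255.0  # normalized gray for moment-based stats
    sigma = z.std()
    smoothness = float(1.0 - 1.0 / (1.0 + sigma**2))
    third_moment = float(((z - z.mean()) ** 3).mean())

    hist, _ = np.histogram(gray.ravel(), bins=256, range=(0.0, 256.0))
    p = hist / hist.sum()
    uniformity = float((p**2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())

    return FeatureVector(
        mean_R=mean_R,
        mean_G=mean_G,
        mean_B=mean_B,
        color_angle=color_angle,
        mean_saturation=mean_saturation,
        mean_luminance=mean_luminance,
        super_green=super_green,
        rg_ratio=rg_ratio,
        mean_hue=mean_hue,
        gray_mean=gray_mean,
        gray_sd=gray_sd,
        smoothness=smoothness,
        third_moment=third_moment,
        uniformity=uniformity,
        entropy=entropy,
    )


class ColorTextureFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: image stack -> (n, 15) feature matrix."""

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        return np.stack([extract_features(img).as_array() for img in X])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
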