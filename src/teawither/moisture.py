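"""Confidence-weighted moisture prediction and withering-degree decision.

The classifier assigns each image a softmax confidence vector over the
trained withering time-point classes. The continuous moisture estimate is
the expectation of the class moisture labels under that distribution,

    Y = sum_i Y_i * N_i,

where Y_i is the wet-basis moisture label of class i and N_i the class
confidence. Because the estimate is a convex combination of the labels it
can land between trained time points — which is what lets whole held-out
withering classes be predicted by interpolation.

Reported confidences are conventionally rounded to eight decimal places and
the weighted sum is taken over the rounded values without renormalizing, so
a vector whose printed sum is 0.99999997 is used exactly as printed.

The withering-degree verdict compares the estimate with the industry
moderate-withering band: moderate for moisture in [0.58, 0.66], insufficient
above 0.66, excessive below 0.58.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from .synthetic import TRAINING_MOISTURE_LABELS

__all__ = [
    "MoistureLabelTable",
    "WitheringDegree",
    "WitheringAssessment",
    "MODERATE_BAND",
    "predict_moisture",
    "assess_withering",
    "predict_sample",
    "predict_batch",
]

#: Industry moderate-withering moisture band (wet basis), inclusive ends.
MODERATE_BAND: tuple[float, float] = (0.58, 0.66)


class WitheringDegree(str, Enum):
    INSUFFICIENT = "insufficient"
    MODERATE = "moderate"
    EXCESSIVE = "excessive"


@dataclass(frozen=True)
class MoistureLabelTable:
    """Ordered map from class index to wet-basis moisture fraction."""

    labels: tuple[float, ...]

    def __post_init__(self):
        labels = tuple(float(v) for v in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ValueError("need at least two classes")
        if any(not 0.0 < v < 1.0 for v in labels):
            raise ValueError("moisture labels must lie in (0, 1)")
        if not all(a > b for a, b in zip(labels, labels[1:])):
            raise ValueError("moisture labels must be strictly decreasing")

    def __len__(self):
        return len(self.labels)

    def __getitem__(self, idx: int) -> float:
        return self.labels[idx]

    @property
    def n(self) -> int:
        """Highest class index (classes run 0..n)."""
        return len(self.labels) - 1

    @classmethod
    def reference(cls) -> "MoistureLabelTable":
        """The ten-point trained trajectory (0.7843 down to 0.4863)."""
        return cls(TRAINING_MOISTURE_LABELS)

    @classmethod
    def from_csv(cls, path) -> "MoistureLabelTable":
        rows: dict[int, float] = {}
        with open(path) as fh:
            for row in csv.DictReader(fh):
                rows[int(row["class_index"])] = float(row["moisture"])
        if sorted(rows) != list(range(len(rows))):
            raise ValueError("class indices must be contiguous from 0")
        return cls(tuple(rows[i] for i in range(len(rows))))

    def to_csv(self, path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["class_index", "moisture"])
            for i, m in enumerate(self.labels):
                writer.writerow([i, m])
        return path


@dataclass(frozen=True)
class WitheringAssessment:
    predicted_moisture: float
    degree: WitheringDegree
    confidences: tuple[float, ...]


def predict_moisture(confidences, table: MoistureLabelTable,
                     decimals: int | None = 8) -> float:
    """Expected moisture under the class-confidence distribution.

    Each confidence is rounded to ``decimals`` places first (None keeps full
    precision) and the weighted sum uses the rounded values as-is — no
    renormalization — matching the reporting convention for printed
    confidence tables. The pre-rounding vector must be non-negative and sum
    to 1 within 1e-6.
    """
    conf = np.asarray(confidences, dtype=np.float64)
    if conf.ndim != 1 or len(conf) != len(table):
        raise ValueError(
            f"confidence length {conf.shape} does not match {len(table)} classes"
        )
    if np.any(conf < 0):
        raise ValueError("confidences must be non-negative")
    if abs(conf.sum() - 1.0) > 1e-6:
        raise ValueError(f"confidences sum to {conf.sum():.8f}, not 1")
    if decimals is not None:
        conf = np.round(conf, decimals)
    value = float(np.dot(np.asarray(table.labels), conf))
    return round(value, decimals) if decimals is not None else value


def assess_withering(moisture: float) -> WitheringDegree:
    """Compare a moisture fraction with the moderate band [0.58, 0.66]."""
    if not 0.0 <= moisture <= 1.0:
        raise ValueError("moisture must be a fraction in [0, 1]")
    low, high = MODERATE_BAND
    if moisture > high:
        return WitheringDegree.INSUFFICIENT
    if moisture < low:
        return WitheringDegree.EXCESSIVE
    return WitheringDegree.MODERATE


def predict_sample(image, model, table: MoistureLabelTable,
                   decimals: int | None = 8) -> WitheringAssessment:
    """Classifier -> confidences -> moisture -> degree, for one image."""
    return predict_batch([image], model, table, decimals)[0]


def predict_batch(images, model, table: MoistureLabelTable,
                  decimals: int | None = 8) -> list[WitheringAssessment]:
    """Order-preserving batched assessment.

    ``model`` is anything with predict_proba over an (n, H, W, 3) stack whose
    class count matches the label table (e.g. a fitted LeafImageClassifier).
    """
    X = np.stack([np.asarray(im) for im in images])
    proba = model.predict_proba(X)
    if proba.shape[1] != len(table):
        raise ValueError(
            f"model outputs {proba.shape[1]} classes but table has {len(table)}"
        )
    out = []
    for row in proba:
        m = predict_moisture(row, table, decimals)
        out.append(WitheringAssessment(m, assess_withering(m), tuple(row.tolist())))
    return out
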