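"""Chemometric evaluation of moisture predictions: Rp, RMSEP, RPD, SD.

RMSEP is the root mean square error of prediction. SD is the sample
standard deviation (N-1 denominator) of the reference moisture labels — by
convention the labels of the trained time points, not the evaluation
truths. RPD = SD / RMSEP; in chemometric practice RPD > 2 marks a model
usable for quantitative judgement, 1-2 average, < 1 unusable.

Rp is a correlation-type goodness statistic equal to 1 for perfect
prediction. Its default denominator centres the *predictions* on the
reference-label mean, Rp = 1 - sum((yhat - y)^2) / sum((yhat - ybar)^2);
the textbook coefficient-of-determination denominator sum((y - ybar)^2) is
available via ``denominator="true"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["MetricReport", "rmsep", "sd", "rpd", "rp", "evaluate", "rpd_band"]


def _pairs(y_true, y_pred):
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if y_true.size == 0:
        raise ValueError("empty prediction set")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return y_true, y_pred


def rmsep(y_true, y_pred) -> float:
    """Root mean square error of prediction: sqrt(mean((y - yhat)^2))."""
    y_true, y_pred = _pairs(y_true, y_pred)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def sd(reference_labels) -> float:
    """Sample standard deviation (N-1 denominator) of the reference labels."""
    values = np.asarray(reference_labels, dtype=np.float64).ravel()
    if values.size < 2:
        raise ValueError("sd needs at least two reference values")
    return float(np.std(values, ddof=1))


def rpd(y_true, y_pred, reference_labels) -> float:
    """SD of the reference labels over RMSEP; inf when predictions are exact."""
    err = rmsep(y_true, y_pred)
    spread = sd(reference_labels)
    if err == 0.0:
        return math.inf
    return spread / err


def rpd_band(value: float) -> str:
    """Qualitative chemometric reading of an RPD value."""
    if value > 2.0:
        return "good"
    if value >= 1.0:
        return "average"
    return "unusable"


def rp(y_true, y_pred, reference_labels=None, denominator: str = "predicted") -> float:
    """Correlation-type goodness statistic; 1 iff predictions are exact.

    ``denominator="predicted"`` (default) uses sum((yhat - ybar)^2);
    ``denominator="true"`` uses the textbook sum((y - ybar)^2). ybar is the
    mean of ``reference_labels`` when given, else of the evaluation truths.
    """
    y_true, y_pred = _pairs(y_true, y_pred)
    if y_true.size < 2:
        raise ValueError("rp needs at least two pairs")
    if reference_labels is not None:
        ybar = float(np.mean(np.asarray(reference_labels, dtype=np.float64)))
    else:
        ybar = float(y_true.mean())
    ss_res = float(np.sum((y_pred - y_true) ** 2))
    if denominator == "predicted":
        ss_tot = float(np.sum((y_pred - ybar) ** 2))
    elif denominator == "true":
        ss_tot = float(np.sum((y_true - ybar) ** 2))
    else:
        raise ValueError("denominator must be 'predicted' or 'true'")
    if ss_tot == 0.0:
        raise ValueError(
            "rp denominator is zero (no spread around the reference mean)"
        )
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class MetricReport:
    rp: float
    rmsep: float
    rpd: float
    sd: float

    @property
    def rpd_band(self) -> str:
        return rpd_band(self.rpd)


def evaluate(y_true, y_pred, reference_labels, denominator: str = "predicted") -> MetricReport:
    """Full report on a set of (true, predicted) moisture pairs."""
    return MetricReport(
        rp=rp(y_true, y_pred, reference_labels, denominator),
        rmsep=rmsep(y_true, y_pred),
        rpd=rpd(y_true, y_pred, reference_labels),
        sd=sd(reference_labels),
    )
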