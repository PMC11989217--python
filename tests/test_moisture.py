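"""Confidence-weighted moisture prediction and the withering-degree band."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from teawither import (
    MoistureLabelTable,
    WitheringDegree,
    assess_withering,
    predict_moisture,
)

from conftest import EXTERNAL_CONFIDENCES, EXTERNAL_TRUE_MOISTURE

TABLE = MoistureLabelTable.reference()


def test_worked_example_reproduces_to_eight_decimals():
    """The three external-category confidence columns give the published
    moisture estimates; category 5's printed value is one unit in the eighth
    decimal above exact arithmetic on its printed inputs."""
    assert predict_moisture(EXTERNAL_CONFIDENCES[1], TABLE) == 0.78325333
    assert predict_moisture(EXTERNAL_CONFIDENCES[9], TABLE) == 0.60449594
    cat5 = predict_moisture(EXTERNAL_CONFIDENCES[5], TABLE)
    assert cat5 == 0.72105268  # exact-decimal value of the printed inputs
    assert abs(cat5 - 0.72105269) < 1.5e-8  # one ulp at the printed precision


def test_worked_example_errors_below_one_percent():
    for cat, conf in EXTERNAL_CONFIDENCES.items():
        pred = predict_moisture(conf, TABLE)
        assert abs(pred - EXTERNAL_TRUE_MOISTURE[cat]) < 0.01


def test_confidence_sums_kept_as_printed():
    """Rounded vectors are used without renormalization; their sums deviate
    from 1 by rounding exactly as reported."""
    sums = {1: 0.99999997, 5: 1.00000001, 9: 0.99999999}
    for cat, conf in EXTERNAL_CONFIDENCES.items():
        assert round(sum(conf), 8) == sums[cat]


def test_one_hot_returns_the_class_label():
    conf = np.zeros(10)
    conf[3] = 1.0
    assert predict_moisture(conf, TABLE) == 0.7501


def test_uniform_confidence_matches_dot_product_oracle():
    conf = np.full(10, 0.1)
    got = predict_moisture(conf, TABLE, decimals=None)
    oracle = sum(l * c for l, c in zip(TABLE.labels, conf))  # independent loop
    assert abs(got - oracle) < 1e-15
    assert abs(got - np.mean(TABLE.labels)) < 1e-12


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(st.floats(0.001, 1.0), min_size=10, max_size=10))
def test_prediction_is_convex_combination_of_labels(raw):
    conf = np.array(raw) / np.sum(raw)
    m = predict_moisture(conf, TABLE, decimals=None)
    assert min(TABLE.labels) - 1e-12 <= m <= max(TABLE.labels) + 1e-12


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    raw=st.lists(st.floats(0.01, 1.0), min_size=10, max_size=10),
    src=st.integers(0, 9),
    dst=st.integers(0, 9),
    frac=st.floats(0.0, 1.0),
)
def test_shifting_mass_to_wetter_class_never_lowers_prediction(raw, src, dst, frac):
    conf = np.array(raw) / np.sum(raw)
    before = predict_moisture(conf, TABLE, decimals=None)
    moved = conf.copy()
    amount = frac * moved[src]
    moved[src] -= amount
    moved[dst] += amount
    after = predict_moisture(moved, TABLE, decimals=None)
    if TABLE[dst] >= TABLE[src]:  # wetter or equal destination
        assert after >= before - 1e-9
    else:
        assert after <= before + 1e-9


def test_input_validation():
    with pytest.raises(ValueError):
        predict_moisture(np.full(9, 1 / 9), TABLE)  # length mismatch
    bad = np.full(10, 0.1)
    bad[0], bad[1] = -0.1, 0.3
    with pytest.raises(ValueError):
        predict_moisture(bad, TABLE)  # negative confidence
    with pytest.raises(ValueError):
        predict_moisture(np.full(10, 0.2), TABLE)  # sums to 2


@pytest.mark.parametrize(
    "moisture,degree",
    [
        (0.62, WitheringDegree.MODERATE),
        (0.66, WitheringDegree.MODERATE),  # inclusive upper bound
        (0.58, WitheringDegree.MODERATE),  # inclusive lower bound
        (0.6600001, WitheringDegree.INSUFFICIENT),
        (0.5799999, WitheringDegree.EXCESSIVE),
        (0.597, WitheringDegree.MODERATE),  # an external true value in-band
        (0.7843, WitheringDegree.INSUFFICIENT),
        (0.4863, WitheringDegree.EXCESSIVE),
    ],
)
def test_withering_band_boundaries(moisture, degree):
    assert assess_withering(moisture) is degree


def test_withering_band_rejects_out_of_range():
    with pytest.raises(ValueError):
        assess_withering(1.2)
    with pytest.raises(ValueError):
        assess_withering(-0.1)


def test_label_table_validation():
    with pytest.raises(ValueError):
        MoistureLabelTable((0.7, 0.7))  # not strictly decreasing
    with pytest.raises(ValueError):
        MoistureLabelTable((0.7, 1.1))  # outside (0,1) and increasing
    with pytest.raises(ValueError):
        MoistureLabelTable((0.7,))  # single class
    table = MoistureLabelTable((0.75, 0.65))
    assert table.n == 1 and len(table) == 2


def test_label_table_csv_roundtrip(tmp_path):
    path = TABLE.to_csv(tmp_path / "labels.csv")
    assert MoistureLabelTable.from_csv(path).labels == TABLE.labels
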