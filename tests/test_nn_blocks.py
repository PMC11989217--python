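"""Contracts of the attention/fusion blocks and the classifier builder."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from teawither import ArchitecturePlan, build_classifier, default_plan, mini_plan
from teawither.autodiff import Tensor
from teawither import nn


def _x(rng, *shape):
    return Tensor(rng.normal(size=shape).astype(np.float32))


# ---------------------------------------------------------------------------
# RFAConv
# ---------------------------------------------------------------------------
def test_rfaconv_shape_contract_stride1(rng):
    blk = nn.RFAConv(8, 8, kernel_size=3, stride=1, rng=rng)
    out = blk(_x(rng, 2, 8, 16, 16))
    assert out.shape == (2, 8, 16, 16)


@settings(max_examples=15, derandomize=True, deadline=None)
@given(
    cin=st.integers(1, 6),
    cout=st.integers(2, 10),
    hw=st.integers(5, 14),
    stride=st.sampled_from([1, 2]),
)
def test_rfaconv_shape_matches_standard_conv(cin, cout, hw, stride):
    """Output spatial dims equal a same-padded stride-s convolution's."""
    rng = np.random.default_rng(0)
    blk = nn.RFAConv(cin, cout, kernel_size=3, stride=stride, rng=rng)
    out = blk(_x(rng, 2, cin, hw, hw))
    expect = (hw + 2 * 1 - 3) // stride + 1
    assert out.shape == (2, cout, expect, expect)


def test_rfaconv_attention_uniform_for_equal_logits(rng):
    """Softmax symmetry: when the attention branch emits equal logits over
    the k^2 receptive-field positions, every weight is exactly 1/9."""
    blk = nn.RFAConv(4, 4, kernel_size=3, stride=1, rng=rng)
    blk.att.weight.data[:] = 0.0  # constant logits regardless of input
    blk.att.bias.data[:] = 0.0
    x = Tensor(np.ones((1, 4, 8, 8), dtype=np.float32) * 0.37)
    a = blk._attention(x).data
    np.testing.assert_allclose(a, 1.0 / 9.0, atol=1e-6)


def test_rfaconv_attention_normalized_everywhere(rng):
    """Attention weights sum to 1 over the k^2 positions at every location,
    and match an independent exponent-and-normalize oracle."""
    blk = nn.RFAConv(3, 6, kernel_size=3, stride=2, rng=rng)
    x = _x(rng, 2, 3, 11, 11)
    a = blk._attention(x).data
    assert np.all(a >= 0)
    np.testing.assert_allclose(a.sum(axis=2), 1.0, atol=1e-6)
    # oracle: recompute from the raw logits of the attention branch
    from teawither.autodiff import avg_pool2d

    pooled = avg_pool2d(x, 3, stride=2, padding=1)
    logits = blk.att(pooled).data.reshape(a.shape).astype(np.float64)
    e = np.exp(logits - logits.max(axis=2, keepdims=True))
    np.testing.assert_allclose(a, e / e.sum(axis=2, keepdims=True), atol=1e-5)


# ---------------------------------------------------------------------------
# Coordinate attention
# ---------------------------------------------------------------------------
@settings(max_examples=10, derandomize=True, deadline=None)
@given(c=st.integers(2, 12), h=st.integers(3, 10), w=st.integers(3, 10))
def test_coordinate_attention_preserves_shape(c, h, w):
    rng = np.random.default_rng(0)
    blk = nn.CoordinateAttention(c, reduction=4, rng=rng)
    out = blk(_x(rng, 2, c, h, w))
    assert out.shape == (2, c, h, w)


def test_coordinate_attention_zero_weights_quarter_input(rng):
    """With the gate convolutions zeroed both sigmoids output 0.5,
    so the block returns input / 4."""
    blk = nn.CoordinateAttention(6, reduction=2, rng=rng)
    blk.conv_h.weight.data[:] = 0
    blk.conv_h.bias.data[:] = 0
    blk.conv_w.weight.data[:] = 0
    blk.conv_w.bias.data[:] = 0
    x = _x(rng, 2, 6, 5, 7)
    np.testing.assert_allclose(blk(x).data, x.data / 4.0, atol=1e-6)


def test_coordinate_attention_saturated_gates_identity(rng):
    """Large positive gate biases drive both sigmoids to 1: identity map."""
    blk = nn.CoordinateAttention(6, reduction=2, rng=rng)
    blk.conv_h.weight.data[:] = 0
    blk.conv_w.weight.data[:] = 0
    blk.conv_h.bias.data[:] = 50.0
    blk.conv_w.bias.data[:] = 50.0
    x = _x(rng, 2, 6, 5, 7)
    np.testing.assert_allclose(blk(x).data, x.data, atol=1e-5)


def test_directional_pooling_matches_loop_oracle(rng):
    x = _x(rng, 2, 3, 4, 5)
    pool_h = x.mean(axis=3, keepdims=True).data
    for b in range(2):
        for c in range(3):
            for i in range(4):
                total = 0.0
                for j in range(5):
                    total += float(x.data[b, c, i, j])
                assert abs(pool_h[b, c, i, 0] - total / 5) < 1e-5


# ---------------------------------------------------------------------------
# C2f_CA
# ---------------------------------------------------------------------------
def test_c2fca_shape_contract(rng):
    blk = nn.C2fCA(16, 16, repeats=3, rng=rng)
    out = blk(_x(rng, 2, 16, 8, 8))
    assert out.shape == (2, 16, 8, 8)


def test_c2fca_rejects_odd_channels(rng):
    with pytest.raises(ValueError):
        nn.C2fCA(16, 15, repeats=1, rng=rng)


def test_c2fca_parameter_count_grows_with_repeats(rng):
    """Each extra bottleneck adds parameters, counted by module enumeration."""
    n1 = nn.count_parameters(nn.C2fCA(16, 16, repeats=1, rng=rng))
    n3 = nn.count_parameters(nn.C2fCA(16, 16, repeats=3, rng=rng))
    assert n3 > n1
    # the increment is exactly two bottlenecks plus wider fusion input
    bott = nn.count_parameters(nn.Bottleneck(8, rng=rng))
    assert n3 - n1 >= 2 * bott


def test_c2fca_zero_input_is_finite(rng):
    blk = nn.C2fCA(8, 8, repeats=2, rng=rng)
    out = blk(Tensor(np.zeros((2, 8, 6, 6), dtype=np.float32)))
    assert np.all(np.isfinite(out.data))


# ---------------------------------------------------------------------------
# classifier builder
# ---------------------------------------------------------------------------
def test_default_plan_mirrors_backbone_table():
    plan = default_plan(10)
    assert len(plan.stages) == 9  # nine backbone stages + classify head
    kinds = [s[0] for s in plan.stages]
    assert kinds == ["RFAConv", "RFAConv", "C2f_CA", "RFAConv", "C2f_CA",
                     "RFAConv", "C2f_CA", "RFAConv", "C2f_CA"]
    assert [s[2] for s in plan.stages] == [64, 128, 128, 256, 256, 512, 512,
                                           1024, 1024]
    assert [s[1] for s in plan.stages] == [1, 1, 3, 1, 6, 1, 6, 1, 3]
    model = build_classifier(mini_plan(10), seed=0)
    assert len(model.layers) == 9
    assert isinstance(model.head, nn.ClassifyHead)


def test_classifier_outputs_normalized_confidences(rng):
    model = build_classifier(mini_plan(10), seed=1)
    model.eval()
    x = Tensor(rng.random((4, 3, 64, 64)).astype(np.float32))
    proba = model.predict_proba(x)
    assert proba.shape == (4, 10)
    assert np.all(proba >= 0)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)


def test_forward_is_deterministic(rng):
    x = Tensor(rng.random((2, 3, 64, 64)).astype(np.float32))
    a = build_classifier(mini_plan(10), seed=3).eval().predict_proba(x)
    b = build_classifier(mini_plan(10), seed=3).eval().predict_proba(x)
    np.testing.assert_array_equal(a, b)


def test_plan_yaml_roundtrip():
    plan = mini_plan(7)
    again = ArchitecturePlan.from_yaml(plan.to_yaml())
    assert again == plan


def test_plan_validation():
    with pytest.raises(ValueError):
        ArchitecturePlan(stages=(("Pool", 1, 64),))
    with pytest.raises(ValueError):
        ArchitecturePlan(n_classes=1)
    with pytest.raises(ValueError):
        ArchitecturePlan(width_multiplier=0.0)


def test_training_loss_decreases_on_tiny_problem():
    """A few epochs on a 3-class toy set must reduce the training loss."""
    from teawither import LeafImageClassifier, make_withering_leaves

    X, y, _ = make_withering_leaves(n_classes=3, images_per_class=8,
                                    image_size=32, seed=0,
                                    moisture_labels=(0.75, 0.65, 0.55))
    clf = LeafImageClassifier(epochs=4, batch_size=8, random_state=0)
    clf.fit(X, y)
    assert clf.loss_curve_[-1] < clf.loss_curve_[0]
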