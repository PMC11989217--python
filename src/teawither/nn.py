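"""Network blocks for the withering classifier.

The backbone follows the cross-stage-partial classification design: a stack
of downsampling convolutions and C2f fusion blocks, with two substitutions
that target fine colour/texture discrimination between consecutive withering
time points:

* ``RFAConv`` — receptive-field attention convolution. Each k x k receptive
  field gets its own softmax weighting (k^2 non-negative weights summing to 1
  per output location and channel), computed from an average-pooled summary
  through a grouped 1x1 convolution. The weighted receptive-field features
  are laid out as non-overlapping k x k tiles and reduced by a stride-k
  convolution, so every field is effectively convolved with its own kernel —
  relieving the parameter sharing of a plain convolution.
* ``C2fCA`` — a C2f block (split, n bottlenecks, concatenate, fuse) with a
  coordinate-attention gate on the fused output, which multiplies the map by
  per-height and per-width sigmoid gates derived from directional pooling.

All layers run on the package's numpy autodiff engine (float32, CPU).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import yaml

from .autodiff import (
    Tensor,
    avg_pool2d,
    concat,
    conv2d,
    hard_swish,
    log_softmax,
    relu,
    sigmoid,
    silu,
    softmax,
)

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ConvBNSiLU",
    "RFAConv",
    "CoordinateAttention",
    "Bottleneck",
    "C2fCA",
    "ClassifyHead",
    "WitherNet",
    "ArchitecturePlan",
    "default_plan",
    "mini_plan",
    "build_classifier",
    "cross_entropy",
    "Adam",
    "count_parameters",
]


class Module:
    """Tiny module base: parameter discovery, train/eval mode, state dicts."""

    training: bool = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self.children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # state dicts include non-trainable buffers (BN running stats)
    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_buffers(prefix + name + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({k: v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        expected = set(params) | {k for k, _ in self.named_buffers()}
        if expected != set(state):
            missing = expected - set(state)
            extra = set(state) - expected
            raise ValueError(f"state mismatch: missing={missing} extra={extra}")
        for key, value in state.items():
            if key in params:
                params[key].data = np.asarray(value, dtype=np.float32)
        # buffers are plain attributes; walk again and assign
        self._assign_buffers(state, "")

    def _assign_buffers(self, state, prefix):
        for name, value in list(vars(self).items()):
            if isinstance(value, np.ndarray):
                setattr(self, name, np.asarray(state[prefix + name], dtype=value.dtype))
        for name, child in self.children():
            child._assign_buffers(state, prefix + name + ".")


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"channels ({in_channels}->{out_channels}) not divisible by groups={groups}"
            )
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = (in_channels // groups) * k * k
        self.weight = Tensor(
            _he_normal(rng, (out_channels, in_channels // groups, k, k), fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(
            x, self.weight, self.bias, self.stride, self.padding, self.groups
        )


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        from .autodiff import batchnorm2d_train, scale_shift

        if self.training:
            y, mu, var = batchnorm2d_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbias = n / max(n - 1, 1)
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(np.float32)
            self.running_var = (
                (1 - m) * self.running_var + m * unbias * var
            ).astype(np.float32)
            return y
        invsd = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = self.gamma.data * invsd
        shift = self.beta.data - self.running_mean * scale
        return scale_shift(x, scale, shift)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(
            _he_normal(rng, (in_features, out_features), in_features),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ConvBNSiLU(Module):
    """Standard conv + batch norm + SiLU unit used throughout the backbone."""

    def __init__(self, cin, cout, k, stride=1, groups=1, rng=None):
        self.conv = Conv2d(
            cin, cout, k, stride=stride, padding=k // 2, groups=groups, bias=False, rng=rng
        )
        self.bn = BatchNorm2d(cout)

    def forward(self, x):
        return silu(self.bn(self.conv(x)))


class RFAConv(Module):
    """Receptive-field attention convolution.

    For each output location the k^2 positions of the receptive field are
    weighted by a softmax attention map derived from average pooling followed
    by a grouped 1x1 convolution; receptive-field features come from a
    depthwise k x k expansion gated by ReLU(BatchNorm(.)). The weighted
    features are rearranged into non-overlapping k x k tiles and reduced by a
    stride-k convolution, so output spatial dims match a standard
    stride-``stride`` convolution with "same" padding.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, rng=None):
        if kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        k = kernel_size
        self.k, self.stride = k, stride
        self.cin = in_channels
        self.att = Conv2d(in_channels, in_channels * k * k, 1, groups=in_channels,
                          bias=True, rng=rng)
        self.feat = Conv2d(in_channels, in_channels * k * k, k, stride=stride,
                           padding=k // 2, groups=in_channels, bias=False, rng=rng)
        self.feat_bn = BatchNorm2d(in_channels * k * k)
        self.reduce = Conv2d(in_channels, out_channels, k, stride=k, bias=False, rng=rng)
        self.out_bn = BatchNorm2d(out_channels)

    def _attention(self, x: Tensor) -> Tensor:
        """Softmax attention over the k^2 receptive-field positions.

        Returns shape (B, C_in, k^2, H_out, W_out); sums to 1 along axis 2.
        """
        k = self.k
        pooled = avg_pool2d(x, k, stride=self.stride, padding=k // 2)
        logits = self.att(pooled)
        b, _, ho, wo = logits.shape
        return softmax(logits.reshape(b, self.cin, k * k, ho, wo), axis=2)

    def forward(self, x: Tensor) -> Tensor:
        k = self.k
        a = self._attention(x)
        f = relu(self.feat_bn(self.feat(x)))
        b, _, ho, wo = f.shape
        weighted = (a * f.reshape(b, self.cin, k * k, ho, wo)).reshape(
            b, self.cin, k, k, ho, wo
        )
        # tile layout: (B, C, H*k, W*k) with each k x k tile one receptive field
        tiles = weighted.transpose(0, 1, 4, 2, 5, 3).reshape(b, self.cin, ho * k, wo * k)
        return silu(self.out_bn(self.reduce(tiles)))


class CoordinateAttention(Module):
    """Directional (height/width factorized) channel attention gate."""

    def __init__(self, channels: int, reduction: int = 32, rng=None):
        mid = max(1, channels // reduction)
        self.conv1 = Conv2d(channels, mid, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(mid)
        self.conv_h = Conv2d(mid, channels, 1, bias=True, rng=rng)
        self.conv_w = Conv2d(mid, channels, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        pool_h = x.mean(axis=3, keepdims=True)  # (B,C,H,1)
        pool_w = x.mean(axis=2, keepdims=True)  # (B,C,1,W)
        y = concat([pool_h, pool_w.transpose(0, 1, 3, 2)], axis=2)  # (B,C,H+W,1)
        y = hard_swish(self.bn1(self.conv1(y)))
        y_h = y[:, :, :h, :]
        y_w = y[:, :, h:, :].transpose(0, 1, 3, 2)
        gate_h = sigmoid(self.conv_h(y_h))  # (B,C,H,1)
        gate_w = sigmoid(self.conv_w(y_w))  # (B,C,1,W)
        return x * gate_h * gate_w


class Bottleneck(Module):
    """Residual 3x3-3x3 bottleneck (classification variant, shortcut on)."""

    def __init__(self, channels: int, rng=None):
        self.cv1 = ConvBNSiLU(channels, channels, 3, rng=rng)
        self.cv2 = ConvBNSiLU(channels, channels, 3, rng=rng)

    def forward(self, x):
        return x + self.cv2(self.cv1(x))


class C2fCA(Module):
    """Cross-stage feature fusion with a coordinate-attention gate.

    Split -> n bottlenecks (each fed the previous branch) -> concatenate all
    branches -> 1x1 fusion -> coordinate attention on the fused map.
    """

    def __init__(self, in_channels: int, out_channels: int, repeats: int = 1,
                 reduction: int = 32, rng=None):
        if out_channels % 2:
            raise ValueError("C2fCA needs an even output channel count (split branch)")
        hidden = out_channels // 2
        self.hidden = hidden
        self.cv1 = ConvBNSiLU(in_channels, 2 * hidden, 1, rng=rng)
        self.blocks = [Bottleneck(hidden, rng=rng) for _ in range(repeats)]
        self.cv2 = ConvBNSiLU((2 + repeats) * hidden, out_channels, 1, rng=rng)
        self.ca = CoordinateAttention(out_channels, reduction=reduction, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        branches = [y[:, : self.hidden], y[:, self.hidden :]]
        for block in self.blocks:
            branches.append(block(branches[-1]))
        return self.ca(self.cv2(concat(branches, axis=1)))


class ClassifyHead(Module):
    """1x1 conv expansion, global average pooling, linear logits."""

    def __init__(self, in_channels: int, hidden: int, n_classes: int, rng=None):
        self.conv = ConvBNSiLU(in_channels, hidden, 1, rng=rng)
        self.fc = Linear(hidden, n_classes, rng=rng)

    def forward(self, x):
        y = self.conv(x).mean(axis=(2, 3))
        return self.fc(y)


# ---------------------------------------------------------------------------
# architecture plan
# ---------------------------------------------------------------------------
_STAGE_KINDS = ("RFAConv", "C2f_CA")

# backbone stage table: (kind, repeats, nominal channel width)
_DEFAULT_STAGES: tuple[tuple[str, int, int], ...] = (
    ("RFAConv", 1, 64),
    ("RFAConv", 1, 128),
    ("C2f_CA", 3, 128),
    ("RFAConv", 1, 256),
    ("C2f_CA", 6, 256),
    ("RFAConv", 1, 512),
    ("C2f_CA", 6, 512),
    ("RFAConv", 1, 1024),
    ("C2f_CA", 3, 1024),
)


@dataclass
class ArchitecturePlan:
    """Backbone/head layout at a configurable width.

    ``stages`` mirrors the nine-stage backbone table (kind, repeats, nominal
    channels); the head is always a Classify layer. ``width_multiplier``
    scales every channel count so a miniature profile trains on CPU.
    """

    stages: tuple[tuple[str, int, int], ...] = _DEFAULT_STAGES
    n_classes: int = 10
    width_multiplier: float = 1.0
    head_channels: int = 1280
    ca_reduction: int = 32

    def __post_init__(self):
        self.stages = tuple(tuple(s) for s in self.stages)
        if not self.stages:
            raise ValueError("plan needs at least one backbone stage")
        for kind, repeats, channels in self.stages:
            if kind not in _STAGE_KINDS:
                raise ValueError(f"unknown stage kind {kind!r}")
            if repeats < 1 or channels < 1:
                raise ValueError("repeats and channels must be positive")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")

    def scaled_channels(self, nominal: int) -> int:
        c = max(2, int(round(nominal * self.width_multiplier)))
        return c + (c % 2)  # C2f branches split channels in half

    def scaled_head(self) -> int:
        return max(8, int(round(self.head_channels * self.width_multiplier)))

    # YAML round-trip so a plan can live next to a checkpoint
    def to_dict(self) -> dict:
        return {
            "stages": [list(s) for s in self.stages],
            "n_classes": self.n_classes,
            "width_multiplier": self.width_multiplier,
            "head_channels": self.head_channels,
            "ca_reduction": self.ca_reduction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitecturePlan":
        return cls(
            stages=tuple(tuple(s) for s in d["stages"]),
            n_classes=int(d["n_classes"]),
            width_multiplier=float(d["width_multiplier"]),
            head_channels=int(d.get("head_channels", 1280)),
            ca_reduction=int(d.get("ca_reduction", 32)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ArchitecturePlan":
        return cls.from_dict(yaml.safe_load(text))


def default_plan(n_classes: int = 10) -> ArchitecturePlan:
    """Full-width plan: nine backbone stages plus the Classify head."""
    return ArchitecturePlan(n_classes=n_classes, width_multiplier=1.0)


def mini_plan(n_classes: int = 10) -> ArchitecturePlan:
    """CPU-scale profile: 1/16 channel width, intended for 64x64 inputs."""
    return ArchitecturePlan(n_classes=n_classes, width_multiplier=1.0 / 16.0)


class WitherNet(Module):
    """Backbone + classify head; maps (B, 3, H, W) in [0,1] to class logits."""

    def __init__(self, plan: ArchitecturePlan, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.plan = plan
        layers: list[Module] = []
        cin = 3
        for kind, repeats, nominal in plan.stages:
            cout = plan.scaled_channels(nominal)
            if kind == "RFAConv":
                layers.append(RFAConv(cin, cout, kernel_size=3, stride=2, rng=rng))
            else:
                layers.append(
                    C2fCA(cin, cout, repeats=repeats, reduction=plan.ca_reduction, rng=rng)
                )
            cin = cout
        self.layers = layers
        self.head = ClassifyHead(cin, plan.scaled_head(), plan.n_classes, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return self.head(x)

    def predict_proba(self, x: Tensor) -> np.ndarray:
        logits = self.forward(x)
        return softmax(logits, axis=1).data


def build_classifier(
    plan: ArchitecturePlan, seed: int | None = 0
) -> WitherNet:
    """Instantiate the classifier from a plan with seeded initialization."""
    return WitherNet(plan, rng=np.random.default_rng(seed))


def count_parameters(module: Module) -> int:
    return int(sum(p.data.size for p in module.parameters()))


# ---------------------------------------------------------------------------
# loss and optimizer
# ---------------------------------------------------------------------------
def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer targets under softmax logits."""
    targets = np.asarray(targets)
    n, k = logits.shape
    onehot = np.zeros((n, k), dtype=np.float32)
    onehot[np.arange(n), targets] = 1.0
    logp = log_softmax(logits, axis=1)
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)


class Adam:
    """Adam with L2 weight decay; beta1 doubles as the momentum setting."""

    def __init__(self, params, lr=0.01, betas=(0.937, 0.999), eps=1e-8,
                 weight_decay=5e-4):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# checkpoint io
# ---------------------------------------------------------------------------
def save_checkpoint(path, model: WitherNet, extra: dict | None = None) -> None:
    """Write parameters + running stats (.npz) with the plan as a JSON key."""
    state = model.state_dict()
    state["__plan__"] = np.frombuffer(
        json.dumps(model.plan.to_dict()).encode(), dtype=np.uint8
    )
    if extra:
        state.update(extra)
    np.savez(path, **state)


def load_checkpoint(path) -> tuple[WitherNet, dict]:
    with np.load(path) as data:
        state = {k: data[k] for k in data.files}
    plan = ArchitecturePlan.from_dict(
        json.loads(state.pop("__plan__").tobytes().decode())
    )
    extra = {k: state.pop(k) for k in list(state) if k.startswith("__")}
    model = WitherNet(plan, rng=np.random.default_rng(0))
    model.load_state_dict(state)
    return model, extra
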