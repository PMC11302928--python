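"""Building blocks of the segmentation network.

Four bespoke blocks plus the standard double-convolution block:

* **Squeeze-Excitation (SE)** — global average pool per channel, a two-layer
  bottleneck MLP (ReLU then sigmoid), and channel-wise rescaling of the input.
* **Self-Attention (SA)** — a 1x1 convolution with sigmoid activation produces
  a spatial-channel gate in (0, 1) that multiplies the input elementwise.
* **Spatial Pyramid Pooling (SPP)** — parallel max-pooling at several window
  sizes, 1x1 channel reduction per level, nearest-neighbor upsampling back to
  the input resolution, and channel concatenation (optionally including the
  original input).
* **Fusion** — channel concatenation of several same-resolution feature maps
  followed by a convolution; the decoder's skip-connection merger.
* **Conv block** — two successive same-padding convolutions with ReLU.

Each block exists twice: as a :class:`~gnet.nn.Module` layer (trainable, used
by the full model) and as a pure-numpy function taking a single ``(H, W, C)``
image plus explicit weights. The functional forms define the value contract
the layers must honor and are what the loop-based test oracles check against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .exceptions import ConfigurationError, ShapeError

__all__ = [
    "SEWeights",
    "SPPParams",
    "ConvParams",
    "global_average_pool",
    "se_block",
    "sa_block",
    "max_pool",
    "spp_block",
    "fusion_block",
    "conv_block",
    "SEBlock",
    "SelfAttention2D",
    "SPPBlock",
    "FusionBlock",
    "ConvBlock",
]


def _check_image(x: np.ndarray, name: str = "x") -> np.ndarray:
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float64)
    if x.ndim != 3:
        raise ShapeError(f"{name} must be (H, W, C), got shape {x.shape}")
    if min(x.shape) < 1:
        raise ShapeError(f"{name} has an empty dimension: {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ShapeError(f"{name} contains non-finite values")
    return x


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class SEWeights:
    """Weights of the excitation MLP: ``sigmoid(w2 @ relu(w1 @ z + b1) + b2)``.

    ``w1`` maps ``C -> hidden`` (hidden = max(C // reduction, 1) by default),
    ``w2`` maps ``hidden -> C``. Biases default to zero, matching Dense-layer
    semantics; pass ``None`` to drop them.
    """

    w1: np.ndarray
    w2: np.ndarray
    b1: np.ndarray | None = None
    b2: np.ndarray | None = None

    @classmethod
    def random(cls, channels: int, reduction: int = 16,
               rng: np.random.Generator | None = None) -> "SEWeights":
        rng = rng if rng is not None else np.random.default_rng(0)
        hidden = max(channels // reduction, 1)
        return cls(
            w1=nn.he_normal(rng, (channels, hidden), channels),
            w2=nn.he_normal(rng, (hidden, channels), hidden),
            b1=np.zeros(hidden, dtype=np.float32),
            b2=np.zeros(channels, dtype=np.float32),
        )


@dataclass
class SPPParams:
    """Configuration (and, for the functional form, weights) of an SPP block.

    ``conv_weights[p]``/``conv_biases[p]`` hold the 1x1 reduction kernel for
    level ``p`` as ``(C, filters_per_level)`` matrices; when absent the layer
    class initializes its own.
    """

    pool_sizes: tuple[int, ...] = (2, 4, 8)
    filters_per_level: int = 256
    include_input: bool = True
    conv_weights: list[np.ndarray] | None = None
    conv_biases: list[np.ndarray] | None = None

    def __post_init__(self):
        self.pool_sizes = tuple(int(p) for p in self.pool_sizes)
        if len(self.pool_sizes) == 0:
            raise ConfigurationError("pool_sizes must be non-empty")
        if any(p < 1 for p in self.pool_sizes):
            raise ConfigurationError(f"pool sizes must be >= 1: {self.pool_sizes}")
        if self.filters_per_level < 1:
            raise ConfigurationError("filters_per_level must be >= 1")


@dataclass
class ConvParams:
    """Hyperparameters of a convolutional layer."""

    filters: int
    kernel_size: int = 3
    activation: str = "relu"
    padding: str = "same"
    initializer: str = "he_normal"

    def __post_init__(self):
        if self.filters < 1:
            raise ConfigurationError("filters must be >= 1")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ConfigurationError(
                f"kernel_size must be odd and >= 1, got {self.kernel_size}")
        if self.padding != "same":
            raise ConfigurationError("only 'same' padding is supported")


# --------------------------------------------------------------------------
# functional forms on a single (H, W, C) image
# --------------------------------------------------------------------------

def global_average_pool(x: np.ndarray) -> np.ndarray:
    """Mean of each channel over all spatial positions (the SE squeeze)."""
    x = _check_image(x)
    return x.mean(axis=(0, 1))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def se_block(x: np.ndarray, weights: SEWeights) -> np.ndarray:
    """Squeeze-excitation: rescale each channel by a learned gate in (0, 1)."""
    x = _check_image(x)
    c = x.shape[-1]
    if weights.w1.shape[0] != c or weights.w2.shape[1] != c:
        raise ShapeError(
            f"SE weights expect {weights.w1.shape[0]} channels, input has {c}")
    z = global_average_pool(x)
    h = z @ weights.w1
    if weights.b1 is not None:
        h = h + weights.b1
    h = np.maximum(h, 0.0)
    e = h @ weights.w2
    if weights.b2 is not None:
        e = e + weights.b2
    gate = _sigmoid(e)
    return x * gate[None, None, :]


def sa_block(x: np.ndarray, weight: np.ndarray,
             bias: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Self-attention gating; returns ``(gated_output, attention_map)``.

    ``weight`` is the 1x1 kernel, either ``(1, 1, C, C)`` or ``(C, C)``.
    """
    x = _check_image(x)
    weight = np.asarray(weight)
    if weight.ndim == 2:
        weight = weight[None, None]
    if weight.ndim != 4 or weight.shape[0] != 1 or weight.shape[1] != 1:
        raise ConfigurationError(
            f"attention kernel must be 1x1, got spatial shape {weight.shape[:2]}")
    if weight.shape[2] != x.shape[-1]:
        raise ShapeError(
            f"kernel expects {weight.shape[2]} channels, input has {x.shape[-1]}")
    logits = x @ weight[0, 0]
    if bias is not None:
        logits = logits + np.asarray(bias)
    attn = _sigmoid(logits)
    return x * attn, attn


def max_pool(x: np.ndarray, p: int) -> np.ndarray:
    """Non-overlapping ``p x p`` max pooling (floor mode on a single image)."""
    x = _check_image(x)
    h, w, _ = x.shape
    if p < 1 or p > h or p > w:
        raise ValueError(f"pool size {p} invalid for image of shape ({h}, {w})")
    ho, wo = h // p, w // p
    return x[:ho * p, :wo * p].reshape(ho, p, wo, p, -1).max(axis=(1, 3))


def spp_block(x: np.ndarray, params: SPPParams) -> np.ndarray:
    """Spatial pyramid pooling on a single image with explicit 1x1 weights."""
    x = _check_image(x)
    h, w, c = x.shape
    if params.conv_weights is None:
        raise ConfigurationError("functional spp_block needs conv_weights")
    if len(params.conv_weights) != len(params.pool_sizes):
        raise ConfigurationError("one 1x1 kernel per pyramid level required")
    for p in params.pool_sizes:
        if p > h or p > w:
            raise ValueError(f"pool size {p} exceeds spatial dims ({h}, {w})")
    maps = [x] if params.include_input else []
    biases = params.conv_biases or [None] * len(params.pool_sizes)
    for p, wmat, b in zip(params.pool_sizes, params.conv_weights, biases):
        wmat = np.asarray(wmat)
        pooled = nn.max_pool2d_array(x[None], p)[0]  # ceil mode
        reduced = pooled @ wmat
        if b is not None:
            reduced = reduced + np.asarray(b)
        maps.append(nn.upsample_nearest_array(reduced[None], (h, w), p)[0])
    return np.concatenate(maps, axis=-1)


def fusion_block(inputs: Sequence[np.ndarray], weight: np.ndarray,
                 bias: np.ndarray | None = None,
                 activation: str = "relu") -> np.ndarray:
    """Concatenate same-resolution maps along channels, then convolve."""
    if len(inputs) == 0:
        raise ValueError("fusion_block requires at least one input")
    imgs = [_check_image(im, f"inputs[{i}]") for i, im in enumerate(inputs)]
    hw = imgs[0].shape[:2]
    for i, im in enumerate(imgs[1:], 1):
        if im.shape[:2] != hw:
            raise ShapeError(
                f"inputs[{i}] has spatial dims {im.shape[:2]}, expected {hw}")
    fused = np.concatenate(imgs, axis=-1)
    out = nn.conv2d_array(fused[None], weight, bias)[0]
    if activation == "relu":
        out = np.maximum(out, 0.0)
    elif activation not in (None, "linear"):
        raise ConfigurationError(f"unsupported activation {activation!r}")
    return out


def conv_block(x: np.ndarray, w1: np.ndarray, b1: np.ndarray | None,
               w2: np.ndarray, b2: np.ndarray | None) -> np.ndarray:
    """Two successive same-padding convolutions, each followed by ReLU."""
    x = _check_image(x)
    y = np.maximum(nn.conv2d_array(x[None], w1, b1), 0.0)
    y = np.maximum(nn.conv2d_array(y, w2, b2), 0.0)
    return y[0]


# --------------------------------------------------------------------------
# trainable layer classes (batched NHWC tensors)
# --------------------------------------------------------------------------

class SEBlock(nn.Module):
    """Channel recalibration via a squeeze-excitation gate."""

    def __init__(self, channels: int, reduction: int = 16, use_bias: bool = True,
                 rng: np.random.Generator | None = None):
        if reduction < 1:
            raise ConfigurationError("reduction must be >= 1")
        hidden = max(channels // reduction, 1)
        self.channels = channels
        self.fc1 = nn.Dense(channels, hidden, activation="relu",
                            use_bias=use_bias, rng=rng)
        self.fc2 = nn.Dense(hidden, channels, activation="sigmoid",
                            use_bias=use_bias, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        n = x.shape[0]
        z = x.mean(axis=(1, 2))            # squeeze: (N, C)
        gate = self.fc2(self.fc1(z))       # excitation: (N, C) in (0, 1)
        return x * gate.reshape(n, 1, 1, self.channels)


class SelfAttention2D(nn.Module):
    """1x1-conv sigmoid gate multiplied elementwise with the input."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        self.conv = nn.Conv2D(channels, channels, kernel_size=1,
                              activation="sigmoid", rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return x * self.conv(x)

    def forward_with_attention(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        attn = self.conv(x)
        return x * attn, attn


class SPPBlock(nn.Module):
    """Multi-scale context: pool / 1x1-reduce / upsample / concatenate."""

    def __init__(self, in_channels: int, params: SPPParams | None = None,
                 rng: np.random.Generator | None = None):
        params = params if params is not None else SPPParams()
        self.params = params
        self.in_channels = in_channels
        self.convs = [
            nn.Conv2D(in_channels, params.filters_per_level, kernel_size=1,
                      activation=None, rng=rng)
            for _ in params.pool_sizes
        ]

    @property
    def out_channels(self) -> int:
        base = self.in_channels if self.params.include_input else 0
        return base + self.params.filters_per_level * len(self.params.pool_sizes)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h, w = x.shape[1], x.shape[2]
        maps = [x] if self.params.include_input else []
        for p, conv in zip(self.params.pool_sizes, self.convs):
            level = conv(nn.max_pool2d(x, p))
            maps.append(nn.upsample_nearest(level, (h, w), p))
        return nn.concatenate(maps, axis=-1)


class FusionBlock(nn.Module):
    """Concatenate feature maps along channels and convolve."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int = 3,
                 activation: str = "relu",
                 rng: np.random.Generator | None = None):
        self.conv = nn.Conv2D(in_channels, filters, kernel_size=kernel_size,
                              activation=activation, rng=rng)

    def forward(self, inputs: Sequence[nn.Tensor]) -> nn.Tensor:
        if len(inputs) == 0:
            raise ValueError("fusion block requires at least one input")
        fused = inputs[0] if len(inputs) == 1 else nn.concatenate(list(inputs), axis=-1)
        return self.conv(fused)


class ConvBlock(nn.Module):
    """Two successive 3x3 (by default) convolutions with ReLU."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None):
        self.conv1 = nn.Conv2D(in_channels, filters, kernel_size,
                               activation="relu", rng=rng)
        self.conv2 = nn.Conv2D(filters, filters, kernel_size,
                               activation="relu", rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.conv2(self.conv1(x))
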