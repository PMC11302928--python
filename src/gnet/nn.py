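"""Minimal reverse-mode automatic differentiation over numpy arrays.

This module is the numerical core the segmentation network is built on: a
small tape-based autodiff engine (:class:`Tensor`), the layer primitives the
architecture needs (2-D convolution via im2col, max-pooling, nearest-neighbor
upsampling, dense layers), and an Adam optimizer.

Conventions
-----------
* Feature maps are NHWC ``float32`` arrays: ``(batch, height, width, channels)``.
* Convolutions are stride-1 with "same" zero padding; kernels are stored as
  ``(k, k, in_channels, out_channels)``.
* Max-pooling uses non-overlapping ``p x p`` windows with ceil-mode padding
  (``-inf`` fill) so any spatial size is accepted.
* Nearest-neighbor upsampling realizes ``out[i, j] = in[i // p, j // p]``,
  the exact inverse index map of the pooling grid.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Dense",
    "Conv2D",
    "Adam",
    "relu",
    "sigmoid",
    "softmax",
    "log_softmax",
    "concatenate",
    "conv2d",
    "max_pool2d",
    "upsample_nearest",
    "conv2d_array",
    "max_pool2d_array",
    "upsample_nearest_array",
    "he_normal",
]

DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a gradient back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _accum(t: "Tensor", g: np.ndarray) -> None:
        if not t.requires_grad:
            return
        if t.grad is None:
            t.grad = g.astype(DTYPE, copy=True)
        else:
            t.grad += g

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; model graphs can be a few hundred deep
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- basic properties ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic ---------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data + other.data

        def backward(g):
            Tensor._accum(self, _unbroadcast(g, self.data.shape))
            Tensor._accum(other, _unbroadcast(g, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            Tensor._accum(self, -g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data * other.data

        def backward(g):
            Tensor._accum(self, _unbroadcast(g * other.data, self.data.shape))
            Tensor._accum(other, _unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data / other.data

        def backward(g):
            Tensor._accum(self, _unbroadcast(g / other.data, self.data.shape))
            Tensor._accum(other, _unbroadcast(-g * self.data / other.data ** 2,
                                              other.data.shape))

        return Tensor._make(data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, exponent: float):
        data = self.data ** exponent

        def backward(g):
            Tensor._accum(self, g * exponent * self.data ** (exponent - 1))

        return Tensor._make(data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data @ other.data

        def backward(g):
            Tensor._accum(self, g @ other.data.T)
            Tensor._accum(other, self.data.T @ g)

        return Tensor._make(data, (self, other), backward)

    # -- reductions / shaping -----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            Tensor._accum(self, np.broadcast_to(g, self.data.shape).astype(DTYPE))

        return Tensor._make(data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        data = self.data.reshape(shape)

        def backward(g):
            Tensor._accum(self, g.reshape(old))

        return Tensor._make(data, (self,), backward)

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        data = self.data.transpose(axes)

        def backward(g):
            Tensor._accum(self, g.transpose(inv))

        return Tensor._make(data, (self,), backward)

    def abs(self):
        data = np.abs(self.data)
        sign = np.sign(self.data)

        def backward(g):
            Tensor._accum(self, g * sign)

        return Tensor._make(data, (self,), backward)

    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            Tensor._accum(self, g * data)

        return Tensor._make(data, (self,), backward)

    def log(self):
        data = np.log(self.data)

        def backward(g):
            Tensor._accum(self, g / self.data)

        return Tensor._make(data, (self,), backward)

    def sqrt(self):
        data = np.sqrt(self.data)

        def backward(g):
            Tensor._accum(self, g * 0.5 / np.maximum(data, 1e-12))

        return Tensor._make(data, (self,), backward)

    def item(self) -> float:
        return float(self.data)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# --------------------------------------------------------------------------
# activations and structural ops
# --------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    data = np.where(mask, x.data, 0.0).astype(DTYPE)

    def backward(g):
        Tensor._accum(x, g * mask)

    return Tensor._make(data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        Tensor._accum(x, g * data * (1.0 - data))

    return Tensor._make(data, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    logsum = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    data = shifted - logsum
    probs = np.exp(data)

    def backward(g):
        Tensor._accum(x, g - probs * g.sum(axis=axis, keepdims=True))

    return Tensor._make(data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        inner = (g * data).sum(axis=axis, keepdims=True)
        Tensor._accum(x, data * (g - inner))

    return Tensor._make(data, (x,), backward)


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            Tensor._accum(t, g[tuple(idx)])

    return Tensor._make(data, tensors, backward)


# --------------------------------------------------------------------------
# convolution / pooling / upsampling (forward helpers + autodiff wrappers)
# --------------------------------------------------------------------------

def _conv_forward(x: np.ndarray, weight: np.ndarray,
                  keep_patches: bool = False
                  ) -> tuple[np.ndarray, list[np.ndarray] | None]:
    """Same-padding stride-1 convolution as a sum of k^2 shifted matmuls.

    Returns ``(output (N*H*W, C_out), patches)``; with ``keep_patches`` the
    per-tap patch matrices are kept for the weight-gradient computation.
    """
    k, _, c_in, c_out = weight.shape
    n, h, w = x.shape[:3]
    if k == 1:
        flat = x.reshape(n * h * w, c_in)
        return flat @ weight[0, 0], ([flat] if keep_patches else None)
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    out = np.zeros((n * h * w, c_out), dtype=np.result_type(x, weight))
    patches: list[np.ndarray] | None = [] if keep_patches else None
    for a in range(k):
        for b in range(k):
            patch = np.ascontiguousarray(
                xp[:, a:a + h, b:b + w, :]).reshape(n * h * w, c_in)
            out += patch @ weight[a, b]
            if keep_patches:
                patches.append(patch)
    return out, patches


def conv2d_array(x: np.ndarray, weight: np.ndarray,
                 bias: np.ndarray | None = None) -> np.ndarray:
    """Plain-numpy stride-1 same-padding convolution (cross-correlation).

    Preserves the input float dtype, so contracts can be checked in float64.
    """
    x = np.asarray(x)
    weight = np.asarray(weight)
    k, k2, c_in, c_out = weight.shape
    if k != k2:
        raise ValueError(f"kernel must be square, got {weight.shape[:2]}")
    if x.shape[-1] != c_in:
        raise ValueError(
            f"input has {x.shape[-1]} channels but kernel expects {c_in}")
    n, h, w = x.shape[:3]
    out, _ = _conv_forward(x, weight)
    if bias is not None:
        out = out + np.asarray(bias)
    return out.reshape(n, h, w, c_out)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    k, _, c_in, c_out = weight.data.shape
    if x.data.shape[-1] != c_in:
        raise ValueError(
            f"input has {x.data.shape[-1]} channels but kernel expects {c_in}")
    n, h, w = x.data.shape[:3]
    needs_grad = x.requires_grad or weight.requires_grad
    out, patches = _conv_forward(x.data, weight.data,
                                 keep_patches=weight.requires_grad and needs_grad)
    if bias is not None:
        out = out + bias.data
    data = out.reshape(n, h, w, c_out)

    def backward(g):
        g_flat = np.ascontiguousarray(g).reshape(n * h * w, c_out)
        if bias is not None:
            Tensor._accum(bias, g_flat.sum(axis=0))
        pad = k // 2
        if weight.requires_grad:
            dw = np.empty_like(weight.data)
            for t, patch in enumerate(patches):
                dw[t // k, t % k] = patch.T @ g_flat
            Tensor._accum(weight, dw)
        if x.requires_grad:
            if k == 1:
                Tensor._accum(
                    x, (g_flat @ weight.data[0, 0].T).reshape(x.data.shape))
            else:
                gxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c_in), dtype=DTYPE)
                for a in range(k):
                    for b in range(k):
                        gxp[:, a:a + h, b:b + w, :] += (
                            g_flat @ weight.data[a, b].T).reshape(n, h, w, c_in)
                Tensor._accum(
                    x, np.ascontiguousarray(gxp[:, pad:pad + h, pad:pad + w, :]))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(data, parents, backward)


def _pool_geometry(h: int, w: int, p: int) -> tuple[int, int]:
    return math.ceil(h / p), math.ceil(w / p)


def max_pool2d_array(x: np.ndarray, p: int) -> np.ndarray:
    x = np.asarray(x)
    n, h, w, c = x.shape
    if p < 1 or p > h or p > w:
        raise ValueError(f"pool size {p} invalid for spatial dims ({h}, {w})")
    ho, wo = _pool_geometry(h, w, p)
    xp = np.pad(x, ((0, 0), (0, ho * p - h), (0, wo * p - w), (0, 0)),
                constant_values=-np.inf)
    win = xp.reshape(n, ho, p, wo, p, c)
    return win.max(axis=(2, 4))


def max_pool2d(x: Tensor, p: int) -> Tensor:
    n, h, w, c = x.data.shape
    if p < 1 or p > h or p > w:
        raise ValueError(f"pool size {p} invalid for spatial dims ({h}, {w})")
    ho, wo = _pool_geometry(h, w, p)
    xp = np.pad(x.data, ((0, 0), (0, ho * p - h), (0, wo * p - w), (0, 0)),
                constant_values=-np.inf)
    flat = xp.reshape(n, ho, p, wo, p, c).transpose(0, 1, 3, 2, 4, 5)
    flat = np.ascontiguousarray(flat).reshape(n, ho, wo, p * p, c)
    idx = flat.argmax(axis=3)  # first max wins on ties
    data = np.take_along_axis(flat, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(g):
        d_flat = np.zeros((n, ho, wo, p * p, c), dtype=DTYPE)
        np.put_along_axis(d_flat, idx[:, :, :, None, :], g[:, :, :, None, :],
                          axis=3)
        d_win = d_flat.reshape(n, ho, wo, p, p, c).transpose(0, 1, 3, 2, 4, 5)
        gx = d_win.reshape(n, ho * p, wo * p, c)[:, :h, :w, :]
        Tensor._accum(x, np.ascontiguousarray(gx))

    return Tensor._make(data, (x,), backward)


def upsample_nearest_array(x: np.ndarray, out_hw: tuple[int, int],
                           p: int) -> np.ndarray:
    """Nearest-neighbor upsample: ``out[i, j] = x[i // p, j // p]``."""
    x = np.asarray(x)
    ho, wo = out_hw
    rows = np.minimum(np.arange(ho) // p, x.shape[1] - 1)
    cols = np.minimum(np.arange(wo) // p, x.shape[2] - 1)
    return x[:, rows][:, :, cols]


def upsample_nearest(x: Tensor, out_hw: tuple[int, int], p: int) -> Tensor:
    n, hp, wp, c = x.data.shape
    ho, wo = out_hw
    if ho > hp * p or wo > wp * p:
        raise ValueError(f"cannot upsample ({hp}, {wp}) by {p} to ({ho}, {wo})")
    data = upsample_nearest_array(x.data, out_hw, p)

    def backward(g):
        gp = np.pad(g, ((0, 0), (0, hp * p - ho), (0, wp * p - wo), (0, 0)))
        gx = gp.reshape(n, hp, p, wp, p, c).sum(axis=(2, 4))
        Tensor._accum(x, gx)

    return Tensor._make(data, (x,), backward)


def pad_replicate(x: Tensor, p: int = 1) -> Tensor:
    """Edge-replication padding of the two spatial axes of an NHWC tensor."""
    n, h, w, c = x.data.shape
    rows = np.clip(np.arange(-p, h + p), 0, h - 1)
    cols = np.clip(np.arange(-p, w + p), 0, w - 1)
    data = x.data[:, rows][:, :, cols]

    def backward(g):
        tmp = np.zeros((n, h, w + 2 * p, c), dtype=DTYPE)
        np.add.at(tmp, (slice(None), rows), g)
        gx = np.zeros((n, h, w, c), dtype=DTYPE)
        np.add.at(gx.transpose(0, 2, 1, 3), (slice(None), cols),
                  tmp.transpose(0, 2, 1, 3))
        Tensor._accum(x, gx)

    return Tensor._make(data, (x,), backward)


def crop_center(x: Tensor, p: int) -> Tensor:
    """Remove a ``p``-pixel border from the two spatial axes."""
    n, h, w, c = x.data.shape
    data = np.ascontiguousarray(x.data[:, p:h - p, p:w - p, :])

    def backward(g):
        gx = np.zeros((n, h, w, c), dtype=DTYPE)
        gx[:, p:h - p, p:w - p, :] = g
        Tensor._accum(x, gx)

    return Tensor._make(data, (x,), backward)


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(DTYPE)


def glorot_uniform(rng: np.random.Generator, shape: tuple, fan_in: int,
                   fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


_ACTIVATIONS: dict[str, Callable[[Tensor], Tensor]] = {
    "relu": relu,
    "sigmoid": sigmoid,
    "linear": lambda t: t,
}


def _apply_activation(x: Tensor, name: str | None) -> Tensor:
    if name is None:
        return x
    try:
        return _ACTIVATIONS[name](x)
    except KeyError:
        raise ValueError(f"unknown activation {name!r}") from None


class Module:
    """Base class providing parameter discovery and (de)serialization."""

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if prefix == "" else f"{prefix}.{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def count_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, "
                           f"unexpected={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{p.data.shape} vs {state[name].shape}")
            p.data = _as_array(state[name]).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Dense(Module):
    """Fully connected layer on ``(N, in_features)`` inputs."""

    def __init__(self, in_features: int, out_features: int,
                 activation: str | None = None, use_bias: bool = True,
                 rng: np.random.Generator | None = None,
                 init: str = "he_normal"):
        rng = rng if rng is not None else np.random.default_rng(0)
        if init == "he_normal":
            w = he_normal(rng, (in_features, out_features), in_features)
        else:
            w = glorot_uniform(rng, (in_features, out_features),
                               in_features, out_features)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features, dtype=DTYPE)) if use_bias else None
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return _apply_activation(y, self.activation)


class Conv2D(Module):
    """Stride-1, same-padding 2-D convolution on NHWC inputs."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 activation: str | None = None, use_bias: bool = True,
                 rng: np.random.Generator | None = None,
                 init: str = "he_normal"):
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd and >= 1, got {kernel_size}")
        rng = rng if rng is not None else np.random.default_rng(0)
        shape = (kernel_size, kernel_size, in_channels, out_channels)
        fan_in = kernel_size * kernel_size * in_channels
        if init == "he_normal":
            w = he_normal(rng, shape, fan_in)
        else:
            w = glorot_uniform(rng, shape, fan_in,
                               kernel_size * kernel_size * out_channels)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE)) if use_bias else None
        self.activation = activation
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        y = conv2d(x, self.weight, self.bias)
        return _apply_activation(y, self.activation)


class Adam:
    """Adam optimizer (Kingma & Ba) over a parameter list."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
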