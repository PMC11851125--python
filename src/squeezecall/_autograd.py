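"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The basecaller's encoder, losses and optimizer are built on this engine.
It implements exactly the operations the model needs — broadcast-aware
arithmetic, (batched) matmul, 1-D dense/depthwise convolution, layer norm,
GELU/sigmoid, softmax/log-softmax, slicing/reshape/transpose/concat,
nearest-neighbour time upsampling and dropout — each with an analytic
backward pass.  Gradients are accumulated by a topological sweep from the
loss node.

Arrays keep whatever float dtype they are given; the model uses float32,
the finite-difference tests use float64.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = [
    "Tensor",
    "no_grad",
    "add", "sub", "mul", "scale", "matmul", "concat", "getitem",
    "reshape", "transpose", "tsum", "tmean", "layer_norm", "gelu",
    "sigmoid", "softmax", "log_softmax", "conv1d", "depthwise_conv1d",
    "repeat_time", "dropout",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (forward-only inference)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}, name={self.name!r})"

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, seed_grad: np.ndarray | None = None):
        """Backpropagate from this node (default seed: ones)."""
        if seed_grad is None:
            seed_grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be thousands of nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(seed_grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                g = g.astype(parent.data.dtype, copy=False)
                if parent.grad is None:
                    parent.grad = g.copy() if g.base is not None else g
                else:
                    parent.grad += g

    # operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        if isinstance(other, Tensor):
            return mul(self, other)
        return scale(self, other)

    __rmul__ = __mul__

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _tracing(*tensors: Tensor) -> bool:
    return _GRAD_ENABLED and any(t.requires_grad for t in tensors)


def _make(data, parents: Iterable[Tensor], backward) -> Tensor:
    parents = tuple(parents)
    out = Tensor(data)
    if _tracing(*parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- arithmetic ----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(a.data + b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)))


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(a.data - b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape)))


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(a.data * b.data, (a, b),
                 lambda g: (_unbroadcast(g * b.data, a.data.shape),
                            _unbroadcast(g * a.data, b.data.shape)))


def scale(a, c: float) -> Tensor:
    a = _as_tensor(a)
    c = float(c)
    return _make(a.data * c, (a,), lambda g: (g * c,))


def matmul(a, b) -> Tensor:
    """Matrix product; supports stacked (batched) operands like np.matmul."""
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

    return _make(np.matmul(a.data, b.data), (a, b), backward)


# -- shape ops -----------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    return _make(a.data.reshape(shape), (a,), lambda g: (g.reshape(a.data.shape),))


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    inv = np.argsort(axes)
    return _make(a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),))


def getitem(a, idx) -> Tensor:
    a = _as_tensor(a)
    # integer-array indices may repeat -> need unbuffered np.add.at; plain
    # slices/ints cannot, and += is much faster there
    simple = isinstance(idx, (int, slice)) or (
        isinstance(idx, tuple) and all(isinstance(i, (int, slice)) for i in idx))

    def backward(g):
        out = np.zeros_like(a.data)
        if simple:
            out[idx] += g
        else:
            np.add.at(out, idx, g)
        return (out,)

    return _make(a.data[idx], (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def tsum(a, axis=None) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        return (np.broadcast_to(np.expand_dims(g, axis), a.data.shape).copy(),)

    return _make(a.data.sum(axis=axis), (a,), backward)


def tmean(a, axis=None) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return scale(tsum(a, axis=axis), 1.0 / n)


# -- nonlinearities and normalizations -----------------------------------

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(a) -> Tensor:
    """Exact (erf-based) Gaussian Error Linear Unit."""
    a = _as_tensor(a)
    x = a.data
    cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2))

    def backward(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
        return (g * (cdf + x * pdf),)

    return _make(x * cdf, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    return _make(s, (a,), lambda g: (g * s * (1.0 - s),))


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * p).sum(axis=axis, keepdims=True)
        return (p * (g - dot),)

    return _make(p, (a,), backward)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    logp = z - lse

    def backward(g):
        return (g - np.exp(logp) * g.sum(axis=axis, keepdims=True),)

    return _make(logp, (a,), backward)


def layer_norm(a, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    a = _as_tensor(a)
    x = a.data
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv

    def backward(g):
        n = x.shape[-1]
        gg = g * gain.data
        gx = inv / n * (n * gg - gg.sum(axis=-1, keepdims=True)
                        - xhat * (gg * xhat).sum(axis=-1, keepdims=True))
        ggain = _unbroadcast(g * xhat, gain.data.shape)
        gbias = _unbroadcast(g, bias.data.shape)
        return gx, ggain, gbias

    return _make(xhat * gain.data + bias.data, (a, gain, bias), backward)


# -- convolutions --------------------------------------------------------

def conv1d(a, weight: Tensor, bias: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """Dense 1-D convolution on (B, T, C_in) input.

    weight has shape (K, C_in, C_out); output is (B, T', C_out) with
    T' = floor((T + 2*padding - K) / stride) + 1.
    """
    a = _as_tensor(a)
    K, cin, cout = weight.data.shape
    x = a.data
    if padding:
        xp = np.pad(x, ((0, 0), (padding, padding), (0, 0)))
    else:
        xp = x
    t_out = (xp.shape[1] - K) // stride + 1
    win = sliding_window_view(xp, K, axis=1)[:, ::stride]      # (B, T', C_in, K)
    win = np.ascontiguousarray(np.swapaxes(win, 2, 3))         # (B, T', K, C_in)
    flat = win.reshape(x.shape[0], t_out, K * cin)
    y = flat @ weight.data.reshape(K * cin, cout) + bias.data

    def backward(g):
        gw = np.tensordot(flat, g, axes=([0, 1], [0, 1])).reshape(K, cin, cout)
        gb = g.sum(axis=(0, 1))
        gxp = np.zeros_like(xp)
        for k in range(K):
            # g @ W_k^T scattered back to the samples the k-th tap touched
            gxp[:, k:k + t_out * stride:stride] += g @ weight.data[k].T
        gx = gxp[:, padding:xp.shape[1] - padding] if padding else gxp
        return gx, gw, gb

    return _make(y, (a, weight, bias), backward)


def depthwise_conv1d(a, weight: Tensor, bias: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """Per-channel 1-D convolution on (B, T, C); weight shape (K, C)."""
    a = _as_tensor(a)
    K, c = weight.data.shape
    x = a.data
    xp = np.pad(x, ((0, 0), (padding, padding), (0, 0))) if padding else x
    t_out = (xp.shape[1] - K) // stride + 1
    y = np.zeros((x.shape[0], t_out, c), dtype=x.dtype)
    for k in range(K):
        y += xp[:, k:k + t_out * stride:stride] * weight.data[k]
    y += bias.data

    def backward(g):
        gw = np.empty_like(weight.data)
        gxp = np.zeros_like(xp)
        for k in range(K):
            seg = xp[:, k:k + t_out * stride:stride]
            gw[k] = (g * seg).sum(axis=(0, 1))
            gxp[:, k:k + t_out * stride:stride] += g * weight.data[k]
        gx = gxp[:, padding:xp.shape[1] - padding] if padding else gxp
        return gx, gw, g.sum(axis=(0, 1))

    return _make(y, (a, weight, bias), backward)


# -- resampling and regularization ---------------------------------------

def repeat_time(a, factor: int, out_len: int) -> Tensor:
    """Nearest-neighbour upsampling along axis 1, truncated to out_len."""
    a = _as_tensor(a)
    T = a.data.shape[1]

    def backward(g):
        pad = T * factor - out_len
        if pad:
            g = np.concatenate([g, np.zeros(g.shape[:1] + (pad,) + g.shape[2:], g.dtype)], axis=1)
        return (g.reshape(g.shape[0], T, factor, *g.shape[2:]).sum(axis=2),)

    y = np.repeat(a.data, factor, axis=1)[:, :out_len]
    return _make(y, (a,), backward)


def dropout(a, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when p == 0 or rng is None (eval mode)."""
    a = _as_tensor(a)
    if p <= 0.0 or rng is None:
        return a
    keep = (rng.random(a.data.shape) >= p).astype(a.data.dtype) / (1.0 - p)
    return _make(a.data * keep, (a,), lambda g: (g * keep,))
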