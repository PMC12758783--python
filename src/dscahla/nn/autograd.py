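"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine provides exactly the primitives the presentation model needs:
broadcast-aware arithmetic, (batched) matrix products, masked softmax,
layer normalization, 1-D convolution, masked/adaptive max pooling, row
gathering and row-wise L2 normalization.  Composite operations carry
hand-written backward rules, which keeps the tape short and the training
loop fast enough for CPU use.

Gradients are accumulated on :class:`Tensor` leaves with
``requires_grad=True`` after calling :meth:`Tensor.backward` on a scalar.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "mul", "matmul", "concat", "swap_last", "gather_rows",
    "reduce_sum", "reduce_mean", "masked_softmax", "layer_norm",
    "relu", "gelu", "sigmoid", "log", "l2_normalize",
    "masked_max", "adaptive_max_pool", "conv1d", "dropout",
]


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic protocol -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- operators ------------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), _const(-1.0, self)))

    def __neg__(self):
        return mul(self, _const(-1.0, self))

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("tensor/tensor division is not a supported primitive")
        return mul(self, _const(1.0 / float(scalar), self))

    def __matmul__(self, other):
        return matmul(self, other)

    # -- backward -------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order over the tape
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _const(value, like: Tensor) -> Tensor:
    return Tensor(np.asarray(value, dtype=like.data.dtype))


def _needs(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._backward is not None for t in tensors)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _needs(*parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- arithmetic ---------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data
    return _node(data, (a, b), lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data
    return _node(
        data, (a, b),
        lambda g: (_unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)),
    )


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = np.matmul(a.data, b.data)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return _node(data, (a, b), backward)


def swap_last(a: Tensor) -> Tensor:
    return _node(np.swapaxes(a.data, -1, -2), (a,), lambda g: (np.swapaxes(g, -1, -2),))


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(data, tuple(tensors), backward)


def gather_rows(a: Tensor, index: np.ndarray) -> Tensor:
    """Select leading-axis slices: out[i] = a[index[i]]."""
    index = np.asarray(index)
    data = a.data[index]

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, index, g)
        return (ga,)

    return _node(data, (a,), backward)


def reduce_sum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.shape).copy(),)
        g2 = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(g2, a.shape).copy(),)

    return _node(data, (a,), backward)


def reduce_mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return reduce_sum(a, axis=axis, keepdims=keepdims) / n


# -- nonlinearities -----------------------------------------------------

def relu(a: Tensor) -> Tensor:
    data = np.maximum(a.data, 0)
    return _node(data, (a,), lambda g: (g * (a.data > 0),))


_GELU_C = 0.7978845608028654  # sqrt(2/pi)


def gelu(a: Tensor) -> Tensor:
    """tanh-approximated Gaussian error linear unit."""
    x = a.data
    x2 = x * x
    inner = x2 * x
    inner *= np.asarray(0.044715, dtype=x.dtype)
    inner += x
    inner *= np.asarray(_GELU_C, dtype=x.dtype)
    t = np.tanh(inner, out=inner)
    data = (1.0 + t) * x
    data *= np.asarray(0.5, dtype=x.dtype)

    def backward(g):
        dt = (1.0 - t * t) * _GELU_C * (1.0 + 0.134145 * x2)
        return (g * (0.5 * (1.0 + t) + 0.5 * x * dt),)

    return _node(data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-a.data))
    return _node(data, (a,), lambda g: (g * data * (1.0 - data),))


def log(a: Tensor) -> Tensor:
    return _node(np.log(a.data), (a,), lambda g: (g / a.data,))


# -- normalizations -----------------------------------------------------

def masked_softmax(scores: Tensor, mask: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis; ``mask`` (broadcastable, bool) marks valid keys.

    Fully masked rows would be ill-defined and must not occur; callers
    guarantee at least one valid key per row.
    """
    x = scores.data
    if mask is not None:
        x = np.where(mask, x, np.asarray(-1e30, dtype=x.dtype))
    y = x - x.max(axis=-1, keepdims=True)
    np.exp(y, out=y)
    y /= y.sum(axis=-1, keepdims=True)
    s = y

    def backward(g):
        dot = (g * s).sum(axis=-1, keepdims=True)
        return (s * (g - dot),)

    return _node(s, (scores,), backward)


def layer_norm(a: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learned gain/bias."""
    x = a.data
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    data = xhat * gain.data + bias.data
    d = x.shape[-1]

    def backward(g):
        ggain = _unbroadcast(g * xhat, gain.shape)
        gbias = _unbroadcast(g, bias.shape)
        gh = g * gain.data
        gx = inv * (gh - gh.mean(axis=-1, keepdims=True)
                    - xhat * (gh * xhat).mean(axis=-1, keepdims=True))
        return gx, ggain, gbias

    return _node(data, (a, gain, bias), backward)


def l2_normalize(a: Tensor, eps: float = 1e-8) -> Tensor:
    """Divide each last-axis row by its Euclidean norm (guarded by ``eps``)."""
    x = a.data
    nrm = np.sqrt((x ** 2).sum(axis=-1, keepdims=True))
    denom = nrm + eps
    data = x / denom

    def backward(g):
        safe = np.maximum(nrm, eps)
        gx = g / denom - x * ((g * x).sum(axis=-1, keepdims=True) / (denom ** 2 * safe))
        return (gx,)

    return _node(data, (a,), backward)


# -- pooling ------------------------------------------------------------

def masked_max(a: Tensor, mask: np.ndarray, axis: int = 1) -> Tensor:
    """Max over ``axis`` restricted to positions where ``mask`` is True."""
    x = np.where(np.expand_dims(mask, -1) if mask.ndim == a.ndim - 1 else mask,
                 a.data, -np.inf)
    idx = x.argmax(axis=axis)
    data = np.take_along_axis(x, np.expand_dims(idx, axis), axis=axis).squeeze(axis)

    def backward(g):
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis)
        return (ga,)

    return _node(data, (a,), backward)


def adaptive_max_pool(a: Tensor, out_len: int) -> Tensor:
    """Adaptive max pooling along axis 1: (B, L, C) -> (B, out_len, C).

    Segment *i* covers [floor(i*L/out), ceil((i+1)*L/out)).
    """
    b, length, c = a.shape
    if out_len > length:
        raise ValueError(f"cannot pool length {length} up to {out_len}")
    outs, idxs = [], []
    for i in range(out_len):
        lo = (i * length) // out_len
        hi = -(-((i + 1) * length) // out_len)
        seg = a.data[:, lo:hi]
        k = seg.argmax(axis=1)
        outs.append(np.take_along_axis(seg, k[:, None], axis=1)[:, 0])
        idxs.append(k + lo)
    data = np.stack(outs, axis=1)
    index = np.stack(idxs, axis=1)  # (B, out_len, C) absolute argmax positions

    def backward(g):
        ga = np.zeros_like(a.data)
        bi = np.arange(b)[:, None, None]
        ci = np.arange(c)[None, None, :]
        np.add.at(ga, (bi, index, ci), g)
        return (ga,)

    return _node(data, (a,), backward)


# -- convolution --------------------------------------------------------

def conv1d(a: Tensor, weight: Tensor, bias: Tensor | None, mode: str = "valid") -> Tensor:
    """1-D convolution along the sequence axis.

    ``a``: (B, L, C_in); ``weight``: (k, C_in, C_out); ``bias``: (C_out,) or None.
    ``mode='valid'`` emits L-k+1 windows; ``mode='same'`` zero-pads to keep L.
    """
    k, cin, cout = weight.shape
    x = a.data
    pad_l = pad_r = 0
    if mode == "same":
        pad_l = (k - 1) // 2
        pad_r = k // 2
        x = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
    elif mode != "valid":
        raise ValueError(f"unknown conv mode {mode!r}")
    b, lp, _ = x.shape
    lout = lp - k + 1
    if lout < 1:
        raise ValueError(f"sequence length {a.shape[1]} shorter than kernel {k}")
    windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (B, Lout, Cin, k)
    w2 = weight.data.reshape(k * cin, cout)
    data = np.tensordot(windows, weight.data, axes=([3, 2], [0, 1]))
    if bias is not None:
        data += bias.data

    def backward(g):
        gw = np.tensordot(windows, g, axes=([0, 1], [0, 1])).transpose(1, 0, 2)
        gb = None if bias is None else g.sum(axis=(0, 1))
        gcol = (g @ w2.T).reshape(b, lout, k, cin)
        gx = np.zeros_like(x)
        for j in range(k):
            gx[:, j:j + lout] += gcol[:, :, j]
        if pad_l or pad_r:
            gx = gx[:, pad_l:lp - pad_r]
        if bias is None:
            return gx, gw
        return gx, gw, gb

    parents = (a, weight) if bias is None else (a, weight, bias)
    return _node(data, parents, backward)


def dropout(a: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return a
    u = rng.random(a.shape, dtype=np.float32) if a.data.dtype == np.float32 \
        else rng.random(a.shape)
    keep = (u >= p).astype(a.data.dtype)
    keep /= (1.0 - p)
    return mul(a, Tensor(keep))
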