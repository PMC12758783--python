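"""Layer building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{key}.{i}."))
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def set_training(self, flag: bool):
        self.training = flag
        for value in vars(self).values():
            if isinstance(value, Module):
                value.set_training(flag)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.set_training(flag)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Tensor(_glorot(rng, d_in, d_out, (d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = ag.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, d: int):
        super().__init__()
        self.gain = Tensor(np.ones(d, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(d, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.layer_norm(x, self.gain, self.bias)


class Conv1d(Module):
    """Sequence-axis convolution, (B, L, C_in) -> (B, L', C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 mode: str = "valid"):
        super().__init__()
        self.kernel = kernel
        self.mode = mode
        fan_in = kernel * c_in
        self.weight = Tensor(_glorot(rng, fan_in, c_out, (kernel, c_in, c_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv1d(x, self.weight, self.bias, mode=self.mode)


class SelfAttention(Module):
    """Single-head scaled dot-product self-attention with key masking."""

    def __init__(self, d_in: int, d_attn: int, rng: np.random.Generator):
        super().__init__()
        self.d_attn = d_attn
        self.w_q = Linear(d_in, d_attn, rng, bias=False)
        self.w_k = Linear(d_in, d_attn, rng, bias=False)
        self.w_v = Linear(d_in, d_attn, rng, bias=False)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None,
                 return_attn: bool = False):
        q, k, v = self.w_q(x), self.w_k(x), self.w_v(x)
        scores = ag.matmul(q, ag.swap_last(k)) / np.sqrt(self.d_attn)
        key_mask = None if mask is None else mask[..., None, :]
        attn = ag.masked_softmax(scores, key_mask)
        out = ag.matmul(attn, v)
        if mask is not None:  # zero rows of padded query positions
            out = out * Tensor(mask[..., :, None].astype(np.float32))
        if return_attn:
            return out, attn
        return out


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.w_q = Linear(d_model, d_model, rng, bias=False)
        self.w_k = Linear(d_model, d_model, rng, bias=False)
        self.w_v = Linear(d_model, d_model, rng, bias=False)
        self.w_o = Linear(d_model, d_model, rng, bias=False)

    def _split(self, x: Tensor) -> Tensor:
        # (B, L, D) -> (B, H, L, d_head) via two cheap view ops on the tape
        b, l, d = x.shape
        data = x.data.reshape(b, l, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

        def backward(g):
            return (g.transpose(0, 2, 1, 3).reshape(b, l, d),)

        return ag._node(data, (x,), backward)

    def _merge(self, x: Tensor) -> Tensor:
        b, h, l, dh = x.shape
        data = x.data.transpose(0, 2, 1, 3).reshape(b, l, h * dh)

        def backward(g):
            return (g.reshape(b, l, h, dh).transpose(0, 2, 1, 3),)

        return ag._node(data, (x,), backward)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None,
                 return_attn: bool = False):
        q = self._split(self.w_q(x))
        k = self._split(self.w_k(x))
        v = self._split(self.w_v(x))
        scores = ag.matmul(q, ag.swap_last(k)) / np.sqrt(self.d_head)
        key_mask = None if mask is None else mask[:, None, None, :]
        attn = ag.masked_softmax(scores, key_mask)
        out = self.w_o(self._merge(ag.matmul(attn, v)))
        if return_attn:
            return out, attn
        return out


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: LN(x + MHSA(x)) then LN(z + FFN(z))."""

    def __init__(self, d_model: int, n_heads: int, d_ffn: int,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        self.mhsa = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ffn1 = Linear(d_model, d_ffn, rng)
        self.ffn2 = Linear(d_ffn, d_model, rng)
        self.ln2 = LayerNorm(d_model)
        self.p_drop = dropout

    def __call__(self, x: Tensor, mask: np.ndarray | None,
                 rng: np.random.Generator) -> Tensor:
        a = self.mhsa(x, mask)
        a = ag.dropout(a, self.p_drop, rng, self.training)
        z = self.ln1(x + a)
        f = self.ffn2(ag.gelu(self.ffn1(z)))
        f = ag.dropout(f, self.p_drop, rng, self.training)
        return self.ln2(z + f)


def sinusoidal_positions(length: int, d_model: int) -> np.ndarray:
    """Fixed sine/cosine positional encoding table, shape (length, d_model)."""
    pos = np.arange(length)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    table = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return table.astype(np.float32)
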