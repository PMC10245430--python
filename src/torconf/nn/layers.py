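"""Neural layers built on the autodiff tensors: linear maps, embeddings,
layer norm, multi-head attention and transformer encoder/decoder blocks."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor, concat, softmax

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "MultiHeadAttention",
    "FeedForward",
    "EncoderLayer",
    "DecoderLayer",
    "sinusoidal_encoding",
]


class Module:
    """Base class with recursive parameter discovery and state (de)serialisation."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, v in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {v.data.shape}")
            v.data[...] = arr

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _init(rng: np.random.Generator, *shape) -> Tensor:
    # Glorot-uniform
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = _init(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Embedding(Module):
    def __init__(self, n_vocab: int, d: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 0.02, size=(n_vocab, d)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.weight[np.asarray(idx, dtype=np.intp)]


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class MultiHeadAttention(Module):
    """Scaled dot-product attention over (..., L, D) sequences.

    Supports self-attention (kv = q) and cross-attention; an optional boolean
    ``mask[i, j]`` (query i may attend to key j) implements causal decoding.
    The last attention weights are kept on ``self.last_weights`` for
    inspection of what the model attends to.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads:
            raise ValueError("hidden width must be divisible by the head count")
        self.d, self.n_heads, self.d_head = d, n_heads, d // n_heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self.last_weights: np.ndarray | None = None

    def _split(self, x: Tensor) -> Tensor:
        *lead, L, _ = x.shape
        return x.reshape(*lead, L, self.n_heads, self.d_head).transpose(
            *range(len(lead)), len(lead) + 1, len(lead), len(lead) + 2
        )

    def __call__(self, q: Tensor, kv: Tensor | None = None, mask: np.ndarray | None = None) -> Tensor:
        kv = q if kv is None else kv
        Q, K, V = self._split(self.wq(q)), self._split(self.wk(kv)), self._split(self.wv(kv))
        scores = (Q @ K.transpose(*range(Q.ndim - 2), Q.ndim - 1, Q.ndim - 2)) * (
            1.0 / math.sqrt(self.d_head)
        )
        attn = softmax(scores, axis=-1, mask=None if mask is None else np.broadcast_to(mask, scores.shape))
        self.last_weights = attn.data.copy()
        ctx = attn @ V
        *lead, H, L, dh = ctx.shape
        ctx = ctx.transpose(*range(len(lead)), len(lead) + 1, len(lead), len(lead) + 2)
        return self.wo(ctx.reshape(*lead, L, H * dh))


class FeedForward(Module):
    def __init__(self, d: int, d_ff: int, rng: np.random.Generator):
        self.fc1 = Linear(d, d_ff, rng)
        self.fc2 = Linear(d_ff, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class EncoderLayer(Module):
    """Pre-norm transformer encoder block (self-attention + FFN, residuals)."""

    def __init__(self, d: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.attn = MultiHeadAttention(d, n_heads, rng)
        self.ffn = FeedForward(d, d_ff, rng)
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        x = x + self.attn(self.ln1(x), mask=mask)
        return x + self.ffn(self.ln2(x))


class DecoderLayer(Module):
    """Pre-norm decoder block: causal self-attention, cross-attention, FFN."""

    def __init__(self, d: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.self_attn = MultiHeadAttention(d, n_heads, rng)
        self.cross_attn = MultiHeadAttention(d, n_heads, rng)
        self.ffn = FeedForward(d, d_ff, rng)
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)
        self.ln3 = LayerNorm(d)

    def __call__(self, x: Tensor, memory: Tensor, causal_mask: np.ndarray) -> Tensor:
        x = x + self.self_attn(self.ln1(x), mask=causal_mask)
        x = x + self.cross_attn(self.ln2(x), kv=memory)
        return x + self.ffn(self.ln3(x))


def sinusoidal_encoding(positions: np.ndarray, d: int) -> np.ndarray:
    """Classic fixed sine/cosine encoding of integer sequence positions."""
    positions = np.asarray(positions, dtype=np.float64)[..., None]
    half = d // 2
    freq = np.exp(-math.log(10000.0) * np.arange(half) / max(half - 1, 1))
    enc = np.zeros(positions.shape[:-1] + (d,))
    enc[..., 0::2] = np.sin(positions * freq)
    enc[..., 1::2] = np.cos(positions * freq[: d - half])
    return enc
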