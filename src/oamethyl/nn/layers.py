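"""Neural building blocks for the dual-branch methylation classifier.

All layers hold `Tensor` parameters and are initialized from an explicit
`numpy.random.Generator`, so a model built twice from the same seed has
bit-identical weights.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autograd import Tensor, concat, softmax


class Module:
    """Base class: parameter discovery by attribute walk."""

    def parameters(self) -> Iterator[Tensor]:
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                yield value
            elif isinstance(value, Module):
                yield from value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.parameters()
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield item

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, arr in zip(self.parameters(), state, strict=True):
            p.data = arr.copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Tensor(_glorot(rng, in_dim, out_dim, (in_dim, out_dim)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps).pow(-0.5) * self.gamma + self.beta


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None,
            training: bool) -> Tensor:
    if not training or rate <= 0.0 or rng is None:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over the CpG token axis."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ValueError(
                f"n_heads={n_heads} must divide d_model={d_model}"
            )
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self.last_attention: np.ndarray | None = None

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        return x.reshape(B, L, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, D = x.shape
        q = self._split(self.wq(x), B, L)
        k = self._split(self.wk(x), B, L)
        v = self._split(self.wv(x), B, L)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.d_head))
        attn = softmax(scores, axis=-1)
        self.last_attention = attn.data
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.wo(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder block: self-attention + position-wise feed-forward."""

    def __init__(self, d_model: int, n_heads: int, ff_dim: int,
                 drop_rate: float, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ff1 = Linear(d_model, ff_dim, rng)
        self.ff2 = Linear(ff_dim, d_model, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.drop_rate = drop_rate

    def __call__(self, x: Tensor, rng=None, training: bool = False) -> Tensor:
        a = dropout(self.attn(x), self.drop_rate, rng, training)
        x = self.norm1(x + a)
        f = dropout(self.ff2(self.ff1(x).relu()), self.drop_rate, rng, training)
        return self.norm2(x + f)


class Conv1d(Module):
    """1-D convolution along the token axis with 'same' zero padding.

    Input (B, L, C_in) -> output (B, L, C_out); kernel must not exceed L.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        self.kernel = kernel
        fan_in = kernel * in_ch
        self.weight = Tensor(_glorot(rng, fan_in, out_ch, (kernel, in_ch, out_ch)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        if self.kernel > L:
            raise ValueError(
                f"kernel width {self.kernel} exceeds sequence length {L}"
            )
        left = (self.kernel - 1) // 2
        xp = x.pad_axis(1, left, self.kernel - 1 - left)
        out = None
        for j in range(self.kernel):
            term = xp[:, j:j + L, :] @ self.weight[j]
            out = term if out is None else out + term
        return out + self.bias


class CpGEmbedding(Module):
    """Per-site affine projection of the scalar beta value plus a learned
    position embedding indexed by genomic order."""

    def __init__(self, n_features: int, d_model: int, rng: np.random.Generator):
        self.n_features = n_features
        self.value_weight = Tensor(
            rng.normal(0.0, 1.0 / math.sqrt(d_model), (n_features, d_model)),
            requires_grad=True)
        self.value_bias = Tensor(np.zeros((n_features, d_model)),
                                 requires_grad=True)
        self.position = Tensor(
            rng.normal(0.0, 0.02, (n_features, d_model)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.n_features:
            raise ValueError(
                f"input has {x.shape[-1]} features, embedding expects "
                f"{self.n_features}"
            )
        B, L = x.shape
        tokens = x.reshape(B, L, 1) * self.value_weight + self.value_bias
        return tokens + self.position


class GatedFusion(Module):
    """Dynamic weight gating: g = sigmoid(W2 relu(W1 [pa;pb] + b1) + b2),
    fused = g * pa + (1 - g) * pb."""

    def __init__(self, fusion_dim: int, hidden_dim: int,
                 rng: np.random.Generator):
        self.fc1 = Linear(2 * fusion_dim, hidden_dim, rng)
        self.fc2 = Linear(hidden_dim, fusion_dim, rng)

    def gate(self, p_a: Tensor, p_b: Tensor) -> Tensor:
        z = concat([p_a, p_b], axis=-1)
        return self.fc2(self.fc1(z).relu()).sigmoid()

    def __call__(self, p_a: Tensor, p_b: Tensor) -> tuple[Tensor, Tensor]:
        g = self.gate(p_a, p_b)
        fused = g * p_a + (1.0 - g) * p_b
        return fused, g


class Adam:
    """Adaptive-moment optimizer (standard bias-corrected form)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
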