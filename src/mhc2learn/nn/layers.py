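"""Neural building blocks: dense layers, pre-norm transformer encoders,
and low-rank bilinear attention pooling."""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Module", "Linear", "LayerNorm", "FeedForward",
    "MultiHeadSelfAttention", "TransformerEncoderLayer",
    "PositionalEmbedding", "SequenceEncoder", "BilinearAttention", "MLP",
]


class Module:
    """Base class: recursively collects :class:`Tensor` parameters."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            obj = stack.pop()
            for value in vars(obj).values():
                if isinstance(value, Tensor) and value.requires_grad:
                    if id(value) not in seen:
                        seen.add(id(value))
                        params.append(value)
                elif isinstance(value, Module):
                    stack.append(value)
                elif isinstance(value, (list, tuple)):
                    stack.extend(v for v in value if isinstance(v, Module))
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.array(a, dtype=np.float64)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape) -> np.ndarray:
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.w = Tensor(_glorot(rng, d_in, d_out, (d_in, d_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.w
        return out + self.b if self.b is not None else out


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class FeedForward(Module):
    def __init__(self, d_model: int, d_hidden: int, rng):
        self.fc1 = Linear(d_model, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng):
        if d_model % n_heads:
            raise ValueError(
                f"n_heads={n_heads} must divide d_model={d_model}")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, L, d_model)
        B, L, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, L, h, dh).transpose(0, 2, 1, 3)  # (B,h,L,dh)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dh))
        att = scores.softmax(axis=-1)
        out = att @ v                                      # (B,h,L,dh)
        out = out.transpose(0, 2, 1, 3).reshape(B, L, d)
        return self.wo(out)


class TransformerEncoderLayer(Module):
    """Pre-norm encoder block (attention + feed-forward, residual)."""

    def __init__(self, d_model: int, n_heads: int, rng,
                 ff_mult: int = 2):
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ln2 = LayerNorm(d_model)
        self.ff = FeedForward(d_model, ff_mult * d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.ff(self.ln2(x))


class PositionalEmbedding(Module):
    """Learned per-position embedding added to the input projection."""

    def __init__(self, max_len: int, d_model: int, rng):
        self.emb = Tensor(rng.normal(0.0, 0.02, size=(max_len, d_model)),
                          requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        L = x.shape[-2]
        return x + self.emb[:L]


class SequenceEncoder(Module):
    """Input projection + positional embedding + a stack of encoder blocks.

    Maps an encoded sequence batch (B, L, C) to contextual features
    (B, L, d_model).
    """

    def __init__(self, d_in: int, d_model: int, n_heads: int,
                 n_layers: int, max_len: int, rng):
        self.proj = Linear(d_in, d_model, rng)
        self.pos = PositionalEmbedding(max_len, d_model, rng)
        self.layers = [TransformerEncoderLayer(d_model, n_heads, rng)
                       for _ in range(n_layers)]
        self.ln_out = LayerNorm(d_model)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.pos(self.proj(x))
        for layer in self.layers:
            h = layer(h)
        return self.ln_out(h)


class BilinearAttention(Module):
    """Low-rank bilinear attention pooling over a pair of sequences.

    Computes a pairwise interaction map between peptide positions and
    HLA residues and pools a joint representation of rank ``rank``.
    The normalized map is retained for interpretability exports.
    """

    def __init__(self, d_model: int, rank: int, rng):
        self.u = Linear(d_model, rank, rng, bias=False)
        self.v = Linear(d_model, rank, rng, bias=False)
        self.rank = rank
        self.last_attention: np.ndarray | None = None

    def __call__(self, pep: Tensor, hla: Tensor) -> Tensor:
        # pep: (B, Lp, d), hla: (B, La, d)
        hp = self.u(pep).tanh()                 # (B, Lp, r)
        ha = self.v(hla).tanh()                 # (B, La, r)
        scores = hp @ ha.swapaxes(-1, -2)       # (B, Lp, La)
        B, Lp, La = scores.shape
        att = scores.reshape(B, Lp * La).softmax(axis=-1).reshape(B, Lp, La)
        self.last_attention = att.data.copy()
        # pooled joint feature: sum_ij att_ij * (hp_i ∘ ha_j)
        weighted = att @ ha                     # (B, Lp, r)
        joint = (hp * weighted).sum(axis=1)     # (B, r)
        return joint


class MLP(Module):
    """Dense stack with ReLU activations; linear final layer."""

    def __init__(self, dims: list[int], rng):
        self.fcs = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for fc in self.fcs[:-1]:
            x = fc(x).relu()
        return self.fcs[-1](x)
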