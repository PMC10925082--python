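"""Building blocks for the pair-track network.

All layers operate on batched tensors: the sequence track is (B, L, d_seq)
and the pair track is (B, L, L, d_pair).  Weights are plain
:class:`~rkit.nn.autodiff.Tensor` parameters initialized from a shared
numpy Generator so the whole network is deterministic given one seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, softmax

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "Conv1d",
    "PairBiasedSelfAttention",
    "OuterProductMean",
    "TriangularUpdate",
]


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params


def _glorot(rng, fan_in: int, fan_out: int, shape) -> Tensor:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng, bias: bool = True):
        self.weight = _glorot(rng, d_in, d_out, (d_in, d_out))
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered * (var + self.eps) ** -0.5
        return normed * self.gamma + self.beta


class Conv1d(Module):
    """Same-padded 1D convolution along the sequence axis of (B, L, d)."""

    def __init__(self, d_in: int, d_out: int, kernel: int, rng):
        if kernel % 2 == 0:
            raise ValueError("conv kernel must be odd")
        self.kernel = kernel
        self.weight = _glorot(rng, d_in * kernel, d_out, (kernel, d_in, d_out))
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        half = self.kernel // 2
        L = x.shape[-2]
        xp = x.pad(((0, 0), (half, half), (0, 0)))
        out = None
        for o in range(self.kernel):
            term = xp[:, o : o + L, :] @ self.weight[o]
            out = term if out is None else out + term
        return out + self.bias


class PairBiasedSelfAttention(Module):
    """Multi-head self-attention on the sequence track whose logits are
    biased by a per-head projection of the pair track (information flowing
    pair -> sequence)."""

    def __init__(self, d_seq: int, d_pair: int, n_heads: int, rng):
        if d_seq % n_heads:
            raise ValueError("d_seq must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_seq // n_heads
        self.q = Linear(d_seq, d_seq, rng, bias=False)
        self.k = Linear(d_seq, d_seq, rng, bias=False)
        self.v = Linear(d_seq, d_seq, rng, bias=False)
        self.pair_bias = Linear(d_pair, n_heads, rng, bias=False)
        self.out = Linear(d_seq, d_seq, rng)

    def __call__(self, x: Tensor, pair: Tensor) -> Tensor:
        B, L, d = x.shape

        def split(t: Tensor) -> Tensor:  # (B, L, d) -> (B, H, L, dh)
            return t.reshape(B, L, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        bias = self.pair_bias(pair).transpose(0, 3, 1, 2)  # (B, H, L, L)
        attn = softmax(logits + bias, axis=-1)
        mixed = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, d)
        return self.out(mixed)


class OuterProductMean(Module):
    """Update the pair track from projected outer products of the sequence
    track (information flowing sequence -> pair)."""

    def __init__(self, d_seq: int, d_pair: int, rank: int, rng):
        self.rank = rank
        self.proj_a = Linear(d_seq, rank, rng)
        self.proj_b = Linear(d_seq, rank, rng)
        self.out = Linear(rank * rank, d_pair, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        r = self.rank
        a = self.proj_a(x).reshape(B, L, 1, r, 1)
        b = self.proj_b(x).reshape(B, 1, L, 1, r)
        outer = (a * b).reshape(B, L, L, r * r)
        return self.out(outer)


class TriangularUpdate(Module):
    """Triangular multiplicative update of the pair track.

    Edge (i, j) is updated from gated products of the two edges sharing its
    endpoints: (i, k) and (j, k) for the outgoing direction, (k, i) and
    (k, j) for the incoming one, aggregated over k.
    """

    def __init__(self, d_pair: int, direction: str, rng):
        if direction not in ("outgoing", "incoming"):
            raise ValueError("direction must be 'outgoing' or 'incoming'")
        self.direction = direction
        self.proj_a = Linear(d_pair, d_pair, rng)
        self.gate_a = Linear(d_pair, d_pair, rng)
        self.proj_b = Linear(d_pair, d_pair, rng)
        self.gate_b = Linear(d_pair, d_pair, rng)
        self.gate_out = Linear(d_pair, d_pair, rng)
        self.out = Linear(d_pair, d_pair, rng)

    def __call__(self, pair: Tensor) -> Tensor:
        B, L, _, d = pair.shape
        a = self.gate_a(pair).sigmoid() * self.proj_a(pair)  # (B, L, L, d)
        b = self.gate_b(pair).sigmoid() * self.proj_b(pair)
        at = a.transpose(0, 3, 1, 2)  # (B, d, L, L)
        bt = b.transpose(0, 3, 1, 2)
        if self.direction == "outgoing":
            # sum_k a[i, k] * b[j, k]
            agg = at @ bt.transpose(0, 1, 3, 2)
        else:
            # sum_k a[k, i] * b[k, j]
            agg = at.transpose(0, 1, 3, 2) @ bt
        update = self.out(agg.transpose(0, 2, 3, 1))
        return self.gate_out(pair).sigmoid() * update
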