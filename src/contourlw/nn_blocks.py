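"""Shared attention building block.

The transformer block used by both the contour-refinement stage and the
weight regressor follows the residual form

    MHSA(P) = P + (ReLU(P + Attention(P)) W_z1) W_z2

with scaled dot-product attention over H heads and a 4x feed-forward
expansion; all projections are bare matrices (no biases).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["MhsaBlock", "init_matrix"]


def init_matrix(rng, n_in: int, n_out: int, gain: float = 1.0) -> Tensor:
    std = gain / np.sqrt(n_in)
    return Tensor(rng.normal(0.0, std, (n_in, n_out)), requires_grad=True)


class MhsaBlock:
    """Multi-head self-attention block with residual feed-forward.

    Operates on (N, d) or batched (B, N, d) inputs; `d` must be divisible
    by the head count. The per-head attention maps of the latest forward
    pass are kept on ``last_attention`` (heads, N, N) for inspection.
    """

    def __init__(self, d: int, heads: int, rng, ffn_mult: int = 4):
        if d % heads:
            raise ValueError("d must be divisible by the head count")
        self.d = d
        self.heads = heads
        self.dk = d // heads
        self.w_q = init_matrix(rng, d, d)
        self.w_k = init_matrix(rng, d, d)
        self.w_v = init_matrix(rng, d, d)
        self.w_o = init_matrix(rng, d, d)
        self.w_z1 = init_matrix(rng, d, ffn_mult * d)
        self.w_z2 = init_matrix(rng, ffn_mult * d, d)
        self.last_attention = None

    def parameters(self):
        return [self.w_q, self.w_k, self.w_v, self.w_o, self.w_z1, self.w_z2]

    def attention(self, p: Tensor) -> Tensor:
        squeeze = p.ndim == 2
        if squeeze:
            p = p.reshape(1, *p.shape)
        b, n, d = p.shape
        h, dk = self.heads, self.dk

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(b, n, h, dk).transpose(0, 2, 1, 3)  # (b, h, n, dk)

        q = split_heads(p @ self.w_q)
        k = split_heads(p @ self.w_k)
        v = split_heads(p @ self.w_v)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
        att = scores.softmax(axis=-1)  # (b, h, n, n)
        self.last_attention = att.data[0] if squeeze else att.data
        mixed = att @ v  # (b, h, n, dk)
        merged = mixed.transpose(0, 2, 1, 3).reshape(b, n, d)
        out = merged @ self.w_o
        return out.reshape(n, d) if squeeze else out

    def forward(self, p: Tensor) -> Tensor:
        inner = (p + self.attention(p)).relu()
        return p + (inner @ self.w_z1) @ self.w_z2

    __call__ = forward
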