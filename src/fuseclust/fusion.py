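"""Multi-head attention information-fusion block.

Each block merges a topological embedding H (from the graph branch) with a
denoising embedding E (from the autoencoder branch).  Per head, the query is
projected from H and the key/value from E; scaled dot-product attention over
all cells yields an n x n score matrix per head, the attended values are
concatenated, linearly projected, and E is added back as a residual:

    R = W . Concat(a_1 V_1, ..., a_M V_M) + E

The per-head score matrices are kept on the block after every forward pass so
they can be exported for interpretability (cell–cell attention heatmaps).
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, concat, softmax_rows
from .nn import Linear, Module

__all__ = ["FusionBlock", "attention_scores", "fuse"]


class FusionBlock(Module):
    def __init__(self, d: int, n_heads: int, rng: np.random.Generator,
                 residual: bool = True, scale_scores: bool = True):
        if d % n_heads != 0:
            raise ValueError(f"embedding dim {d} not divisible by {n_heads} heads")
        self.d = d
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.residual = residual
        self.scale_scores = scale_scores
        self.w_q = [Linear(d, self.d_head, rng, bias=False) for _ in range(n_heads)]
        self.w_k = [Linear(d, self.d_head, rng, bias=False) for _ in range(n_heads)]
        self.w_v = [Linear(d, self.d_head, rng, bias=False) for _ in range(n_heads)]
        self.w_out = Linear(d, d, rng, bias=False)
        self.last_scores: np.ndarray | None = None  # (M, n, n) after forward

    def scores(self, h_topo: Tensor, e_denoise: Tensor) -> list[Tensor]:
        scale = 1.0 / np.sqrt(self.d_head) if self.scale_scores else 1.0
        out = []
        for m in range(self.n_heads):
            q = self.w_q[m](h_topo)
            k = self.w_k[m](e_denoise)
            out.append(softmax_rows((q @ k.T) * scale))
        return out

    def __call__(self, h_topo: Tensor, e_denoise: Tensor) -> Tensor:
        score_list = self.scores(h_topo, e_denoise)
        attended = [score_list[m] @ self.w_v[m](e_denoise)
                    for m in range(self.n_heads)]
        r = self.w_out(concat(attended, axis=1))
        if self.residual:
            r = r + e_denoise
        self.last_scores = np.stack([s.data for s in score_list])
        return r


def attention_scores(h_topo, e_denoise, block: FusionBlock) -> np.ndarray:
    """Per-head (M, n, n) attention score matrices; rows sum to one."""
    h = h_topo if isinstance(h_topo, Tensor) else Tensor(h_topo)
    e = e_denoise if isinstance(e_denoise, Tensor) else Tensor(e_denoise)
    return np.stack([s.data for s in block.scores(h, e)])


def fuse(h_topo, e_denoise, block: FusionBlock) -> np.ndarray:
    """Functional fused embedding for plain arrays (testing convenience)."""
    h = h_topo if isinstance(h_topo, Tensor) else Tensor(h_topo)
    e = e_denoise if isinstance(e_denoise, Tensor) else Tensor(e_denoise)
    return block(h, e).data
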