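"""Graph autoencoder pieces: GCN propagation and dot-product reconstruction.

The encoder unit is a graph convolution H_l = tanh(A_norm H_{l-1} W) over the
symmetrically normalised cell–cell adjacency.  The decoder reconstructs the
adjacency as sigmoid(H H^T) and the graph loss is the mean squared error
between reconstruction and the original kernel adjacency.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor
from .nn import Linear, Module

__all__ = ["GCNLayer", "gcn_layer", "reconstruct_adjacency", "graph_loss"]


class GCNLayer(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.linear = Linear(d_in, d_out, rng, bias=False)

    def __call__(self, h: Tensor, a_norm: Tensor) -> Tensor:
        return ((a_norm @ h) @ self.linear.weight).tanh()


def gcn_layer(h_prev, adjacency_norm, weight):
    """Functional form tanh(A_norm @ H @ W); accepts arrays or tensors."""
    h = h_prev if isinstance(h_prev, Tensor) else Tensor(h_prev)
    a = adjacency_norm if isinstance(adjacency_norm, Tensor) else Tensor(adjacency_norm)
    w = weight if isinstance(weight, Tensor) else Tensor(weight)
    if h.shape[1] != w.shape[0] or a.shape[1] != h.shape[0]:
        raise ValueError("shape mismatch between adjacency, features and weight")
    return ((a @ h) @ w).tanh()


def reconstruct_adjacency(h_last) -> Tensor:
    """A_recon = sigmoid(H H^T); symmetric by construction."""
    h = h_last if isinstance(h_last, Tensor) else Tensor(h_last)
    return (h @ h.T).sigmoid()


def graph_loss(a_recon, adjacency) -> Tensor:
    """Mean squared error between reconstructed and original adjacency."""
    a_hat = a_recon if isinstance(a_recon, Tensor) else Tensor(a_recon)
    a = adjacency if isinstance(adjacency, Tensor) else Tensor(adjacency)
    if a_hat.shape != a.shape:
        raise ValueError("adjacency shapes differ")
    diff = a_hat - a
    return (diff * diff).mean()
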