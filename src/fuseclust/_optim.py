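"""Adam optimiser and global L2 gradient clipping for the autograd tensors."""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor

__all__ = ["Adam", "clip_grad_norm"]


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``.

    Returns the pre-clipping global norm (useful for auditing the clip
    contract during training).
    """
    sq = 0.0
    for p in params:
        if p.grad is not None:
            sq += float((p.grad**2).sum())
    total = float(np.sqrt(sq))
    if total > max_norm and total > 0.0:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        # state keyed by tensor identity so parameters can be swapped out
        # (the clustering stage rebuilds the center tensor when a cluster dies)
        self._state: dict[int, dict] = {}

    def replace_param(self, old: Tensor, new: Tensor) -> None:
        """Swap a parameter; the replacement starts with fresh moments."""
        idx = next(i for i, p in enumerate(self.params) if p is old)
        self.params[idx] = new
        self._state.pop(id(old), None)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p in self.params:
            if p.grad is None:
                continue
            st = self._state.get(id(p))
            if st is None:
                st = {"m": np.zeros_like(p.data), "v": np.zeros_like(p.data), "t": 0}
                self._state[id(p)] = st
            st["t"] += 1
            st["m"] = self.b1 * st["m"] + (1 - self.b1) * p.grad
            st["v"] = self.b2 * st["v"] + (1 - self.b2) * p.grad**2
            mhat = st["m"] / (1 - self.b1 ** st["t"])
            vhat = st["v"] / (1 - self.b2 ** st["t"])
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
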