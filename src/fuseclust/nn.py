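"""Small layer library on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor

__all__ = ["Module", "Linear"]


class Module:
    """Base class: parameter collection via attribute traversal."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]


class Linear(Module):
    """Dense layer y = x W + b with Glorot-uniform initialisation."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.weight = Tensor(rng.uniform(-limit, limit, size=(d_in, d_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out
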