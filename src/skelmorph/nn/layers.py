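"""Small building blocks (linear layers, MLPs) on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, as_tensor


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class Linear:
    def __init__(self, rng, d_in, d_out, bias=True):
        self.W = Parameter(glorot(rng, d_in, d_out))
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = as_tensor(x) @ self.W
        return out + self.b if self.b is not None else out

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class MLP:
    """Stack of linear layers with ReLU between them (none after the last)."""

    def __init__(self, rng, widths, final_relu=False):
        self.layers = [
            Linear(rng, a, b) for a, b in zip(widths[:-1], widths[1:])
        ]
        self.final_relu = final_relu

    def __call__(self, x: Tensor) -> Tensor:
        h = as_tensor(x)
        for i, lin in enumerate(self.layers):
            h = lin(h)
            if i < len(self.layers) - 1 or self.final_relu:
                h = h.relu()
        return h

    def parameters(self):
        return [p for lin in self.layers for p in lin.parameters()]
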