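"""Neural-network layers built on the autodiff engine.

Minimal module system: each layer owns named parameters; `Module.parameters()`
walks the tree in a stable order so optimizer state and checkpoints line up
across runs.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, max_pool2d

DTYPE = np.float32


class Module:
    """Base class with stable, recursive parameter discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for _, value in sorted(vars(self).items()):
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        named: list[tuple[str, Tensor]] = []
        for name, value in sorted(vars(self).items()):
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                named.append((key, value))
            elif isinstance(value, Module):
                named.extend(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        named.extend(item.named_parameters(f"{key}.{i}."))
        return named

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """3x3 (by default) convolution with 'same' zero padding, He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)).astype(DTYPE),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True)
        self.padding = kernel // 2

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_dim)
        self.weight = Tensor(rng.normal(0.0, std, (in_dim, out_dim)).astype(DTYPE),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class DoubleConv(Module):
    """Two 3x3 conv + ReLU blocks, the standard U-Net building unit."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv1 = Conv2d(in_ch, out_ch, rng=rng)
        self.conv2 = Conv2d(out_ch, out_ch, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv2(self.conv1(x).relu()).relu()


class Down(Module):
    """2x2 max-pool followed by a DoubleConv."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.block = DoubleConv(in_ch, out_ch, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.block(max_pool2d(x))
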