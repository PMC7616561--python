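"""Layer modules over the autograd core: convolutions, activations, blocks."""

from __future__ import annotations

import math

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class; children registered via attribute assignment."""

    def __init__(self):
        self._modules: dict[str, Module] = {}
        self._params: dict[str, Tensor] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for name, m in self._modules.items():
            out.extend(m.named_parameters(prefix + name + "."))
        return out

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: p.data.copy() for n, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, p in self.named_parameters():
            p.data[...] = state[n]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)
    return Tensor(w, requires_grad=True)


class _ConvBase(Module):
    nd: int

    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=0, bias=True, *, rng):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        fan_in = in_ch * kernel**self.nd
        self.weight = _he_init(rng, (out_ch, in_ch) + (kernel,) * self.nd, fan_in)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv(x, self.weight, self.bias, self.stride, self.pad)

    def out_spatial(self, in_spatial: tuple[int, ...]) -> tuple[int, ...]:
        return tuple((s + 2 * self.pad - self.kernel) // self.stride + 1 for s in in_spatial)

    def mac_count(self, in_spatial: tuple[int, ...]) -> int:
        out = self.out_spatial(in_spatial)
        return int(np.prod(out)) * self.out_ch * self.in_ch * self.kernel**self.nd


class Conv2d(_ConvBase):
    nd = 2


class Conv3d(_ConvBase):
    nd = 3


class ConvTranspose3d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=0, output_padding=0, bias=True, *, rng):
        super().__init__()
        if output_padding >= stride:
            raise ValueError("output_padding must be smaller than stride")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.output_padding = output_padding
        fan_in = in_ch * kernel**3
        self.weight = _he_init(rng, (in_ch, out_ch) + (kernel,) * 3, fan_in)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_transpose(x, self.weight, self.bias, self.stride, self.pad, self.output_padding)

    def out_spatial(self, in_spatial: tuple[int, ...]) -> tuple[int, ...]:
        return tuple(
            (s - 1) * self.stride - 2 * self.pad + self.kernel + self.output_padding for s in in_spatial
        )

    def mac_count(self, in_spatial: tuple[int, ...]) -> int:
        # input-centric count: every input element meets every kernel tap
        return int(np.prod(in_spatial)) * self.in_ch * self.out_ch * self.kernel**3


class ReLU(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class Sigmoid(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x: Tensor) -> Tensor:
        return ag.sigmoid(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
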