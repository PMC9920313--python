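"""Network layers built on the autodiff engine.

Layers follow the usual Module pattern: parameters are ``Tensor``s with
``requires_grad=True``, discovered recursively through attributes, and a
module is called on an (N, C, D, H, W) tensor.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from . import functional as F

__all__ = [
    "Module",
    "Sequential",
    "Conv3d",
    "ConvTranspose3d",
    "InstanceNorm3d",
    "PReLU",
    "LeakyReLU",
    "Tanh",
]


class Module:
    def parameters(self) -> list[Tensor]:
        params = []
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

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = []
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                out.append((key, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(prefix=f"{key}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        if set(params) != set(state):
            missing = set(params) ^ set(state)
            raise ValueError(f"state dict keys do not match module parameters: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x


class Conv3d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1, padding=0,
                 bias=True, rng: np.random.Generator | None = None, init_std=0.02):
        rng = rng or np.random.default_rng()
        k = F._triple(kernel_size)
        self.stride = F._triple(stride)
        self.padding = F._triple(padding)
        self.weight = Tensor(rng.normal(0.0, init_std, size=(out_channels, in_channels, *k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose3d(Module):
    """Upsampling transposed convolution with kernel == stride."""

    def __init__(self, in_channels, out_channels, stride=2, bias=True,
                 rng: np.random.Generator | None = None, init_std=0.02):
        rng = rng or np.random.default_rng()
        k = F._triple(stride)
        self.stride = k
        self.weight = Tensor(rng.normal(0.0, init_std, size=(in_channels, out_channels, *k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose3d(x, self.weight, self.bias, stride=self.stride)


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalisation over the spatial axes.

    No running statistics are kept, so batch size 1 is fully well-defined —
    the property that makes instance norm the right choice for patch-based
    translation.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, affine: bool = True):
        self.eps = eps
        if affine:
            self.weight = Tensor(np.ones(num_features), requires_grad=True)
            self.bias_p = Tensor(np.zeros(num_features), requires_grad=True)
        else:
            self.weight = None
            self.bias_p = None

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(2, x.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=axes, keepdims=True)
        y = centered * (var + self.eps) ** -0.5
        if self.weight is not None:
            c = x.shape[1]
            shape = (1, c) + (1,) * (x.ndim - 2)
            y = y * self.weight.reshape(shape) + self.bias_p.reshape(shape)
        return y


class PReLU(Module):
    def __init__(self, num_channels: int, init: float = 0.25):
        self.alpha = Tensor(np.full(num_channels, init), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.prelu(x, self.alpha)


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.2):
        self.negative_slope = negative_slope

    def forward(self, x: Tensor) -> Tensor:
        return F.leaky_relu(x, self.negative_slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()
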