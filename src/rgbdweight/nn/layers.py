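"""Neural-network modules over the autodiff tensor.

Follows the familiar Module/Parameter pattern: modules own named parameters
and submodules, expose ``parameters()`` / ``state_dict()`` and a train/eval
flag (used by batch normalisation).  Weight init is Kaiming-uniform for
convolutions and linear layers.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = ["Parameter", "Module", "Conv2d", "DepthwiseSeparableConv2d",
           "Linear", "BatchNorm2d", "ReLU", "Sequential", "ModuleList"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # ------------------------------------------------------------- traversal
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        seen: set[int] = set()
        yield from self._named_parameters(prefix, seen)

    def _named_parameters(self, prefix, seen):
        for name, p in self._params.items():
            if id(p) not in seen:
                seen.add(id(p))
                yield prefix + name, p
        for name, m in self._modules.items():
            yield from m._named_parameters(f"{prefix}{name}.", seen)

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix.rstrip("."), self
        for name, m in self._modules.items():
            yield from m.named_modules(f"{prefix}{name}.")

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # ------------------------------------------------------------ state dict
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for mname, m in self.named_modules():
            for bname, buf in m._buffers.items():
                key = f"{mname}.{bname}" if mname else bname
                state[key] = np.asarray(getattr(m, bname)).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        consumed = set()
        for name, p in params.items():
            p.data = np.asarray(state[name], dtype=p.data.dtype).reshape(p.shape)
            consumed.add(name)
        for mname, m in self.named_modules():
            for bname in list(m._buffers):
                key = f"{mname}.{bname}" if mname else bname
                m.register_buffer(bname, np.asarray(state[key]))
                consumed.add(key)
        missing = set(state) - consumed
        if missing:
            raise KeyError(f"unexpected keys in state dict: {sorted(missing)[:5]}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError


def _kaiming_uniform(shape, fan_in, rng):
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


def _xavier_uniform(shape, fan_in, fan_out, rng):
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


_INIT_RNG = np.random.default_rng(0)


def seed_init(seed: int):
    """Reseed the parameter-initialisation stream (model init determinism)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 groups: int = 1, bias: bool = True):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.dilation, self.groups = dilation, groups
        k = kernel_size
        fan_in = (in_channels // groups) * k * k
        fan_out = (out_channels // groups) * k * k
        # Xavier: variance-preserving through the network's many conv chains
        # that have no interposed nonlinearity (FF / RFB blocks)
        self.weight = Parameter(_xavier_uniform(
            (out_channels, in_channels // groups, k, k), fan_in, fan_out, _INIT_RNG))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation,
                        groups=self.groups)


class DepthwiseSeparableConv2d(Module):
    """Per-channel 3x3 spatial convolution followed by 1x1 pointwise mixing."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, padding: int = 1, bias: bool = True):
        super().__init__()
        self.depthwise = Conv2d(in_channels, in_channels, kernel_size,
                                stride=stride, padding=padding,
                                groups=in_channels, bias=False)
        self.pointwise = Conv2d(in_channels, out_channels, 1, bias=bias)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.weight = Parameter(
            _kaiming_uniform((in_features, out_features), in_features, _INIT_RNG))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.register_buffer(
                "running_mean",
                (1 - m) * self.running_mean + m * mu.data.reshape(-1))
            self.register_buffer(
                "running_var",
                (1 - m) * self.running_var + m * var.data.reshape(-1))
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self._seq = list(modules)
        for i, m in enumerate(modules):
            setattr(self, f"m{i}", m)

    def forward(self, x: Tensor) -> Tensor:
        for m in self._seq:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._seq)

    def __getitem__(self, i):
        return self._seq[i]


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        setattr(self, f"m{len(self._list)}", m)
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]
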