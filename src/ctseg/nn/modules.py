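"""Lightweight module/parameter containers for the numpy networks."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module", "ModuleList", "Conv3d", "Conv1x1", "DownConv", "UpConv",
    "InstanceNorm3d", "ConvBlock", "he_fan_in_std",
]


def he_fan_in_std(fan_in: int) -> float:
    """Standard deviation of the He normal initializer, sqrt(2/fan_in)."""
    return float(np.sqrt(2.0 / fan_in))


class Module:
    """Base class: tracks child modules and parameter tensors by attribute."""

    def __init__(self):
        self.training = False

    # -- traversal --------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor):
                yield f"{prefix}{name}", value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- (de)serialisation -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._items: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._items)), m)
        self._items.append(m)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


def _param(shape, std, rng: np.random.Generator) -> Tensor:
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32),
                  requires_grad=True)


class Conv3d(Module):
    """Stride-1 'same' 3D convolution with He-normal initial weights."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3, *,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        fan_in = in_ch * ksize ** 3
        self.weight = _param((out_ch, in_ch, ksize, ksize, ksize),
                             he_fan_in_std(fan_in), rng)
        self.bias = Tensor(np.zeros(out_ch, np.float32), requires_grad=True) \
            if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.weight, self.bias)

    __call__ = forward


class Conv1x1(Module):
    def __init__(self, in_ch: int, out_ch: int, *, rng: np.random.Generator,
                 bias: bool = True, stride: tuple[int, int, int] = (1, 1, 1)):
        super().__init__()
        self.stride = stride
        self.weight = _param((out_ch, in_ch), he_fan_in_std(in_ch), rng)
        self.bias = Tensor(np.zeros(out_ch, np.float32), requires_grad=True) \
            if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv1x1(x, self.weight, self.bias, self.stride)

    __call__ = forward


class DownConv(Module):
    """Strided convolution (kernel = stride) replacing pooling in the
    fully convolutional variant."""

    def __init__(self, in_ch: int, out_ch: int,
                 factors: tuple[int, int, int], *, rng: np.random.Generator):
        super().__init__()
        self.factors = factors
        fan_in = in_ch * int(np.prod(factors))
        self.weight = _param((out_ch, in_ch, *factors),
                             he_fan_in_std(fan_in), rng)
        self.bias = Tensor(np.zeros(out_ch, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.down_conv(x, self.weight, self.bias, self.factors)

    __call__ = forward


class UpConv(Module):
    """Transposed convolution (kernel = stride) for decoder upsampling."""

    def __init__(self, in_ch: int, out_ch: int,
                 factors: tuple[int, int, int], *, rng: np.random.Generator):
        super().__init__()
        self.factors = factors
        self.weight = _param((in_ch, out_ch, *factors),
                             he_fan_in_std(in_ch), rng)
        self.bias = Tensor(np.zeros(out_ch, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.up_conv(x, self.weight, self.bias, self.factors)

    __call__ = forward


class InstanceNorm3d(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.instance_norm(x, self.gamma, self.beta, self.eps)

    __call__ = forward


class ConvBlock(Module):
    """Convolution -> dropout -> instance norm -> leaky rectifier."""

    def __init__(self, in_ch: int, out_ch: int, *, rng: np.random.Generator,
                 dropout_p: float = 0.1, leaky_slope: float = 0.01):
        super().__init__()
        self.conv = Conv3d(in_ch, out_ch, rng=rng)
        self.norm = InstanceNorm3d(out_ch)
        self.dropout_p = dropout_p
        self.leaky_slope = leaky_slope
        self._rng = np.random.default_rng(0)

    def set_dropout_rng(self, rng: np.random.Generator):
        self._rng = rng

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        y = F.dropout(y, self.dropout_p, self._rng, self.training)
        y = self.norm(y)
        return F.leaky_relu(y, self.leaky_slope)

    __call__ = forward
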