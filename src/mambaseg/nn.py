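"""Neural-network building blocks on top of the autodiff core.

Layout conventions: feature maps are NCHW; token sequences are (B, L, C).
Each `Module` owns `Parameter`s and exposes `parameters()` /
`named_parameters()` for the optimizer and checkpointing.
"""

from __future__ import annotations

import math

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self._modules: dict[str, "Module"] = {}
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield prefix + n, b
        for n, m in self._modules.items():
            yield from m.named_buffers(prefix + n + ".")

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- flat name→array checkpointing ------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        state.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        for n, p in params.items():
            if n not in state:
                raise KeyError(f"checkpoint missing parameter {n!r}")
            if state[n].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {n!r}: "
                                 f"{state[n].shape} vs {p.data.shape}")
            p.data[...] = state[n]
        for n, b in self.named_buffers():
            key = "buffer:" + n
            if key in state:
                b[...] = state[key]


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


# -- initialisers ----------------------------------------------------------

_init_rng = np.random.default_rng(0)


def set_init_seed(seed: int):
    """Reseed the stream used for weight initialisation (full determinism)."""
    global _init_rng
    _init_rng = np.random.default_rng(seed)


def trunc_normal(shape, std=0.02):
    w = _init_rng.normal(0.0, std, size=shape)
    return np.clip(w, -2 * std, 2 * std).astype(np.float32)


def kaiming_uniform(shape, fan_in):
    bound = math.sqrt(6.0 / fan_in)
    return _init_rng.uniform(-bound, bound, size=shape).astype(np.float32)


# -- layers ----------------------------------------------------------------

class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        self.weight = Parameter(trunc_normal((in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, stride: int = 1,
                 padding: int = 0, dilation: int = 1, groups: int = 1,
                 bias: bool = True):
        super().__init__()
        if in_ch % groups or out_ch % groups:
            raise ValueError("groups must divide channel counts")
        self.stride, self.padding, self.dilation, self.groups = \
            stride, padding, dilation, groups
        fan_in = (in_ch // groups) * kernel * kernel
        self.weight = Parameter(
            kaiming_uniform((out_ch, in_ch // groups, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, dilation=self.dilation,
                         groups=self.groups)


class ConvTranspose2d(Module):
    """Kernel-2 / stride-2 transposed convolution: exact 2× upsampling."""

    def __init__(self, in_ch: int, out_ch: int, *, stride: int = 2, bias: bool = True):
        super().__init__()
        self.stride = stride
        self.weight = Parameter(
            kaiming_uniform((in_ch, out_ch, stride, stride), in_ch))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class LayerNorm(Module):
    """Normalises the trailing feature axis (tokens are channel-last)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        return xn * self.weight + self.bias


class BatchNorm2d(Module):
    """Standard batch norm over (B, H, W) with running statistics."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            self.running_mean *= (1 - self.momentum)
            self.running_mean += self.momentum * mu.data.reshape(C)
            unbiased = var.data.reshape(C) * (n / max(n - 1, 1))
            self.running_var *= (1 - self.momentum)
            self.running_var += self.momentum * unbiased
            xn = xc / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.reshape(1, C, 1, 1)
            sd = np.sqrt(self.running_var.reshape(1, C, 1, 1) + self.eps)
            xn = (x - Tensor(mu)) / Tensor(sd)
        return xn * self.weight.reshape(1, C, 1, 1) + self.bias.reshape(1, C, 1, 1)

    def set_identity(self):
        """Pin BN to the identity transform (deterministic unit testing)."""
        self.weight.data[...] = 1.0
        self.bias.data[...] = 0.0
        self.running_mean[...] = 0.0
        self.running_var[...] = 1.0
        self.eval()
        return self


# -- optimiser -------------------------------------------------------------

class SGD:
    """SGD with classical momentum (v ← m·v + g; p ← p − lr·v)."""

    def __init__(self, params, lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
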