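"""Neural-network layers and the Adam optimizer on top of :mod:`cropseg.autodiff`.

Initialisation follows common practice for segmentation nets trained from
scratch: Kaiming fan-in normal for convolution and linear weights, unit gamma /
zero beta for batch norm, and a configurable shared initial slope for PReLU.
No pretraining is used anywhere.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    """Trainable tensor; stored in float32 for throughput."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Container with recursive parameter/buffer discovery and train/eval modes."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield path, v
            elif isinstance(v, Module):
                yield from v.named_parameters(path + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, np.ndarray):
                yield path, v
            elif isinstance(v, Module):
                yield from v.named_buffers(path + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{path}.{i}.")

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        state = {f"param:{k}": p.data.copy() for k, p in self.named_parameters()}
        state.update({f"buffer:{k}": b.copy() for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                params[name].data = np.asarray(value).copy()
            else:
                obj = self
                *path, attr = name.split(".")
                for part in path:
                    obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
                getattr(obj, attr)[...] = value

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, padding: int | None = None,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming(rng, (in_f, out_f), in_f))
        self.bias = Parameter(np.zeros(out_f))

    def forward(self, x):
        return ad.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        x = ad.as_tensor(x)
        gamma, beta = self.gamma, self.beta
        n, c, h, w = x.shape
        if self.training:
            m = n * h * w
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            unbiased = var * (m / max(m - 1, 1))
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
        training = self.training

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gi = gamma.data[None, :, None, None] * inv[None, :, None, None]
                if training:
                    m = n * h * w
                    gsum = g.sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
                    gxsum = (g * xhat).sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
                    x._accumulate(gi * (g - gsum / m - xhat * gxsum / m))
                else:
                    x._accumulate(gi * g)

        return ad._node(out, (x, gamma, beta), backward)


class PReLU(Module):
    def __init__(self, channels: int, init: float = 0.25):
        super().__init__()
        self.slope = Parameter(np.full(channels, init))

    def forward(self, x):
        return ad.prelu(x, self.slope)


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


def make_activation(kind: str, channels: int, prelu_init: float = 0.25) -> Module:
    if kind == "prelu":
        return PReLU(channels, prelu_init)
    if kind == "relu":
        return ReLU()
    raise ValueError(f"unknown activation {kind!r}")


class Adam:
    """Adam with the standard bias-corrected first/second moment estimates."""

    def __init__(self, params, lr: float = 3e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
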