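"""Small neural-network layer library on top of :mod:`stainshift.autodiff`.

Layers are plain Python objects holding ``Tensor`` parameters; every module
takes an explicit ``numpy.random.Generator`` at construction so that weight
initialisation is fully seeded.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, parameter


class Module:
    """Base class providing parameter traversal and state (de)serialisation."""

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield from v.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.named_modules(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield from v.named_modules(f"{prefix}{name}.{i}.")

    def layer_by_name(self, name: str) -> "Module":
        for n, m in self.named_modules():
            if n == name:
                return m
        raise KeyError(f"no submodule named {name!r}")

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {n: p.data.copy() for n, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict key mismatch: {sorted(missing)}")
        for n, p in own.items():
            a = np.asarray(state[n], dtype=p.data.dtype)
            if a.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {n}: {a.shape} vs {p.data.shape}")
            p.data = a.copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, bias: bool = True):
        fan_in = c_in * kernel * kernel
        std = float(np.sqrt(2.0 / fan_in))
        self.w = parameter(rng.normal(0.0, std, size=(c_out, c_in, kernel, kernel)))
        self.b = parameter(np.zeros(c_out)) if bias else None
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding

    def forward(self, x):
        return ad.conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class InstanceNorm2d(Module):
    """Per-sample, per-channel spatial normalisation with affine parameters."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = parameter(np.ones((1, channels, 1, 1)))
        self.beta = parameter(np.zeros((1, channels, 1, 1)))
        self.eps = eps

    def forward(self, x):
        m = ad.mean(x, axis=(2, 3), keepdims=True)
        xc = x - m
        v = ad.mean(xc * xc, axis=(2, 3), keepdims=True)
        return self.gamma * (xc * ad.power(v + self.eps, -0.5)) + self.beta


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        return ad.leaky_relu(x, self.slope)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adaptive-moment optimizer (standard GAN settings by default)."""

    def __init__(self, params, lr: float = 2e-4, betas=(0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        state = {"t": np.array(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            state[f"m{i}"] = m.copy()
            state[f"v{i}"] = v.copy()
        return state

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        for i in range(len(self.params)):
            self.m[i] = np.asarray(state[f"m{i}"]).copy()
            self.v[i] = np.asarray(state[f"v{i}"]).copy()
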