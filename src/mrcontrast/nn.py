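"""Layers, parameter containers and optimizers on top of :mod:`.autodiff`."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and state (de)serialization."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Parameter):
                        yield f"{full}.{i}", item
                    elif isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise ValueError(f"state mismatch for keys: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """3x3/1x1 convolution with He-normal initialization."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 padding: int | None = None, rng: np.random.Generator | None = None,
                 weight_scale: float = 1.0):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        std = weight_scale * np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch))
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, weight_scale: float = 1.0):
        rng = rng or np.random.default_rng(0)
        std = weight_scale * np.sqrt(1.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, std, size=(out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x):
        return ad.add(ad.matmul(x, ad.swapaxes(self.weight, 0, 1)), self.bias)


class Adam:
    """Adam optimizer; GAN-style defaults lr=1e-4, beta1=0, beta2=0.99."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 beta1: float = 0.0, beta2: float = 0.99, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.data.astype(p.data.dtype, copy=False)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def ema_update(current: dict[str, np.ndarray], shadow: dict[str, np.ndarray],
               decay: float) -> dict[str, np.ndarray]:
    """shadow <- decay * shadow + (1 - decay) * current, elementwise."""
    if not 0.0 <= decay < 1.0:
        raise ValueError("decay must lie in [0, 1)")
    if set(current) != set(shadow):
        raise ValueError("parameter sets do not match")
    return {k: decay * shadow[k] + (1.0 - decay) * current[k] for k in shadow}


class EMA:
    """Exponential moving average of a module's parameters.

    Translation and evaluation use the shadow weights; training updates the
    live weights and calls :meth:`update` once per generator step.
    """

    def __init__(self, module: Module, decay: float = 0.999):
        if not 0.0 <= decay < 1.0:
            raise ValueError("decay must lie in [0, 1)")
        self.decay = decay
        self.shadow = module.state_dict()

    def update(self, module: Module) -> None:
        self.shadow = ema_update(module.state_dict(), self.shadow, self.decay)

    def copy_to(self, module: Module) -> None:
        module.load_state_dict(self.shadow)


class swap_parameters:
    """Context manager that temporarily loads a state dict into a module."""

    def __init__(self, module: Module, state: dict[str, np.ndarray]):
        self.module = module
        self.state = state

    def __enter__(self):
        self._saved = self.module.state_dict()
        self.module.load_state_dict(self.state)
        return self.module

    def __exit__(self, *exc):
        self.module.load_state_dict(self._saved)
        return False
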