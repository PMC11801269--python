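"""Modules, parameter containers and the Adam optimizer.

A deliberately small imitation of the familiar module pattern: modules
register parameters and child modules via ``__setattr__``, expose
``parameters()`` / ``state_dict()`` and a train/eval flag. All parameter
initialization draws from an explicit ``numpy.random.Generator`` so that a
single seed makes an entire model build (and hence training) reproducible.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Linear", "Conv2d", "MLP", "Adam", "glorot", "he"]


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


def he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Module:
    def __init__(self) -> None:
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value) -> None:
        self._params.pop(name, None)
        self._modules.pop(name, None)
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        elif isinstance(value, dict) and value and all(isinstance(v, Module) for v in value.values()):
            for k, v in value.items():
                self._modules[f"{name}.{k}"] = v
        object.__setattr__(self, name, value)

    # ---------------------------------------------------------------- params
    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> "Module":
        object.__setattr__(self, "training", True)
        for m in self._modules.values():
            m.train()
        return self

    def eval(self) -> "Module":
        object.__setattr__(self, "training", False)
        for m in self._modules.values():
            m.eval()
        return self

    # ----------------------------------------------------------- persistence
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((d_in, d_out))
        else:
            w = glorot(rng, (d_in, d_out), d_in, d_out)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        from .autodiff import conv2d

        self._op = conv2d
        self.stride = stride
        self.weight = Tensor(he(rng, (c_out, c_in, k, k), c_in * k * k), requires_grad=True)
        # bias=False keeps a frozen zero bias out of the parameter list
        self.bias = Tensor(np.zeros(c_out), requires_grad=bias)

    def __call__(self, x: Tensor) -> Tensor:
        return self._op(x, self.weight, self.bias, stride=self.stride)


class MLP(Module):
    """Plain feedforward stack with ReLU between layers."""

    def __init__(self, dims: list[int], rng: np.random.Generator, final_relu: bool = False):
        super().__init__()
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.final_relu = final_relu

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1 or self.final_relu:
                x = x.relu()
        return x


class Adam:
    """Adam with decoupled weight decay (AdamW-style when weight_decay > 0)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
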