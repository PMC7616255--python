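"""Layers and parameter management on top of the autodiff engine.

Mirrors the familiar Module/Parameter idiom at the smallest scale the
networks here need: named parameters, state dicts, Kaiming initialisation,
instance normalisation and an Adam optimiser.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import (
    Tensor,
    add,
    broadcast_to,
    conv3d,
    div,
    matmul,
    mul,
    reshape,
    scalar,
    sqrt,
    sub,
    tmean,
)

__all__ = [
    "Module",
    "Linear",
    "Conv3d",
    "instance_norm",
    "Adam",
]


class Module:
    """Base class: anything with named ``Tensor`` parameters."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(
                f"state dict mismatch; missing={sorted(missing)} unexpected={sorted(extra)}"
            )
        for name, p in params.items():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: checkpoint {arr.shape} vs model {p.data.shape}"
                )
            p.data = arr.astype(p.data.dtype, copy=True)


def _kaiming(rng: np.random.Generator, shape: tuple, fan_in: int, slope: float) -> np.ndarray:
    gain = math.sqrt(2.0 / (1.0 + slope**2))
    std = gain / math.sqrt(fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator,
        zero_init: bool = False,
        slope: float = 0.2,
    ):
        if zero_init:
            w = np.zeros((in_features, out_features), dtype=np.float32)
        else:
            w = _kaiming(rng, (in_features, out_features), in_features, slope)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.weight), self.bias)


class Conv3d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        kernel: int = 3,
        stride: int = 1,
        pad: int = 1,
        zero_init: bool = False,
        slope: float = 0.2,
    ):
        self.stride = stride
        self.pad = pad
        shape = (out_channels, in_channels, kernel, kernel, kernel)
        fan_in = in_channels * kernel**3
        if zero_init:
            w = np.zeros(shape, dtype=np.float32)
        else:
            w = _kaiming(rng, shape, fan_in, slope)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        out = conv3d(x, self.weight, stride=self.stride, pad=self.pad)
        b = reshape(self.bias, (-1, 1, 1, 1, 1))
        return add(out, broadcast_to(b, out.shape))


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel standardisation of a CNDHW tensor."""
    if x.ndim != 5:
        raise ValueError(f"instance_norm expects CNDHW input, got shape {x.shape}")
    axes = (2, 3, 4)
    mean = tmean(x, axis=axes, keepdims=True)
    centred = sub(x, broadcast_to(mean, x.shape))
    var = tmean(mul(centred, centred), axis=axes, keepdims=True)
    denom = sqrt(add(var, scalar(eps)))
    return div(centred, broadcast_to(denom, x.shape))


class Adam:
    """Adam with the (0.5, 0.9) moment decays customary for WGAN-GP training."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.5, 0.9), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads: list[Tensor]) -> None:
        if len(grads) != len(self.params):
            raise ValueError("gradient list does not match parameter list")
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data.astype(p.data.dtype, copy=False)
            m *= self.b1
            m += (1.0 - self.b1) * gd
            v *= self.b2
            v += (1.0 - self.b2) * gd * gd
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m).copy() for m in state["m"]]
        self.v = [np.asarray(v).copy() for v in state["v"]]
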