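"""Layer primitives (Linear, convolutions, LayerNorm) on the autodiff engine.

Parameters are ``Tensor`` objects with ``requires_grad=True``.  Modules form
a tree; ``Module.parameters()`` walks it in a deterministic order so that
optimizer state and checkpoints line up run to run.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02):
    """Normal(0, std) truncated to +/- 2 std, the Swin init convention."""
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std).astype(np.float32)


def he_normal(rng: np.random.Generator, shape, fan_in: int):
    return (rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
            .astype(np.float32))


class Module:
    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []

        def visit(key: str, v):
            if isinstance(v, Tensor):
                if v.requires_grad:
                    out.append((key, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    visit(f"{key}.{i}", item)

        for name in sorted(vars(self)):
            visit(f"{prefix}{name}", vars(self)[name])
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state mismatch on keys: {sorted(missing)[:5]}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = state[k].astype(np.float32).copy()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        self.weight = Tensor(trunc_normal(rng, (in_features, out_features)),
                             requires_grad=True)
        self.bias = (Tensor(np.zeros(out_features, np.float32),
                            requires_grad=True) if bias else None)

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        self.stride = stride
        self.padding = padding
        fan_in = cin * kernel * kernel
        self.weight = Tensor(he_normal(rng, (cout, cin, kernel, kernel),
                                       fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class DepthwiseConv3x3(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        self.weight = Tensor(he_normal(rng, (channels, 3, 3), 9),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(channels, np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.depthwise_conv3x3(x, self.weight, self.bias)


class ConvTranspose2x2(Module):
    """Stride-2 learned upsampler (kernel 2, no output overlap)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.weight = Tensor(he_normal(rng, (cin, cout, 2, 2), cin * 4),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2x2(x, self.weight, self.bias)


class LayerNorm(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.weight = Tensor(np.ones(channels, np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(channels, np.float32),
                           requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.weight, self.bias, eps=self.eps)
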