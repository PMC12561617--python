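"""Layer modules on top of the autodiff core.

Modules register :class:`Parameter` attributes (and sub-modules, including
lists of sub-modules) automatically, and expose ``state_dict`` /
``load_state_dict`` for weight snapshots (early-stopping restore, LoRA
immutability checks).
"""

from __future__ import annotations

import numpy as np

from .tensor import Parameter, Tensor, conv2d, depthwise_conv2d

__all__ = ["Module", "Conv2d", "DepthwiseConv2d", "Dense", "Sequential"]


class Module:
    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    # -- parameter traversal -------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_modules(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_modules(f"{full}.{i}.")

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name!r}: "
                                 f"{p.data.shape} vs {state[name].shape}")
        for name, p in own.items():
            p.data = state[name].copy()


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """Stride-1 convolution with shape-preserving (asymmetric for even K)
    zero padding by default."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 bias: bool = True, padding: str | tuple = "same",
                 rng: np.random.Generator | None = None):
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = (kh, kw)
        self.padding = padding
        self.weight = Parameter(he_normal(rng, (out_channels, in_channels, kh, kw),
                                          in_channels * kh * kw))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class DepthwiseConv2d(Module):
    """Per-channel stride-1 convolution (one KhxKw filter per channel)."""

    def __init__(self, channels: int, kernel_size, bias: bool = True,
                 padding: str | tuple = "same", rng: np.random.Generator | None = None):
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.kernel_size = (kh, kw)
        self.padding = padding
        self.weight = Parameter(he_normal(rng, (channels, kh, kw), kh * kw))
        self.bias = Parameter(np.zeros(channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.weight, self.bias, padding=self.padding)


class Dense(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(he_normal(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
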