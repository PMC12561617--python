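"""Spatial and channel attention for shallow MRI classifiers.

Two parameter-light attention mechanisms:

* **l2-SAB** (l2-normalized spatial attention block).  For a feature map
  ``F`` of shape (C, H, W), channel-wise max- and min-pooled maps are
  l2-normalized, subtracted, convolved with a single KxK filter, and passed
  through a sigmoid to give a spatial gate ``Ms`` in (0,1)^(1,H,W)::

      Ms(F) = sigmoid(conv_KxK(l2(maxpool_C(F)) - l2(minpool_C(F))))
      F'    = Ms(F) * F          (broadcast over channels)

* **GCT** (Gaussian context transformer), a parameter-free channel gate.
  Each channel's global-average context is standardized across channels and
  mapped through a Gaussian excitation ``a_c = exp(-zhat_c^2 / (2 c^2))``;
  the spread ``c`` controls how strongly off-mean channels are attenuated.
  Gates lie in (0, 1], so GCT never flips signs nor amplifies activations.

The module provides plain-numpy functions operating on single (C, H, W)
arrays — the reference semantics used by the tests — and autodiff
:class:`~ansa_edge.nn.Module` wrappers used inside networks.  Both share the
same padding rule: shape-preserving zero padding, asymmetric for even kernel
sizes (pad (K-1)//2 before, K-1-(K-1)//2 after).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Module, Parameter, Tensor, conv2d, same_padding

__all__ = [
    "L2SABParams", "GCTParams",
    "channel_pool", "l2_normalize_map", "spatial_attention", "l2_sab_apply",
    "gct_apply", "L2SAB", "GCT",
]

EPS = 1e-6


@dataclass
class L2SABParams:
    """Weights of one spatial attention sub-unit: a single-channel KxK
    convolution (bias zero-initialized)."""
    kernel_size: int
    conv_weights: np.ndarray  # (1, 1, K, K)
    conv_bias: float = 0.0

    def __post_init__(self):
        k = self.kernel_size
        if k < 1:
            raise ValueError("kernel_size must be >= 1")
        self.conv_weights = np.asarray(self.conv_weights, dtype=float).reshape(1, 1, k, k)
        if not np.all(np.isfinite(self.conv_weights)):
            raise ValueError("conv weights must be finite")

    @classmethod
    def init(cls, kernel_size: int, rng: np.random.Generator) -> "L2SABParams":
        w = rng.normal(0.0, np.sqrt(2.0 / (kernel_size ** 2)),
                       size=(1, 1, kernel_size, kernel_size))
        return cls(kernel_size=kernel_size, conv_weights=w, conv_bias=0.0)


@dataclass
class GCTParams:
    """Gaussian spread ``c`` and the variance guard epsilon."""
    c: float
    epsilon: float = EPS

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("Gaussian spread c must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _check_chw(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.ndim != 3 or f.shape[0] < 1 or f.shape[1] < 1 or f.shape[2] < 1:
        raise ValueError(f"expected a C x H x W feature map, got shape {f.shape}")
    if not np.all(np.isfinite(f)):
        raise ValueError("feature map contains non-finite entries")
    return f


# ---------------------------------------------------------------------------
# functional reference implementations (single C x H x W arrays)
# ---------------------------------------------------------------------------

def channel_pool(f: np.ndarray, mode: str) -> np.ndarray:
    """Max or min over the channel axis; returns a (1, H, W) map."""
    f = _check_chw(f)
    if mode == "max":
        return f.max(axis=0, keepdims=True)
    if mode == "min":
        return f.min(axis=0, keepdims=True)
    raise ValueError(f"mode must be 'max' or 'min', got {mode!r}")


def l2_normalize_map(m: np.ndarray, epsilon: float = EPS) -> np.ndarray:
    """Scale a (1, H, W) map to unit Euclidean norm (epsilon guards zero)."""
    m = np.asarray(m, dtype=float)
    norm = np.sqrt((m * m).sum())
    return m / max(norm, epsilon)


def spatial_attention(f: np.ndarray, p: L2SABParams) -> np.ndarray:
    """The sigmoid spatial gate Ms(F), shape (1, H, W), entries in (0, 1)."""
    f = _check_chw(f)
    diff = l2_normalize_map(channel_pool(f, "max")) - l2_normalize_map(channel_pool(f, "min"))
    x = Tensor(diff[None])  # (1, 1, H, W)
    conv = conv2d(x, Tensor(p.conv_weights), Tensor(np.array([p.conv_bias])), padding="same")
    return 1.0 / (1.0 + np.exp(-conv.data[0]))


def l2_sab_apply(f: np.ndarray, p: L2SABParams) -> np.ndarray:
    """F' = Ms(F) * F, the gate applied to each channel separately."""
    f = _check_chw(f)
    return spatial_attention(f, p) * f


def gct_apply(f: np.ndarray, g: GCTParams) -> np.ndarray:
    """Gaussian context channel gating of a (C, H, W) map."""
    f = _check_chw(f)
    z = f.mean(axis=(1, 2))                        # per-channel global context
    zhat = (z - z.mean()) / (z.std() + g.epsilon)  # standardize across channels
    gates = np.exp(-zhat ** 2 / (2.0 * g.c ** 2))
    return gates[:, None, None] * f


# ---------------------------------------------------------------------------
# autodiff modules (batched NCHW tensors)
# ---------------------------------------------------------------------------

class L2SAB(Module):
    """l2-normalized spatial attention block as a trainable module.

    Adds exactly K^2 + 1 parameters (one single-channel KxK filter plus its
    bias, zero-initialized so that Ms is 0.5 everywhere when max- and
    min-pooled maps coincide).
    """

    def __init__(self, kernel_size: int, rng: np.random.Generator | None = None):
        if kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.kernel_size = kernel_size
        p = L2SABParams.init(kernel_size, rng)
        self.weight = Parameter(p.conv_weights)
        self.bias = Parameter(np.zeros(1))

    def attention_map(self, x: Tensor) -> Tensor:
        fmax = x.max(axis=1, keepdims=True)
        fmin = x.min(axis=1, keepdims=True)
        nmax = ((fmax * fmax).sum(axis=(1, 2, 3), keepdims=True)).sqrt().clip_min(EPS)
        nmin = ((fmin * fmin).sum(axis=(1, 2, 3), keepdims=True)).sqrt().clip_min(EPS)
        diff = fmax / nmax - fmin / nmin
        return conv2d(diff, self.weight, self.bias, padding="same").sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return self.attention_map(x) * x


class GCT(Module):
    """Parameter-free Gaussian context transformer channel gate."""

    def __init__(self, c: float, epsilon: float = EPS):
        if c <= 0:
            raise ValueError("Gaussian spread c must be positive")
        self.c = float(c)
        self.epsilon = float(epsilon)

    def forward(self, x: Tensor) -> Tensor:
        z = x.mean(axis=(2, 3), keepdims=True)                 # (N, C, 1, 1)
        mu = z.mean(axis=1, keepdims=True)
        var = ((z - mu) ** 2).mean(axis=1, keepdims=True)
        zhat = (z - mu) / (var.sqrt() + self.epsilon)
        gates = (-(zhat ** 2) * (1.0 / (2.0 * self.c ** 2))).exp()
        return gates * x
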