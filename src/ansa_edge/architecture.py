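"""Declarative construction of the shallow attention-guided classifier.

The network is a four-stage convolutional backbone (increasing filter
counts, decreasing kernel sizes, 2x2 max pooling after each stage) with an
optional attention block after each stage and a small dense head.  Each
attention block stacks three sub-units; a sub-unit is a Gaussian context
channel gate (GCT) followed by an l2-normalized spatial attention block
(l2-SAB).  The fully configured model — four blocks, kernel triplets
(8,6,4)/(8,6,4)/(6,4,2)/(1,1,1), spreads (4,2,1) — is the ANSA_Ensemble
configuration; with ``use_gct=False`` it degrades to spatial attention only,
and with zero blocks to the plain backbone used as the ablation baseline.

Specs are plain dataclasses serializable to YAML/JSON, so model variants
(compression rewrites, ablation grids) are spec-to-spec transforms wherever
possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml

from .attention import GCT, L2SAB
from .nn import Conv2d, Dense, Module, Tensor, maxpool2d

__all__ = [
    "BackboneConfig", "AttentionBlockConfig", "ModelSpec",
    "ansa_ensemble_spec", "shallow_alexnet_spec", "build_model",
    "count_parameters", "ablation_variants", "Network",
]

ENSEMBLE_BLOCK_KERNELS = ((8, 6, 4), (8, 6, 4), (6, 4, 2), (1, 1, 1))
ENSEMBLE_GCT_SPREADS = (4.0, 2.0, 1.0)

DEFAULT_FILTERS = (64, 128, 256, 512)
REDUCED_FILTERS = (8, 16, 32, 64)


@dataclass(frozen=True)
class BackboneConfig:
    filters: tuple = DEFAULT_FILTERS
    kernel_sizes: tuple = (7, 5, 3, 3)
    input_size: int = 256
    in_channels: int = 1

    def __post_init__(self):
        if len(self.filters) != 4 or len(self.kernel_sizes) != 4:
            raise ValueError("backbone needs exactly four conv stages")
        if any(f < 1 for f in self.filters) or any(k < 1 for k in self.kernel_sizes):
            raise ValueError("filters and kernel sizes must be positive")
        if any(a < b for a, b in zip(self.kernel_sizes, self.kernel_sizes[1:])):
            raise ValueError("kernel sizes must be non-increasing with depth")


@dataclass(frozen=True)
class AttentionBlockConfig:
    sab_kernels: tuple = (8, 6, 4)
    gct_cs: tuple = ENSEMBLE_GCT_SPREADS

    def __post_init__(self):
        if len(self.sab_kernels) != 3 or len(self.gct_cs) != 3:
            raise ValueError("an attention block has exactly three sub-units")


@dataclass(frozen=True)
class ModelSpec:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    attention_blocks: tuple = ()
    use_gct: bool = True
    head_hidden: int = 128
    num_classes: int = 3

    def __post_init__(self):
        if len(self.attention_blocks) > 4:
            raise ValueError("at most one attention block per conv stage (4)")

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            backbone=BackboneConfig(
                filters=tuple(d["backbone"]["filters"]),
                kernel_sizes=tuple(d["backbone"]["kernel_sizes"]),
                input_size=d["backbone"]["input_size"],
                in_channels=d["backbone"]["in_channels"],
            ),
            attention_blocks=tuple(
                AttentionBlockConfig(sab_kernels=tuple(b["sab_kernels"]),
                                     gct_cs=tuple(b["gct_cs"]))
                for b in d["attention_blocks"]),
            use_gct=d["use_gct"],
            head_hidden=d["head_hidden"],
            num_classes=d["num_classes"],
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(text))


def ansa_ensemble_spec(num_classes: int, input_size: int = 256,
                        filters: tuple = DEFAULT_FILTERS) -> ModelSpec:
    """The fully configured four-block model with the published kernel/spread
    schedule: kernels (8,6,4), (8,6,4), (6,4,2), (1,1,1); c = (4,2,1) in
    every block."""
    if num_classes not in (3, 4):
        raise ValueError(f"num_classes must be 3 or 4, got {num_classes}")
    blocks = tuple(AttentionBlockConfig(sab_kernels=k, gct_cs=ENSEMBLE_GCT_SPREADS)
                   for k in ENSEMBLE_BLOCK_KERNELS)
    return ModelSpec(backbone=BackboneConfig(filters=filters, input_size=input_size),
                     attention_blocks=blocks, use_gct=True, num_classes=num_classes)


def shallow_alexnet_spec(num_classes: int, input_size: int = 256) -> ModelSpec:
    """Attention-free shallow baseline preset (plain backbone)."""
    if num_classes not in (3, 4):
        raise ValueError(f"num_classes must be 3 or 4, got {num_classes}")
    return ModelSpec(backbone=BackboneConfig(input_size=input_size),
                     attention_blocks=(), num_classes=num_classes)


class AttentionBlock(Module):
    """Three (GCT then l2-SAB) sub-units applied in order."""

    def __init__(self, cfg: AttentionBlockConfig, use_gct: bool,
                 rng: np.random.Generator):
        self.units = []
        for k, c in zip(cfg.sab_kernels, cfg.gct_cs):
            unit = []
            if use_gct:
                unit.append(GCT(c))
            unit.append(L2SAB(k, rng=rng))
            self.units.append(unit)
        # flatten for parameter traversal
        self.modules_flat = [m for unit in self.units for m in unit]

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules_flat:
            x = m(x)
        return x


class Stage(Module):
    """One conv -> relu -> pool -> attention unit.  ``gain`` is a fixed
    (non-trainable) output scale, 1.0 unless initialization calibration sets
    it; it compensates the systematic attenuation of the stacked attention
    gates without inflating the conv weights themselves."""

    def __init__(self, conv: Conv2d, attention: AttentionBlock | None):
        self.conv = conv
        self.attention = attention
        self.gain = 1.0

    def forward(self, x: Tensor) -> Tensor:
        x = maxpool2d(self.conv(x).relu())
        if self.attention is not None:
            x = self.attention(x)
        if self.gain != 1.0:
            x = x * self.gain
        return x


class Network(Module):
    """The built classifier.  ``forward`` returns raw class scores; with
    ``record=True`` the post-attention output of every stage is kept in
    ``self.stage_outputs`` (autodiff tensors, so their gradients are
    available after a backward pass — used by Grad-CAM)."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        bb = spec.backbone
        if bb.input_size % 16 != 0:
            raise ValueError(
                f"input_size must be divisible by 16 (four 2x pools), got {bb.input_size}")
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.stages = []
        cin = bb.in_channels
        for i in range(4):
            conv = Conv2d(cin, bb.filters[i], bb.kernel_sizes[i], rng=rng)
            att = None
            if i < len(spec.attention_blocks):
                att = AttentionBlock(spec.attention_blocks[i], spec.use_gct, rng)
            self.stages.append(Stage(conv, att))
            cin = bb.filters[i]
        feat_hw = bb.input_size // 16
        self.flat_features = bb.filters[3] * feat_hw * feat_hw
        self.fc1 = Dense(self.flat_features, spec.head_hidden, rng=rng)
        self.fc2 = Dense(spec.head_hidden, spec.num_classes, rng=rng)
        self.stage_outputs: list[Tensor] = []

    def forward(self, x: Tensor, record: bool = False) -> Tensor:
        if record:
            self.stage_outputs = []
        for stage in self.stages:
            x = stage(x)
            if record:
                self.stage_outputs.append(x)
        n = x.data.shape[0]
        h = self.fc1(x.reshape(n, self.flat_features)).relu()
        return self.fc2(h)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class labels for a (N, C, H, W) batch."""
        return self.forward(Tensor(x)).data.argmax(axis=1)

    def stage_names(self) -> list[str]:
        return [f"stage{i + 1}" for i in range(len(self.stages))]


def build_model(spec: ModelSpec, seed: int = 0) -> Network:
    return Network(spec, seed=seed)


def count_parameters(net: Module, trainable_only: bool = False) -> int:
    return sum(p.data.size for p in net.parameters()
               if (p.requires_grad or not trainable_only))


def ablation_variants(spec: ModelSpec) -> list[ModelSpec]:
    """The 5 x 2 ablation grid: keep the first n of the four attention blocks
    (n = 0..4), crossed with GCT on/off."""
    if len(spec.attention_blocks) != 4:
        raise ValueError("ablation grid requires the full four-block spec")
    variants = []
    for use_gct in (False, True):
        for n in range(5):
            variants.append(replace(spec, attention_blocks=spec.attention_blocks[:n],
                                    use_gct=use_gct))
    return variants
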