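"""Model-compression transforms: five model-to-model rewrites.

* depthwise-separable convolutions (DSC): split each backbone KxK conv into a
  per-channel KxK conv plus a 1x1 cross-channel conv,
* reduced feature maps (RFM): shrink the filter schedule 64-128-256-512 to
  8-16-32-64 (a spec-to-spec transform),
* low-rank adaptation (LoRA): freeze base weights, train additive low-rank
  factors,
* canonical polyadic tensor decomposition (CPTD): factorize the first conv
  kernel into R rank-1 terms and replace the layer with a pointwise ->
  vertical depthwise -> horizontal depthwise -> pointwise sequence,
* global magnitude pruning with mask-preserving fine-tuning.

Each transform returns a rewritten network plus a :class:`CompressionReport`
with parameter accounting and a functional probe diagnostic.  Transforms
never mutate their input network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .architecture import (DEFAULT_FILTERS, REDUCED_FILTERS, ModelSpec, Network,
                           build_model, count_parameters)
from .nn import (Conv2d, Dense, DepthwiseConv2d, Module, Parameter, Tensor,
                 Adam, conv2d, softmax_cross_entropy)

__all__ = [
    "CompressionReport", "PruneMask", "CPFactors",
    "to_depthwise_separable", "dsc_rewrite_conv", "to_reduced_feature_maps",
    "attach_lora", "cp_als", "cp_error_curve", "cp_decompose_first_conv",
    "magnitude_prune", "finetune_pruned",
]


@dataclass
class CompressionReport:
    method: str
    params_before: int
    params_after: int
    trainable_after: int
    max_output_deviation: float
    settings: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "params_before": self.params_before,
            "params_after": self.params_after,
            "trainable_after": self.trainable_after,
            "max_output_deviation": self.max_output_deviation,
            "settings": self.settings,
            "diagnostics": self.diagnostics,
        }


def _clone(net: Network) -> Network:
    out = build_model(net.spec, seed=0)
    out.load_state_dict(net.state_dict())
    for src, dst in zip(net.stages, out.stages):
        dst.gain = src.gain
    return out


def _probe_batch(net: Network, rng: np.random.Generator) -> np.ndarray:
    bb = net.spec.backbone
    return rng.standard_normal((2, bb.in_channels, bb.input_size, bb.input_size))


def _max_logit_deviation(a: Network | Module, b: Network | Module, x: np.ndarray) -> float:
    ya = a.forward(Tensor(x)).data
    yb = b.forward(Tensor(x)).data
    return float(np.abs(ya - yb).max())


# ---------------------------------------------------------------------------
# depthwise-separable convolutions
# ---------------------------------------------------------------------------

class DSCBlock(Module):
    """Depthwise KxK conv followed by a pointwise 1x1 conv; drop-in
    replacement (same spatial contract) for a dense KxK conv."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.depthwise = DepthwiseConv2d(in_channels, kernel_size, bias=bias, rng=rng)
        self.pointwise = Conv2d(in_channels, out_channels, 1, bias=bias, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))

    def weight_param_count(self) -> int:
        return self.depthwise.weight.data.size + self.pointwise.weight.data.size


def dsc_rewrite_conv(conv: Conv2d, rng: np.random.Generator | None = None) -> DSCBlock:
    """Rewrite one dense conv as a freshly initialized depthwise-separable
    pair (weights are re-trained after the rewrite)."""
    return DSCBlock(conv.in_channels, conv.out_channels, conv.kernel_size[0],
                    bias=conv.bias is not None, rng=rng)


def to_depthwise_separable(net: Network, seed: int = 0) -> tuple[Network, CompressionReport]:
    """Rewrite every backbone conv with K > 1; 1x1 convs and the
    single-channel attention convs are left untouched."""
    out = _clone(net)
    rng = np.random.default_rng(seed)
    params_before = count_parameters(net)
    rewritten = []
    for i, stage in enumerate(out.stages):
        if stage.conv.kernel_size[0] > 1:
            rewritten.append(f"stage{i + 1}")
            stage.conv = dsc_rewrite_conv(stage.conv, rng=rng)
    report = CompressionReport(
        method="DSC",
        params_before=params_before,
        params_after=count_parameters(out),
        trainable_after=count_parameters(out, trainable_only=True),
        max_output_deviation=_max_logit_deviation(net, out, _probe_batch(net, rng)),
        settings={"rewritten_stages": rewritten},
    )
    return out, report


# ---------------------------------------------------------------------------
# reduced feature maps
# ---------------------------------------------------------------------------

def to_reduced_feature_maps(spec: ModelSpec) -> ModelSpec:
    """Shrink the filter schedule 64-128-256-512 to 8-16-32-64."""
    if tuple(spec.backbone.filters) != DEFAULT_FILTERS:
        raise ValueError("reduced-feature-map transform expects the default filter schedule")
    from dataclasses import replace
    return replace(spec, backbone=replace(spec.backbone, filters=REDUCED_FILTERS))


# ---------------------------------------------------------------------------
# low-rank adaptation
# ---------------------------------------------------------------------------

class LoRAConv2d(Module):
    """Frozen base conv plus trainable additive low-rank factors on the
    (Cout, Cin*Kh*Kw) unfolded weight.  B is zero-initialized, so the adapted
    forward equals the base forward at attachment."""

    def __init__(self, base: Conv2d, rank: int, rng: np.random.Generator):
        base.weight.requires_grad = False
        if base.bias is not None:
            base.bias.requires_grad = False
        self.base = base
        cout, cin, kh, kw = base.weight.data.shape
        d_out, d_in = cout, cin * kh * kw
        self.rank = _clamp_rank(rank, d_in, d_out)
        self.A = Parameter(rng.normal(0.0, 1.0 / np.sqrt(d_in), (d_out, self.rank)))
        self.B = Parameter(np.zeros((self.rank, d_in)))

    def forward(self, x: Tensor) -> Tensor:
        cout, cin, kh, kw = self.base.weight.data.shape
        delta = (self.A @ self.B).reshape(cout, cin, kh, kw)
        return conv2d(x, self.base.weight + delta, self.base.bias,
                      padding=self.base.padding)


class LoRADense(Module):
    def __init__(self, base: Dense, rank: int, rng: np.random.Generator):
        base.weight.requires_grad = False
        if base.bias is not None:
            base.bias.requires_grad = False
        self.base = base
        d_in, d_out = base.weight.data.shape
        self.rank = _clamp_rank(rank, d_in, d_out)
        self.A = Parameter(rng.normal(0.0, 1.0 / np.sqrt(d_in), (d_out, self.rank)))
        self.B = Parameter(np.zeros((self.rank, d_in)))

    def forward(self, x: Tensor) -> Tensor:
        delta = (self.A @ self.B).transpose2d()  # (d_in, d_out)
        out = x @ (self.base.weight + delta)
        if self.base.bias is not None:
            out = out + self.base.bias
        return out


def _clamp_rank(rank: int, d_in: int, d_out: int) -> int:
    if rank < 1:
        raise ValueError("LoRA rank must be >= 1")
    cap = min(d_in, d_out)
    if rank > cap:
        warnings.warn(f"LoRA rank {rank} exceeds min(d_in, d_out) = {cap}; clamping")
        return cap
    return rank


def attach_lora(net: Network, rank: int = 8, seed: int = 0) -> tuple[Network, CompressionReport]:
    """Attach low-rank adapters to the four backbone convs and both dense
    head layers; base weights are frozen."""
    out = _clone(net)
    rng = np.random.default_rng(seed)
    params_before = count_parameters(net)
    for stage in out.stages:
        stage.conv = LoRAConv2d(stage.conv, rank, rng)
    out.fc1 = LoRADense(out.fc1, rank, rng)
    out.fc2 = LoRADense(out.fc2, rank, rng)
    # attention-block parameters remain trainable alongside the adapters
    report = CompressionReport(
        method="PEFT_LORA",
        params_before=params_before,
        params_after=count_parameters(out),
        trainable_after=count_parameters(out, trainable_only=True),
        max_output_deviation=_max_logit_deviation(net, out, _probe_batch(net, rng)),
        settings={"rank": rank},
    )
    return out, report


# ---------------------------------------------------------------------------
# canonical polyadic decomposition
# ---------------------------------------------------------------------------

@dataclass
class CPFactors:
    """Rank-R factors of a 4-way conv kernel (Cout, Cin, Kh, Kw)."""
    rank: int
    out_factor: np.ndarray   # (Cout, R)
    in_factor: np.ndarray    # (Cin, R)
    h_factor: np.ndarray     # (Kh, R)
    w_factor: np.ndarray     # (Kw, R)
    converged: bool = True

    def reconstruct(self) -> np.ndarray:
        return np.einsum("or,cr,hr,wr->ochw", self.out_factor, self.in_factor,
                         self.h_factor, self.w_factor, optimize=True)

    def relative_error(self, x: np.ndarray) -> float:
        return float(np.linalg.norm(x - self.reconstruct()) / np.linalg.norm(x))


def _khatri_rao(mats: list[np.ndarray]) -> np.ndarray:
    out = mats[0]
    for m in mats[1:]:
        out = (out[:, None, :] * m[None, :, :]).reshape(-1, out.shape[-1])
    return out


def _svd_init(x: np.ndarray, rank: int, rng: np.random.Generator) -> list[np.ndarray]:
    factors = []
    for n in range(x.ndim):
        unfold = np.moveaxis(x, n, 0).reshape(x.shape[n], -1)
        u, _, _ = np.linalg.svd(unfold, full_matrices=False)
        f = u[:, :rank]
        if f.shape[1] < rank:  # pad with random columns when mode dim < rank
            extra = rng.standard_normal((x.shape[n], rank - f.shape[1]))
            f = np.concatenate([f, extra / np.linalg.norm(extra, axis=0)], axis=1)
        factors.append(f)
    return factors


def cp_als(x: np.ndarray, rank: int, iters: int = 50, tol: float = 1e-7,
           init: list[np.ndarray] | None = None, seed: int = 0) -> CPFactors:
    """Alternating least squares for the canonical polyadic decomposition of
    a 4-way tensor, minimizing the Frobenius error ||X - Xhat||.

    The objective is non-increasing across factor updates.  Initialization is
    deterministic (leading singular vectors of each unfolding) unless an
    explicit ``init`` is supplied.
    """
    if rank < 1:
        raise ValueError("CP rank must be >= 1")
    rng = np.random.default_rng(seed)
    factors = [f.copy() for f in init] if init is not None else _svd_init(x, rank, rng)
    norm_x = np.linalg.norm(x)
    prev_err = np.inf
    err = np.inf
    converged = False
    for _ in range(iters):
        for n in range(x.ndim):
            others = [factors[m] for m in range(x.ndim) if m != n]
            kr = _khatri_rao(others)
            gram = np.ones((rank, rank))
            for f in others:
                gram *= f.T @ f
            unfold = np.moveaxis(x, n, 0).reshape(x.shape[n], -1)
            factors[n] = unfold @ kr @ np.linalg.pinv(gram)
        err = np.linalg.norm(x - np.einsum("or,cr,hr,wr->ochw", *factors, optimize=True)) / norm_x
        if abs(prev_err - err) < tol:
            converged = True
            break
        prev_err = err
    if not converged and err > tol:
        warnings.warn(f"CP-ALS did not converge after {iters} iterations "
                      f"(relative error {err:.3e}); returning best factors")
    return CPFactors(rank=rank, out_factor=factors[0], in_factor=factors[1],
                     h_factor=factors[2], w_factor=factors[3], converged=converged)


def cp_error_curve(x: np.ndarray, ranks: list[int], iters: int = 50,
                   seed: int = 0) -> dict[int, float]:
    """Relative reconstruction error at each rank, warm-starting every rank
    from the previous one (so the curve is non-increasing)."""
    rng = np.random.default_rng(seed)
    errors: dict[int, float] = {}
    prev: CPFactors | None = None
    for r in sorted(ranks):
        if prev is None:
            init = None
        else:
            init = []
            for f in (prev.out_factor, prev.in_factor, prev.h_factor, prev.w_factor):
                extra = 1e-8 * rng.standard_normal((f.shape[0], r - f.shape[1]))
                init.append(np.concatenate([f, extra], axis=1))
        factors = cp_als(x, r, iters=iters, init=init, seed=seed)
        errors[r] = factors.relative_error(x)
        prev = factors
    return errors


class CPConvBlock(Module):
    """Exact conv-with-reconstructed-kernel as a sequence of four cheap
    layers: pointwise (Cin->R), depthwise Kh x 1, depthwise 1 x Kw,
    pointwise (R->Cout) carrying the original bias."""

    def __init__(self, factors: CPFactors, bias: np.ndarray | None):
        a, b, c, d = (factors.out_factor, factors.in_factor,
                      factors.h_factor, factors.w_factor)
        cout, r = a.shape
        cin = b.shape[0]
        kh, kw = c.shape[0], d.shape[0]
        self.rank = r
        self.pw_in = Conv2d(cin, r, 1, bias=False)
        self.pw_in.weight.data = b.T.reshape(r, cin, 1, 1).astype(float)
        self.dw_h = DepthwiseConv2d(r, (kh, 1), bias=False)
        self.dw_h.weight.data = c.T.reshape(r, kh, 1).astype(float)
        self.dw_w = DepthwiseConv2d(r, (1, kw), bias=False)
        self.dw_w.weight.data = d.T.reshape(r, 1, kw).astype(float)
        self.pw_out = Conv2d(r, cout, 1, bias=bias is not None)
        self.pw_out.weight.data = a.reshape(cout, r, 1, 1).astype(float)
        if bias is not None:
            self.pw_out.bias.data = bias.astype(float)

    def forward(self, x: Tensor) -> Tensor:
        return self.pw_out(self.dw_w(self.dw_h(self.pw_in(x))))


def cp_decompose_first_conv(net: Network, rank: int | None = None, iters: int = 50,
                            seed: int = 0) -> tuple[Network, CompressionReport]:
    """Decompose the first conv layer's kernel at the given rank (default
    Cout/4) and replace the layer by the CP sequence."""
    out = _clone(net)
    first = out.stages[0].conv
    kernel = first.weight.data
    if rank is None:
        rank = max(1, kernel.shape[0] // 4)
    factors = cp_als(kernel, rank, iters=iters, seed=seed)
    bias = first.bias.data if first.bias is not None else None
    out.stages[0].conv = CPConvBlock(factors, bias)
    rng = np.random.default_rng(seed)
    report = CompressionReport(
        method="CPTD",
        params_before=count_parameters(net),
        params_after=count_parameters(out),
        trainable_after=count_parameters(out, trainable_only=True),
        max_output_deviation=_max_logit_deviation(net, out, _probe_batch(net, rng)),
        settings={"rank": rank, "iters": iters},
        diagnostics={"relative_reconstruction_error": factors.relative_error(kernel),
                     "converged": factors.converged},
    )
    return out, report


# ---------------------------------------------------------------------------
# magnitude pruning
# ---------------------------------------------------------------------------

@dataclass
class PruneMask:
    """Binary keep-masks congruent to the weight arrays (1 = keep)."""
    masks: dict[str, np.ndarray]
    target_fraction: float

    def sparsity(self) -> float:
        total = sum(m.size for m in self.masks.values())
        zeros = sum(int((m == 0).sum()) for m in self.masks.values())
        return zeros / total


def _prunable_weights(net: Module) -> dict[str, Parameter]:
    """All conv and dense weight matrices/kernels (biases excluded)."""
    return {name: p for name, p in net.named_parameters()
            if name.endswith("weight") and p.data.ndim >= 2}


def magnitude_prune(net: Network, fraction: float,
                    ) -> tuple[Network, PruneMask, CompressionReport]:
    """Zero the globally smallest-magnitude `fraction` of conv+dense weights."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("prune fraction must lie in [0, 1]")
    out = _clone(net)
    weights = _prunable_weights(out)
    flat = np.concatenate([np.abs(p.data).ravel() for p in weights.values()])
    k = int(round(fraction * flat.size))
    masks: dict[str, np.ndarray] = {}
    if k > 0:
        order = np.argsort(flat, kind="stable")
        cut = np.zeros(flat.size, dtype=bool)
        cut[order[:k]] = True
    else:
        cut = np.zeros(flat.size, dtype=bool)
    offset = 0
    for name, p in weights.items():
        sel = cut[offset:offset + p.data.size].reshape(p.data.shape)
        offset += p.data.size
        mask = (~sel).astype(float)
        masks[name] = mask
        p.data = p.data * mask
    prune_mask = PruneMask(masks=masks, target_fraction=fraction)
    rng = np.random.default_rng(0)
    report = CompressionReport(
        method="PRUNE",
        params_before=count_parameters(net),
        params_after=count_parameters(out),
        trainable_after=count_parameters(out, trainable_only=True),
        max_output_deviation=_max_logit_deviation(net, out, _probe_batch(net, rng)),
        settings={"fraction": fraction},
        diagnostics={"achieved_sparsity": prune_mask.sparsity()},
    )
    return out, prune_mask, report


def apply_mask(net: Module, mask: PruneMask) -> None:
    params = dict(net.named_parameters())
    for name, m in mask.masks.items():
        if name not in params:
            raise ValueError(f"mask refers to unknown parameter {name!r}")
        if params[name].data.shape != m.shape:
            raise ValueError(f"mask shape mismatch for {name!r}")
        params[name].data = params[name].data * m


def finetune_pruned(net: Network, mask: PruneMask, x: np.ndarray, y: np.ndarray,
                    steps: int = 0, lr: float = 1e-3, batch_size: int = 32,
                    seed: int = 0) -> Network:
    """Fine-tune a pruned network while holding every masked weight at
    exactly zero (the mask is re-applied after each optimizer step)."""
    params = dict(net.named_parameters())
    for name in mask.masks:
        if name not in params or params[name].data.shape != mask.masks[name].shape:
            raise ValueError(f"mask incompatible with network at {name!r}")
    apply_mask(net, mask)
    if steps == 0:
        return net
    opt = Adam(net.parameters(), lr=lr)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    for _ in range(steps):
        idx = rng.choice(n, size=min(batch_size, n), replace=False)
        net.zero_grad()
        loss = softmax_cross_entropy(net.forward(Tensor(x[idx])), y[idx])
        loss.backward()
        opt.step()
        apply_mask(net, mask)
    return net
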