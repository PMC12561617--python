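"""Compression transforms: closed-form parameter counts, functional
contracts, CP-ALS behavior, pruning and mask-preserving fine-tuning."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from ansa_edge.architecture import (REDUCED_FILTERS, build_model,
                                    count_parameters, ansa_ensemble_spec)
from ansa_edge.compression import (CPConvBlock, attach_lora, cp_als,
                                   cp_decompose_first_conv, cp_error_curve,
                                   dsc_rewrite_conv, finetune_pruned,
                                   magnitude_prune, to_depthwise_separable,
                                   to_reduced_feature_maps)
from ansa_edge.data import to_arrays
from ansa_edge.nn import Adam, Conv2d, Dense, Tensor
from ansa_edge.synthetic import generate_synthetic_dataset


@pytest.fixture(scope="module")
def small_net():
    spec = ansa_ensemble_spec(3, input_size=32, filters=REDUCED_FILTERS)
    return build_model(spec, seed=11)


# ---------------------------------------------------------------------------
# depthwise-separable convolutions
# ---------------------------------------------------------------------------

def test_dsc_closed_form_64_128_k3(rng):
    conv = Conv2d(64, 128, 3, bias=False, rng=rng)
    assert count_parameters(conv) == 73_728
    block = dsc_rewrite_conv(conv, rng=rng)
    assert block.weight_param_count() == 64 * 9 + 64 * 128 == 8_768


def test_dsc_rewrites_backbone_and_preserves_shapes(small_net, rng):
    net, report = to_depthwise_separable(small_net)
    assert report.params_after < report.params_before
    assert report.settings["rewritten_stages"] == ["stage1", "stage2", "stage3", "stage4"]
    x = rng.standard_normal((2, 1, 32, 32))
    assert net.forward(Tensor(x)).shape == small_net.forward(Tensor(x)).shape
    # original untouched
    assert count_parameters(small_net) == report.params_before


def test_dsc_parameter_inequality_per_layer(rng):
    for cin, cout, k in [(8, 16, 3), (16, 32, 5), (64, 128, 7)]:
        dense_params = cin * cout * k * k
        dsc_params = cin * k * k + cin * cout
        assert dsc_params < dense_params


# ---------------------------------------------------------------------------
# reduced feature maps
# ---------------------------------------------------------------------------

def test_rfm_spec_transform():
    spec = ansa_ensemble_spec(3, input_size=32)
    reduced = to_reduced_feature_maps(spec)
    assert reduced.backbone.filters == (8, 16, 32, 64)
    assert reduced.attention_blocks == spec.attention_blocks
    assert count_parameters(build_model(reduced)) < count_parameters(build_model(spec))
    with pytest.raises(ValueError):
        to_reduced_feature_maps(reduced)


def test_rfm_leaves_attention_parameter_count_unchanged():
    spec = ansa_ensemble_spec(3, input_size=32)
    reduced = to_reduced_feature_maps(spec)
    att = sum(k * k + 1 for b in spec.attention_blocks for k in b.sab_kernels)
    for s in (spec, reduced):
        net = build_model(s)
        bare = build_model(replace(s, attention_blocks=()))
        assert count_parameters(net) - count_parameters(bare) == att


# ---------------------------------------------------------------------------
# low-rank adaptation
# ---------------------------------------------------------------------------

def test_lora_dense_closed_form(rng):
    from ansa_edge.compression import LoRADense

    layer = Dense(100, 50, rng=rng)
    wrapped = LoRADense(layer, rank=4, rng=rng)
    trainable = sum(p.data.size for p in wrapped.parameters() if p.requires_grad)
    assert trainable == 4 * (100 + 50) == 600
    assert not layer.weight.requires_grad


def test_lora_identity_at_attachment_and_freeze(small_net, rng):
    net, report = attach_lora(small_net, rank=4)
    assert report.max_output_deviation < 1e-9
    assert report.trainable_after < report.params_before
    x, y = to_arrays(generate_synthetic_dataset(4, 3, 32, seed=0))
    base_before = {n: p.data.copy() for n, p in net.named_parameters()
                   if not p.requires_grad}
    opt = Adam(net.parameters(), lr=1e-2)
    from ansa_edge.nn import softmax_cross_entropy
    net.zero_grad()
    softmax_cross_entropy(net.forward(Tensor(x)), y).backward()
    opt.step()
    for n, p in net.named_parameters():
        if n in base_before:
            np.testing.assert_array_equal(p.data, base_before[n])
    factors = [p for n, p in net.named_parameters()
               if p.requires_grad and (n.endswith(".A") or n.endswith(".B"))]
    assert any(np.abs(p.data).max() > 0 for p in factors if p.data.size)


def test_lora_rank_clamped_with_warning(rng):
    layer = Dense(3, 2, rng=rng)
    from ansa_edge.compression import LoRADense

    with pytest.warns(UserWarning, match="clamping"):
        wrapped = LoRADense(layer, rank=10, rng=rng)
    assert wrapped.rank == 2


# ---------------------------------------------------------------------------
# canonical polyadic decomposition
# ---------------------------------------------------------------------------

def test_cp_rank1_kernel_exact(rng):
    a, b, c, d = (rng.standard_normal(s) for s in (6, 3, 5, 5))
    kernel = np.einsum("o,c,h,w->ochw", a, b, c, d)
    factors = cp_als(kernel, rank=1, iters=20)
    assert factors.relative_error(kernel) < 1e-6


def test_cp_error_non_increasing_in_rank(rng):
    kernel = rng.standard_normal((8, 4, 5, 5))
    errors = cp_error_curve(kernel, ranks=[1, 2, 4, 8], iters=30)
    vals = [errors[r] for r in sorted(errors)]
    for lo, hi in zip(vals[1:], vals[:-1]):
        assert lo <= hi + 1e-8


def test_cp_block_equals_conv_with_reconstructed_kernel(rng):
    kernel = rng.standard_normal((6, 3, 5, 5))
    bias = rng.standard_normal(6)
    factors = cp_als(kernel, rank=4, iters=30)
    block = CPConvBlock(factors, bias)
    x = rng.standard_normal((2, 3, 10, 10))
    from ansa_edge.nn import conv2d
    ref = conv2d(Tensor(x), Tensor(factors.reconstruct()), Tensor(bias)).data
    np.testing.assert_allclose(block(Tensor(x)).data, ref, atol=1e-9)


def test_cp_first_conv_deviation_bounded_by_error_times_input_norm(small_net, rng):
    net, report = cp_decompose_first_conv(small_net, rank=4, iters=30)
    rel_err = report.diagnostics["relative_reconstruction_error"]
    orig = small_net.stages[0].conv
    kernel = orig.weight.data
    x = rng.standard_normal((1, 1, 32, 32))
    from ansa_edge.nn import conv2d
    y_orig = conv2d(Tensor(x), Tensor(kernel), orig.bias).data
    y_new = net.stages[0].conv(Tensor(x)).data
    bound = rel_err * np.linalg.norm(kernel) * np.linalg.norm(x)
    assert np.abs(y_new - y_orig).max() <= bound + 1e-9


# ---------------------------------------------------------------------------
# magnitude pruning
# ---------------------------------------------------------------------------

def test_prune_toy_vector_semantics():
    """fraction=0.5 on magnitudes [0.1, 0.5, 0.2, 0.05] zeroes the two
    smallest."""
    w = np.array([0.1, -0.5, 0.2, -0.05])
    order = np.argsort(np.abs(w))
    keep = np.ones(4)
    keep[order[:2]] = 0
    np.testing.assert_array_equal(w * keep, [0.0, -0.5, 0.2, 0.0])


@pytest.mark.parametrize("fraction", [0.0, 0.3, 0.7, 1.0])
def test_prune_global_sparsity_within_one_weight(small_net, fraction):
    net, mask, report = magnitude_prune(small_net, fraction)
    total = sum(m.size for m in mask.masks.values())
    zeros = sum(int((m == 0).sum()) for m in mask.masks.values())
    assert abs(zeros - fraction * total) <= 1.0
    # masked weights really are zero in the network
    for name, p in net.named_parameters():
        if name in mask.masks:
            assert np.all(p.data[mask.masks[name] == 0] == 0)
    if fraction == 1.0:
        for name in mask.masks:
            assert np.all(dict(net.named_parameters())[name].data == 0)
    if fraction == 0.0:
        assert report.max_output_deviation < 1e-12


def test_pruned_zeros_survive_finetuning(small_net):
    images = generate_synthetic_dataset(8, 3, 32, seed=5)
    x, y = to_arrays(images)
    net, mask, _ = magnitude_prune(small_net, 0.5)
    zero_sets = {n: (m == 0) for n, m in mask.masks.items()}
    net = finetune_pruned(net, mask, x, y, steps=5, lr=1e-3, seed=1)
    params = dict(net.named_parameters())
    changed = 0
    for name, zs in zero_sets.items():
        assert np.all(params[name].data[zs] == 0.0)
        changed += int((params[name].data[~zs] != 0).sum())
    assert changed > 0  # unpruned weights did train


def test_finetune_zero_steps_is_identity(small_net):
    images = generate_synthetic_dataset(4, 3, 32, seed=5)
    x, y = to_arrays(images)
    net, mask, _ = magnitude_prune(small_net, 0.3)
    before = net.state_dict()
    net = finetune_pruned(net, mask, x, y, steps=0)
    for name, arr in net.state_dict().items():
        np.testing.assert_array_equal(arr, before[name])


def test_finetune_reduces_training_loss(small_net):
    from ansa_edge.nn import softmax_cross_entropy

    images = generate_synthetic_dataset(10, 3, 32, seed=6)
    x, y = to_arrays(images)
    net, mask, _ = magnitude_prune(small_net, 0.5)
    loss_before = softmax_cross_entropy(net.forward(Tensor(x)), y).item()
    net = finetune_pruned(net, mask, x, y, steps=30, lr=3e-3, batch_size=30, seed=2)
    loss_after = softmax_cross_entropy(net.forward(Tensor(x)), y).item()
    assert loss_after <= loss_before


def test_prune_mask_mismatch_rejected(small_net):
    images = generate_synthetic_dataset(4, 3, 32, seed=5)
    x, y = to_arrays(images)
    _, mask, _ = magnitude_prune(small_net, 0.3)
    other = build_model(ansa_ensemble_spec(3, input_size=32), seed=0)
    with pytest.raises(ValueError):
        finetune_pruned(other, mask, x, y)
    with pytest.raises(ValueError):
        magnitude_prune(small_net, 1.5)
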