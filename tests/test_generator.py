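"""Generator architecture: attention normalization, residual
identities, shapes, and gradient reachability."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from msfgan_pat.generator import (FeatureEnhanceBlock, Generator,
                                  GeneratorConfig, PSABlock,
                                  SqueezeExcite)
from msfgan_pat.nn import Tensor
from msfgan_pat.nn import autograd as ag

CFG = GeneratorConfig(base_channels=16, n_blocks=2)


def _feat(rng, c=16, n=2, h=8):
    return Tensor(rng.normal(size=(c, n, h, h)).astype(np.float32))


def test_se_gate_constant_input_and_range(rng):
    se = SqueezeExcite(8, 4, np.random.default_rng(0))
    const = Tensor(np.full((8, 3, 6, 6), 0.37, np.float32))
    z = ag.transpose(ag.tmean(const, axis=(2, 3)), (1, 0))
    assert np.allclose(z.data, 0.37, atol=1e-6)

    out = se(_feat(rng, c=8))
    assert np.all(out.data > 0) and np.all(out.data < 1)

    for p in se.named_parameters().values():
        p.data = np.zeros_like(p.data)
    assert np.allclose(se(_feat(rng, c=8)).data, 0.5)


def test_psa_softmax_multipliers_sum_to_one(rng):
    psa = PSABlock(CFG, np.random.default_rng(1))
    _, weights = psa.scale_weights(_feat(rng))
    total = sum(w.data for w in weights)
    assert np.allclose(total, 1.0, atol=1e-6)


def test_psa_equal_logits_give_quarter_weights(rng):
    psa = PSABlock(CFG, np.random.default_rng(1))
    for gate in psa.gates:           # zero gates -> all logits sigmoid(0)
        for p in gate.named_parameters().values():
            p.data = np.zeros_like(p.data)
    _, weights = psa.scale_weights(_feat(rng))
    for w in weights:
        assert np.allclose(w.data, 0.25, atol=1e-6)


def test_psa_zeroed_fusion_is_identity(rng):
    psa = PSABlock(CFG, np.random.default_rng(2))
    psa.fuse.w.data = np.zeros_like(psa.fuse.w.data)
    x = _feat(rng)
    assert np.array_equal(psa(x).data, x.data)


def test_feb_zeroed_conv_is_identity_and_residual_flags(rng):
    feb = FeatureEnhanceBlock(CFG, np.random.default_rng(3))
    feb.conv.w.data = np.zeros_like(feb.conv.w.data)
    x = _feat(rng)
    assert np.array_equal(feb(x).data, x.data)

    no_outer = FeatureEnhanceBlock(replace(CFG, outer_residual=False),
                                   np.random.default_rng(3))
    with_outer = FeatureEnhanceBlock(CFG, np.random.default_rng(3))
    d = np.abs(no_outer(x).data - with_outer(x).data)
    assert d.max() > 0

    assert np.all(np.isfinite(with_outer(x).data))


@pytest.mark.parametrize("side", [16, 32, 64])
def test_same_mode_shape_preservation(rng, side):
    gen = Generator(CFG, seed=0)
    x = Tensor(rng.normal(size=(1, 1, side, side)).astype(np.float32))
    assert gen(x).shape == (1, 1, side, side)


def test_sr4_mode_upscales_four_times(rng):
    gen = Generator(replace(CFG, scale_mode="sr4"), seed=0)
    x = Tensor(rng.normal(size=(1, 1, 16, 16)).astype(np.float32))
    assert gen(x).shape == (1, 1, 64, 64)


def test_input_validation(rng):
    gen = Generator(CFG, seed=0)
    with pytest.raises(ValueError):
        gen(Tensor(np.zeros((1, 1, 30, 30), np.float32)))
    with pytest.raises(ValueError):
        gen(Tensor(np.zeros((1, 2, 16, 16), np.float32)))
    with pytest.raises(ValueError):
        GeneratorConfig(base_channels=18)
    with pytest.raises(ValueError):
        GeneratorConfig(branch_kernels=(2, 3, 5, 7))


def test_all_parameters_reachable_by_gradients(rng):
    """Every trainable parameter receives a nonzero gradient from a
    mean-absolute-difference objective.  (A batch of several samples
    keeps the narrow SE bottlenecks out of full ReLU saturation, which
    would zero their gradients for data-dependent reasons.)"""
    gen = Generator(replace(CFG, se_reduction=2), seed=0)
    x = Tensor(rng.normal(size=(8, 1, 16, 16)).astype(np.float32))
    target = Tensor(rng.normal(size=(8, 1, 16, 16)).astype(np.float32))
    out = gen(x)
    loss = ag.tmean(ag.power(ag.power(out - target, 2.0) + 1e-12, 0.5))
    loss.backward()
    dead = [k for k, p in gen.named_parameters().items()
            if p.grad is None or not np.any(p.grad)]
    assert dead == []


def test_ablation_flags_change_parameter_count():
    full = len(Generator(CFG, seed=0).parameters())
    no_psa = len(Generator(replace(CFG, use_psa=False), seed=0)
                 .parameters())
    assert no_psa < full


def test_subpixel_unit_doubles_resolution(rng):
    from msfgan_pat.generator import SubPixelUnit
    unit = SubPixelUnit(16, np.random.default_rng(4))
    x = _feat(rng, c=16, n=2, h=16)
    assert unit(x).shape == (16, 2, 32, 32)
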