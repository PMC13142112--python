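"""Loss arithmetic: relativistic pairing closed forms, R1/R2 gradient
penalties against analytic and finite-difference oracles, total-loss
assembly, and a one-step descent smoke property."""

from __future__ import annotations

import numpy as np
import pytest

from msfgan_pat.losses import (LossWeights, dual_gradient_penalty,
                               pixel_l1, r1_penalty, r2_penalty,
                               relativistic_loss, total_losses)
from msfgan_pat.nn import Tensor
from msfgan_pat.nn import autograd as ag

from conftest import numerical_gradient


def test_relativistic_loss_closed_forms(rng):
    s = rng.normal(size=(2, 1, 8, 8))
    assert np.isclose(float(relativistic_loss(s, s).data), np.log(2.0))

    gap = float(relativistic_loss(s + 10.0, s).data)
    assert np.isclose(gap, np.log1p(np.exp(-10.0)), rtol=1e-6)

    with pytest.raises(ValueError):
        relativistic_loss(np.zeros((2, 4)), np.zeros((2, 5)))


def test_relativistic_loss_symmetric_sum_bound(rng):
    """loss(a,b) + loss(b,a) >= 2 ln 2, equality iff a == b (softplus
    convexity)."""
    for _ in range(10):
        a = rng.normal(size=(1, 1, 4, 4))
        b = rng.normal(size=(1, 1, 4, 4))
        total = (float(relativistic_loss(a, b).data)
                 + float(relativistic_loss(b, a).data))
        assert total >= 2 * np.log(2.0) - 1e-12
    same = rng.normal(size=(1, 1, 4, 4))
    total = (float(relativistic_loss(same, same).data)
             + float(relativistic_loss(same, same).data))
    assert np.isclose(total, 2 * np.log(2.0))


def test_r1_closed_form_quadratic(rng):
    """D(x) = sum x^2 with ||x||^2 = 1, gamma = 0.5 ->
    (0.5/2) ||2x||^2 = 1."""
    x = rng.normal(size=(1, 1, 4, 4))
    x /= np.linalg.norm(x)
    d_quad = lambda t: ag.tsum(ag.power(t, 2.0), axis=(1, 2, 3))
    val = float(r1_penalty(d_quad, Tensor(x), 0.5).data)
    assert np.isclose(val, 1.0, rtol=1e-5)

    d_const = lambda t: ag.tsum(t * 0.0, axis=(1, 2, 3))
    assert float(r1_penalty(d_const, Tensor(x), 0.5).data) == 0.0


def test_r2_closed_form_linear(rng):
    """D(x) = <w, x> with ||w||^2 = 4, gamma = 1 -> penalty = 2."""
    w = rng.normal(size=(1, 1, 4, 4))
    w *= 2.0 / np.linalg.norm(w)
    x = rng.normal(size=(1, 1, 4, 4))
    d_lin = lambda t: ag.tsum(t * Tensor(w), axis=(1, 2, 3))
    assert np.isclose(float(r2_penalty(d_lin, Tensor(x), 1.0).data), 2.0,
                      rtol=1e-5)
    assert float(r2_penalty(d_lin, Tensor(x), 0.0).data) == 0.0

    d_shift = lambda t: ag.tsum(t * Tensor(w), axis=(1, 2, 3)) + 5.0
    assert np.isclose(float(r2_penalty(d_shift, Tensor(x), 1.0).data),
                      2.0, rtol=1e-5)


def test_penalty_matches_finite_difference_oracle(rng):
    """||grad_x D||^2 via autodiff equals central differences on a
    small nonlinear discriminator."""
    w = rng.normal(size=(2, 1, 3, 3))

    def d_fn(t):
        return ag.tmean(ag.sigmoid(ag.corr2d(
            ag.transpose(t, (1, 0, 2, 3)), Tensor(w), 1, 1)),
            axis=(0, 2, 3))

    x = rng.normal(size=(1, 1, 8, 8))
    auto = float(r1_penalty(d_fn, Tensor(x), 2.0).data)   # = ||g||^2

    def scalar(xa):
        return float(d_fn(Tensor(xa)).data.sum())

    g_ref = numerical_gradient(lambda: scalar(x), x, eps=1e-6)
    assert np.isclose(auto, (g_ref ** 2).sum(), rtol=1e-4)


def test_dual_penalty_equals_separate_penalties(rng):
    w = rng.normal(size=(2, 1, 3, 3))

    def d_fn(t):
        y = ag.corr2d(ag.transpose(t, (1, 0, 2, 3)), Tensor(w), 1, 1)
        return ag.sigmoid(ag.transpose(y, (1, 0, 2, 3)))  # (N,2,H,W)

    xf = rng.normal(size=(3, 1, 8, 8))
    xh = rng.normal(size=(3, 1, 8, 8))
    r1s = float(r1_penalty(d_fn, Tensor(xf), 0.5).data)
    r2s = float(r2_penalty(d_fn, Tensor(xh), 1.0).data)
    r1f, r2f = dual_gradient_penalty(d_fn, Tensor(xf), Tensor(xh),
                                     0.5, 1.0)
    assert np.isclose(float(r1f.data), r1s, rtol=1e-5)
    assert np.isclose(float(r2f.data), r2s, rtol=1e-5)


def test_total_losses_assembly(rng):
    s = rng.normal(size=(2, 1, 4, 4))
    w = LossWeights()       # gamma1=0.5, gamma2=1, lambda1=1, lambda2=0.8
    assert (w.gamma1, w.gamma2, w.lambda1, w.lambda2) == (0.5, 1.0, 1.0,
                                                          0.8)
    ld, lg, rep = total_losses(s, s, 0.25, 0.5, w)
    assert np.isclose(rep.L_Rp, np.log(2.0))
    assert np.isclose(float(ld.data), np.log(2.0) + 1.0 * 0.25
                      + 0.8 * 0.5)
    assert np.isclose(float(lg.data), np.log(2.0))

    zero_w = LossWeights(lambda1=0.0, lambda2=0.0)
    ld0, _, rep0 = total_losses(s, s, 0.0, 0.0, zero_w)
    assert np.isclose(float(ld0.data), rep0.L_Rp)

    with pytest.raises(ValueError):
        LossWeights(lambda1=-1.0)


def test_pixel_term_included_when_requested(rng):
    s = np.zeros((1, 1, 2, 2))
    xh = Tensor(np.ones((1, 1, 2, 2), np.float32))
    xf = Tensor(np.zeros((1, 1, 2, 2), np.float32))
    _, lg, rep = total_losses(s, s, 0.0, 0.0, LossWeights(),
                              x_hat=xh, x_full=xf, pixel_weight=10.0)
    assert np.isclose(float(lg.data), np.log(2.0) + 10.0, rtol=1e-4)
    assert np.isclose(rep.pixel, 1.0, rtol=1e-4)


def test_one_gradient_step_decreases_discriminator_loss(rng):
    """A small D step on a fixed toy pair reduces L_D — the basic
    adversarial-learning smoke property."""
    from msfgan_pat.discriminator import Discriminator, \
        DiscriminatorConfig
    disc = Discriminator(DiscriminatorConfig(widths=(4, 8)), seed=0)
    xf = Tensor(rng.normal(size=(2, 1, 8, 8)).astype(np.float32))
    xh = Tensor(rng.normal(size=(2, 1, 8, 8)).astype(np.float32))
    w = LossWeights()

    def loss_value():
        sr = disc(xf)
        sf = disc(xh)
        r1, r2 = dual_gradient_penalty(disc, xf, xh, w.gamma1, w.gamma2)
        return total_losses(sr, sf, r1, r2, w)

    disc.eval()                     # freeze power iteration for parity
    ld, _, _ = loss_value()
    before = float(ld.data)
    ld.backward()
    for p in disc.parameters():
        if p.grad is not None:
            p.data = p.data - 1e-3 * p.grad
    disc.zero_grad()
    ld2, _, _ = loss_value()
    assert float(ld2.data) < before
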