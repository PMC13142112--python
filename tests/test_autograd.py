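"""Engine-level checks: every primitive's gradient against central
finite differences, convolution against scipy, and second-order
differentiation (the basis of the R1/R2 penalties)."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import correlate

from msfgan_pat.nn import autograd as ag
from msfgan_pat.nn.autograd import Tensor, grad

from conftest import numerical_gradient


def _scipy_corr(x, w, stride, pad):
    C, N = x.shape[:2]
    Co = w.shape[0]
    xp = np.pad(x, [(0, 0), (0, 0), (pad, pad), (pad, pad)])
    out = np.stack([
        [sum(correlate(xp[c, n], w[o, c], mode="valid")
             for c in range(C))[::stride, ::stride]
         for n in range(N)]
        for o in range(Co)])
    return out


@pytest.mark.parametrize("shape,kernel,stride,pad", [
    ((3, 2, 8, 8), (5, 3, 3, 3), 1, 1),
    ((3, 2, 9, 9), (4, 3, 3, 3), 2, 1),     # inexact tiling
    ((2, 1, 12, 12), (3, 2, 5, 5), 1, 2),
    ((1, 2, 33, 33), (4, 1, 3, 3), 1, 1),   # direct path, C=1
    ((4, 2, 33, 33), (1, 4, 3, 3), 1, 1),   # direct path, Co=1
])
def test_conv_forward_matches_scipy_and_gradcheck(rng, shape, kernel,
                                                  stride, pad):
    x = rng.normal(size=shape)
    w = rng.normal(size=kernel)
    xt = Tensor(x.copy(), requires_grad=True)
    wt = Tensor(w.copy(), requires_grad=True)
    y = ag.corr2d(xt, wt, stride=stride, padding=pad)
    assert np.allclose(y.data, _scipy_corr(x, w, stride, pad), atol=1e-10)

    L = ag.tsum(ag.power(y, 2.0))
    gx, gw = grad(L, [xt, wt])

    def f():
        return float((ag.corr2d(Tensor(x), Tensor(w), stride=stride,
                                padding=pad).data ** 2).sum())

    ref_x = numerical_gradient(f, x)
    ref_w = numerical_gradient(f, w)
    assert np.allclose(gx.data, ref_x, rtol=1e-4, atol=1e-4)
    assert np.allclose(gw.data, ref_w, rtol=1e-4, atol=1e-4)


def test_second_order_gradient_matches_finite_differences(rng):
    """d/dw of || d/dx sum(sigmoid(conv(x, w))) ||^2 — the structure of
    the discriminator gradient penalties."""
    x = rng.normal(size=(3, 2, 7, 7))
    w = rng.normal(size=(4, 3, 3, 3))

    def penalty(wa):
        xt = Tensor(x.copy(), requires_grad=True)
        y = ag.corr2d(xt, Tensor(wa, requires_grad=True), stride=2,
                      padding=1)
        g, = grad(ag.tsum(ag.sigmoid(y)), [xt], create_graph=True)
        return ag.tsum(ag.power(g, 2.0))

    wt = Tensor(w.copy(), requires_grad=True)
    xt = Tensor(x.copy(), requires_grad=True)
    y = ag.corr2d(xt, wt, stride=2, padding=1)
    g, = grad(ag.tsum(ag.sigmoid(y)), [xt], create_graph=True)
    gw, = grad(ag.tsum(ag.power(g, 2.0)), [wt])

    ref = numerical_gradient(lambda: float(penalty(w).data), w, eps=1e-5)
    assert np.allclose(gw.data, ref, rtol=1e-4, atol=1e-6)


@pytest.mark.parametrize("op,dom", [
    (ag.texp, None), (ag.tlog, "pos"), (ag.sigmoid, None),
    (ag.softplus, None), (ag.relu, None),
    (lambda t: ag.leaky_relu(t, 0.2), None),
    (lambda t: ag.power(t, 3.0), None),
])
def test_elementwise_gradients(rng, op, dom):
    x = rng.normal(size=(4, 5)) + (2.0 if dom == "pos" else 0.0)
    xt = Tensor(x.copy(), requires_grad=True)
    L = ag.tsum(ag.power(op(xt), 2.0))
    g, = grad(L, [xt])

    def f():
        return float((op(Tensor(x)).data ** 2).sum())

    assert np.allclose(g.data, numerical_gradient(f, x),
                       rtol=1e-5, atol=1e-7)


def test_reductions_broadcast_matmul_gradients(rng):
    x = rng.normal(size=(3, 4))
    w = rng.normal(size=(4, 2))
    xt = Tensor(x.copy(), requires_grad=True)
    wt = Tensor(w.copy(), requires_grad=True)
    y = ag.matmul(xt, wt)
    L = ag.tsum(ag.power(ag.tmean(y, axis=0) + ag.tmax(y, axis=0), 2.0))
    gx, gw = grad(L, [xt, wt])

    def f():
        yy = x @ w
        return float(((yy.mean(axis=0) + yy.max(axis=0)) ** 2).sum())

    assert np.allclose(gx.data, numerical_gradient(f, x), atol=1e-6)
    assert np.allclose(gw.data, numerical_gradient(f, w), atol=1e-6)


def test_pixel_shuffle_matches_index_map(rng):
    """Depth-to-space equals the brute-force index permutation."""
    C, N, H, W, r = 2, 3, 4, 5, 2
    x = rng.normal(size=(C * r * r, N, H, W))
    y = ag.pixel_shuffle(Tensor(x), r).data
    ref = np.zeros((C, N, H * r, W * r))
    for c in range(C):
        for a in range(r):
            for b in range(r):
                ref[c, :, a::r, b::r] = x[c * r * r + a * r + b]
    assert np.array_equal(y, ref)


def test_pixel_shuffle_and_bilinear_gradients(rng):
    x = rng.normal(size=(4, 2, 3, 3))
    xt = Tensor(x.copy(), requires_grad=True)
    L = ag.tsum(ag.power(ag.pixel_shuffle(xt, 2), 2.0))
    g, = grad(L, [xt])
    assert np.allclose(g.data, 2 * x)   # permutation is orthogonal

    xb = rng.normal(size=(1, 2, 4, 4))
    xbt = Tensor(xb.copy(), requires_grad=True)
    L = ag.tsum(ag.power(ag.bilinear_upsample2x(xbt), 2.0))
    g, = grad(L, [xbt])

    def f():
        return float((ag.bilinear_upsample2x(Tensor(xb)).data ** 2).sum())

    assert np.allclose(g.data, numerical_gradient(f, xb), atol=1e-6)


def test_bilinear_upsample_values():
    """x2 upsampling of a linear ramp stays linear in the interior."""
    ramp = np.arange(4, dtype=float)[None, None, None, :] * np.ones(
        (1, 1, 4, 1))
    up = ag.bilinear_upsample2x(Tensor(ramp)).data[0, 0, 0]
    assert np.allclose(np.diff(up[1:-1]), 0.5)


def test_no_grad_disables_taping(rng):
    with ag.no_grad():
        t = Tensor(rng.normal(size=(2, 2)), requires_grad=True)
        y = ag.sigmoid(t * 2.0)
    assert y.parents == () and y._vjp is None


def test_backward_accumulates_and_frees(rng):
    x = Tensor(rng.normal(size=(3,)), requires_grad=True)
    y = ag.tsum(ag.power(x, 2.0))
    y.backward()
    assert np.allclose(x.grad, 2 * x.data)
    assert y.parents == ()          # graph released after backward
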