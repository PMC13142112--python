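"""Dual-gradient-regularized relativistic adversarial objective.

The discriminator is trained with the relativistic pairing loss

    L_Rp = E[ -log sigmoid( D(x_f) - D(x_hat) ) ]

computed per pixel of the realness maps (the discriminator outputs a
spatial map; a config switch reduces it to a scalar pairing), plus two
gradient penalties: R1 = (gamma1/2) E ||grad_x D(x_f)||^2 on full-view
images and R2 = (gamma2/2) E ||grad_x D(x_hat)||^2 on generated images,
with total L_D = L_Rp + lambda1 R1 + lambda2 R2.  The generator
minimizes the role-swapped pairing, optionally plus an L1 pixel term
(off by default here; the trainer enables it).

Defaults: gamma1 = 0.5, gamma2 = 1, lambda1 = 1, lambda2 = 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor, grad

__all__ = ["LossWeights", "LossReport", "relativistic_loss", "r1_penalty",
           "r2_penalty", "pixel_l1", "total_losses"]


@dataclass(frozen=True)
class LossWeights:
    gamma1: float = 0.5
    gamma2: float = 1.0
    lambda1: float = 1.0
    lambda2: float = 0.8

    def __post_init__(self):
        for name in ("gamma1", "gamma2", "lambda1", "lambda2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class LossReport:
    L_Rp: float
    R1: float
    R2: float
    L_total: float
    L_G: float
    pixel: float = 0.0
    weights: LossWeights = LossWeights()


def _as_t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def relativistic_loss(s_real, s_fake, reduce_maps: bool = False) -> Tensor:
    """Mean of -log sigmoid(S_real - S_fake) over pixels and batch.

    With ``reduce_maps=True`` each realness map is first mean-pooled to
    a scalar and the pairing is applied to the scalars.
    """
    s_real, s_fake = _as_t(s_real), _as_t(s_fake)
    if s_real.shape != s_fake.shape:
        raise ValueError("realness maps must share a shape")
    if reduce_maps and s_real.ndim > 1:
        axes = tuple(range(1, s_real.ndim))
        s_real = ag.tmean(s_real, axis=axes)
        s_fake = ag.tmean(s_fake, axis=axes)
    return ag.tmean(ag.softplus(s_fake - s_real))


def _gradient_penalty(d_fn, x, gamma: float,
                      create_graph: bool = True) -> Tensor:
    """(gamma/2) E_batch sum_pixels (d mean-reduced D / d x)^2."""
    if gamma == 0.0:
        return Tensor(np.zeros(()))
    x = _as_t(x)
    leaf = Tensor(x.data, requires_grad=True)
    out = d_fn(leaf)
    if not isinstance(out, Tensor):
        raise TypeError("discriminator must return a Tensor")
    if out.ndim > 1:
        out = ag.tmean(out, axis=tuple(range(1, out.ndim)))
    total = ag.tsum(out)
    g, = grad(total, [leaf], create_graph=create_graph)
    n_batch = x.shape[0] if x.ndim > 0 else 1
    sq = ag.tsum(ag.power(g, 2.0))
    return sq * (gamma / 2.0 / n_batch)


def r1_penalty(d_fn, x_full, gamma1: float,
               create_graph: bool = True) -> Tensor:
    """Gradient penalty of the discriminator at full-view images."""
    return _gradient_penalty(d_fn, x_full, gamma1, create_graph)


def r2_penalty(d_fn, x_generated, gamma2: float,
               create_graph: bool = True) -> Tensor:
    """Gradient penalty at generated images (detached from the
    generator: only the discriminator update uses it)."""
    return _gradient_penalty(d_fn, x_generated, gamma2, create_graph)


def dual_gradient_penalty(d_fn, x_full, x_generated, gamma1: float,
                          gamma2: float) -> tuple[Tensor, Tensor]:
    """R1 and R2 evaluated in a single differentiation pass.

    The discriminator scores samples independently, so stacking the
    full-view and generated batches, differentiating the summed
    per-sample mean scores once, and splitting the input gradient gives
    exactly the two penalties at half the cost of separate passes.
    """
    x_full, x_generated = _as_t(x_full), _as_t(x_generated)
    n1 = x_full.shape[0]
    leaf = Tensor(np.concatenate([x_full.data, x_generated.data]),
                  requires_grad=True)
    out = d_fn(leaf)
    if out.ndim > 1:
        out = ag.tmean(out, axis=tuple(range(1, out.ndim)))
    g, = grad(ag.tsum(out), [leaf], create_graph=True)
    g1 = getitem_rows(g, 0, n1)
    g2 = getitem_rows(g, n1, g.shape[0])
    r1 = ag.tsum(ag.power(g1, 2.0)) * (gamma1 / 2.0 / n1)
    r2 = ag.tsum(ag.power(g2, 2.0)) * (gamma2 / 2.0
                                       / x_generated.shape[0])
    return r1, r2


def getitem_rows(t: Tensor, a: int, b: int) -> Tensor:
    return ag.getitem(t, (slice(a, b),))


def pixel_l1(x_hat, x_full) -> Tensor:
    x_hat, x_full = _as_t(x_hat), _as_t(x_full)
    return ag.tmean(ag.power(ag.power(x_hat - x_full, 2.0) + 1e-12, 0.5))


def total_losses(s_real, s_fake, r1, r2, weights: LossWeights,
                 x_hat=None, x_full=None, pixel_weight: float = 0.0,
                 reduce_maps: bool = False):
    """Assemble L_D and L_G; returns (L_D, L_G, LossReport).

    ``r1``/``r2`` are the already-evaluated penalties (they depend on
    the discriminator as a function, not only on the maps).  The pixel
    fidelity term is off by default.
    """
    r1 = _as_t(r1)
    r2 = _as_t(r2)
    l_rp = relativistic_loss(s_real, s_fake, reduce_maps)
    l_d = l_rp + weights.lambda1 * r1 + weights.lambda2 * r2
    l_g = relativistic_loss(s_fake, s_real, reduce_maps)
    pix = 0.0
    if pixel_weight > 0.0:
        if x_hat is None or x_full is None:
            raise ValueError("pixel term requires x_hat and x_full")
        p = pixel_l1(x_hat, x_full)
        l_g = l_g + pixel_weight * p
        pix = float(p.data)
    report = LossReport(L_Rp=float(l_rp.data), R1=float(r1.data),
                        R2=float(r2.data), L_total=float(l_d.data),
                        L_G=float(l_g.data), pixel=pix, weights=weights)
    return l_d, l_g, report
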