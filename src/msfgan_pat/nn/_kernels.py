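"""Numba-jitted inner loops behind the convolution primitives.

Features live in (C, N, H, W) layout: with channels leading, the
im2col matrix (C*kh*kw, N*Ho*Wo) multiplies the (Co, C*kh*kw) weight
into a (Co, N*Ho*Wo) output that *is* the next layer's feature map —
no transposition copies anywhere in the conv forward or backward.
Zero padding is folded into the gather/scatter bounds.  ``corr_direct``
and friends skip the cols matrix entirely for convolutions where it
would dwarf the actual work.

Implementation note: inner loops index pre-sliced rows from offset 0,
so every subscript is provably non-negative — index expressions whose
sign the compiler cannot prove carry wraparound checks that defeat
vectorization.  Kernels compile per dtype and cache on disk.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["im2col", "col2im", "corr_direct", "corrT_direct",
           "wgrad_direct"]


@njit(cache=True, fastmath=True, inline="always")
def _jbounds(pad, dj, stride, W, Wo):
    """Valid output range [jlo, jhi] with 0 <= j*stride + dj - pad < W."""
    jlo = max(0, -(-(pad - dj) // stride))
    jhi = min(Wo - 1, (W - 1 - dj + pad) // stride)
    return jlo, jhi


@njit(cache=True, fastmath=True)
def im2col(x, kh, kw, stride, pad):
    """x (C,N,H,W) -> cols (C*kh*kw, N*Ho*Wo), zero-padded virtually."""
    C, N, H, W = x.shape
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    L = Ho * Wo
    cols = np.zeros((C * kh * kw, N * L), dtype=x.dtype)
    for c in range(C):
        for di in range(kh):
            for dj in range(kw):
                r = (c * kh + di) * kw + dj
                crow = cols[r]
                jlo, jhi = _jbounds(pad, dj, stride, W, Wo)
                if jhi < jlo:
                    continue
                m = jhi + 1 - jlo
                src0 = jlo * stride + dj - pad
                for n in range(N):
                    xplane = x[c, n]
                    base = n * L
                    for i in range(Ho):
                        hi = i * stride + di - pad
                        if hi < 0 or hi >= H:
                            continue
                        dst = crow[base + i * Wo + jlo:]
                        xs = xplane[hi, src0:]
                        if stride == 1:
                            for j in range(m):
                                dst[j] = xs[j]
                        else:
                            for j in range(m):
                                dst[j] = xs[j * stride]
    return cols


@njit(cache=True, fastmath=True)
def col2im(cols, C, N, H, W, kh, kw, stride, pad):
    """Transpose of ``im2col``: scatter-add cols back to (C,N,H,W)."""
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    L = Ho * Wo
    x = np.zeros((C, N, H, W), dtype=cols.dtype)
    for c in range(C):
        for di in range(kh):
            for dj in range(kw):
                r = (c * kh + di) * kw + dj
                crow = cols[r]
                jlo, jhi = _jbounds(pad, dj, stride, W, Wo)
                if jhi < jlo:
                    continue
                m = jhi + 1 - jlo
                src0 = jlo * stride + dj - pad
                for n in range(N):
                    xplane = x[c, n]
                    base = n * L
                    for i in range(Ho):
                        hi = i * stride + di - pad
                        if hi < 0 or hi >= H:
                            continue
                        src = crow[base + i * Wo + jlo:]
                        xs = xplane[hi, src0:]
                        if stride == 1:
                            for j in range(m):
                                xs[j] += src[j]
                        else:
                            for j in range(m):
                                xs[j * stride] += src[j]
    return x


@njit(cache=True, fastmath=True)
def corr_direct(x, w, pad):
    """Stride-1 correlation without materializing cols."""
    C, N, H, W = x.shape
    Co, _, kh, kw = w.shape
    Ho = H + 2 * pad - kh + 1
    Wo = W + 2 * pad - kw + 1
    y = np.zeros((Co, N, Ho, Wo), dtype=x.dtype)
    for o in range(Co):
        for n in range(N):
            yplane = y[o, n]
            for c in range(C):
                xplane = x[c, n]
                for di in range(kh):
                    ilo = max(0, pad - di)
                    ihi = min(Ho - 1, H - 1 + pad - di)
                    for dj in range(kw):
                        wv = w[o, c, di, dj]
                        jlo, jhi = _jbounds(pad, dj, 1, W, Wo)
                        if jhi < jlo:
                            continue
                        m = jhi + 1 - jlo
                        src0 = jlo + dj - pad
                        for i in range(ilo, ihi + 1):
                            xs = xplane[i + di - pad, src0:]
                            ys = yplane[i, jlo:]
                            for j in range(m):
                                ys[j] += wv * xs[j]
    return y


@njit(cache=True, fastmath=True)
def corrT_direct(g, w, pad, H, W):
    """Transpose of stride-1 ``corr_direct``: g (Co,N,Ho,Wo) -> (C,N,H,W)."""
    Co, N, Ho, Wo = g.shape
    _, C, kh, kw = w.shape
    x = np.zeros((C, N, H, W), dtype=g.dtype)
    for c in range(C):
        for n in range(N):
            xplane = x[c, n]
            for o in range(Co):
                gplane = g[o, n]
                for di in range(kh):
                    ilo = max(0, pad - di)
                    ihi = min(Ho - 1, H - 1 + pad - di)
                    for dj in range(kw):
                        wv = w[o, c, di, dj]
                        jlo, jhi = _jbounds(pad, dj, 1, W, Wo)
                        if jhi < jlo:
                            continue
                        m = jhi + 1 - jlo
                        src0 = jlo + dj - pad
                        for i in range(ilo, ihi + 1):
                            xs = xplane[i + di - pad, src0:]
                            gs = gplane[i, jlo:]
                            for j in range(m):
                                xs[j] += wv * gs[j]
    return x


@njit(cache=True, fastmath=True)
def wgrad_direct(x, g, pad, kh, kw):
    """Weight gradient for stride-1 correlation: -> (Co,C,kh,kw)."""
    C, N, H, W = x.shape
    Co, _, Ho, Wo = g.shape
    gw = np.zeros((Co, C, kh, kw), dtype=x.dtype)
    for o in range(Co):
        for c in range(C):
            for di in range(kh):
                ilo = max(0, pad - di)
                ihi = min(Ho - 1, H - 1 + pad - di)
                for dj in range(kw):
                    jlo, jhi = _jbounds(pad, dj, 1, W, Wo)
                    if jhi < jlo:
                        continue
                    m = jhi + 1 - jlo
                    src0 = jlo + dj - pad
                    acc = 0.0
                    for n in range(N):
                        xplane = x[c, n]
                        gplane = g[o, n]
                        for i in range(ilo, ihi + 1):
                            xs = xplane[i + di - pad, src0:]
                            gs = gplane[i, jlo:]
                            for j in range(m):
                                acc += gs[j] * xs[j]
                    gw[o, c, di, dj] = acc
    return gw
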