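"""Trace preprocessing and delay-and-sum (DAS) beamforming.

DAS forms the sparse-view network input x0: each image pixel sums the
recorded traces evaluated at the time-of-flight delay |r - r_i| / c,
with linear interpolation between time samples.  Delays outside the
recorded window contribute zero, so the map is linear in the sinogram.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .acoustics import ArrayGeometry, Sinogram, _check_grid_in_ring
from .containers import ReconImage

__all__ = ["bandpass", "envelope", "das_reconstruct", "image_envelope",
           "normalize_image"]


def bandpass(sino: Sinogram, low_hz: float, high_hz: float) -> Sinogram:
    """Zero-phase 4th-order Butterworth band-pass applied per trace."""
    nyquist = 0.5 / sino.geometry.dt
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz:.3g}, {high_hz:.3g}) Hz must lie strictly "
            f"inside (0, {nyquist:.3g}) Hz")
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass",
                        fs=1.0 / sino.geometry.dt, output="sos")
    filtered = signal.sosfiltfilt(sos, sino.traces, axis=1)
    filtered = filtered - filtered.mean(axis=1, keepdims=True)
    return Sinogram(filtered, sino.view_indices.copy(), sino.geometry)


def envelope(sino: Sinogram) -> Sinogram:
    """Per-trace magnitude of the analytic (Hilbert) signal."""
    if sino.geometry.n_time < 8:
        raise ValueError("need at least 8 time samples for the envelope")
    env = np.abs(signal.hilbert(sino.traces, axis=1))
    return Sinogram(env, sino.view_indices.copy(), sino.geometry)


def das_reconstruct(sino: Sinogram, geom: ArrayGeometry, grid_size: int,
                    dx: float) -> ReconImage:
    """Delay-and-sum beamforming onto a square grid (no apodization)."""
    _check_grid_in_ring(geom, grid_size, dx)
    G = grid_size
    half = (G - 1) / 2.0
    jj, ii = np.meshgrid(np.arange(G), np.arange(G))
    x = (jj - half) * dx
    y = (half - ii) * dx
    pos = geom.element_positions
    n_t = geom.n_time
    img = np.zeros((G, G))
    for row, e in enumerate(sino.view_indices):
        ex, ey = pos[e]
        tau = np.hypot(x - ex, y - ey) / geom.sound_speed / geom.dt
        k0 = np.floor(tau).astype(np.int64)
        frac = tau - k0
        valid = (k0 >= 0) & (k0 <= n_t - 2)
        k0c = np.clip(k0, 0, n_t - 2)
        tr = sino.traces[row]
        contrib = (1.0 - frac) * tr[k0c] + frac * tr[k0c + 1]
        img += np.where(valid, contrib, 0.0)
    return ReconImage(img, dx, provenance="das", view_count=sino.n_views)


def image_envelope(img: ReconImage, method: str = "abs") -> ReconImage:
    """Envelope of a bipolar beamformed image, applied after DAS.

    The band-limited reconstruction oscillates around zero; its
    magnitude is the display form.  ``abs`` rectifies the image
    (isotropic, the default); ``hilbert`` takes the magnitude of the
    analytic image along the first axis.
    """
    if method == "abs":
        out = np.abs(img.grid)
    elif method == "hilbert":
        out = np.abs(signal.hilbert(img.grid, axis=0))
    else:
        raise ValueError(f"unknown envelope method '{method}'")
    return ReconImage(out, img.dx, provenance=img.provenance,
                      view_count=img.view_count)


def normalize_image(img: ReconImage) -> ReconImage:
    """Min-max rescale to [0, 1]; a constant image maps to all-zeros."""
    g = img.grid
    if not np.all(np.isfinite(g)):
        raise ValueError("image contains NaN or Inf")
    lo, hi = g.min(), g.max()
    out = np.zeros_like(g) if hi == lo else (g - lo) / (hi - lo)
    return ReconImage(out, img.dx, provenance=img.provenance,
                      view_count=img.view_count)
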