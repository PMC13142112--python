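"""Preprocessing and delay-and-sum beamforming."""

from __future__ import annotations

import numpy as np
import pytest

from msfgan_pat.acoustics import Sinogram, project, subsample_views
from msfgan_pat.containers import PressureMap, ReconImage
from msfgan_pat.das import bandpass, das_reconstruct, envelope, \
    normalize_image
from msfgan_pat.evaluation import psnr
from msfgan_pat.phantom import PhantomConfig, generate_vessel_phantom


def _tone(geom, freq, n_views=4):
    t = np.arange(geom.n_time) * geom.dt
    return Sinogram(np.tile(np.sin(2 * np.pi * freq * t), (n_views, 1)),
                    np.arange(n_views) * (geom.n_elements // n_views),
                    geom)


def test_bandpass_preserves_passband_kills_dc(small_geometry):
    g = small_geometry
    fc = g.center_frequency
    tone = _tone(g, fc)
    out = bandpass(tone, 0.5 * fc, 1.5 * fc)
    core = slice(g.n_time // 4, 3 * g.n_time // 4)
    ratio = (np.abs(out.traces[0][core]).max()
             / np.abs(tone.traces[0][core]).max())
    assert abs(ratio - 1.0) < 0.01

    dc = Sinogram(np.ones((2, g.n_time)), np.array([0, 1]), g)
    flat = bandpass(dc, 0.5 * fc, 1.5 * fc)
    assert np.abs(flat.traces).max() < 1e-6

    twice = bandpass(out, 0.5 * fc, 1.5 * fc)
    ratio2 = (np.abs(twice.traces[0][core]).max()
              / np.abs(out.traces[0][core]).max())
    assert abs(ratio2 - 1.0) < 0.02

    with pytest.raises(ValueError):
        bandpass(tone, 0.0, fc)
    with pytest.raises(ValueError):
        bandpass(tone, fc, 1.0 / g.dt)


def test_envelope_of_cosine_is_constant(small_geometry):
    g = small_geometry
    t = np.arange(g.n_time) * g.dt
    sino = Sinogram(np.cos(2 * np.pi * g.center_frequency * t)[None, :],
                    np.array([0]), g)
    env = envelope(sino)
    core = env.traces[0][20:-20]
    assert np.allclose(core, 1.0, atol=0.02)
    assert np.all(env.traces >= np.abs(sino.traces) - 1e-9)

    zero = Sinogram(np.zeros((1, g.n_time)), np.array([0]), g)
    assert not envelope(zero).traces.any()


def test_das_point_localization(small_geometry, grid64):
    """Envelope-DAS localizes a point source at its pixel."""
    pt = np.zeros((64, 64))
    pt[20, 40] = 1.0
    sino = project(PressureMap(pt, grid64["dx"]), small_geometry)
    img = das_reconstruct(envelope(sino), small_geometry, 64,
                          grid64["dx"]).grid
    peak = np.unravel_index(img.argmax(), img.shape)
    assert np.hypot(peak[0] - 20, peak[1] - 40) <= 2.0


def test_das_zero_and_linearity(rng, small_geometry, grid64):
    g = small_geometry
    zero = Sinogram(np.zeros((g.n_elements, g.n_time)),
                    np.arange(g.n_elements), g)
    assert not das_reconstruct(zero, g, 64, grid64["dx"]).grid.any()

    a = Sinogram(rng.normal(size=(g.n_elements, g.n_time)),
                 np.arange(g.n_elements), g)
    b = Sinogram(rng.normal(size=(g.n_elements, g.n_time)),
                 np.arange(g.n_elements), g)
    ia = das_reconstruct(a, g, 64, grid64["dx"]).grid
    ib = das_reconstruct(b, g, 64, grid64["dx"]).grid
    combo = Sinogram(3.0 * a.traces + b.traces, a.view_indices, g)
    ic = das_reconstruct(combo, g, 64, grid64["dx"]).grid
    assert np.allclose(ic, 3.0 * ia + ib, rtol=1e-9, atol=1e-12)


def test_view_additivity(rng, small_geometry, grid64):
    """DAS over a union of disjoint view sets is the sum of the parts."""
    g = small_geometry
    sino = Sinogram(rng.normal(size=(g.n_elements, g.n_time)),
                    np.arange(g.n_elements), g)
    evens = Sinogram(sino.traces[::2], np.arange(0, 64, 2), g)
    odds = Sinogram(sino.traces[1::2], np.arange(1, 64, 2), g)
    total = das_reconstruct(sino, g, 64, grid64["dx"]).grid
    parts = (das_reconstruct(evens, g, 64, grid64["dx"]).grid
             + das_reconstruct(odds, g, 64, grid64["dx"]).grid)
    assert np.allclose(total, parts, rtol=1e-10, atol=1e-12)


def test_sparse_views_degrade_psnr_and_raise_background(small_geometry,
                                                        grid64):
    """Fewer views -> lower fidelity and more streak energy outside the
    vessels, the artifact the network exists to remove."""
    g = small_geometry
    cfg = PhantomConfig(grid_size=64, max_radius=2.0, min_radius=0.5)
    pm = generate_vessel_phantom(cfg, seed=3)
    pm = PressureMap(pm.grid, grid64["dx"])
    sino = project(pm, g)
    full = normalize_image(das_reconstruct(sino, g, 64, grid64["dx"]))
    sparse, _ = subsample_views(sino, 16)
    low = normalize_image(das_reconstruct(sparse, g, 64, grid64["dx"]))
    ref = normalize_image(ReconImage(pm.grid, grid64["dx"]))
    assert psnr(low.grid, ref.grid) < psnr(full.grid, ref.grid)

    from scipy.ndimage import binary_dilation
    mask = binary_dilation(pm.grid > 0.1, iterations=2)
    assert (low.grid[~mask] ** 2).mean() > (full.grid[~mask] ** 2).mean()


def test_normalize_image():
    img = ReconImage(np.array([[2.0, 3.0], [4.0, 2.0]]), 1.0)
    out = normalize_image(img)
    assert np.allclose(out.grid, [[0.0, 0.5], [1.0, 0.0]])

    const = normalize_image(ReconImage(np.full((4, 4), 7.0), 1.0))
    assert not const.grid.any()

    again = normalize_image(normalize_image(img))
    assert np.allclose(again.grid, out.grid)

    with pytest.raises(ValueError):
        normalize_image(ReconImage(np.array([[np.nan, 1.0]]), 1.0))
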