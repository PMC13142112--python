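"""Forward-operator physics: geometry, linearity, adjointness,
arrival times, symmetry, noise and view subsampling."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import hilbert

from msfgan_pat.acoustics import (Sinogram, add_noise, build_geometry,
                                  default_geometry, project, adjoint,
                                  subsample_views)
from msfgan_pat.containers import PressureMap


def test_geometry_angles_and_validation():
    geom = build_geometry(4.5e-3, 256, 5.5e6, 0.8, 1500.0, 1.5e-8, 900)
    assert geom.n_elements == 256
    assert np.allclose(np.diff(geom.element_angles), 2 * np.pi / 256)
    g4 = build_geometry(4.5e-3, 4, 5.5e6, 0.8, 1500.0, 1.5e-8, 900)
    assert np.allclose(g4.element_angles,
                       [0, np.pi / 2, np.pi, 3 * np.pi / 2])
    with pytest.raises(ValueError):
        build_geometry(4.5e-3, 3, 5.5e6, 0.8, 1500.0, 1.5e-8, 900)
    with pytest.raises(ValueError):
        build_geometry(4.5e-3, 64, 5.5e6, 2.5, 1500.0, 1.5e-8, 900)


def test_ring_must_enclose_grid(grid64):
    tight = build_geometry(1e-3, 64, 2.5e6, 0.8, 1500.0, 6.7e-8, 100)
    pm = PressureMap(np.zeros((64, 64)), grid64["dx"])
    with pytest.raises(ValueError):
        project(pm, tight)


def test_projection_linearity(rng, small_geometry, grid64):
    a = PressureMap(rng.random((64, 64)), grid64["dx"])
    b = PressureMap(rng.random((64, 64)), grid64["dx"])
    ya = project(a, small_geometry).traces
    yb = project(b, small_geometry).traces
    combo = PressureMap(2.5 * a.grid + b.grid, grid64["dx"])
    yc = project(combo, small_geometry).traces
    assert np.allclose(yc, 2.5 * ya + yb, rtol=1e-6, atol=1e-9)


def test_rotational_symmetry_of_centered_disc(small_geometry, grid64):
    """A centered disc gives identical traces: exactly so for elements
    related by the grid's 90-degree symmetries, and to within bilinear
    interpolation error for all other elements (the pixelized disc is
    only approximately rotation invariant at generic angles)."""
    yy, xx = np.mgrid[0:64, 0:64]
    r = np.hypot(yy - 31.5, xx - 31.5)
    disc = np.exp(-(r / 8.0) ** 4)        # sharp but band-limited edge
    traces = project(PressureMap(disc, grid64["dx"]),
                     small_geometry).traces
    scale = np.abs(traces).max()
    quarter = small_geometry.n_elements // 4
    sub = traces[::quarter]               # elements at 0/90/180/270 deg
    assert np.abs(sub - sub[0]).max() <= 1e-10 * scale
    assert np.abs(traces - traces[0]).max() <= 3e-2 * scale


def test_point_source_arrival_time(small_geometry, grid64):
    """Envelope peak of each trace sits at distance/(c dt)."""
    pt = np.zeros((64, 64))
    pt[32, 32] = 1.0
    sino = project(PressureMap(pt, grid64["dx"]), small_geometry)
    g = small_geometry
    pos = g.element_positions
    src = np.array([0.5 * grid64["dx"], -0.5 * grid64["dx"]])
    for e in [0, 13, 40]:
        env = np.abs(hilbert(sino.traces[e]))
        expected = np.linalg.norm(pos[e] - src) / (g.sound_speed * g.dt)
        assert abs(env.argmax() - expected) <= 1.0


def test_traces_quiet_before_first_arrival(small_geometry, grid64):
    pt = np.zeros((64, 64))
    pt[20, 40] = 1.0
    sino = project(PressureMap(pt, grid64["dx"]), small_geometry)
    g = small_geometry
    src = np.array([(40 - 31.5), (31.5 - 20)]) * grid64["dx"]
    halfwidth = 12   # impulse-response half-width in samples
    for e in [0, 21]:
        dist = np.linalg.norm(g.element_positions[e] - src)
        k_first = int(dist / (g.sound_speed * g.dt)) - halfwidth
        quiet = np.abs(sino.traces[e][:max(k_first, 0)])
        assert quiet.max() <= 1e-9 * np.abs(sino.traces[e]).max()


def test_adjoint_identity(rng, small_geometry, grid64):
    """<A x, y> == <x, A' y> to high precision, over random pairs."""
    g = small_geometry
    errs = []
    for _ in range(20):
        x = PressureMap(rng.random((64, 64)), grid64["dx"])
        y = rng.normal(size=(g.n_elements, g.n_time))
        ax = project(x, g).traces
        aty = adjoint(Sinogram(y, np.arange(g.n_elements), g), g, 64,
                      grid64["dx"]).grid
        lhs = float((ax * y).sum())
        rhs = float((x.grid * aty).sum())
        errs.append(abs(lhs - rhs) / abs(lhs))
    assert max(errs) < 1e-6


def test_adjoint_zero_and_backprojection_peak(small_geometry, grid64):
    g = small_geometry
    zero = Sinogram(np.zeros((g.n_elements, g.n_time)),
                    np.arange(g.n_elements), g)
    assert not adjoint(zero, g, 64, grid64["dx"]).grid.any()

    pt = np.zeros((64, 64))
    pt[25, 30] = 1.0
    sino = project(PressureMap(pt, grid64["dx"]), g)
    bp = adjoint(sino, g, 64, grid64["dx"]).grid
    peak = np.unravel_index(np.abs(bp).argmax(), bp.shape)
    assert np.hypot(peak[0] - 25, peak[1] - 30) <= 2.0


def test_noise_snr_calibration(rng, small_geometry, grid64):
    pm = PressureMap(rng.random((64, 64)), grid64["dx"])
    sino = project(pm, small_geometry)
    noisy = add_noise(sino, snr_db=40.0, seed=11)
    noise = noisy.traces - sino.traces
    assert noise.size > 1e4
    snr = 10 * np.log10((sino.traces ** 2).mean() / (noise ** 2).mean())
    assert abs(snr - 40.0) < 0.5

    again = add_noise(sino, snr_db=40.0, seed=11)
    assert np.array_equal(noisy.traces, again.traces)

    clean = add_noise(sino, snr_db=np.inf, seed=0)
    assert np.array_equal(clean.traces, sino.traces)

    silent = Sinogram(np.zeros_like(sino.traces), sino.view_indices,
                      small_geometry)
    with pytest.raises(ValueError):
        add_noise(silent, 40.0, 0)


def test_subsample_views_strides(rng, small_geometry):
    g = small_geometry
    sino = Sinogram(rng.normal(size=(g.n_elements, g.n_time)),
                    np.arange(g.n_elements), g)
    sub, mask = subsample_views(sino, 16)
    assert np.array_equal(sub.view_indices, np.arange(0, 64, 4))
    assert mask.full_count == 64
    assert np.array_equal(sub.traces, sino.traces[::4])

    full, _ = subsample_views(sino, 64)
    assert np.array_equal(full.traces, sino.traces)

    with pytest.raises(ValueError):
        subsample_views(sino, 7)


def test_rotating_phantom_permutes_traces(rng, grid64):
    """Rotating p0 by one inter-element angle cyclically shifts the
    sinogram (within bilinear-interpolation tolerance)."""
    g = default_geometry(64, grid64["dx"], n_elements=4,
                         center_frequency=2.5e6)
    base = np.zeros((64, 64))
    base[40, 40] = 1.0
    rot = np.rot90(base, -1).copy()   # rotate the phantom by -90 deg
    t_base = project(PressureMap(base, grid64["dx"]), g).traces
    t_rot = project(PressureMap(rot, grid64["dx"]), g).traces
    shifted = np.roll(t_base, -1, axis=0)
    scale = np.abs(t_base).max()
    assert np.abs(t_rot - shifted).max() < 1e-10 * scale
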