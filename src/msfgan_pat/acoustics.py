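"""Discrete circular-array photoacoustic forward operator.

The measurement model is y = A x + n.  A is factored as

    A = H  .  Dt  .  S

where S takes arc integrals of the initial pressure over circles of
radius c t centered at each transducer element (the 2-D spherical-mean,
computed by bilinear sampling with quadrature step <= 0.5 dx), Dt is a
centered finite-difference time derivative, and H convolves each trace
with a Gaussian-modulated sinusoid impulse response whose -6 dB
fractional bandwidth matches the transducer specification.  Each factor
has an exact transpose, so ``adjoint`` is the exact transpose of
``project`` as a linear map — verifiable through the inner-product
identity <A x, y> = <x, A' y>.

S is materialized once per (geometry, grid) as a sparse matrix per
element and cached, which makes repeated projection of many phantoms
cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .containers import PressureMap

__all__ = [
    "ArrayGeometry",
    "Sinogram",
    "ViewMask",
    "build_geometry",
    "default_geometry",
    "project",
    "adjoint",
    "add_noise",
    "subsample_views",
]


@dataclass(frozen=True)
class ArrayGeometry:
    """Ring-array geometry and acquisition parameters."""

    ring_radius: float            # meters
    n_elements: int
    center_frequency: float       # Hz
    fractional_bandwidth: float   # -6 dB fractional bandwidth, (0, 2)
    sound_speed: float            # m/s
    dt: float                     # seconds
    n_time: int

    def __post_init__(self):
        if self.n_elements < 4:
            raise ValueError("need at least 4 elements")
        if not (0.0 < self.fractional_bandwidth < 2.0):
            raise ValueError("fractional bandwidth must be in (0, 2)")
        for name in ("ring_radius", "center_frequency", "sound_speed", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_time < 2:
            raise ValueError("n_time must be >= 2")

    @property
    def element_angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_elements) / self.n_elements

    @property
    def element_positions(self) -> np.ndarray:
        a = self.element_angles
        return self.ring_radius * np.stack([np.cos(a), np.sin(a)], axis=1)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_time) * self.dt


def build_geometry(ring_radius: float, n_elements: int,
                   center_frequency: float, fractional_bandwidth: float,
                   sound_speed: float, dt: float,
                   n_time: int) -> ArrayGeometry:
    return ArrayGeometry(ring_radius, n_elements, center_frequency,
                         fractional_bandwidth, sound_speed, dt, n_time)


def default_geometry(grid_size: int, dx: float, n_elements: int = 256,
                     center_frequency: float = 5.5e6,
                     fractional_bandwidth: float = 0.8,
                     sound_speed: float = 1500.0,
                     margin: float = 1.10,
                     window_factor: float = 2.2) -> ArrayGeometry:
    """Geometry with the ring just enclosing the grid.

    dt is chosen so that c dt = dx (the recommended temporal sampling),
    and the time window covers ``window_factor`` times the ring diameter.
    """
    half_diag = (grid_size - 1) / 2 * dx * np.sqrt(2.0)
    ring_radius = margin * half_diag
    dt = dx / sound_speed
    n_time = int(np.ceil(window_factor * 2 * ring_radius
                         / (sound_speed * dt)))
    return ArrayGeometry(ring_radius, n_elements, center_frequency,
                         fractional_bandwidth, sound_speed, dt, n_time)


@dataclass
class Sinogram:
    """Detector-by-time pressure traces with view metadata."""

    traces: np.ndarray            # (n_views, n_time)
    view_indices: np.ndarray      # indices into the full element ring
    geometry: ArrayGeometry

    def __post_init__(self):
        self.traces = np.asarray(self.traces, dtype=np.float64)
        self.view_indices = np.asarray(self.view_indices, dtype=np.int64)
        if self.traces.ndim != 2:
            raise ValueError("traces must be (n_views, n_time)")
        if self.traces.shape[0] != self.view_indices.size:
            raise ValueError("view_indices length must match traces")
        if self.traces.shape[1] != self.geometry.n_time:
            raise ValueError("trace length must match geometry n_time")
        d = np.diff(self.view_indices)
        if self.view_indices.size and (np.any(d <= 0)
                                       or self.view_indices[0] < 0
                                       or self.view_indices[-1]
                                       >= self.geometry.n_elements):
            raise ValueError("view_indices must be strictly increasing and "
                             "within [0, n_elements)")

    @property
    def n_views(self) -> int:
        return self.traces.shape[0]


@dataclass(frozen=True)
class ViewMask:
    kept: tuple
    full_count: int


# ---------------------------------------------------------------------------
# arc-integral factor S (sparse, cached)
# ---------------------------------------------------------------------------

_ARC_CACHE: dict = {}


def _check_grid_in_ring(geom: ArrayGeometry, grid_size: int, dx: float):
    half_diag = (grid_size - 1) / 2 * dx * np.sqrt(2.0)
    if geom.ring_radius <= half_diag:
        raise ValueError(
            f"ring radius {geom.ring_radius:.4g} m does not enclose the "
            f"grid (half-diagonal {half_diag:.4g} m)")


def _arc_matrices(geom: ArrayGeometry, grid_size: int,
                  dx: float) -> list[sparse.csr_matrix]:
    """Per-element sparse matrices mapping p0 (flat) to arc integrals."""
    key = (id(geom), geom.ring_radius, geom.n_elements, geom.sound_speed,
           geom.dt, geom.n_time, grid_size, dx)
    # id() alone is unsafe across GC; include the physical parameters too
    key = key[1:]
    if key in _ARC_CACHE:
        return _ARC_CACHE[key]
    _check_grid_in_ring(geom, grid_size, dx)
    G = grid_size
    half = (G - 1) / 2.0
    c, dt = geom.sound_speed, geom.dt
    quad = 0.5 * dx                  # arc quadrature step
    mats = []
    corner = half * dx * np.sqrt(2.0)
    for e, (ex, ey) in enumerate(geom.element_positions):
        theta = geom.element_angles[e]
        dist_center = np.hypot(ex, ey)
        rho_min = max(dist_center - corner, 0.0)
        rho_max = dist_center + corner
        rows, cols, vals = [], [], []
        for k in range(geom.n_time):
            rho = c * k * dt
            if rho < rho_min - dx or rho > rho_max + dx:
                continue
            n_s = max(8, int(np.ceil(2 * np.pi * rho / quad)))
            # angles tied to the element's own frame so that the sampling
            # pattern is congruent for every element (rotational symmetry)
            phi = theta + np.pi + 2 * np.pi * np.arange(n_s) / n_s
            px = ex + rho * np.cos(phi)
            py = ey + rho * np.sin(phi)
            fx = px / dx + half          # column
            fy = half - py / dx          # row
            keep = ((fx >= 0) & (fx <= G - 1) & (fy >= 0) & (fy <= G - 1))
            if not np.any(keep):
                continue
            fx, fy = fx[keep], fy[keep]
            dl = rho * 2 * np.pi / n_s
            j0 = np.minimum(fx.astype(np.int64), G - 2)
            i0 = np.minimum(fy.astype(np.int64), G - 2)
            tx = fx - j0
            ty = fy - i0
            for di, dj, w in ((0, 0, (1 - ty) * (1 - tx)),
                              (0, 1, (1 - ty) * tx),
                              (1, 0, ty * (1 - tx)),
                              (1, 1, ty * tx)):
                rows.append(np.full(fx.size, k))
                cols.append((i0 + di) * G + (j0 + dj))
                vals.append(w * dl)
        if rows:
            m = sparse.csr_matrix(
                (np.concatenate(vals),
                 (np.concatenate(rows), np.concatenate(cols))),
                shape=(geom.n_time, G * G))
        else:
            m = sparse.csr_matrix((geom.n_time, G * G))
        mats.append(m)
    _ARC_CACHE[key] = mats
    return mats


# ---------------------------------------------------------------------------
# time derivative Dt and band-limiting H
# ---------------------------------------------------------------------------

def _time_derivative(traces: np.ndarray, dt: float) -> np.ndarray:
    out = np.zeros_like(traces)
    out[:, 1:-1] = (traces[:, 2:] - traces[:, :-2]) / (2.0 * dt)
    return out


def _time_derivative_T(traces: np.ndarray, dt: float) -> np.ndarray:
    out = np.zeros_like(traces)
    inner = traces[:, 1:-1] / (2.0 * dt)
    out[:, 2:] += inner
    out[:, :-2] -= inner
    return out


def impulse_response(geom: ArrayGeometry) -> np.ndarray:
    """Gaussian-modulated sinusoid with the geometry's -6 dB fractional
    bandwidth; symmetric (even) kernel, so H is self-adjoint."""
    fc = geom.center_frequency
    bw = geom.fractional_bandwidth
    sigma_f = bw * fc / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    half = max(1, int(np.ceil(3.0 * sigma_t / geom.dt)))
    t = np.arange(-half, half + 1) * geom.dt
    return np.exp(-t ** 2 / (2 * sigma_t ** 2)) * np.cos(2 * np.pi * fc * t)


def _bandlimit(traces: np.ndarray, h: np.ndarray) -> np.ndarray:
    out = np.empty_like(traces)
    for i in range(traces.shape[0]):
        out[i] = np.convolve(traces[i], h, mode="same")
    return out


# ---------------------------------------------------------------------------
# public operators
# ---------------------------------------------------------------------------

def project(p0: PressureMap, geom: ArrayGeometry) -> Sinogram:
    """Forward-project an initial pressure map to band-limited traces."""
    mats = _arc_matrices(geom, p0.grid_size, p0.dx)
    flat = p0.grid.ravel()
    arcs = np.stack([m @ flat for m in mats])
    d = _time_derivative(arcs, geom.dt)
    traces = _bandlimit(d, impulse_response(geom))
    return Sinogram(traces, np.arange(geom.n_elements), geom)


def adjoint(sino: Sinogram, geom: ArrayGeometry, grid_size: int,
            dx: float) -> PressureMap:
    """Exact transpose of ``project`` restricted to the recorded views."""
    if sino.geometry.n_time != geom.n_time:
        raise ValueError("sinogram/geometry n_time mismatch")
    mats = _arc_matrices(geom, grid_size, dx)
    h = impulse_response(geom)
    hb = _bandlimit(sino.traces, h)          # H is self-adjoint
    dtb = _time_derivative_T(hb, geom.dt)
    flat = np.zeros(grid_size * grid_size)
    for row, e in enumerate(sino.view_indices):
        flat += mats[e].T @ dtb[row]
    img = PressureMap.__new__(PressureMap)   # bypass [0,1] semantics
    img.grid = flat.reshape(grid_size, grid_size)
    img.dx = dx
    img.origin = (-(grid_size - 1) / 2 * dx, (grid_size - 1) / 2 * dx)
    return img


def add_noise(sino: Sinogram, snr_db: float, seed: int) -> Sinogram:
    """Add white Gaussian noise at the requested SNR (dB); inf = no-op."""
    if np.isinf(snr_db) and snr_db > 0:
        return Sinogram(sino.traces.copy(), sino.view_indices.copy(),
                        sino.geometry)
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite or +inf")
    p_sig = np.mean(sino.traces ** 2)
    if p_sig == 0:
        raise ValueError("signal power is zero; SNR undefined")
    p_noise = p_sig / (10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, np.sqrt(p_noise), size=sino.traces.shape)
    return Sinogram(sino.traces + noise, sino.view_indices.copy(),
                    sino.geometry)


def subsample_views(sino: Sinogram, n_keep: int) -> tuple[Sinogram, ViewMask]:
    """Keep every (n/n_keep)-th element starting at index 0."""
    n = sino.geometry.n_elements
    if sino.n_views != n:
        raise ValueError("subsampling expects a full-view sinogram")
    if n_keep <= 0 or n % n_keep:
        raise ValueError(f"n_keep={n_keep} must divide n_elements={n}")
    stride = n // n_keep
    kept = np.arange(0, n, stride)
    sub = Sinogram(sino.traces[kept].copy(), kept, sino.geometry)
    return sub, ViewMask(tuple(int(k) for k in kept), n)
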