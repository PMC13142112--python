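"""Seeded synthetic initial-pressure phantoms and dataset assembly.

Two phantom families are provided:

* branching vascular trees grown by a random walk (heading perturbed by
  Gaussian noise each step, branching with a fixed per-step probability,
  radius multiplied by ``radius_decay`` at branch points), rasterized
  with a Gaussian cross-profile on a 2x supersampled canvas;
* torso-like maps: an elliptical body with an elevated-intensity skin
  boundary, a few smooth internal organ-like regions, and superimposed
  vessels.

Every generator output is a pure function of (config, seed) and lies in
[0, 1].  ``build_dataset`` writes phantoms to an HDF5 container and
splits them train/val/test with seeded assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np

from .containers import PressureMap

__all__ = [
    "PhantomConfig",
    "DatasetIndex",
    "generate_vessel_phantom",
    "generate_torso_phantom",
    "generate_phantom",
    "build_dataset",
    "load_phantoms",
]

_SS = 2  # supersampling factor for anti-aliased rasterization


@dataclass(frozen=True)
class PhantomConfig:
    grid_size: int = 256
    n_trunks: int = 3
    branch_probability: float = 0.04   # per walk step
    radius_decay: float = 0.72
    min_radius: float = 0.7            # pixels, at output resolution
    max_radius: float = 4.0
    torso_mode: bool = False
    background_level: float = 0.0
    n_organs: tuple[int, int] = (2, 6)  # inclusive range, torso mode only

    def __post_init__(self):
        if self.grid_size < 32:
            raise ValueError("grid_size must be >= 32")
        if not (0.0 <= self.branch_probability <= 1.0):
            raise ValueError("branch_probability must be in [0, 1]")
        if not (0.0 < self.radius_decay < 1.0):
            raise ValueError("radius_decay must be in (0, 1)")
        if self.min_radius <= 0 or self.max_radius < self.min_radius:
            raise ValueError("need 0 < min_radius <= max_radius")
        if not (0.0 <= self.background_level <= 1.0):
            raise ValueError("background_level must be in [0, 1]")
        if self.n_trunks < 0:
            raise ValueError("n_trunks must be >= 0")


@dataclass
class DatasetIndex:
    entries: list[tuple[int, str, str]]   # (phantom id, file path, split)
    seed: int

    def ids(self, split: str) -> list[int]:
        return [i for i, _, s in self.entries if s == split]

    @property
    def path(self) -> str:
        return self.entries[0][1] if self.entries else ""


def _stamp(canvas: np.ndarray, cx: float, cy: float, radius: float):
    """Max-combine a Gaussian cross-profile disc into the canvas."""
    G = canvas.shape[0]
    sigma = max(radius * 0.55, 0.45)
    ext = int(np.ceil(3 * sigma))
    i0, i1 = int(cy) - ext, int(cy) + ext + 1
    j0, j1 = int(cx) - ext, int(cx) + ext + 1
    i0c, i1c = max(i0, 0), min(i1, G)
    j0c, j1c = max(j0, 0), min(j1, G)
    if i0c >= i1c or j0c >= j1c:
        return
    ii = np.arange(i0c, i1c)[:, None] - cy
    jj = np.arange(j0c, j1c)[None, :] - cx
    patch = np.exp(-(ii ** 2 + jj ** 2) / (2 * sigma ** 2))
    np.maximum(canvas[i0c:i1c, j0c:j1c], patch,
               out=canvas[i0c:i1c, j0c:j1c])


def _grow_tree(canvas: np.ndarray, rng: np.random.Generator,
               start: tuple[float, float], heading: float, radius: float,
               cfg: PhantomConfig, scale: int):
    """Random-walk vessel growth with branching; draws onto canvas."""
    G = canvas.shape[0]
    min_r = cfg.min_radius * scale
    queue = [(start[0], start[1], heading, radius)]
    segments = 0
    while queue and segments < 64:
        x, y, h, r = queue.pop()
        segments += 1
        steps = 0
        max_steps = int(2.2 * G)
        while r >= min_r and steps < max_steps:
            steps += 1
            x += np.cos(h)
            y += np.sin(h)
            if not (0 <= x < G and 0 <= y < G):
                break
            _stamp(canvas, x, y, r)
            h += rng.normal(0.0, 0.12)
            if rng.random() < cfg.branch_probability:
                r *= cfg.radius_decay
                split = rng.uniform(0.35, 0.9)
                side = 1.0 if rng.random() < 0.5 else -1.0
                queue.append((x, y, h - side * split, r))
                h += side * split * 0.5


def generate_vessel_phantom(config: PhantomConfig, seed: int) -> PressureMap:
    """A connected branching vessel tree; deterministic per (config, seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E55E1]))
    G = config.grid_size * _SS
    canvas = np.zeros((G, G))
    for _ in range(config.n_trunks):
        ang = rng.uniform(0, 2 * np.pi)
        rad0 = 0.44 * G
        cx = G / 2 + rad0 * np.cos(ang)
        cy = G / 2 + rad0 * np.sin(ang)
        heading = ang + np.pi + rng.uniform(-0.5, 0.5)
        r = rng.uniform(0.6, 1.0) * config.max_radius * _SS
        _grow_tree(canvas, rng, (cx, cy), heading, r, config, _SS)
    out = canvas.reshape(config.grid_size, _SS, config.grid_size,
                         _SS).mean(axis=(1, 3))
    if config.background_level > 0:
        out = np.maximum(out, config.background_level)
    return PressureMap(np.clip(out, 0.0, 1.0), dx=1.0)


def generate_torso_phantom(config: PhantomConfig, seed: int) -> PressureMap:
    """Elliptical body with skin ring, organ-like blobs, and vessels."""
    if not config.torso_mode:
        raise ValueError("torso_mode must be enabled for torso phantoms")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x70_50]))
    G = config.grid_size * _SS
    yy, xx = np.mgrid[0:G, 0:G]
    cx = G / 2 + rng.uniform(-0.02, 0.02) * G
    cy = G / 2 + rng.uniform(-0.02, 0.02) * G
    a = rng.uniform(0.30, 0.38) * G
    b = rng.uniform(0.26, 0.34) * G
    rot = rng.uniform(0, np.pi)
    xr = (xx - cx) * np.cos(rot) + (yy - cy) * np.sin(rot)
    yr = -(xx - cx) * np.sin(rot) + (yy - cy) * np.cos(rot)
    f = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    body = f <= 1.0
    ring_width = 0.012 * G
    skin = 0.9 * np.exp(-((f - 1.0) * min(a, b) / ring_width) ** 2)
    canvas = np.where(body, config.background_level, 0.0) + skin
    lo, hi = config.n_organs
    n_org = int(rng.integers(lo, hi + 1)) if hi >= lo and hi > 0 else 0
    for _ in range(n_org):
        oa = rng.uniform(0, 2 * np.pi)
        od = rng.uniform(0.0, 0.55)
        ox = cx + od * a * np.cos(oa)
        oy = cy + od * b * np.sin(oa)
        osig = rng.uniform(0.05, 0.13) * G
        amp = rng.uniform(0.25, 0.6)
        blob = amp * np.exp(-((xx - ox) ** 2 + (yy - oy) ** 2)
                            / (2 * osig ** 2))
        canvas = np.maximum(canvas, np.where(body, blob, 0.0))
    if config.n_trunks > 0:
        vessels = np.zeros((G, G))
        for _ in range(config.n_trunks):
            ang = rng.uniform(0, 2 * np.pi)
            vx = cx + 0.8 * a * np.cos(ang)
            vy = cy + 0.8 * b * np.sin(ang)
            heading = ang + np.pi + rng.uniform(-0.4, 0.4)
            r = rng.uniform(0.5, 1.0) * config.max_radius * _SS
            _grow_tree(vessels, rng, (vx, vy), heading, r, config, _SS)
        canvas = np.maximum(canvas, np.where(body, vessels, 0.0))
    out = canvas.reshape(config.grid_size, _SS, config.grid_size,
                         _SS).mean(axis=(1, 3))
    return PressureMap(np.clip(out, 0.0, 1.0), dx=1.0)


def generate_phantom(config: PhantomConfig, seed: int) -> PressureMap:
    if config.torso_mode:
        return generate_torso_phantom(config, seed)
    return generate_vessel_phantom(config, seed)


def _split_sizes(n: int, ratios: tuple[float, float, float]) -> list[int]:
    sizes = [int(round(n * r)) for r in ratios]
    sizes[0] += n - sum(sizes)        # remainder goes to the train split
    if min(sizes) < 0:
        raise ValueError("ratios produce a negative split size")
    return sizes


def build_dataset(n: int, ratios: tuple[float, float, float], seed: int,
                  out_path, config: PhantomConfig | None = None,
                  dx: float = 1e-4) -> DatasetIndex:
    """Generate ``n`` phantoms, write them to HDF5, assign splits 8:1:1
    (or any requested ratios) with a seeded shuffle."""
    if n < 10:
        raise ValueError("need n >= 10")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    config = config or PhantomConfig()
    sizes = _split_sizes(n, ratios)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDA7A]))
    perm = rng.permutation(n)
    split_of = {}
    start = 0
    for label, size in zip(("train", "val", "test"), sizes):
        for i in perm[start:start + size]:
            split_of[int(i)] = label
        start += size
    out_path = Path(out_path)
    entries = []
    try:
        f = h5py.File(out_path, "w")
    except OSError as exc:
        raise OSError(f"cannot write dataset to {out_path}") from exc
    with f:
        grp = f.create_group("phantoms")
        for i in range(n):
            pm = generate_phantom(config, seed=seed * 1_000_003 + i)
            ds = grp.create_dataset(str(i), data=pm.grid.astype(np.float32))
            ds.attrs["dx"] = dx
            ds.attrs["seed"] = seed * 1_000_003 + i
            entries.append((i, str(out_path), split_of[i]))
        idx = f.create_group("index")
        idx.create_dataset("ids", data=np.arange(n))
        idx.create_dataset(
            "split", data=np.array([split_of[i] for i in range(n)],
                                   dtype="S5"))
        idx.attrs["seed"] = seed
        idx.attrs["grid_size"] = config.grid_size
        idx.attrs["dx"] = dx
    return DatasetIndex(entries, seed)


def load_index(path) -> DatasetIndex:
    with h5py.File(path, "r") as f:
        ids = f["index/ids"][...]
        split = [s.decode() for s in f["index/split"][...]]
        seed = int(f["index"].attrs["seed"])
    return DatasetIndex([(int(i), str(path), s) for i, s in zip(ids, split)],
                        seed)


def load_phantoms(index: DatasetIndex, split: str | None = None
                  ) -> tuple[np.ndarray, float, list[int]]:
    """Load phantom grids for a split; returns (stack, dx, ids)."""
    wanted = [i for i, _, s in index.entries if split is None or s == split]
    with h5py.File(index.path, "r") as f:
        dx = float(f["index"].attrs["dx"])
        grids = np.stack([f[f"phantoms/{i}"][...] for i in wanted])
    return grids.astype(np.float64), dx, wanted
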