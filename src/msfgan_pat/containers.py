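"""Shared image containers for the reconstruction pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PressureMap", "ReconImage"]


@dataclass
class PressureMap:
    """Ground-truth initial pressure p0 on a square 2-D grid.

    ``grid`` holds unitless normalized pressure in [0, 1]; ``dx`` is the
    pixel pitch in meters.  The physical origin is the grid center:
    pixel (i, j) sits at x = (j - (G-1)/2) dx, y = ((G-1)/2 - i) dx.
    """

    grid: np.ndarray
    dx: float
    origin: tuple[float, float] = field(default=None)  # coord of pixel (0,0)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("pressure map must be square 2-D")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.origin is None:
            g = self.grid.shape[0]
            self.origin = (-(g - 1) / 2 * self.dx, (g - 1) / 2 * self.dx)

    @property
    def grid_size(self) -> int:
        return self.grid.shape[0]


@dataclass
class ReconImage:
    """A reconstructed image on the p0 grid (DAS, network, or reference)."""

    grid: np.ndarray
    dx: float
    provenance: str = "das"          # {das, network, ground_truth}
    view_count: int = 0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 2:
            raise ValueError("recon image must be 2-D")
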