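"""Shared fixtures and numerical-gradient helpers."""

from __future__ import annotations

import numpy as np
import pytest

from msfgan_pat.acoustics import default_geometry


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x0 = x[i]
        x[i] = x0 + eps
        fp = f()
        x[i] = x0 - eps
        fm = f()
        x[i] = x0
        g[i] = (fp - fm) / (2 * eps)
    return g


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_geometry():
    """64-element ring around a 64x64 grid at 0.1 mm pitch, 2.5 MHz."""
    return default_geometry(64, 1e-4, n_elements=64,
                            center_frequency=2.5e6)


@pytest.fixture(scope="session")
def grid64():
    return {"grid_size": 64, "dx": 1e-4}
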