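"""Quantitative evaluation: PSNR, SSIM, error maps, FWHM resolution.

PSNR uses a fixed data range of 1.0 on min-max normalized images and
caps identical pairs at 99 dB.  SSIM is the standard Gaussian-window
form (11x11, sigma=1.5, K1=0.01, K2=0.03).  Aggregated reports carry
mean +/- (n-1)-denominator standard deviation and the derived pairwise
differences and relative gains in percent, the arithmetic used when
comparing reconstruction methods on a shared test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .containers import ReconImage

__all__ = [
    "PSNR_CAP_DB",
    "psnr",
    "ssim",
    "error_map",
    "fwhm",
    "relative_gain",
    "MetricReport",
    "evaluate",
    "theoretical_axial_resolution",
    "sampling_reduction_percent",
]

PSNR_CAP_DB = 99.0


def _grid(a) -> np.ndarray:
    return a.grid if isinstance(a, ReconImage) else np.asarray(a, float)


def psnr(a, b, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio, 10 log10(R^2 / MSE), in dB."""
    ga, gb = _grid(a), _grid(b)
    if ga.shape != gb.shape:
        raise ValueError("shape mismatch")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((ga - gb) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(10.0 * np.log10(data_range ** 2 / mse), PSNR_CAP_DB)


def ssim(a, b) -> float:
    """Mean local structural similarity (Gaussian 11x11 window,
    sigma=1.5, K1=0.01, K2=0.03, data range 1)."""
    ga, gb = _grid(a), _grid(b)
    if ga.shape != gb.shape:
        raise ValueError("shape mismatch")
    if min(ga.shape) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    return float(structural_similarity(
        ga, gb, data_range=1.0, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03))


def error_map(x_hat, x_ref) -> np.ndarray:
    """Signed difference image x_hat - x_ref."""
    ga, gb = _grid(x_hat), _grid(x_ref)
    if ga.shape != gb.shape:
        raise ValueError("shape mismatch")
    return ga - gb


def fwhm(profile: np.ndarray, dx: float = 1.0) -> float:
    """Full width at half maximum of a 1-D profile, by linear
    interpolation of the half-maximum crossings, scaled by ``dx``."""
    p = np.asarray(profile, float)
    if p.ndim != 1 or p.size < 3:
        raise ValueError("need a 1-D profile with at least 3 samples")
    k = int(np.argmax(p))
    peak = p[k]
    background = np.median(np.concatenate([p[: max(p.size // 10, 1)],
                                           p[-max(p.size // 10, 1):]]))
    if not peak > 2 * abs(background) or peak <= 0:
        raise ValueError("profile lacks a clear maximum above background")
    half = peak / 2.0

    def cross(idx_range):
        for i in idx_range:
            if p[i] < half <= p[i + 1] or p[i] >= half > p[i + 1]:
                # linear interpolation between samples i and i+1
                return i + (half - p[i]) / (p[i + 1] - p[i])
        raise ValueError("no half-maximum crossing found")

    left = cross(range(k - 1, -1, -1))
    right = cross(range(k, p.size - 1))
    return float((right - left) * dx)


def relative_gain(a: float, b: float) -> float:
    """100 * (a - b) / b, rounded to 3 decimals."""
    return round(100.0 * (a - b) / b, 3)


@dataclass
class MetricReport:
    records: dict = field(default_factory=dict)
    # records[method] = {psnr_mean, psnr_std, ssim_mean, ssim_std, n}

    def add(self, method: str, psnrs, ssims):
        psnrs = np.asarray(psnrs, float)
        ssims = np.asarray(ssims, float)
        if psnrs.size != ssims.size or psnrs.size < 1:
            raise ValueError("need matched, nonempty metric lists")
        n = psnrs.size
        self.records[method] = {
            "psnr_mean": float(psnrs.mean()),
            "psnr_std": float(psnrs.std(ddof=1)) if n > 1 else None,
            "ssim_mean": float(ssims.mean()),
            "ssim_std": float(ssims.std(ddof=1)) if n > 1 else None,
            "n": int(n),
        }

    def difference(self, a: str, b: str, metric: str = "psnr") -> float:
        return round(self.records[a][f"{metric}_mean"]
                     - self.records[b][f"{metric}_mean"], 3)

    def gain_percent(self, a: str, b: str, metric: str = "psnr") -> float:
        return relative_gain(self.records[a][f"{metric}_mean"],
                             self.records[b][f"{metric}_mean"])


def evaluate(outputs: dict, ground_truths) -> MetricReport:
    """Per-method PSNR/SSIM against paired ground truths.

    ``outputs``: {method name: list of images}; images and ground
    truths are paired by position.
    """
    report = MetricReport()
    truths = list(ground_truths)
    for method, imgs in outputs.items():
        imgs = list(imgs)
        if len(imgs) != len(truths):
            raise ValueError(f"{method}: length mismatch")
        ps = [psnr(i, t) for i, t in zip(imgs, truths)]
        ss = [ssim(i, t) for i, t in zip(imgs, truths)]
        report.add(method, ps, ss)
    return report


def theoretical_axial_resolution(center_frequency: float,
                                 fractional_bandwidth: float = 0.8,
                                 sound_speed: float = 1540.0) -> float:
    """Axial resolution c / (2 delta-f) in meters, with the detection
    bandwidth delta-f = fractional_bandwidth * center frequency and the
    soft-tissue sound speed 1540 m/s."""
    if center_frequency <= 0 or fractional_bandwidth <= 0:
        raise ValueError("frequency and bandwidth must be positive")
    return sound_speed / (2.0 * fractional_bandwidth * center_frequency)


def sampling_reduction_percent(n_views: int, n_full: int = 256) -> int:
    """Acquisition reduction 1 - views/full as a nearest-integer percent."""
    if not (0 < n_views <= n_full):
        raise ValueError("need 0 < n_views <= n_full")
    return int(round(100.0 * (1.0 - n_views / n_full)))
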