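"""Structure-aware U-Net discriminator with channel-attention skips.

The discriminator scores an image with a spatially resolved realness
map S at the input resolution, giving the adversarial game both pixel-
and global-level feedback.  Encoder stages are stride-2 convolutions
with spectral normalization and LeakyReLU; the decoder mirrors them
with bilinear x2 upsampling.  Each skip connection is gated by a
channel attention module (CAM): global average- and max-pooled channel
descriptors pass through a shared two-layer gate, and the sigmoid
attention map rescales the encoder feature before it is added to the
upsampled decoder feature.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import Module, SNConv2d, power_iteration_sigma

__all__ = ["DiscriminatorConfig", "ChannelAttention", "Discriminator",
           "spectral_normalize"]


@dataclass(frozen=True)
class DiscriminatorConfig:
    widths: tuple[int, ...] = (64, 128, 256)
    cam_reduction: int = 8
    leaky_slope: float = 0.2
    use_cam: bool = True

    def __post_init__(self):
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be positive")
        if any(a > b for a, b in zip(self.widths, self.widths[1:])):
            raise ValueError("widths must be non-decreasing")

    @property
    def n_levels(self) -> int:
        return len(self.widths)

    def to_dict(self) -> dict:
        return asdict(self)


def spectral_normalize(weight: np.ndarray, n_iter: int = 1,
                       u: np.ndarray | None = None) -> np.ndarray:
    """Divide a weight by its largest singular value (power iteration).

    A zero weight is returned unchanged (no division).
    """
    sigma, _, _ = power_iteration_sigma(weight, n_iter=n_iter, u=u)
    if sigma == 0.0:
        return weight.copy()
    return weight / sigma


class ChannelAttention(Module):
    """CAM skip gate: sigmoid(W2 L(W1 avg) + W2 L(W1 max)), shared gate."""

    def __init__(self, channels: int, cfg: DiscriminatorConfig,
                 rng: np.random.Generator):
        super().__init__()
        hidden = max(channels // cfg.cam_reduction, 1)
        self.slope = cfg.leaky_slope
        # L(.) = 1x1 conv + spectral norm + LeakyReLU on pooled vectors
        self.w1 = SNConv2d(channels, hidden, 1, rng)
        self.w2 = SNConv2d(hidden, channels, 1, rng)

    def attention(self, x: Tensor) -> Tensor:
        favg = ag.tmean(x, axis=(2, 3), keepdims=True)   # (C, N, 1, 1)
        fmax = ag.tmax(x, axis=(2, 3), keepdims=True)
        ha = ag.leaky_relu(self.w1(favg), self.slope)
        hm = ag.leaky_relu(self.w1(fmax), self.slope)
        return ag.sigmoid(self.w2(ha) + self.w2(hm))

    def forward(self, x: Tensor) -> Tensor:
        return x * self.attention(x)


class _UpStage(Module):
    """Bilinear x2 upsampling + SN conv + LeakyReLU."""

    def __init__(self, cin: int, cout: int, slope: float,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = SNConv2d(cin, cout, 3, rng)
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return ag.leaky_relu(self.conv(ag.bilinear_upsample2x(x)),
                             self.slope)


class Discriminator(Module):
    def __init__(self, cfg: DiscriminatorConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD15C]))
        widths = cfg.widths
        self.enc = []
        cin = 1
        for w in widths:
            self.enc.append(SNConv2d(cin, w, 3, rng, stride=2))
            cin = w
        self.cams = ([ChannelAttention(w, cfg, rng) for w in widths[:-1]]
                     if cfg.use_cam else [])
        self.dec = []
        for i in range(len(widths) - 1, 0, -1):
            self.dec.append(_UpStage(widths[i], widths[i - 1],
                                     cfg.leaky_slope, rng))
        self.final_up = _UpStage(widths[0], widths[0], cfg.leaky_slope, rng)
        self.out_conv = SNConv2d(widths[0], 1, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("input must be (N, 1, H, W)")
        side = x.shape[2]
        if side % (2 ** self.cfg.n_levels):
            raise ValueError(
                f"side {side} must be divisible by {2 ** self.cfg.n_levels}")
        skips = []
        f = ag.transpose(x, (1, 0, 2, 3))    # internal (C, N, H, W)
        for conv in self.enc:
            f = ag.leaky_relu(conv(f), self.cfg.leaky_slope)
            skips.append(f)
        d = skips[-1]
        for i, stage in enumerate(self.dec):
            level = len(self.enc) - 2 - i
            skip = skips[level]
            if self.cfg.use_cam:
                skip = self.cams[level](skip)
            d = stage(d) + skip
        d = self.final_up(d)
        return ag.transpose(self.out_conv(d), (1, 0, 2, 3))
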