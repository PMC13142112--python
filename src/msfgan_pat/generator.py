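"""Artifact-removal generator with pyramid squeeze attention (PSA).

The generator maps a sparse-view DAS image x0 to an enhanced image
x-hat.  Structure:

* shallow encoding: 3x3 conv + PReLU;
* (scale_mode="same") two stride-2 conv+PReLU reducers, mirroring the
  two x2 sub-pixel units so that input and output grids match;
* B feature-enhance blocks.  Each block applies the PSA module — a 1x1
  conv+BN+ReLU channel remap, four parallel conv branches with
  different kernel sizes producing Cb channels each, per-branch
  squeeze-and-excitation channel gates, a per-channel softmax across
  the four scales, concatenation and a 1x1 conv+BN+ReLU back to C
  channels, plus an inner residual — followed by conv+BN and an outer
  residual (Fe = F0 + Fr);
* a trunk conv+BN with a global skip from the reduced head features;
* two sub-pixel (conv + pixel-shuffle r=2 + PReLU) upsampling units;
* a final 3x3 conv to one channel.

All sizes are configurable; the defaults (C=64, B=8, kernels 3/5/7/9,
Cb=C/4, SE reduction 4) follow the pyramid-squeeze-attention design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import BatchNorm2d, Conv2d, Module, PReLU, Dense

__all__ = ["GeneratorConfig", "SqueezeExcite", "PSABlock",
           "FeatureEnhanceBlock", "Generator"]


@dataclass(frozen=True)
class GeneratorConfig:
    base_channels: int = 64          # C
    n_blocks: int = 8                # B
    branch_kernels: tuple[int, int, int, int] = (3, 5, 7, 9)
    branch_channels: int | None = None   # Cb; default C // 4
    se_reduction: int = 4
    scale_mode: str = "same"         # {"same", "sr4"}
    use_psa: bool = True
    inner_residual: bool = True
    outer_residual: bool = True

    def __post_init__(self):
        if self.scale_mode not in ("same", "sr4"):
            raise ValueError("scale_mode must be 'same' or 'sr4'")
        if any(k % 2 == 0 for k in self.branch_kernels):
            raise ValueError("branch kernels must be odd")
        if self.branch_channels is None and self.base_channels % 4:
            raise ValueError("base_channels must be divisible by 4 when "
                             "branch_channels is not given")

    @property
    def cb(self) -> int:
        return (self.branch_channels if self.branch_channels is not None
                else self.base_channels // 4)

    def to_dict(self) -> dict:
        return asdict(self)


class SqueezeExcite(Module):
    """Channel gate: global average pool -> W2 relu(W1 z) -> sigmoid."""

    def __init__(self, channels: int, reduction: int,
                 rng: np.random.Generator):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = Dense(channels, hidden, rng)
        self.fc2 = Dense(hidden, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        # x is (Cb, N, H, W); the gate works on per-sample descriptors
        z = ag.transpose(ag.tmean(x, axis=(2, 3)), (1, 0))   # (N, Cb)
        return ag.sigmoid(self.fc2(ag.relu(self.fc1(z))))


class PSABlock(Module):
    """Pyramid squeeze attention with scale softmax and inner residual."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        super().__init__()
        C, Cb = cfg.base_channels, cfg.cb
        self.inner_residual = cfg.inner_residual
        self.remap = Conv2d(C, C, 1, rng, bias=False)
        self.bn0 = BatchNorm2d(C)
        self.branches = [Conv2d(C, Cb, k, rng) for k in cfg.branch_kernels]
        self.gates = [SqueezeExcite(Cb, cfg.se_reduction, rng)
                      for _ in cfg.branch_kernels]
        self.fuse = Conv2d(4 * Cb, C, 1, rng, bias=False)
        self.bn1 = BatchNorm2d(C)

    def scale_weights(self, x: Tensor) -> list[Tensor]:
        """Per-channel softmax-normalized multipliers across the 4 scales."""
        t = ag.relu(self.bn0(self.remap(x)))
        logits = []
        feats = []
        for conv, gate in zip(self.branches, self.gates):
            f = conv(t)
            feats.append(f)
            logits.append(gate(f))                   # (N, Cb), in (0,1)
        exp = [ag.texp(a) for a in logits]
        total = exp[0]
        for e in exp[1:]:
            total = total + e
        weights = [e * ag.power(total, -1.0) for e in exp]
        return feats, weights

    def forward(self, x: Tensor) -> Tensor:
        feats, weights = self.scale_weights(x)
        scaled = [f * ag.reshape(ag.transpose(w, (1, 0)),
                                 (w.shape[1], w.shape[0], 1, 1))
                  for f, w in zip(feats, weights)]
        fused = ag.relu(self.bn1(self.fuse(ag.concat(scaled, axis=0))))
        return x + fused if self.inner_residual else fused


class PlainBlock(Module):
    """Conv+BN+ReLU stand-in used when the PSA module is ablated."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        super().__init__()
        C = cfg.base_channels
        self.conv = Conv2d(C, C, 3, rng, bias=False)
        self.bn = BatchNorm2d(C)

    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(self.bn(self.conv(x)))


class FeatureEnhanceBlock(Module):
    """PSA -> conv+BN, with the outer residual Fe = F0 + Fr."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        super().__init__()
        C = cfg.base_channels
        self.outer_residual = cfg.outer_residual
        self.psa = (PSABlock(cfg, rng) if cfg.use_psa
                    else PlainBlock(cfg, rng))
        self.conv = Conv2d(C, C, 3, rng, bias=False)
        self.bn = BatchNorm2d(C)

    def forward(self, x: Tensor) -> Tensor:
        fr = self.bn(self.conv(self.psa(x)))
        return x + fr if self.outer_residual else fr


class SubPixelUnit(Module):
    """Conv to 4x channels, pixel shuffle (r=2), PReLU: doubles H and W."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(channels, 4 * channels, 3, rng)
        self.act = PReLU(channels)

    def forward(self, x: Tensor) -> Tensor:
        return self.act(ag.pixel_shuffle(self.conv(x), 2))


class Generator(Module):
    def __init__(self, cfg: GeneratorConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E4]))
        C = cfg.base_channels
        self.head = Conv2d(1, C, 3, rng)
        self.head_act = PReLU(C)
        if cfg.scale_mode == "same":
            self.reducers = [Conv2d(C, C, 3, rng, stride=2)
                             for _ in range(2)]
            self.reducer_acts = [PReLU(C) for _ in range(2)]
        else:
            self.reducers = []
            self.reducer_acts = []
        self.blocks = [FeatureEnhanceBlock(cfg, rng)
                       for _ in range(cfg.n_blocks)]
        self.trunk_conv = Conv2d(C, C, 3, rng, bias=False)
        self.trunk_bn = BatchNorm2d(C)
        self.up = [SubPixelUnit(C, rng) for _ in range(2)]
        self.tail = Conv2d(C, 1, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("input must be (N, 1, H, W)")
        if x.shape[2] != x.shape[3]:
            raise ValueError("input must be square")
        if self.cfg.scale_mode == "same" and x.shape[2] % 4:
            raise ValueError("side must be divisible by 4 in 'same' mode")
        f = ag.transpose(x, (1, 0, 2, 3))            # internal (C, N, H, W)
        f = self.head_act(self.head(f))
        for conv, act in zip(self.reducers, self.reducer_acts):
            f = act(conv(f))
        base = f                                     # reduced head features
        for block in self.blocks:
            f = block(f)
        f = self.trunk_bn(self.trunk_conv(f)) + base  # global skip
        for unit in self.up:
            f = unit(f)
        return ag.transpose(self.tail(f), (1, 0, 2, 3))
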