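"""Validated run configuration (YAML) for the command-line interface.

Every section is validated against the module schemas before any
computation runs; unknown keys are rejected with the offending key
named.  The effective (defaults-filled) configuration is echoed to the
output directory so each run is reproducible from its echo plus seed.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .discriminator import DiscriminatorConfig
from .generator import GeneratorConfig
from .losses import LossWeights
from .phantom import PhantomConfig
from .training import TrainConfig

__all__ = ["RunConfig", "parse_config", "echo_config", "config_hash",
           "stack_slices"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Section):
    grid_size: int = 256
    n_trunks: int = 3
    branch_probability: float = 0.04
    radius_decay: float = 0.72
    min_radius: float = 0.7
    max_radius: float = 4.0
    torso_mode: bool = False
    background_level: float = 0.0

    def build(self) -> PhantomConfig:
        return PhantomConfig(**self.model_dump())


class GeometrySection(_Section):
    n_elements: int = 256
    center_frequency: float = 5.5e6
    fractional_bandwidth: float = 0.8
    sound_speed: float = 1500.0
    dx: float = 2.2e-5
    ring_radius: float | None = None   # default: just enclosing the grid


class DasSection(_Section):
    envelope: bool = False
    bandpass_low: float | None = None
    bandpass_high: float | None = None


class GeneratorSection(_Section):
    base_channels: int = 64
    n_blocks: int = 8
    branch_kernels: tuple[int, int, int, int] = (3, 5, 7, 9)
    se_reduction: int = 4
    scale_mode: str = "same"

    def build(self) -> GeneratorConfig:
        return GeneratorConfig(**self.model_dump())


class DiscriminatorSection(_Section):
    widths: tuple[int, ...] = (64, 128, 256)
    cam_reduction: int = 8
    leaky_slope: float = 0.2

    def build(self) -> DiscriminatorConfig:
        return DiscriminatorConfig(**self.model_dump())


class LossSection(_Section):
    gamma1: float = Field(0.5, ge=0)
    gamma2: float = Field(1.0, ge=0)
    lambda1: float = Field(1.0, ge=0)
    lambda2: float = Field(0.8, ge=0)

    def build(self) -> LossWeights:
        return LossWeights(**self.model_dump())


class TrainSection(_Section):
    epochs: int = 200
    batch_size: int = 8
    lr0: float = 1e-4
    beta1: float = 0.9
    halving_epoch: int = 150
    augment: bool = True
    pixel_weight: float = 100.0
    use_psa: bool = True
    use_cam_discriminator: bool = True
    use_dual_gradient_loss: bool = True
    inner_residual: bool = True
    outer_residual: bool = True

    def build(self, seed: int) -> TrainConfig:
        return TrainConfig(seed=seed, **self.model_dump())


class EvalSection(_Section):
    data_range: float = 1.0


class RunConfig(_Section):
    seed: int = 0
    out_dir: str = "runs/default"
    phantom: PhantomSection = Field(default_factory=PhantomSection)
    geometry: GeometrySection = Field(default_factory=GeometrySection)
    das: DasSection = Field(default_factory=DasSection)
    generator: GeneratorSection = Field(default_factory=GeneratorSection)
    discriminator: DiscriminatorSection = Field(
        default_factory=DiscriminatorSection)
    loss: LossSection = Field(default_factory=LossSection)
    train: TrainSection = Field(default_factory=TrainSection)
    eval: EvalSection = Field(default_factory=EvalSection)


class ConfigError(ValueError):
    pass


def parse_config(path) -> RunConfig:
    """Load and validate a YAML config; empty file -> all defaults."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        keys = ", ".join(".".join(str(p) for p in e["loc"])
                         for e in exc.errors())
        raise ConfigError(f"invalid configuration key(s): {keys}") from exc


def echo_config(cfg: RunConfig, out_dir) -> Path:
    """Write the effective configuration to ``out_dir``/config.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "config.yaml"
    path.write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
    return path


def config_hash(cfg: RunConfig) -> str:
    payload = yaml.safe_dump(cfg.model_dump(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def stack_slices(images) -> "np.ndarray":
    """Stack same-shape 2-D slices into an H x W x N volume, preserving
    acquisition order."""
    import numpy as np
    from .containers import ReconImage
    grids = [im.grid if isinstance(im, ReconImage) else np.asarray(im)
             for im in images]
    if not grids:
        raise ValueError("no slices")
    shape = grids[0].shape
    if any(g.shape != shape for g in grids):
        raise ValueError("heterogeneous slice shapes")
    return np.stack(grids, axis=-1)
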