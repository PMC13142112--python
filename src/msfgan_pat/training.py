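"""Alternating adversarial training of the artifact-removal network.

Protocol: per batch one discriminator step minimizing
L_D = L_Rp + lambda1 R1 + lambda2 R2 (R1 on full-view targets, R2 on
detached generator outputs), then one generator step minimizing the
role-swapped pairing plus an L1 fidelity term; Adam (beta1=0.9), the
learning rate halved after ``halving_epoch`` epochs; epoch-end
validation PSNR on the val split; the checkpoint with the best
validation score is returned (ties break to the earliest epoch).
Everything — initialization, data order, augmentation — is seeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

import numpy as np

from . import evaluation
from .acoustics import ArrayGeometry, default_geometry, project, \
    subsample_views
from .containers import PressureMap
from .das import das_reconstruct, normalize_image
from .discriminator import Discriminator, DiscriminatorConfig
from .generator import Generator, GeneratorConfig
from .losses import LossWeights, dual_gradient_penalty, total_losses
from .nn import Adam, Tensor
from .nn import autograd as ag
from .phantom import DatasetIndex, load_phantoms

__all__ = ["TrainConfig", "Checkpoint", "TrainingDiverged", "augment",
           "lr_schedule", "select_best", "prepare_pairs", "train",
           "infer", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 8
    lr0: float = 1e-4
    beta1: float = 0.9
    halving_epoch: int = 150
    seed: int = 0
    augment: bool = True
    pixel_weight: float = 100.0
    # ablation switches
    use_psa: bool = True
    use_cam_discriminator: bool = True
    use_dual_gradient_loss: bool = True
    inner_residual: bool = True
    outer_residual: bool = True
    validation_metric: str = "psnr"

    def __post_init__(self):
        if not (0 < self.halving_epoch <= self.epochs):
            raise ValueError("need 0 < halving_epoch <= epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.validation_metric != "psnr":
            raise ValueError("only PSNR validation is supported")


@dataclass
class Checkpoint:
    gen_state: dict
    disc_state: dict
    epoch: int
    val_score: float
    gen_cfg: GeneratorConfig
    disc_cfg: DiscriminatorConfig
    train_cfg: TrainConfig

    def build_generator(self) -> Generator:
        g = Generator(self.gen_cfg, seed=self.train_cfg.seed)
        g.load_state_dict(self.gen_state)
        return g


class TrainingDiverged(RuntimeError):
    def __init__(self, message: str, last_report=None):
        super().__init__(message)
        self.last_report = last_report


_TRANSFORMS = ("rot90", "rot180", "rot270", "fliph", "flipv")


def _apply(img: np.ndarray, name: str) -> np.ndarray:
    if name == "rot90":
        return np.rot90(img, 1).copy()
    if name == "rot180":
        return np.rot90(img, 2).copy()
    if name == "rot270":
        return np.rot90(img, 3).copy()
    if name == "fliph":
        return img[:, ::-1].copy()
    if name == "flipv":
        return img[::-1, :].copy()
    raise ValueError(name)


def augment(pair: tuple[np.ndarray, np.ndarray], seed: int
            ) -> list[tuple[np.ndarray, np.ndarray]]:
    """The original pair plus 3 seeded joint geometric transforms
    (rotations by 90/180/270 degrees, horizontal/vertical flips),
    quadrupling the data."""
    x, y = (np.asarray(p) for p in pair)
    if x.shape != y.shape:
        raise ValueError("input and target must share a shape")
    if x.shape[0] != x.shape[1]:
        raise ValueError("augmentation with rotations needs square images")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA06]))
    picks = rng.choice(len(_TRANSFORMS), size=3, replace=False)
    out = [(x, y)]
    for t in picks:
        name = _TRANSFORMS[t]
        out.append((_apply(x, name), _apply(y, name)))
    return out


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """lr0 until ``halving_epoch``, lr0/2 afterwards."""
    if not (0 <= epoch < config.epochs):
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    return config.lr0 if epoch < config.halving_epoch else config.lr0 / 2.0


def select_best(checkpoints: list[Checkpoint], val_split=None) -> Checkpoint:
    """Highest validation score; ties break to the earliest epoch."""
    if not checkpoints:
        raise ValueError("no checkpoints")
    best = checkpoints[0]
    for c in checkpoints[1:]:
        if c.val_score > best.val_score:
            best = c
    return best


def prepare_pairs(dataset: DatasetIndex, geom: ArrayGeometry,
                  sparse_views: int, grid_size: int, dx: float,
                  splits=("train", "val", "test"),
                  image_env: bool = True) -> dict:
    """DAS input/target pairs per split.

    Targets are full-view DAS reconstructions of each phantom's
    band-limited projection data; inputs are DAS reconstructions from
    the uniform ``sparse_views`` subset.  With ``image_env`` (default)
    the bipolar beamformed images are envelope-rectified before
    normalization, the display form of PAT reconstructions.  Both
    images are min-max normalized.
    """
    from .das import image_envelope
    out = {}
    for split in splits:
        grids, _, _ = load_phantoms(dataset, split)
        x0s, xfs = [], []
        for g in grids:
            sino = project(PressureMap(g, dx), geom)
            full = das_reconstruct(sino, geom, grid_size, dx)
            sparse, _ = subsample_views(sino, sparse_views)
            x0 = das_reconstruct(sparse, geom, grid_size, dx)
            if image_env:
                full = image_envelope(full)
                x0 = image_envelope(x0)
            full = normalize_image(full)
            x0 = normalize_image(x0)
            x0s.append(x0.grid)
            xfs.append(full.grid)
        out[split] = (
            np.asarray(x0s, np.float32)[:, None],
            np.asarray(xfs, np.float32)[:, None],
        )
    return out


def _augment_arrays(x0: np.ndarray, xf: np.ndarray,
                    seed: int) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for i in range(x0.shape[0]):
        for a, b in augment((x0[i, 0], xf[i, 0]), seed + i):
            xs.append(a)
            ys.append(b)
    return (np.asarray(xs, np.float32)[:, None],
            np.asarray(ys, np.float32)[:, None])


def _val_psnr(gen: Generator, x0: np.ndarray, xf: np.ndarray,
              batch: int = 16) -> float:
    gen.eval()
    scores = []
    with ag.no_grad():
        for s in range(0, x0.shape[0], batch):
            out = gen(Tensor(x0[s:s + batch])).data
            for i in range(out.shape[0]):
                # outputs are trained toward [0, 1] targets; clip rather
                # than rescale (min-max would let one outlier pixel
                # shrink the whole image)
                img = np.clip(out[i, 0], 0.0, 1.0)
                scores.append(evaluation.psnr(img, xf[s + i, 0]))
    gen.train()
    return float(np.mean(scores))


def train(pairs: dict, gen_cfg: GeneratorConfig,
          disc_cfg: DiscriminatorConfig, weights: LossWeights,
          config: TrainConfig, log=None) -> tuple[Checkpoint, list[dict]]:
    """Run the full adversarial protocol; returns (best checkpoint,
    per-epoch history).

    ``pairs`` maps split names to (x0, xf) arrays as produced by
    ``prepare_pairs``; 'train' and 'val' are required.
    """
    if "train" not in pairs or "val" not in pairs:
        raise ValueError("pairs must contain 'train' and 'val' splits")
    gen_cfg = replace(gen_cfg, use_psa=config.use_psa,
                      inner_residual=config.inner_residual,
                      outer_residual=config.outer_residual)
    disc_cfg = replace(disc_cfg, use_cam=config.use_cam_discriminator)
    weights_eff = weights if config.use_dual_gradient_loss else replace(
        weights, lambda1=0.0, lambda2=0.0)

    x0_tr, xf_tr = pairs["train"]
    if x0_tr.shape[0] == 0 or pairs["val"][0].shape[0] == 0:
        raise ValueError("empty train or val split")
    if config.augment:
        x0_tr, xf_tr = _augment_arrays(x0_tr, xf_tr, config.seed)

    gen = Generator(gen_cfg, seed=config.seed)
    disc = Discriminator(disc_cfg, seed=config.seed + 1)
    gparams = gen.named_parameters()
    dparams = disc.named_parameters()
    opt_g = Adam(gparams, lr=config.lr0, betas=(config.beta1, 0.999))
    opt_d = Adam(dparams, lr=config.lr0, betas=(config.beta1, 0.999))

    order_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x0DE5]))
    n = x0_tr.shape[0]
    bs = config.batch_size
    history: list[dict] = []
    best: Checkpoint | None = None
    zero = Tensor(np.zeros((), np.float32))

    for epoch in range(config.epochs):
        lr = lr_schedule(epoch, config)
        opt_g.lr = opt_d.lr = lr
        perm = order_rng.permutation(n)
        ep_report = None
        sums = np.zeros(4)
        n_batches = 0
        for s in range(0, n - bs + 1, bs):
            idx = perm[s:s + bs]
            x0 = Tensor(x0_tr[idx])
            xf = Tensor(xf_tr[idx])
            x_hat = gen(x0)
            x_hat_det = Tensor(x_hat.data)

            # --- discriminator step -----------------------------------
            s_both = disc(Tensor(np.concatenate([xf.data, x_hat.data])))
            s_real = s_both[:bs]
            s_fake = s_both[bs:]
            if weights_eff.lambda1 > 0 or weights_eff.lambda2 > 0:
                r1, r2 = dual_gradient_penalty(
                    disc, xf, x_hat_det,
                    weights_eff.gamma1, weights_eff.gamma2)
            else:
                r1 = r2 = zero
            l_d, _, report = total_losses(s_real, s_fake, r1, r2,
                                          weights_eff)
            l_d.backward()
            opt_d.step()
            disc.zero_grad()

            # --- generator step ---------------------------------------
            s_both2 = disc(ag.concat([x_hat, Tensor(xf.data)], axis=0))
            _, l_g, report2 = total_losses(
                s_both2[bs:], s_both2[:bs], zero, zero, weights_eff,
                x_hat=x_hat, x_full=xf,
                pixel_weight=config.pixel_weight)
            l_g.backward()
            opt_g.step()
            gen.zero_grad()
            disc.zero_grad()

            vals = (report.L_Rp, report.R1, report.R2, report2.L_G)
            if not all(np.isfinite(v) for v in vals):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}", report)
            sums += vals
            n_batches += 1
            ep_report = report

        val = _val_psnr(gen, *pairs["val"])
        record = {
            "epoch": epoch, "lr": lr,
            "L_Rp": sums[0] / n_batches, "R1": sums[1] / n_batches,
            "R2": sums[2] / n_batches, "L_G": sums[3] / n_batches,
            "val_psnr": val,
        }
        history.append(record)
        if log is not None:
            log(record)
        if best is None or val > best.val_score:
            best = Checkpoint(gen.state_dict(), disc.state_dict(), epoch,
                              val, gen_cfg, disc_cfg, config)
    return best, history


def infer(checkpoint: Checkpoint, x0: np.ndarray,
          batch: int = 16) -> np.ndarray:
    """Run the generator of a checkpoint over a stack of inputs
    (N,1,H,W) or (N,H,W); returns images (N,H,W) clipped to [0, 1]."""
    x0 = np.asarray(x0, np.float32)
    if x0.ndim == 3:
        x0 = x0[:, None]
    gen = checkpoint.build_generator()
    gen.eval()
    outs = []
    with ag.no_grad():
        for s in range(0, x0.shape[0], batch):
            out = gen(Tensor(x0[s:s + batch])).data
            for i in range(out.shape[0]):
                outs.append(np.clip(out[i, 0], 0.0, 1.0))
    return np.asarray(outs)


def save_checkpoint(ckpt: Checkpoint, path):
    """Single-file archive: parameter arrays keyed by module path plus
    the full configuration as JSON."""
    meta = json.dumps({
        "epoch": ckpt.epoch,
        "val_score": ckpt.val_score,
        "gen_cfg": ckpt.gen_cfg.to_dict(),
        "disc_cfg": ckpt.disc_cfg.to_dict(),
        "train_cfg": asdict(ckpt.train_cfg),
    })
    arrays = {f"gen/{k}": v for k, v in ckpt.gen_state.items()}
    arrays.update({f"disc/{k}": v for k, v in ckpt.disc_state.items()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), np.uint8),
             **arrays)


def load_checkpoint(path) -> Checkpoint:
    with np.load(path) as f:
        meta = json.loads(bytes(f["__meta__"]).decode())
        gen_state = {k[4:]: f[k] for k in f.files if k.startswith("gen/")}
        disc_state = {k[5:]: f[k] for k in f.files if k.startswith("disc/")}
    gcfg = meta["gen_cfg"]
    gcfg["branch_kernels"] = tuple(gcfg["branch_kernels"])
    dcfg = meta["disc_cfg"]
    dcfg["widths"] = tuple(dcfg["widths"])
    return Checkpoint(gen_state, disc_state, meta["epoch"],
                      meta["val_score"], GeneratorConfig(**gcfg),
                      DiscriminatorConfig(**dcfg),
                      TrainConfig(**meta["train_cfg"]))
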