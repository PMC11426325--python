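"""Seeded cGAN training loop, checkpointing, and whole-scene segmentation.

Training alternates one discriminator update (BCE on real vs generated pairs)
and one generator update (adversarial BCE + lambda * L1, or pure L1 in
``paper_literal`` mode) per batch, with Adam (lr 2e-4, beta1 0.5). Images are
normalized to [-1, 1]; targets are the palette-encoded masks in the same
range. Everything is driven by one integer seed, so two single-threaded runs
produce identical loss logs.

``segment_scene`` applies a trained generator to an orthophoto of any size:
plan overlapping windows, run the generator tile by tile (batch-norm in
evaluation mode), quantize each output to the palette, and fuse by majority
vote.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .dataset import PairedSample
from .nn import Adam, bce_with_logits, bce_with_logits_grad
from .pix2pix import (DiscriminatorSpec, GeneratorSpec, LossConfig,
                      PatchDiscriminator, UNetGenerator, build_discriminator,
                      build_generator, count_parameters)
from .raster_io import ClassPalette, DEFAULT_PALETTE, GeoRaster, decode_mask, encode_mask
from .tiling import TileSpec, extract_tiles, plan_tiles, reassemble

__all__ = ["TrainConfig", "TrainLog", "TrainingDivergedError", "train",
           "segment_scene", "save_checkpoint", "load_checkpoint"]


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 1
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    width_multiplier: float = 1.0
    tile_size: int = 256
    checkpoint_dir: Optional[str] = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def generator_spec(self) -> GeneratorSpec:
        depth = min(8, int(np.log2(self.tile_size)))
        return GeneratorSpec.scaled(self.width_multiplier, depth=depth)

    def discriminator_spec(self) -> DiscriminatorSpec:
        return DiscriminatorSpec(width_multiplier=self.width_multiplier)


@dataclass
class TrainLog:
    g_loss: List[float] = field(default_factory=list)
    d_loss: List[float] = field(default_factory=list)
    epoch_g_mean: List[float] = field(default_factory=list)
    epoch_d_mean: List[float] = field(default_factory=list)
    wall_time_s: float = 0.0

    @property
    def n_steps(self) -> int:
        return len(self.g_loss)

    def to_csv(self, path: str, steps_per_epoch: int) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["step", "epoch", "g_loss", "d_loss"])
            for i, (g, d) in enumerate(zip(self.g_loss, self.d_loss)):
                w.writerow([i, i // steps_per_epoch, f"{g:.6f}", f"{d:.6f}"])


def _to_pm1(img: np.ndarray) -> np.ndarray:
    """uint8 HxWx3 -> float32 3xHxW in [-1, 1]."""
    return (np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 127.5) - 1.0


def _from_pm1(arr: np.ndarray) -> np.ndarray:
    """float 3xHxW in [-1, 1] -> uint8 HxWx3."""
    out = np.clip((arr + 1.0) * 127.5, 0, 255)
    return np.rint(out).astype(np.uint8).transpose(1, 2, 0)


def train(pairs: Sequence[PairedSample], config: TrainConfig = TrainConfig(),
          palette: ClassPalette = DEFAULT_PALETTE,
          generator: Optional[UNetGenerator] = None,
          discriminator: Optional[PatchDiscriminator] = None
          ) -> Tuple[UNetGenerator, TrainLog]:
    """Train the conditional GAN on paired (image, mask) tiles.

    Masks are rendered through the palette and regressed in RGB space, which
    is exactly the image-to-image translation framing: the network never sees
    class indices, only palette colors, and predictions are recovered by
    nearest-color quantization afterwards.
    """
    import time
    if len(pairs) == 0:
        raise ValueError("need at least one training pair")
    rng = np.random.default_rng(config.seed)
    gen = generator or build_generator(config.generator_spec(), rng)
    adversarial = config.loss.mode == "standard"
    disc = discriminator or (
        build_discriminator(config.discriminator_spec(), rng)
        if adversarial else None)

    xs = [_to_pm1(p.source) for p in pairs]
    ys = [_to_pm1(encode_mask(p.target, palette)) for p in pairs]

    opt_g = Adam(gen.layers, config.learning_rate, config.beta1, config.beta2)
    opt_d = (Adam(disc.layers, config.learning_rate, config.beta1, config.beta2)
             if adversarial else None)

    log = TrainLog()
    t0 = time.time()
    n = len(pairs)
    bs = config.batch_size
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        eg, ed = [], []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            x = np.stack([xs[i] for i in idx])
            y = np.stack([ys[i] for i in idx])

            fake = gen.forward(x, train=True)

            d_loss_val = 0.0
            if adversarial:
                # discriminator update on real and generated pairs
                z_real = disc.forward(x, y, train=True)
                g_real = bce_with_logits_grad(z_real, 1.0)
                loss_real = bce_with_logits(z_real, 1.0)
                disc.backward(g_real)
                grads_real = {id(l): {k: v.copy() for k, v in l.grads.items()}
                              for l in disc.layers if l.grads}
                z_fake = disc.forward(x, fake, train=True)
                loss_fake = bce_with_logits(z_fake, 0.0)
                disc.backward(bce_with_logits_grad(z_fake, 0.0))
                for l in disc.layers:
                    prev = grads_real.get(id(l))
                    if prev:
                        for k in l.grads:
                            l.grads[k] += prev[k]
                opt_d.step()
                d_loss_val = loss_real + loss_fake

            # generator update (discriminator weights frozen this half-step)
            l1 = float(np.mean(np.abs(fake - y)))
            d_l1 = (np.sign(fake - y) / fake.size).astype(np.float32)
            if adversarial:
                z_fake = disc.forward(x, fake, train=True)
                adv = bce_with_logits(z_fake, 1.0)
                _, d_fake_adv = disc.backward(bce_with_logits_grad(z_fake, 1.0))
                g_loss_val = adv + config.loss.lambda_l1 * l1
                d_fake = d_fake_adv + config.loss.lambda_l1 * d_l1
            else:
                g_loss_val = l1
                d_fake = d_l1
            gen.backward(d_fake)
            opt_g.step()

            if not (np.isfinite(g_loss_val) and np.isfinite(d_loss_val)):
                raise TrainingDivergedError(
                    f"non-finite loss at step {step} (epoch {epoch}): "
                    f"g={g_loss_val}, d={d_loss_val}")
            log.g_loss.append(float(g_loss_val))
            log.d_loss.append(float(d_loss_val))
            eg.append(g_loss_val)
            ed.append(d_loss_val)
            step += 1
        log.epoch_g_mean.append(float(np.mean(eg)))
        log.epoch_d_mean.append(float(np.mean(ed)))
        if config.checkpoint_dir:
            os.makedirs(config.checkpoint_dir, exist_ok=True)
            save_checkpoint(gen, os.path.join(
                config.checkpoint_dir, f"generator_epoch{epoch:03d}.npz"),
                config=config)
    log.wall_time_s = time.time() - t0
    return gen, log


def save_checkpoint(model: UNetGenerator, path: str,
                    config: Optional[TrainConfig] = None) -> None:
    """Serialize weights (npz) plus a JSON architecture fingerprint."""
    np.savez(path, **model.state_dict())
    pc = count_parameters(model)
    fp = {
        "spec": asdict(model.spec),
        "trainable": pc.trainable,
        "non_trainable": pc.non_trainable,
    }
    if config is not None:
        cfg = asdict(config)
        cfg["loss"] = asdict(config.loss)
        fp["train_config"] = cfg
    with open(path + ".json", "w") as fh:
        json.dump(fp, fh, indent=1, default=str)


def load_checkpoint(path: str) -> UNetGenerator:
    """Rebuild a generator from a checkpoint, verifying its fingerprint."""
    with open(path + ".json") as fh:
        fp = json.load(fh)
    sp = fp["spec"]
    spec = GeneratorSpec(
        encoder_widths=tuple(sp["encoder_widths"]),
        decoder_widths=tuple(sp["decoder_widths"]),
        dropout_blocks=sp["dropout_blocks"], dropout_p=sp["dropout_p"],
        kernel=sp["kernel"], stride=sp["stride"],
        in_channels=sp["in_channels"], out_channels=sp["out_channels"],
        init_std=sp["init_std"], leaky_slope=sp["leaky_slope"],
        width_multiplier=sp["width_multiplier"])
    gen = UNetGenerator(spec, rng=np.random.default_rng(0))
    pc = count_parameters(gen)
    if pc.trainable != fp["trainable"] or pc.non_trainable != fp["non_trainable"]:
        raise ValueError("checkpoint fingerprint does not match rebuilt model")
    with np.load(path) as state:
        gen.load_state_dict(dict(state))
    return gen


def segment_scene(generator: UNetGenerator, scene: GeoRaster,
                  spec: TileSpec = TileSpec(),
                  palette: ClassPalette = DEFAULT_PALETTE,
                  norm_stats: str = "batch") -> GeoRaster:
    """Segment a whole orthophoto into a label mask via overlapping windows.

    Tiles are forwarded one at a time so that, with the default per-sample
    ("batch") normalization statistics, each tile is normalized independently
    of how tiles happen to be grouped — inference is deterministic and
    tile-order independent. The georeference (if any) is copied from the
    input; an ungeoreferenced scene yields an ungeoreferenced mask, and any
    later area computation on it fails loudly.
    """
    if scene.data.ndim != 3:
        raise ValueError("segment_scene expects an RGB scene")
    grid = plan_tiles(scene.height, scene.width, spec)
    tiles = extract_tiles(scene.data, grid)
    masks: List[np.ndarray] = []
    for t in tiles:
        out = generator.forward(_to_pm1(t)[None], train=False,
                                norm_stats=norm_stats)
        masks.append(decode_mask(_from_pm1(out[0]), palette))
    full = reassemble(masks, grid, n_classes=len(palette))
    return GeoRaster(data=full, georef=scene.georef)
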