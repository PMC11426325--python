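"""The pix2pix conditional GAN: U-Net generator and PatchGAN discriminator.

The generator is an encoder-decoder U-Net: eight stride-2 4x4 convolution
blocks C64-C128-C256-C512-C512-C512-C512-C512 (LeakyReLU, batch norm on every
block except the first), mirrored by seven transposed-convolution decoder
blocks CD512-CD512-CD512-C512-C256-C128-C64 (ReLU, batch norm everywhere,
dropout 0.5 on the first three) with mirror-wise skip concatenations, and a
final transposed convolution to 3 channels through tanh. The discriminator is
a 70x70 PatchGAN over the channel-concatenated (source, target) pair:
C64-C128-C256 at stride 2, C512 at stride 1, then a 1-channel 4x4 stride-1
head emitting a 30x30 grid of patch logits for 256x256 input.

Bias convention: a convolution followed by batch normalization carries no
bias (the norm's shift absorbs it); convolutions without a following norm
(generator input block and output layer, discriminator input block and head)
carry one. Weights are initialized from a Gaussian with mean 0 and standard
deviation 0.02.

A ``width_multiplier`` (and, for small tiles, a reduced ``depth``) scales
every channel width for desk-scale experiments; at multiplier 1 and depth 8
the trainable/non-trainable parameter tallies are the canonical ones
(generator 54,415,043 / 10,880; discriminator 2,768,705 / 1,792).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .nn import (Adam, BatchNorm2d, Conv2d, ConvTranspose2d, Dropout, Layer,
                 LeakyReLU, ReLU, Tanh, bce_with_logits, sigmoid)

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "LossConfig", "ParameterCount",
    "UNetGenerator", "PatchDiscriminator",
    "build_generator", "build_discriminator", "count_parameters",
    "generator_loss", "discriminator_loss",
]

_CANONICAL_ENCODER = (64, 128, 256, 512, 512, 512, 512, 512)


def _scale(widths: Sequence[int], m: float) -> Tuple[int, ...]:
    return tuple(max(1, int(round(w * m))) for w in widths)


@dataclass(frozen=True)
class GeneratorSpec:
    """Architecture of the U-Net generator."""

    encoder_widths: tuple = _CANONICAL_ENCODER
    decoder_widths: tuple = (512, 512, 512, 512, 256, 128, 64)
    dropout_blocks: int = 3
    dropout_p: float = 0.5
    kernel: int = 4
    stride: int = 2
    in_channels: int = 3
    out_channels: int = 3
    init_std: float = 0.02
    leaky_slope: float = 0.2
    width_multiplier: float = 1.0

    def __post_init__(self):
        if len(self.decoder_widths) != len(self.encoder_widths) - 1:
            raise ValueError("decoder must have one block fewer than encoder")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")

    @property
    def depth(self) -> int:
        return len(self.encoder_widths)

    def scaled_encoder(self) -> Tuple[int, ...]:
        return _scale(self.encoder_widths, self.width_multiplier)

    def scaled_decoder(self) -> Tuple[int, ...]:
        return _scale(self.decoder_widths, self.width_multiplier)

    @classmethod
    def scaled(cls, width_multiplier: float = 1.0,
               depth: Optional[int] = None) -> "GeneratorSpec":
        """Desk-scale variant: narrower widths and/or fewer halvings.

        ``depth`` D (>= 5) truncates the canonical schedule: encoder = first D
        canonical widths, decoder = (512,)*(D-4) + (256, 128, 64). Depth 8 is
        the full model (256x256 tiles); depth 6 fits 64x64 tiles.
        """
        d = depth or len(_CANONICAL_ENCODER)
        if not (5 <= d <= len(_CANONICAL_ENCODER)):
            raise ValueError("depth must be between 5 and 8")
        return cls(encoder_widths=_CANONICAL_ENCODER[:d],
                   decoder_widths=(512,) * (d - 4) + (256, 128, 64),
                   width_multiplier=width_multiplier)


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Architecture of the PatchGAN discriminator."""

    widths: tuple = (64, 128, 256, 512)
    strides: tuple = (2, 2, 2, 1)
    kernel: int = 4
    in_channels: int = 6        # channel-concatenated (source, target)
    init_std: float = 0.02
    leaky_slope: float = 0.2
    width_multiplier: float = 1.0

    def __post_init__(self):
        if len(self.widths) != len(self.strides):
            raise ValueError("widths and strides must have equal length")

    def scaled_widths(self) -> Tuple[int, ...]:
        return _scale(self.widths, self.width_multiplier)


@dataclass(frozen=True)
class LossConfig:
    """Generator objective: ``standard`` cGAN (BCE + lambda*L1) or
    ``paper_literal`` (pure mean-absolute-error regression)."""

    mode: str = "standard"
    lambda_l1: float = 100.0

    def __post_init__(self):
        if self.mode not in ("standard", "paper_literal"):
            raise ValueError("loss mode must be 'standard' or 'paper_literal'")
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")


@dataclass(frozen=True)
class ParameterCount:
    trainable: int
    non_trainable: int

    @property
    def total(self) -> int:
        return self.trainable + self.non_trainable


class _Model:
    """Shared plumbing: named layer registry, counting, state I/O."""

    def __init__(self):
        self._layers: List[Tuple[str, Layer]] = []

    def _add(self, name: str, layer: Layer) -> Layer:
        self._layers.append((name, layer))
        return layer

    @property
    def layers(self) -> List[Layer]:
        return [l for _, l in self._layers]

    def state_dict(self) -> dict:
        state = {}
        for name, layer in self._layers:
            for k, v in layer.params.items():
                state[f"{name}.{k}"] = v
            for k, v in layer.buffers.items():
                state[f"{name}.{k}"] = v
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, layer in self._layers:
            for store in (layer.params, layer.buffers):
                for k in store:
                    key = f"{name}.{k}"
                    if key not in state:
                        raise KeyError(f"checkpoint missing tensor {key}")
                    if state[key].shape != store[k].shape:
                        raise ValueError(
                            f"shape mismatch for {key}: checkpoint "
                            f"{state[key].shape} vs model {store[k].shape}")
                    store[k] = np.array(state[key], dtype=store[k].dtype)


class UNetGenerator(_Model):
    """U-Net with skip concatenations; maps (N,3,H,W) in [-1,1] to same."""

    def __init__(self, spec: GeneratorSpec = GeneratorSpec(),
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.spec = spec
        enc_w = spec.scaled_encoder()
        dec_w = spec.scaled_decoder()
        self.depth = spec.depth
        k, s = spec.kernel, spec.stride

        self.enc = []
        c_prev = spec.in_channels
        for i, w in enumerate(enc_w):
            conv = self._add(f"enc{i}.conv", Conv2d(
                c_prev, w, k, s, 1, bias=(i == 0), rng=rng,
                init_std=spec.init_std))
            bn = None if i == 0 else self._add(f"enc{i}.bn", BatchNorm2d(w))
            act = self._add(f"enc{i}.act", LeakyReLU(spec.leaky_slope))
            self.enc.append((conv, bn, act))
            c_prev = w

        self.dec = []
        for i, w in enumerate(dec_w):
            c_in = enc_w[-1] if i == 0 else dec_w[i - 1] + enc_w[self.depth - 1 - i]
            tconv = self._add(f"dec{i}.tconv", ConvTranspose2d(
                c_in, w, k, s, 1, bias=False, rng=rng, init_std=spec.init_std))
            bn = self._add(f"dec{i}.bn", BatchNorm2d(w))
            drop = (self._add(f"dec{i}.drop", Dropout(spec.dropout_p, rng=rng))
                    if i < spec.dropout_blocks else None)
            act = self._add(f"dec{i}.act", ReLU())
            self.dec.append((tconv, bn, drop, act))

        self.out_conv = self._add("out.tconv", ConvTranspose2d(
            dec_w[-1] + enc_w[0], spec.out_channels, k, s, 1, bias=True,
            rng=rng, init_std=spec.init_std))
        self.out_act = self._add("out.act", Tanh())
        self._skip_shapes = None

    def _check_input(self, x: np.ndarray) -> None:
        h, w = x.shape[2], x.shape[3]
        div = 2 ** self.depth
        if h % div or w % div or h < div or w < div:
            raise ValueError(
                f"input {h}x{w} must be divisible by 2^{self.depth}={div} "
                f"(tile size vs. network depth mismatch)")

    def forward(self, x: np.ndarray, train: bool = True,
                norm_stats: str = "batch") -> np.ndarray:
        """Forward pass mapping [-1, 1] RGB to [-1, 1] RGB.

        ``train=False`` disables dropout and freezes the running batch-norm
        buffers. ``norm_stats`` selects the normalization statistics at
        inference: ``"batch"`` (default) normalizes each input by its own
        batch statistics — with single-sample batches this is the
        instance-normalization behavior the original pix2pix relies on at
        test time — while ``"running"`` uses the accumulated training
        statistics. Training always uses batch statistics.
        """
        if norm_stats not in ("batch", "running"):
            raise ValueError("norm_stats must be 'batch' or 'running'")
        bn_batch = train or norm_stats == "batch"
        x = np.asarray(x, dtype=np.float32)
        self._check_input(x)
        skips = []
        h = x
        for conv, bn, act in self.enc:
            h = conv.forward(h, train)
            if bn is not None:
                h = bn.forward(h, bn_batch, update_running=train)
            h = act.forward(h, train)
            skips.append(h)
        for i, (tconv, bn, drop, act) in enumerate(self.dec):
            inp = h if i == 0 else np.concatenate(
                [h, skips[self.depth - 1 - i]], axis=1)
            h = tconv.forward(inp, train)
            h = bn.forward(h, bn_batch, update_running=train)
            if drop is not None:
                h = drop.forward(h, train)
            h = act.forward(h, train)
        inp = np.concatenate([h, skips[0]], axis=1)
        y = self.out_act.forward(self.out_conv.forward(inp, train), train)
        self._skips = skips
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Backpropagate loss gradient through the last forward pass."""
        enc_w = self.spec.scaled_encoder()
        dec_w = self.spec.scaled_decoder()
        skip_grads = [None] * self.depth

        def add_skip(i, g):
            skip_grads[i] = g if skip_grads[i] is None else skip_grads[i] + g

        d = self.out_conv.backward(self.out_act.backward(dy))
        d, dskip0 = d[:, :dec_w[-1]], d[:, dec_w[-1]:]
        add_skip(0, dskip0)
        for i in range(len(self.dec) - 1, -1, -1):
            tconv, bn, drop, act = self.dec[i]
            d = act.backward(d)
            if drop is not None:
                d = drop.backward(d)
            d = tconv.backward(bn.backward(d))
            if i == 0:
                add_skip(self.depth - 1, d)
            else:
                c_prev = dec_w[i - 1]
                add_skip(self.depth - 1 - i, d[:, c_prev:])
                d = d[:, :c_prev]
        dx = None
        for i in range(self.depth - 1, -1, -1):
            conv, bn, act = self.enc[i]
            g = skip_grads[i]
            g = act.backward(g)
            if bn is not None:
                g = bn.backward(g)
            g = conv.backward(g)
            if i == 0:
                dx = g
            else:
                add_skip(i - 1, g)
        return dx

    __call__ = forward


class PatchDiscriminator(_Model):
    """PatchGAN over channel-concatenated pairs; emits a logit grid."""

    def __init__(self, spec: DiscriminatorSpec = DiscriminatorSpec(),
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.spec = spec
        widths = spec.scaled_widths()
        k = spec.kernel
        self.blocks = []
        c_prev = spec.in_channels
        for i, (w, s) in enumerate(zip(widths, spec.strides)):
            conv = self._add(f"blk{i}.conv", Conv2d(
                c_prev, w, k, s, 1, bias=(i == 0), rng=rng,
                init_std=spec.init_std))
            bn = None if i == 0 else self._add(f"blk{i}.bn", BatchNorm2d(w))
            act = self._add(f"blk{i}.act", LeakyReLU(spec.leaky_slope))
            self.blocks.append((conv, bn, act))
            c_prev = w
        self.head = self._add("head.conv", Conv2d(
            c_prev, 1, k, 1, 1, bias=True, rng=rng, init_std=spec.init_std))

    def forward(self, source: np.ndarray, target: np.ndarray,
                train: bool = True) -> np.ndarray:
        source = np.asarray(source, dtype=np.float32)
        target = np.asarray(target, dtype=np.float32)
        if source.shape != target.shape:
            raise ValueError(
                f"source {source.shape} and target {target.shape} must match")
        h = np.concatenate([source, target], axis=1)
        for conv, bn, act in self.blocks:
            h = conv.forward(h, train)
            if bn is not None:
                h = bn.forward(h, train)
            h = act.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Returns gradients w.r.t. (source, target)."""
        d = self.head.backward(dlogits)
        for conv, bn, act in reversed(self.blocks):
            d = act.backward(d)
            if bn is not None:
                d = bn.backward(d)
            d = conv.backward(d)
        c = self.spec.in_channels // 2
        return d[:, :c], d[:, c:]

    __call__ = forward


def build_generator(spec: GeneratorSpec = GeneratorSpec(),
                    rng: Optional[np.random.Generator] = None
                    ) -> UNetGenerator:
    return UNetGenerator(spec, rng)


def build_discriminator(spec: DiscriminatorSpec = DiscriminatorSpec(),
                        rng: Optional[np.random.Generator] = None
                        ) -> PatchDiscriminator:
    return PatchDiscriminator(spec, rng)


def count_parameters(model: _Model) -> ParameterCount:
    """Tally optimizable weights and batch-norm running statistics."""
    return ParameterCount(
        trainable=sum(l.n_trainable() for l in model.layers),
        non_trainable=sum(l.n_non_trainable() for l in model.layers),
    )


def _bce_probs(p: np.ndarray, target: float, eps: float = 1e-12) -> float:
    p = np.clip(np.asarray(p, dtype=np.float64), eps, 1 - eps)
    return float(-np.mean(target * np.log(p) + (1 - target) * np.log(1 - p)))


def generator_loss(disc_on_fake: Optional[np.ndarray], fake: np.ndarray,
                   target: np.ndarray,
                   cfg: LossConfig = LossConfig()) -> float:
    """Generator objective on post-sigmoid patch probabilities.

    ``paper_literal`` is the plain mean absolute error between generator
    output and target; ``standard`` adds the adversarial term
    BCE(disc_on_fake, 1) to lambda_l1 times that error.
    """
    l1 = float(np.mean(np.abs(np.asarray(fake, dtype=np.float64)
                              - np.asarray(target, dtype=np.float64))))
    if cfg.mode == "paper_literal":
        return l1
    if disc_on_fake is None:
        raise ValueError("standard mode needs the discriminator's patch grid")
    return _bce_probs(disc_on_fake, 1.0) + cfg.lambda_l1 * l1


def discriminator_loss(disc_on_real: np.ndarray,
                       disc_on_fake: np.ndarray) -> float:
    """BCE(real, 1) + BCE(fake, 0), each averaged over the patch grid."""
    real = np.asarray(disc_on_real)
    fake = np.asarray(disc_on_fake)
    if real.shape != fake.shape:
        raise ValueError("real and fake patch grids must have equal shape")
    return _bce_probs(real, 1.0) + _bce_probs(fake, 0.0)
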