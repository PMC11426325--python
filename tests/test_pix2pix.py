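import numpy as np
import pytest

from sargmap.nn import BatchNorm2d, Conv2d
from sargmap.pix2pix import (DiscriminatorSpec, GeneratorSpec, LossConfig,
                             build_discriminator, build_generator,
                             count_parameters, discriminator_loss,
                             generator_loss)

# canonical parameter tallies for the full-width architecture
GEN_TRAINABLE = 54_415_043
GEN_NON_TRAINABLE = 10_880
DISC_TRAINABLE = 2_768_705
DISC_NON_TRAINABLE = 1_792
TOTAL = 57_196_420


@pytest.fixture(scope="module")
def full_models():
    rng = np.random.default_rng(0)
    return build_generator(rng=rng), build_discriminator(rng=rng)


class TestParameterCounts:
    def test_generator_counts(self, full_models):
        pc = count_parameters(full_models[0])
        assert pc.trainable == GEN_TRAINABLE
        assert pc.non_trainable == GEN_NON_TRAINABLE

    def test_discriminator_counts(self, full_models):
        pc = count_parameters(full_models[1])
        assert pc.trainable == DISC_TRAINABLE
        assert pc.non_trainable == DISC_NON_TRAINABLE

    def test_grand_total(self, full_models):
        gen, disc = full_models
        assert (count_parameters(gen).total
                + count_parameters(disc).total) == TOTAL

    def test_single_conv_by_hand(self):
        conv = Conv2d(3, 64, 4, 2, 1, bias=True, rng=np.random.default_rng(0))
        assert conv.n_trainable() == 4 * 4 * 3 * 64 + 64 == 3136
        assert conv.n_non_trainable() == 0

    def test_batchnorm_by_hand(self):
        bn = BatchNorm2d(128)
        assert bn.n_trainable() == 256       # gamma + beta
        assert bn.n_non_trainable() == 256   # running mean + var

    def test_bias_convention_first_layers_carry_64(self, full_models):
        gen, disc = full_models
        # only the non-normalized convolutions carry biases; the input blocks
        # contribute exactly 64 bias terms each
        assert gen.enc[0][0].params["b"].size == 64
        assert all("b" not in conv.params for conv, _, _ in gen.enc[1:])
        assert disc.blocks[0][0].params["b"].size == 64
        assert all("b" not in conv.params for conv, _, _ in disc.blocks[1:])


class TestInitialization:
    def test_gaussian_init_statistics(self, full_models):
        gen, _ = full_models
        kernels = np.concatenate([
            l.params["W"].ravel() for l in gen.layers if "W" in l.params])
        n = kernels.size
        assert abs(kernels.mean()) < 4 * 0.02 / np.sqrt(n)
        assert abs(kernels.std() - 0.02) < 0.05 * 0.02


class TestForward:
    def test_generator_output_shape_and_range(self):
        spec = GeneratorSpec.scaled(width_multiplier=0.125)
        gen = build_generator(spec, np.random.default_rng(1))
        x = np.random.default_rng(2).uniform(-1, 1, (1, 3, 256, 256)) \
            .astype(np.float32)
        y = gen.forward(x, train=True)
        assert y.shape == (1, 3, 256, 256)
        assert y.min() >= -1.0 and y.max() <= 1.0

    def test_indivisible_input_rejected_not_weight_bound(self):
        spec = GeneratorSpec.scaled(width_multiplier=0.125, depth=6)
        gen = build_generator(spec, np.random.default_rng(1))
        # fully convolutional: both 64 and 128 inputs pass through the same
        # weights; only divisibility by 2^depth is enforced
        for size in (64, 128):
            x = np.zeros((1, 3, size, size), dtype=np.float32)
            assert gen.forward(x, train=False).shape == (1, 3, size, size)
        with pytest.raises(ValueError, match="divisible"):
            gen.forward(np.zeros((1, 3, 96, 96), dtype=np.float32))

    def test_discriminator_patch_grid_30x30(self):
        spec = DiscriminatorSpec(width_multiplier=0.125)
        disc = build_discriminator(spec, np.random.default_rng(3))
        x = np.zeros((1, 3, 256, 256), dtype=np.float32)
        assert disc.forward(x, x, train=True).shape == (1, 1, 30, 30)

    def test_discriminator_rejects_mismatched_pairs(self):
        disc = build_discriminator(DiscriminatorSpec(width_multiplier=0.125),
                                   np.random.default_rng(3))
        with pytest.raises(ValueError):
            disc.forward(np.zeros((1, 3, 64, 64), np.float32),
                         np.zeros((1, 3, 32, 32), np.float32))

    def test_decoder_depth_mismatch_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec(encoder_widths=(64, 128), decoder_widths=(64, 32))


class TestLosses:
    def test_paper_literal_is_mean_absolute_error(self, rng):
        target = rng.uniform(-0.5, 0.5, (1, 3, 8, 8))
        cfg = LossConfig(mode="paper_literal")
        assert generator_loss(None, target, target, cfg) == 0.0
        assert generator_loss(None, target + 0.25, target, cfg) \
            == pytest.approx(0.25)

    def test_standard_mode_closed_form(self, rng):
        target = rng.uniform(-0.5, 0.5, (1, 3, 8, 8))
        grid = np.full((1, 1, 30, 30), 0.5)
        val = generator_loss(grid, target, target, LossConfig(lambda_l1=100.0))
        assert val == pytest.approx(-np.log(0.5), rel=1e-6)

    def test_discriminator_half_grids(self):
        grid = np.full((1, 1, 30, 30), 0.5)
        assert discriminator_loss(grid, grid) \
            == pytest.approx(2 * np.log(2), rel=1e-9)

    def test_perfect_discriminator_loss_vanishes(self):
        eps = 1e-9
        real = np.full((4, 4), 1 - eps)
        fake = np.full((4, 4), eps)
        assert discriminator_loss(real, fake) < 1e-6

    def test_swap_symmetry(self, rng):
        real = rng.uniform(0.01, 0.99, (5, 5))
        fake = rng.uniform(0.01, 0.99, (5, 5))
        assert discriminator_loss(real, fake) \
            == pytest.approx(discriminator_loss(1 - fake, 1 - real), rel=1e-9)
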