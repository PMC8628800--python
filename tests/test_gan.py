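"""WGAN-GP: architecture rules, gradient penalty, smoke training."""

import numpy as np
import pytest

from sleepscore.dataset import ImageDataset
from sleepscore.gan import (
    GanConfig,
    build_wgan_gp,
    gradient_penalty,
    sample_fake_images,
    train_wgan,
)
from sleepscore.imaging import EpochImage
from sleepscore.nn import Tensor
from sleepscore.nn import functional as F
from sleepscore.nn import tensor as T
from sleepscore.stages import Stage
from sleepscore.workflow import make_subject_images


class TestArchitecture:
    @pytest.mark.parametrize("res,blocks", [(512, 7), (128, 5), (64, 4)])
    def test_generator_block_count(self, res, blocks):
        gan = build_wgan_gp(GanConfig(resolution=res, base_feature_maps=16))
        assert gan.n_generator_blocks == blocks
        assert gan.n_critic_blocks == blocks

    @pytest.mark.parametrize("res", [96, 100, 6, 48])
    def test_non_doubling_resolution_rejected(self, res):
        with pytest.raises(ValueError, match="4 \\* 2"):
            GanConfig(resolution=res).validate()

    def test_generator_output_shape_and_range(self):
        gan = build_wgan_gp(GanConfig(resolution=32, seed=1))
        out = gan.generate(5, np.random.default_rng(0))
        assert out.shape == (5, 32, 32, 1)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_critic_outputs_unbounded_scalar(self):
        gan = build_wgan_gp(GanConfig(resolution=32, seed=1))
        x = Tensor(np.random.default_rng(0).random((3, 32, 32, 1), dtype=np.float32))
        assert gan.critic_forward(x).shape == (3, 1)

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError, match="gp_lambda"):
            GanConfig(gp_lambda=0.0).validate()
        with pytest.raises(ValueError, match="n_critic"):
            GanConfig(n_critic=0).validate()


class TestGradientPenalty:
    def batches(self, n=8, side=2):
        rng = np.random.default_rng(0)
        return (rng.random((n, side, side, 1), dtype=np.float32),
                rng.random((n, side, side, 1), dtype=np.float32))

    def test_constant_critic_gives_lambda(self):
        real, fake = self.batches()
        critic = lambda x: Tensor(np.zeros((x.shape[0], 1), np.float32))
        gp = gradient_penalty(critic, real, fake, gp_lambda=10.0, seed=0)
        assert abs(gp.item() - 10.0) / 10.0 < 1e-5

    @pytest.mark.parametrize("side,expect_factor", [(2, 1.0), (8, 49.0)])
    def test_pixel_sum_critic_closed_form(self, side, expect_factor):
        # gradient is all-ones: ||grad|| = sqrt(n_pixels) -> (sqrt(n)-1)^2
        real, fake = self.batches(side=side)
        critic = lambda x: T.tsum(T.reshape(x, (x.shape[0], -1)),
                                  axis=1, keepdims=True)
        gp = gradient_penalty(critic, real, fake, gp_lambda=10.0, seed=0)
        expect = 10.0 * expect_factor
        assert abs(gp.item() - expect) / expect < 1e-5

    def test_matches_finite_difference_gradient_oracle(self):
        """Random small critics: ||grad critic||_2 against central differences."""
        rng = np.random.default_rng(4)
        w = Tensor(rng.standard_normal((9, 2)).astype(np.float32) * 0.5)
        b = Tensor(np.zeros(2, np.float32))
        wd = Tensor(rng.standard_normal((2 * 16, 1)).astype(np.float32) * 0.3)

        def critic(x):
            h = T.tanh(F.conv2d(x, w, b, stride=1, pad=1))
            return T.matmul(F.flatten(h), wd)

        real = rng.random((4, 4, 4, 1)).astype(np.float32)
        fake = rng.random((4, 4, 4, 1)).astype(np.float32)
        # reproduce the interpolates the penalty uses
        u = np.random.default_rng(7).random((4, 1, 1, 1)).astype(np.float32)
        xhat = u * real + (1 - u) * fake

        eps = 1e-3
        norms = []
        for s in range(4):
            g = np.zeros(16)
            for i in range(16):
                for sign, store in ((1, 0), (-1, 1)):
                    pert = xhat[s].copy().ravel()
                    pert[i] += sign * eps
                    val = critic(Tensor(
                        pert.reshape(1, 4, 4, 1).astype(np.float32))).item()
                    if sign == 1:
                        up = val
                    else:
                        g[i] = (up - val) / (2 * eps)
            norms.append(np.linalg.norm(g))
        expect = 10.0 * np.mean((np.array(norms) - 1) ** 2)
        gp = gradient_penalty(critic, real, fake, gp_lambda=10.0, seed=7)
        assert abs(gp.item() - expect) / abs(expect) < 1e-3

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="share a shape"):
            gradient_penalty(lambda x: x, np.zeros((2, 4, 4, 1)),
                             np.zeros((3, 4, 4, 1)))


def rem_images(n, side=32, seed=0):
    from sleepscore.stages import Hypnogram
    from sleepscore.synth import synthesize_signals
    from sleepscore.imaging import build_window_images

    hyp = Hypnogram(np.full(n, Stage.REM, dtype=np.int8))
    rec = synthesize_signals(hyp, seed=seed)
    return ImageDataset(build_window_images(rec, hyp, out_px=side,
                                            subject_id="remgen"))


class TestTraining:
    def test_zero_steps_leaves_weights_unchanged(self):
        gan = build_wgan_gp(GanConfig(resolution=32, seed=2))
        before = [p.data.copy() for p in gan.gen_params + gan.critic_params]
        train_wgan(gan, rem_images(8), steps=0, seed=0)
        after = [p.data for p in gan.gen_params + gan.critic_params]
        assert all(np.array_equal(a, b) for a, b in zip(before, after))

    def test_trace_lengths(self):
        gan = build_wgan_gp(GanConfig(resolution=32, seed=2, n_critic=3,
                                      batch_size=4))
        train_wgan(gan, rem_images(8), steps=2, seed=0)
        assert len(gan.critic_loss_trace) == 2 * 3
        assert len(gan.gen_loss_trace) == 2

    def test_mixed_stage_input_rejected(self):
        imgs = rem_images(4).images
        imgs[0].label = Stage.WAKE
        gan = build_wgan_gp(GanConfig(resolution=32))
        with pytest.raises(ValueError, match="mixed-stage"):
            train_wgan(gan, ImageDataset(imgs), steps=1, seed=0)

    def test_resolution_mismatch_rejected(self):
        gan = build_wgan_gp(GanConfig(resolution=64))
        with pytest.raises(ValueError, match="resolution"):
            train_wgan(gan, rem_images(4, side=32), steps=1, seed=0)

    def test_lipschitz_pressure_in_most_seeds(self):
        """Gradient penalty falls over 100 steps in >= 2 of 3 seeded runs."""
        wins = 0
        data = rem_images(24, side=32, seed=9)
        for seed in (0, 1, 2):
            gan = build_wgan_gp(GanConfig(resolution=32, seed=seed,
                                          batch_size=8))
            train_wgan(gan, data, steps=100, seed=seed)
            gp = np.array(gan.gp_trace)
            if gp[-50:].mean() < gp[:50].mean():
                wins += 1
        assert wins >= 2


class TestSampling:
    def test_negative_count_rejected(self):
        gan = build_wgan_gp(GanConfig(resolution=32))
        gan.step = 1
        with pytest.raises(ValueError, match="n must be"):
            sample_fake_images(gan, -1, Stage.REM)

    def test_untrained_sampling_rejected(self):
        gan = build_wgan_gp(GanConfig(resolution=32))
        with pytest.raises(RuntimeError, match="untrained"):
            sample_fake_images(gan, 2, Stage.REM)

    def test_seeded_sampling_is_deterministic(self, trained_gan):
        a = sample_fake_images(trained_gan, 3, Stage.REM, seed=5)
        b = sample_fake_images(trained_gan, 3, Stage.REM, seed=5)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))
        assert sample_fake_images(trained_gan, 0, Stage.REM, seed=5) == []

    def test_fakes_carry_label_and_provenance(self, trained_gan):
        fakes = sample_fake_images(trained_gan, 4, Stage.REM, seed=1)
        assert all(im.label == Stage.REM for im in fakes)
        assert all(im.provenance == "generated" for im in fakes)
        assert all(0 <= im.pixels.min() and im.pixels.max() <= 1 for im in fakes)


class TestSmokeTrainedGan:
    def test_gradient_norm_deviation_improves(self, trained_gan):
        """Critic gradient norms sit nearer 1 late in training than at step 1."""
        dev = np.array(trained_gan.grad_norm_dev_trace)
        assert dev[-50:].mean() < dev[0]

    def test_fake_rem_inherits_spectral_profile(self, rem_corpus, trained_gan):
        """Column-averaged bottom-panel brightness of fakes correlates with real REM."""
        fakes = sample_fake_images(trained_gan, 64, Stage.REM, seed=3)
        real = rem_corpus
        half = real.side_px // 2

        def profile(images):
            arr = np.stack([im.pixels for im in images])
            return arr[:, half:, :].mean(axis=(0, 2))  # per-row brightness

        r = np.corrcoef(profile(fakes), profile(list(real)))[0, 1]
        assert r >= 0.5
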