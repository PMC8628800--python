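"""WGAN-GP for synthesizing fake stage images.

One generator/critic pair is trained per sleep stage (the minority
class, REM, in the usual workflow). The generator projects a latent
vector to a 4x4 seed map and doubles the resolution per block
(upsample + conv), so a 512 px output needs 7 blocks and a 128 px
output 5; the critic mirrors this with stride-2 convolutions ending in
a single linear unit — a Wasserstein critic, no sigmoid. The critic's
1-Lipschitz constraint is enforced softly by the gradient penalty
lambda * mean((||grad_xhat D(xhat)|| - 1)^2) evaluated at random
interpolates between real and fake batches; computing its weight
gradient uses the engine's double backpropagation.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from . import nn
from .nn import functional as F
from .nn import tensor as T
from .nn.tensor import Tensor
from .dataset import ImageDataset
from .imaging import EpochImage
from .stages import Stage

__all__ = [
    "GanConfig",
    "GanModel",
    "build_wgan_gp",
    "gradient_penalty",
    "train_wgan",
    "sample_fake_images",
]


@dataclass
class GanConfig:
    resolution: int = 512
    latent_dim: int = 100
    base_feature_maps: int = 64
    gp_lambda: float = 10.0
    n_critic: int = 5
    batch_size: int = 16
    lr_generator: float = 2e-4
    lr_critic: float = 4e-4  # two-timescale update rule, critic 2x faster
    leak: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        res = self.resolution
        if res < 8 or res & (res - 1) or res % 4:
            raise ValueError(
                f"resolution {res} must be 4 * 2^k for integer k >= 1"
            )
        if self.gp_lambda <= 0:
            raise ValueError("gp_lambda must be positive")
        if self.n_critic < 1:
            raise ValueError("n_critic must be >= 1")
        if self.latent_dim < 1 or self.base_feature_maps < 1:
            raise ValueError("latent_dim and base_feature_maps must be positive")

    @property
    def n_blocks(self) -> int:
        """Doubling upsample blocks from the 4x4 seed map to full size."""
        return int(math.log2(self.resolution // 4))


class GanModel:
    """Generator + critic parameter sets with training traces."""

    def __init__(self, config: GanConfig | None = None):
        self.config = config or GanConfig()
        self.config.validate()
        self.step = 0
        self.critic_loss_trace: list[float] = []
        self.gen_loss_trace: list[float] = []
        self.gp_trace: list[float] = []
        self.grad_norm_dev_trace: list[float] = []
        self._init_params(np.random.default_rng(self.config.seed))

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        nb = cfg.n_blocks

        # classic DCGAN initialization, normal(0, 0.02): both networks start
        # near-flat, so the critic's gradient norms grow from ~0 under
        # adversarial pressure while the penalty pulls them toward 1
        def init(shape, fan_in=None):
            return Tensor((rng.standard_normal(shape) * 0.02).astype(np.float32),
                          requires_grad=True)

        # generator feature maps halve as resolution doubles (floor 8)
        gen_fm = [max(cfg.base_feature_maps // (2 ** i), 8) for i in range(nb)]
        self.gen_params: list[Tensor] = []
        w = init((cfg.latent_dim, 4 * 4 * cfg.base_feature_maps))
        b = Tensor(np.zeros(4 * 4 * cfg.base_feature_maps, np.float32),
                   requires_grad=True)
        self._gen_proj = (w, b)
        self.gen_params += [w, b]
        self._gen_convs = []
        c_in = cfg.base_feature_maps
        for f in gen_fm:
            wc = init((9 * c_in, f))
            bc = Tensor(np.zeros(f, np.float32), requires_grad=True)
            self._gen_convs.append((wc, bc))
            self.gen_params += [wc, bc]
            c_in = f
        wo = init((9 * c_in, 1))
        bo = Tensor(np.zeros(1, np.float32), requires_grad=True)
        self._gen_out = (wo, bo)
        self.gen_params += [wo, bo]

        # critic mirrors with stride-2 convs, feature maps doubling (cap base)
        crit_fm = [min(8 * (2 ** i), cfg.base_feature_maps) for i in range(nb)]
        self.critic_params: list[Tensor] = []
        self._crit_convs = []
        c_in = 1
        for f in crit_fm:
            wc = init((9 * c_in, f))
            bc = Tensor(np.zeros(f, np.float32), requires_grad=True)
            self._crit_convs.append((wc, bc))
            self.critic_params += [wc, bc]
            c_in = f
        flat = 4 * 4 * c_in
        wd = init((flat, 1))
        bd = Tensor(np.zeros(1, np.float32), requires_grad=True)
        self._crit_dense = (wd, bd)
        self.critic_params += [wd, bd]

    @property
    def n_generator_blocks(self) -> int:
        return len(self._gen_convs)

    @property
    def n_critic_blocks(self) -> int:
        return len(self._crit_convs)

    # -- forward passes ----------------------------------------------
    def generator_forward(self, z: Tensor) -> Tensor:
        cfg = self.config
        w, b = self._gen_proj
        h = T.leaky_relu(F.dense(z, w, b), cfg.leak)
        h = T.reshape(h, (z.shape[0], 4, 4, cfg.base_feature_maps))
        for wc, bc in self._gen_convs:
            h = T.upsample_nearest(h, 2)
            h = T.leaky_relu(F.conv2d(h, wc, bc), cfg.leak)
        wo, bo = self._gen_out
        return T.sigmoid(F.conv2d(h, wo, bo))  # pixels in (0, 1)

    def critic_forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        h = x
        for wc, bc in self._crit_convs:
            h = T.leaky_relu(F.conv2d(h, wc, bc, stride=2, pad=1), cfg.leak)
        h = F.flatten(h)
        wd, bd = self._crit_dense
        return F.dense(h, wd, bd)  # (N, 1) unbounded Wasserstein score

    def generate(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n fake images as an (n, res, res, 1) array in [0, 1]."""
        out = []
        with nn.no_grad():
            for s in range(0, n, self.config.batch_size):
                m = min(self.config.batch_size, n - s)
                z = Tensor(rng.standard_normal(
                    (m, self.config.latent_dim)).astype(np.float32))
                out.append(self.generator_forward(z).data)
        if not out:
            return np.zeros((0, self.config.resolution, self.config.resolution, 1),
                            np.float32)
        return np.concatenate(out, axis=0)


def build_wgan_gp(config: GanConfig | None = None) -> GanModel:
    return GanModel(config)


def gradient_penalty(
    critic: Callable[[Tensor], Tensor],
    real_batch: np.ndarray,
    fake_batch: np.ndarray,
    gp_lambda: float = 10.0,
    seed: int | np.random.Generator = 0,
    create_graph: bool = False,
) -> Tensor:
    """lambda * mean((||grad_xhat critic(xhat)||_2 - 1)^2).

    ``xhat`` interpolates each real/fake pair at a Uniform(0,1) draw.
    With ``create_graph=True`` the result can be backpropagated to the
    critic's weights (double backprop), which is how training uses it.
    """
    real = np.asarray(real_batch, dtype=np.float32)
    fake = np.asarray(fake_batch, dtype=np.float32)
    if real.shape != fake.shape:
        raise ValueError(
            f"real and fake batches must share a shape, got {real.shape} vs {fake.shape}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = real.shape[0]
    u = rng.random((n,) + (1,) * (real.ndim - 1)).astype(np.float32)
    xhat = Tensor(u * real + (1.0 - u) * fake, requires_grad=True)
    score = critic(xhat)
    ones = np.ones_like(score.data)
    (dx,) = nn.grad(score, [xhat], grad_output=ones, create_graph=True)
    sq = T.tsum(T.reshape(dx * dx, (n, -1)), axis=1)
    norm = T.sqrt(sq + Tensor(np.asarray(1e-12, np.float32)))
    one = Tensor(np.asarray(1.0, np.float32))
    dev = norm - one
    penalty = T.mean(dev * dev) * Tensor(np.asarray(gp_lambda, np.float32))
    if not create_graph:
        return Tensor(penalty.data)
    return penalty


def train_wgan(
    gan: GanModel,
    images: ImageDataset,
    steps: int,
    seed: int = 0,
) -> GanModel:
    """Adversarial training: n_critic critic updates per generator update.

    The critic minimizes mean(D(fake)) - mean(D(real)) + gradient
    penalty; the generator maximizes mean(D(fake)). All sampling is
    driven by one seeded generator stream.
    """
    cfg = gan.config
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if len(images) == 0:
        raise ValueError("training set is empty")
    stages = {im.label for im in images}
    if len(stages) > 1:
        raise ValueError(
            f"mixed-stage GAN input {sorted(s.name for s in stages)}; "
            "train one generator per stage"
        )
    if images.side_px != cfg.resolution:
        raise ValueError(
            f"image size {images.side_px} does not match GAN resolution {cfg.resolution}"
        )
    X, _ = images.to_arrays()
    rng = np.random.default_rng(seed)
    opt_c = nn.Adam(gan.critic_params, lr=cfg.lr_critic, beta1=0.5, beta2=0.9)
    opt_g = nn.Adam(gan.gen_params, lr=cfg.lr_generator, beta1=0.5, beta2=0.9)

    for _ in range(steps):
        for _ in range(cfg.n_critic):
            idx = rng.integers(0, len(X), size=cfg.batch_size)
            real = X[idx]
            z = Tensor(rng.standard_normal(
                (cfg.batch_size, cfg.latent_dim)).astype(np.float32))
            with nn.no_grad():
                fake = gan.generator_forward(z).data  # detached for critic step
            d_real = T.mean(gan.critic_forward(Tensor(real)))
            d_fake = T.mean(gan.critic_forward(Tensor(fake)))
            gp = gradient_penalty(gan.critic_forward, real, fake,
                                  cfg.gp_lambda, rng, create_graph=True)
            loss_c = d_fake - d_real + gp
            grads = nn.grad(loss_c, gan.critic_params)
            opt_c.step(grads)
            gan.critic_loss_trace.append(loss_c.item())
            gan.gp_trace.append(gp.item())
            gan.grad_norm_dev_trace.append(
                float(np.sqrt(gp.item() / cfg.gp_lambda)))
        z = Tensor(rng.standard_normal(
            (cfg.batch_size, cfg.latent_dim)).astype(np.float32))
        fake = gan.generator_forward(z)
        loss_g = T.neg(T.mean(gan.critic_forward(fake)))
        grads = nn.grad(loss_g, gan.gen_params)
        opt_g.step(grads)
        gan.gen_loss_trace.append(loss_g.item())
        gan.step += 1
    return gan


def sample_fake_images(
    gan: GanModel,
    n: int,
    stage_label: Stage,
    seed: int = 0,
) -> list[EpochImage]:
    """Draw n generator samples as labeled EpochImages (provenance=generated)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if gan.step == 0:
        raise RuntimeError("GAN is untrained; call train_wgan() first")
    rng = np.random.default_rng(seed)
    batch = gan.generate(n, rng)
    return [
        EpochImage(np.clip(batch[i, :, :, 0], 0.0, 1.0),
                   label=Stage.from_label(stage_label),
                   provenance="generated", subject_id="__generated__")
        for i in range(n)
    ]
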