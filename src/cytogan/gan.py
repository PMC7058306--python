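"""Progressively grown GAN, DCGAN baseline, and sliced Wasserstein distance.

One GAN is trained per class (benign, malignant).  The progressive generator
starts from a 128-value standard-normal latent vector and produces 4x4
images; each growth stage appends a block that doubles the resolution, and
the new block is blended in with a linear fade-in coefficient alpha
(``out = alpha * new + (1 - alpha) * upsampled old``).  The discriminator
mirrors the generator.  Training follows the Wasserstein formulation
(critic scores are unbounded; d_loss = E[fake] - E[real]), with the critic's
Lipschitz constraint enforced by weight clipping; the norm of the critic's
input gradient is logged as a diagnostic.  Image quality is tracked with the
sliced Wasserstein distance (SWD) between real and generated samples.

Default stage schedule (feature maps per resolution):
512 @ 4, 8, 16 then 256, 128, 64, 32 @ 32, 64, 128, 256.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn

PAPER_FEATURE_MAPS = {4: 512, 8: 512, 16: 512, 32: 256, 64: 128, 128: 64, 256: 32}


@dataclass(frozen=True)
class StageSchedule:
    resolutions: tuple[int, ...]
    feature_maps: tuple[int, ...]
    epochs_per_stage: int = 100
    fadein_fraction: float = 0.5

    def __post_init__(self):
        res = self.resolutions
        if len(res) == 0 or res[0] != 4:
            raise ValueError("schedule must start at resolution 4")
        for a, b in zip(res, res[1:]):
            if b != 2 * a:
                raise ValueError(f"resolutions must double each step, got {a} -> {b}")
        for r in res:
            if r & (r - 1):
                raise ValueError(f"resolution {r} is not a power of 2")
        if len(self.feature_maps) != len(res):
            raise ValueError("need one feature-map count per resolution")

    @classmethod
    def default(cls, max_resolution: int = 256, epochs_per_stage: int = 100,
                fadein_fraction: float = 0.5) -> "StageSchedule":
        res, r = [], 4
        while r <= max_resolution:
            res.append(r)
            r *= 2
        fmaps = tuple(PAPER_FEATURE_MAPS[r] for r in res)
        return cls(tuple(res), fmaps, epochs_per_stage, fadein_fraction)


@dataclass(frozen=True)
class LatentSpec:
    dimension: int = 128

    def __post_init__(self):
        if self.dimension < 1:
            raise ValueError("latent dimension must be >= 1")


@dataclass(frozen=True)
class GanTrainConfig:
    learning_rate: float = 0.001
    beta1: float = 0.0
    beta2: float = 0.999
    minibatch: int = 32
    gp_weight: float = 10.0
    # weight-clipping threshold for the critic.  Parameters are stored in the
    # equalized-learning-rate parametrization (unit-variance weights rescaled
    # by the He constant at run time), so the unit-scale clip plays the role
    # the classic 0.01 plays for raw weights.
    clip_value: float = 1.0
    n_critic: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("Adam betas must lie in [0, 1)")


DCGAN_TRAIN_DEFAULTS = GanTrainConfig(learning_rate=2e-5, beta1=0.5, beta2=0.999, minibatch=32)


def fade_in_alpha(step: int, fade_steps: int) -> float:
    """Linear fade-in coefficient, clamped: alpha = min(step / fade_steps, 1)."""
    if fade_steps < 1:
        raise ValueError("fade_steps must be >= 1")
    if step < 0:
        raise ValueError("step must be non-negative")
    return min(step / fade_steps, 1.0)


def wasserstein_losses(real_scores, fake_scores, gradient_penalty: float = 0.0,
                       gp_weight: float = 10.0) -> tuple[float, float]:
    """Critic and generator losses of the Wasserstein formulation.

    d_loss = mean(fake) - mean(real) + gp_weight * gradient_penalty
    g_loss = -mean(fake)
    """
    real = np.asarray(real_scores, dtype=np.float64).ravel()
    fake = np.asarray(fake_scores, dtype=np.float64).ravel()
    if real.size == 0 or fake.size == 0:
        raise ValueError("score lists must be non-empty")
    d_loss = fake.mean() - real.mean() + gp_weight * gradient_penalty
    g_loss = -fake.mean()
    return float(d_loss), float(g_loss)


def sliced_wasserstein_distance(samples_a, samples_b, n_projections: int = 64,
                                seed: int = 0) -> float:
    """Mean 1-D Wasserstein-1 distance over random unit projections.

    Symmetric, non-negative, zero on identical sample sets; with a single
    projection on 1-D data it reduces to mean |sorted(a) - sorted(b)|.
    """
    a = np.asarray(samples_a, dtype=np.float64).reshape(len(samples_a), -1)
    b = np.asarray(samples_b, dtype=np.float64).reshape(len(samples_b), -1)
    if a.shape != b.shape:
        raise ValueError(f"sample sets must match in shape, got {a.shape} vs {b.shape}")
    rng = np.random.default_rng(seed)
    proj = rng.standard_normal((a.shape[1], n_projections))
    proj /= np.linalg.norm(proj, axis=0, keepdims=True)
    pa = np.sort(a @ proj, axis=0)
    pb = np.sort(b @ proj, axis=0)
    return float(np.abs(pa - pb).mean())


# ---------------------------------------------------------------------------
# progressive generator / discriminator


class PgGenerator:
    def __init__(self, schedule: StageSchedule, latent: LatentSpec, rng: np.random.Generator,
                 pixelnorm: bool = True, equalized: bool = True):
        fm = schedule.feature_maps
        self.schedule = schedule
        self.latent_dim = latent.dimension
        self.pixelnorm = pixelnorm

        def pn():
            return [nn.PixelNorm()] if pixelnorm else []

        self.base = nn.Sequential([
            nn.Dense(latent.dimension, fm[0] * 16, rng, equalized=equalized),
            nn.Reshape(fm[0], 4, 4),
            nn.LeakyReLU(), *pn(),
            nn.Conv2d(fm[0], fm[0], 3, rng, equalized=equalized),
            nn.LeakyReLU(), *pn(),
        ])
        self.blocks = [None]
        for i in range(1, len(fm)):
            self.blocks.append(nn.Sequential([
                nn.UpsampleNearest2(),
                nn.Conv2d(fm[i - 1], fm[i], 3, rng, equalized=equalized),
                nn.LeakyReLU(), *pn(),
                nn.Conv2d(fm[i], fm[i], 3, rng, equalized=equalized),
                nn.LeakyReLU(), *pn(),
            ]))
        self.to_rgb = [nn.Conv2d(f, 3, 1, rng, equalized=equalized, gain=1.0) for f in fm]
        self._up_old = nn.UpsampleNearest2()
        self._tanh = nn.Tanh()

    def params(self) -> list[nn.Param]:
        out = self.base.params()
        for b in self.blocks[1:]:
            out += b.params()
        for t in self.to_rgb:
            out += t.params()
        return out

    def forward(self, z: np.ndarray, stage: int, alpha: float = 1.0, train: bool = True):
        self._stage, self._alpha = stage, alpha
        x = self.base.forward(z.astype(nn.DTYPE), train=train)
        feats = [x]
        for i in range(1, stage + 1):
            x = self.blocks[i].forward(x, train=train)
            feats.append(x)
        if stage > 0 and alpha < 1.0:
            rgb_new = self.to_rgb[stage].forward(x, train=train)
            rgb_old = self._up_old.forward(
                self.to_rgb[stage - 1].forward(feats[stage - 1], train=train), train=train)
            rgb = alpha * rgb_new + (1.0 - alpha) * rgb_old
            self._faded = True
        else:
            rgb = self.to_rgb[stage].forward(x, train=train)
            self._faded = False
        return self._tanh.forward(rgb, train=train)

    def backward(self, grad: np.ndarray) -> None:
        stage, alpha = self._stage, self._alpha
        grad = self._tanh.backward(grad)
        if self._faded:
            g_new = self.to_rgb[stage].backward(alpha * grad)
            g_old = self.to_rgb[stage - 1].backward(self._up_old.backward((1.0 - alpha) * grad))
            g = self.blocks[stage].backward(g_new) + g_old
            lo = stage - 1
        else:
            g = self.to_rgb[stage].backward(grad)
            lo = stage
        for i in range(lo, 0, -1):
            g = self.blocks[i].backward(g)
        self.base.backward(g)


class PgDiscriminator:
    def __init__(self, schedule: StageSchedule, rng: np.random.Generator,
                 minibatch_stddev: bool = True, equalized: bool = True):
        fm = schedule.feature_maps
        self.schedule = schedule
        self.from_rgb = [
            nn.Sequential([nn.Conv2d(3, f, 1, rng, equalized=equalized), nn.LeakyReLU()])
            for f in fm
        ]
        self.blocks = [None]
        for i in range(1, len(fm)):
            self.blocks.append(nn.Sequential([
                nn.Conv2d(fm[i], fm[i], 3, rng, equalized=equalized),
                nn.LeakyReLU(),
                nn.Conv2d(fm[i], fm[i - 1], 3, rng, equalized=equalized),
                nn.LeakyReLU(),
                nn.AvgPool2(),
            ]))
        head = []
        extra = 0
        if minibatch_stddev:
            head.append(nn.MinibatchStdDev())
            extra = 1
        head += [
            nn.Conv2d(fm[0] + extra, fm[0], 3, rng, equalized=equalized),
            nn.LeakyReLU(),
            nn.Flatten(),
            nn.Dense(fm[0] * 16, fm[0], rng, equalized=equalized),
            nn.LeakyReLU(),
            nn.Dense(fm[0], 1, rng, equalized=equalized, gain=1.0),
        ]
        self.head = nn.Sequential(head)
        self._pool_old = nn.AvgPool2()

    def params(self) -> list[nn.Param]:
        out = []
        for f in self.from_rgb:
            out += f.params()
        for b in self.blocks[1:]:
            out += b.params()
        return out + self.head.params()

    def forward(self, img: np.ndarray, stage: int, alpha: float = 1.0, train: bool = True):
        self._stage, self._alpha = stage, alpha
        img = img.astype(nn.DTYPE)
        if stage > 0 and alpha < 1.0:
            x_new = self.blocks[stage].forward(self.from_rgb[stage].forward(img, train=train),
                                               train=train)
            x_old = self.from_rgb[stage - 1].forward(self._pool_old.forward(img, train=train),
                                                     train=train)
            x = alpha * x_new + (1.0 - alpha) * x_old
            self._faded = True
            lo = stage - 1
        else:
            x = self.from_rgb[stage].forward(img, train=train)
            self._faded = False
            lo = stage
        for i in range(lo, 0, -1):
            x = self.blocks[i].forward(x, train=train)
        return self.head.forward(x, train=train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        stage, alpha = self._stage, self._alpha
        g = self.head.backward(grad)
        lo = stage - 1 if self._faded else stage
        for i in range(1, lo + 1):  # reverse of the forward order lo..1
            g = self.blocks[i].backward(g)
        if self._faded:
            g_new = self.from_rgb[stage].backward(self.blocks[stage].backward(alpha * g))
            g_old = self._pool_old.backward(self.from_rgb[stage - 1].backward((1.0 - alpha) * g))
            return g_new + g_old
        return self.from_rgb[stage].backward(g)


@dataclass
class GanBundle:
    generator: object
    discriminator: object
    latent: LatentSpec
    class_tag: str = "benign"
    arch: str = "pggan"
    schedule: StageSchedule | None = None
    stage: int = 0
    alpha: float = 1.0

    @property
    def resolution(self) -> int:
        if self.arch == "pggan":
            return self.schedule.resolutions[self.stage]
        return self.generator.resolution


def build_pggan(schedule: StageSchedule, latent: LatentSpec = LatentSpec(),
                class_tag: str = "benign", seed: int = 0,
                pixelnorm: bool = True, minibatch_stddev: bool = True,
                equalized: bool = True) -> GanBundle:
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    gen = PgGenerator(schedule, latent, rng, pixelnorm=pixelnorm, equalized=equalized)
    disc = PgDiscriminator(schedule, rng, minibatch_stddev=minibatch_stddev, equalized=equalized)
    return GanBundle(gen, disc, latent, class_tag, "pggan", schedule, stage=0, alpha=1.0)


# ---------------------------------------------------------------------------
# training


def _to_float(images: np.ndarray) -> np.ndarray:
    """uint8 HWC images -> float32 NCHW in [-1, 1]."""
    x = images.astype(nn.DTYPE) / 127.5 - 1.0
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _to_uint8(x: np.ndarray) -> np.ndarray:
    """float NCHW in [-1, 1] -> uint8 NHWC."""
    y = np.clip((x + 1.0) * 127.5, 0, 255)
    return np.rint(y).astype(np.uint8).transpose(0, 2, 3, 1)


def downsample_to(images_f: np.ndarray, resolution: int) -> np.ndarray:
    """Average-pool NCHW float images down to a target power-of-2 resolution."""
    n, c, h, w = images_f.shape
    if h == resolution:
        return images_f
    factor = h // resolution
    if factor * resolution != h:
        raise ValueError(f"cannot pool {h} down to {resolution}")
    return images_f.reshape(n, c, resolution, factor, resolution, factor).mean(axis=(3, 5))


def input_gradient_norm(disc, images: np.ndarray, stage: int, alpha: float) -> float:
    """Mean L2 norm of d score / d input over a batch (Lipschitz diagnostic)."""
    scores = disc.forward(images, stage, alpha)
    for p in disc.params():
        p.zero_grad()
    dx = disc.backward(np.ones_like(scores))
    for p in disc.params():
        p.zero_grad()
    norms = np.sqrt((dx.reshape(len(dx), -1) ** 2).sum(axis=1))
    return float(norms.mean())


def train_pggan(bundle: GanBundle, images: np.ndarray, config: GanTrainConfig,
                schedule: StageSchedule | None = None, swd_samples: int = 32,
                checkpoint_dir=None, log_input_grad: bool = False) -> dict:
    """Run the progressive schedule on one class's images.

    ``images``: (N, R, R, 3) uint8 at the schedule's final resolution.  Each
    stage runs a fade-in phase (alpha ramping linearly over
    ``fadein_fraction`` of the stage's steps, skipped at stage 0) followed by
    stabilization at alpha = 1.  Returns a log dict with per-stage SWD between
    real and generated samples; fully deterministic given config.seed.
    """
    schedule = schedule or bundle.schedule
    r_max = schedule.resolutions[-1]
    if images.ndim != 4 or images.shape[1] != images.shape[2] or images.shape[1] < r_max:
        raise ValueError(f"expected (N, R, R, 3) images with R >= {r_max}, got {images.shape}")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    # larger sources are average-pooled down to the schedule's top resolution
    reals_full = downsample_to(_to_float(images), r_max)
    n = len(images)
    gen, disc = bundle.generator, bundle.discriminator
    opt_g = nn.Adam(gen.params(), config.learning_rate, config.beta1, config.beta2)
    opt_d = nn.Adam(disc.params(), config.learning_rate, config.beta1, config.beta2)
    log = {"stages": [], "d_loss": [], "g_loss": [], "swd": [], "input_grad_norm": []}

    for stage, res in enumerate(schedule.resolutions):
        reals = downsample_to(reals_full, res)
        steps_per_epoch = max(1, int(np.ceil(n / config.minibatch)))
        total_steps = schedule.epochs_per_stage * steps_per_epoch
        fade_steps = max(1, int(round(schedule.fadein_fraction * total_steps))) if stage else 0
        step = 0
        for _ in range(schedule.epochs_per_stage):
            order = rng.permutation(n)
            for b0 in range(0, n, config.minibatch):
                batch = reals[order[b0:b0 + config.minibatch]]
                m = len(batch)
                alpha = fade_in_alpha(step, fade_steps) if fade_steps else 1.0
                # --- critic update(s)
                for _c in range(config.n_critic):
                    z = rng.standard_normal((m, bundle.latent.dimension))
                    fake = gen.forward(z, stage, alpha, train=True)
                    opt_d.zero_grad()
                    s_real = disc.forward(batch, stage, alpha)
                    disc.backward(np.full_like(s_real, -1.0 / m))
                    s_fake = disc.forward(fake, stage, alpha)
                    disc.backward(np.full_like(s_fake, 1.0 / m))
                    opt_d.step()
                    nn.clip_params(disc.params(), config.clip_value)
                d_loss, _ = wasserstein_losses(s_real, s_fake, 0.0, config.gp_weight)
                # --- generator update
                z = rng.standard_normal((m, bundle.latent.dimension))
                opt_g.zero_grad()
                fake = gen.forward(z, stage, alpha, train=True)
                s_fake = disc.forward(fake, stage, alpha)
                for p in disc.params():
                    p.zero_grad()
                dimg = disc.backward(np.full_like(s_fake, -1.0 / m))
                for p in disc.params():
                    p.zero_grad()
                gen.backward(dimg)
                opt_g.step()
                _, g_loss = wasserstein_losses(s_real, s_fake, 0.0, config.gp_weight)
                step += 1
        bundle.stage, bundle.alpha = stage, 1.0
        k = min(swd_samples, n)
        fake_s = _to_float(sample_images(bundle, k, seed=config.seed + 1000 + stage))
        swd = sliced_wasserstein_distance(reals[:k].reshape(k, -1),
                                          fake_s.reshape(k, -1), seed=config.seed)
        log["stages"].append(res)
        log["d_loss"].append(float(d_loss))
        log["g_loss"].append(float(g_loss))
        log["swd"].append(swd)
        if log_input_grad:
            log["input_grad_norm"].append(
                input_gradient_norm(disc, reals[:k], stage, 1.0))
        if checkpoint_dir is not None:
            save_bundle(bundle, Path(checkpoint_dir) / f"stage_{res}")
    return log


def sample_images(bundle: GanBundle, n: int, seed: int = 0) -> np.ndarray:
    """Draw n seeded latents and decode them; returns (n, R, R, 3) uint8."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = []
    for b0 in range(0, n, 64):
        m = min(64, n - b0)
        z = rng.standard_normal((m, bundle.latent.dimension))
        if bundle.arch == "pggan":
            img = bundle.generator.forward(z, bundle.stage, bundle.alpha, train=False)
        else:
            img = bundle.generator.forward(z, train=False)
        out.append(_to_uint8(img))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# DCGAN baseline


class DcganGenerator:
    """Direct (non-progressive) generator: 5 conv layers, 4 upscaling layers."""

    def __init__(self, latent: LatentSpec, resolution: int, base_channels: int,
                 rng: np.random.Generator):
        if resolution % 16:
            raise ValueError("resolution must be divisible by 16 (4 upscaling layers)")
        self.resolution = resolution
        self.base_channels = base_channels
        base = resolution // 16
        c = base_channels
        chans = [c, c, max(c // 2, 8), max(c // 4, 8), max(c // 8, 8)]
        layers = [
            nn.Dense(latent.dimension, chans[0] * base * base, rng),
            nn.Reshape(chans[0], base, base),
            nn.LeakyReLU(),
        ]
        for i in range(4):  # 4 scaling layers, each followed by a conv
            layers += [nn.UpsampleNearest2(),
                       nn.Conv2d(chans[i], chans[i + 1], 3, rng),
                       nn.LeakyReLU()]
        layers += [nn.Conv2d(chans[4], 3, 3, rng, gain=1.0), nn.Tanh()]  # 5th conv
        self.net = nn.Sequential(layers)

    def params(self):
        return self.net.params()

    def forward(self, z, train: bool = True):
        return self.net.forward(z.astype(nn.DTYPE), train=train)

    def backward(self, grad):
        return self.net.backward(grad)


class DcganDiscriminator:
    """6 convolutional layers plus 1 output layer."""

    def __init__(self, resolution: int, base_channels: int, rng: np.random.Generator):
        c = base_channels
        chans = [3, max(c // 8, 8), max(c // 4, 8), max(c // 2, 8), c, c, c]
        layers = []
        res = resolution
        for i in range(6):
            layers += [nn.Conv2d(chans[i], chans[i + 1], 3, rng), nn.LeakyReLU()]
            if res > 4:
                layers.append(nn.AvgPool2())
                res //= 2
        layers += [nn.Flatten(), nn.Dense(chans[6] * res * res, 1, rng, gain=1.0)]
        self.net = nn.Sequential(layers)

    def params(self):
        return self.net.params()

    def forward(self, x, train: bool = True):
        return self.net.forward(x.astype(nn.DTYPE), train=train)

    def backward(self, grad):
        return self.net.backward(grad)


def build_dcgan(latent: LatentSpec = LatentSpec(), resolution: int = 256,
                base_channels: int = 64, class_tag: str = "benign",
                seed: int = 0) -> GanBundle:
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    gen = DcganGenerator(latent, resolution, base_channels, rng)
    disc = DcganDiscriminator(resolution, base_channels, rng)
    return GanBundle(gen, disc, latent, class_tag, "dcgan", None, stage=0, alpha=1.0)


def count_layers(module) -> dict:
    """Introspect a generator/discriminator: conv, scaling and dense layer counts."""
    seqs = []
    if hasattr(module, "net"):
        seqs = [module.net]
    counts = {"conv": 0, "dense": 0, "upscale": 0, "downscale": 0}
    for seq in seqs:
        for l in seq.layers:
            if isinstance(l, nn.Conv2d):
                counts["conv"] += 1
            elif isinstance(l, nn.Dense):
                counts["dense"] += 1
            elif isinstance(l, nn.UpsampleNearest2):
                counts["upscale"] += 1
            elif isinstance(l, nn.AvgPool2):
                counts["downscale"] += 1
    return counts


def train_dcgan(bundle: GanBundle, images: np.ndarray,
                config: GanTrainConfig = DCGAN_TRAIN_DEFAULTS, epochs: int = 1) -> dict:
    """Standard (non-saturating) GAN training for the DCGAN baseline."""
    res = bundle.generator.resolution
    if images.shape[1] != res:
        raise ValueError(f"expected {res}-pixel images, got {images.shape}")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    reals = _to_float(images)
    n = len(images)
    gen, disc = bundle.generator, bundle.discriminator
    opt_g = nn.Adam(gen.params(), config.learning_rate, config.beta1, config.beta2)
    opt_d = nn.Adam(disc.params(), config.learning_rate, config.beta1, config.beta2)
    log = {"d_loss": [], "g_loss": []}
    for _ in range(epochs):
        order = rng.permutation(n)
        for b0 in range(0, n, config.minibatch):
            batch = reals[order[b0:b0 + config.minibatch]]
            m = len(batch)
            z = rng.standard_normal((m, bundle.latent.dimension))
            fake = gen.forward(z, train=True)
            opt_d.zero_grad()
            s_real = disc.forward(batch)
            lr_, d = nn.bce_with_logits(s_real, 1)
            disc.backward(d)
            s_fake = disc.forward(fake)
            lf_, d = nn.bce_with_logits(s_fake, 0)
            disc.backward(d)
            opt_d.step()
            z = rng.standard_normal((m, bundle.latent.dimension))
            opt_g.zero_grad()
            fake = gen.forward(z, train=True)
            s_fake = disc.forward(fake)
            lg, d = nn.bce_with_logits(s_fake, 1)
            for p in disc.params():
                p.zero_grad()
            dimg = disc.backward(d)
            for p in disc.params():
                p.zero_grad()
            gen.backward(dimg)
            opt_g.step()
        log["d_loss"].append(lr_ + lf_)
        log["g_loss"].append(lg)
    return log


# ---------------------------------------------------------------------------
# checkpoints


def save_bundle(bundle: GanBundle, ckpt_dir) -> None:
    """Self-describing checkpoint: parameter arrays + JSON metadata."""
    d = Path(ckpt_dir)
    d.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, p in enumerate(bundle.generator.params()):
        arrays[f"g_{i}"] = p.value
    for i, p in enumerate(bundle.discriminator.params()):
        arrays[f"d_{i}"] = p.value
    np.savez(d / "params.npz", **arrays)
    meta = {
        "arch": bundle.arch,
        "class_tag": bundle.class_tag,
        "latent_dim": bundle.latent.dimension,
        "stage": bundle.stage,
        "alpha": bundle.alpha,
    }
    if bundle.arch == "pggan":
        meta["resolutions"] = list(bundle.schedule.resolutions)
        meta["feature_maps"] = list(bundle.schedule.feature_maps)
        meta["epochs_per_stage"] = bundle.schedule.epochs_per_stage
        meta["fadein_fraction"] = bundle.schedule.fadein_fraction
    else:
        meta["resolution"] = bundle.generator.resolution
        meta["base_channels"] = bundle.generator.base_channels
    (d / "meta.json").write_text(json.dumps(meta, indent=2))


def load_bundle(ckpt_dir) -> GanBundle:
    d = Path(ckpt_dir)
    meta = json.loads((d / "meta.json").read_text())
    latent = LatentSpec(meta["latent_dim"])
    if meta["arch"] == "pggan":
        schedule = StageSchedule(tuple(meta["resolutions"]), tuple(meta["feature_maps"]),
                                 meta["epochs_per_stage"], meta["fadein_fraction"])
        bundle = build_pggan(schedule, latent, meta["class_tag"])
    else:
        bundle = build_dcgan(latent, meta["resolution"], meta.get("base_channels", 64),
                             class_tag=meta["class_tag"])
    bundle.stage = meta["stage"]
    bundle.alpha = meta["alpha"]
    with np.load(d / "params.npz") as data:
        for i, p in enumerate(bundle.generator.params()):
            p.value[...] = data[f"g_{i}"]
        for i, p in enumerate(bundle.discriminator.params()):
            p.value[...] = data[f"d_{i}"]
    return bundle
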