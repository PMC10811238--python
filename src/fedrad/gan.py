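"""Per-centre, per-class Wasserstein GAN for representative-data synthesis.

Instead of uploading raw patient images, each centre trains one WGAN per
class on its own data and uploads generated samples with added Gaussian
noise.  The critic maximises ``E[f(real)] - E[f(fake)]`` subject to a
Lipschitz constraint enforced by weight clipping (the original Wasserstein
scheme); the generator minimises ``-E[f(fake)]``.  Both networks are small
convolutional models sized for square grey-level patches, trained with
RMSprop.

Generated sets carry provenance: a :class:`RepresentativeSet` can only be
produced by a generator (or by perturbing another representative set), so
raw cohort images can never leak into an upload payload by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .nn import (
    Conv2d,
    GlobalAvgPool,
    LeakyReLU,
    Linear,
    Module,
    ReLU,
    Reshape,
    RMSprop,
    Sequential,
    Tanh,
    Upsample2x,
)

__all__ = [
    "GanConfig",
    "RepresentativeSet",
    "build_generator",
    "build_critic",
    "train_wgan",
    "generate_representative",
    "perturb_gaussian",
    "save_representative",
    "clip_weights",
]


@dataclass(frozen=True)
class GanConfig:
    latent_dim: int = 16
    critic_steps: int = 2
    lipschitz_mode: str = "clip"
    clip_value: float = 0.01
    gp_lambda: float = 0.0
    generator_steps: int = 120
    batch_size: int = 16
    learning_rate: float = 5e-4
    image_size: int = 64
    base_channels: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.critic_steps < 1:
            raise ValueError("critic_steps must be >= 1")
        if self.clip_value <= 0:
            raise ValueError("clip_value must be > 0")
        if self.gp_lambda < 0:
            raise ValueError("gp_lambda must be >= 0")
        if self.lipschitz_mode not in ("clip", "gradient_penalty"):
            raise ValueError("lipschitz_mode must be 'clip' or 'gradient_penalty'")


@dataclass
class RepresentativeSet:
    """Generated surrogate patches for one centre, value range [-1, 1]."""

    images: np.ndarray  # (n, H, W)
    class_labels: np.ndarray  # (n,)
    centre_id: str
    perturbed: bool = False
    sigma: float = 0.0
    _provenance: str = "generated"

    def __post_init__(self) -> None:
        if len(self.images) != len(self.class_labels):
            raise ValueError("one label per image required")
        if self.perturbed and self.sigma <= 0:
            raise ValueError("perturbed sets must record sigma > 0")
        if self._provenance != "generated":
            raise ValueError("representative sets must come from a generator")


def build_generator(config: GanConfig, rng: np.random.Generator) -> Module:
    s = config.image_size
    if s % 8 != 0:
        raise ValueError("image_size must be a multiple of 8")
    c = config.base_channels
    s0 = s // 8
    return Sequential(
        Linear(config.latent_dim, 4 * c * s0 * s0, rng),
        Reshape((4 * c, s0, s0)),
        ReLU(),
        Upsample2x(),
        Conv2d(4 * c, 2 * c, 3, rng),
        ReLU(),
        Upsample2x(),
        Conv2d(2 * c, c, 3, rng),
        ReLU(),
        Upsample2x(),
        Conv2d(c, c, 3, rng),
        ReLU(),
        Conv2d(c, 1, 3, rng),
        Tanh(),
    )


def build_critic(config: GanConfig, rng: np.random.Generator) -> Module:
    c = config.base_channels
    return Sequential(
        Conv2d(1, c, 3, rng, stride=2),
        LeakyReLU(0.2),
        Conv2d(c, 2 * c, 3, rng, stride=2),
        LeakyReLU(0.2),
        Conv2d(2 * c, 4 * c, 3, rng, stride=2),
        LeakyReLU(0.2),
        GlobalAvgPool(),
        Linear(4 * c, 1, rng),
    )


def clip_weights(model: Module, clip_value: float) -> None:
    for _, module in model.named_modules():
        for p in module.params.values():
            np.clip(p, -clip_value, clip_value, out=p)


def _critic_update(critic, opt, real, fake, config) -> float:
    n_r, n_f = len(real), len(fake)
    batch = np.concatenate([real, fake])
    scores = critic.forward(batch)[:, 0]
    # maximize mean(real) - mean(fake)  ==  minimize the negation
    grad = np.concatenate([np.full(n_r, -1.0 / n_r), np.full(n_f, 1.0 / n_f)])
    critic.zero_grad()
    critic.backward(grad[:, None])
    opt.step()
    clip_weights(critic, config.clip_value)
    return float(scores[:n_r].mean() - scores[n_r:].mean())


def train_wgan(
    class_images: np.ndarray,
    config: GanConfig,
    generator: Module | None = None,
    critic: Module | None = None,
) -> tuple[Module, Module, dict[str, list[float]]]:
    """Train one WGAN on the images of a single class.

    ``class_images`` are (n, H, W) arrays already scaled to [-1, 1].  Returns
    the trained generator, critic and per-step loss traces.  Deterministic
    given ``config.seed``.
    """
    imgs = np.asarray(class_images, dtype=float)
    if imgs.ndim not in (2, 3) or len(imgs) < 2:
        raise ValueError("need at least 2 samples of one class")
    if imgs.ndim == 2 and (generator is None or critic is None):
        raise ValueError("vector-valued data requires explicit generator and critic networks")
    if config.lipschitz_mode == "gradient_penalty":
        raise NotImplementedError(
            "gradient-penalty mode requires double backpropagation, which this "
            "engine does not provide; use lipschitz_mode='clip'"
        )
    rng = np.random.default_rng(config.seed)
    if generator is None:
        generator = build_generator(config, rng)
    if critic is None:
        critic = build_critic(config, rng)
    g_opt = RMSprop(generator, lr=config.learning_rate)
    c_opt = RMSprop(critic, lr=config.learning_rate)
    x = imgs[:, None, :, :] if imgs.ndim == 3 else imgs

    traces: dict[str, list[float]] = {"critic": [], "generator": []}
    for _ in range(config.generator_steps):
        for _ in range(config.critic_steps):
            idx = rng.integers(0, len(x), size=min(config.batch_size, len(x)))
            z = rng.normal(size=(len(idx), config.latent_dim))
            fake = generator.forward(z)
            traces["critic"].append(_critic_update(critic, c_opt, x[idx], fake, config))
        z = rng.normal(size=(config.batch_size, config.latent_dim))
        fake = generator.forward(z)
        scores = critic.forward(fake)[:, 0]
        critic.zero_grad()
        dx_fake = critic.backward(np.full((len(fake), 1), -1.0 / len(fake)))
        generator.zero_grad()
        generator.backward(dx_fake)
        g_opt.step()
        traces["generator"].append(float(-scores.mean()))
    return generator, critic, traces


def generate_representative(
    generators: dict[int, Module],
    n_per_class: int,
    seed: int,
    centre_id: str = "",
    latent_dim: int = 16,
) -> RepresentativeSet:
    """Sample ``n_per_class`` images from each class-conditional generator."""
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for label in sorted(generators):
        z = rng.normal(size=(n_per_class, latent_dim))
        images.append(generators[label].forward(z)[:, 0])
        labels.extend([label] * n_per_class)
    return RepresentativeSet(
        images=np.concatenate(images), class_labels=np.array(labels), centre_id=centre_id
    )


def save_representative(rep: RepresentativeSet, out_dir) -> "Path":
    """Serialize like a cohort fixture: 16-bit PNGs + a CSV recording the
    class labels and the perturbation state."""
    from pathlib import Path

    import pandas as pd
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, label) in enumerate(zip(rep.images, rep.class_labels)):
        rel = f"rep_{i:04d}.png"
        arr = np.clip(np.round((img + 1.0) * 32767.5), 0, 65535).astype(np.uint16)
        Image.fromarray(arr).save(out / rel)
        rows.append(dict(centre=rep.centre_id, label=int(label),
                         perturbed=rep.perturbed, sigma=rep.sigma, path=rel))
    manifest = out / "representative.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def perturb_gaussian(rep: RepresentativeSet, sigma: float, seed: int) -> RepresentativeSet:
    """Privacy perturbation: add i.i.d. N(0, sigma^2) noise elementwise.

    Returns a new set (the input is untouched); sigma=0 is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return replace(rep, images=rep.images.copy())
    rng = np.random.default_rng(seed)
    noisy = rep.images + rng.normal(0.0, sigma, size=rep.images.shape)
    return replace(rep, images=noisy, perturbed=True, sigma=sigma)
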