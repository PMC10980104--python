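"""DCGAN-style image synthesis of phantom cardiomyocyte fields.

One unconditional GAN is trained per maturation class. The generator maps a
64-dimensional standard-normal latent through a linear projection and four
transposed-convolution layers (batch norm + ReLU between, Tanh head) to an
RGB image in [-1,1]; the discriminator mirrors it with four stride-2
convolutions (batch norm + LeakyReLU) and a Sigmoid head. The adversarial
objective is the standard minimax cross-entropy,

    min_G max_D  E[log D(x)] + E[log(1 - D(G(z)))],

with the discriminator loss implemented as its negation and the generator
trained on the non-saturating form -E[log D(G(z))] by default (the saturating
form is available via config).

Defaults follow the original training setup: Adam with lr 2e-4 and betas
(0.5, 0.999), batch size 64, 2000 epochs, 128x128 images from a (64,)
latent. Epochs, image size and network width scale down for CPU-sized runs.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .nn import (Adam, BatchNorm2d, Conv2d, ConvTranspose2d, Flatten,
                 LeakyReLU, Linear, ReLU, Reshape, Sequential, Sigmoid, Tanh)
from .phantom import CLASSES, LabeledImage

_EPS = 1e-7


@dataclass
class GanConfig:
    """Optimizer and architecture hyperparameters for the image GAN."""

    learning_rate: float = 2e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    batch_size: int = 64
    epochs: int = 2000
    image_size: int = 128
    latent_dim: int = 64
    channels: int = 3
    width: int = 256          # top feature-map width; halves at each upsample
    seed: int = 0
    non_saturating: bool = True
    label_smoothing: float = 0.0   # one-sided: real target 1 - s
    checkpoint_every: int = 0   # epochs; 0 disables intermediate checkpoints

    def __post_init__(self):
        if min(self.learning_rate, self.adam_beta1, self.adam_beta2) <= 0:
            raise ValueError("learning rate and betas must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.image_size % 16 != 0:
            raise ValueError("image_size must be divisible by 16 "
                             "(four stride-2 layers)")
        if self.width % 8 != 0:
            raise ValueError("width must be divisible by 8")


@dataclass
class GanBundle:
    """A trained generator/discriminator pair for one class."""

    generator: Sequential
    discriminator: Sequential
    label: str
    config: GanConfig
    history: list[dict[str, float]] = field(default_factory=list)

    def save(self, out_dir: str | os.PathLike) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.generator.save(os.path.join(out_dir, "generator.npz"))
        self.discriminator.save(os.path.join(out_dir, "discriminator.npz"))
        with open(os.path.join(out_dir, "meta.json"), "w") as fh:
            json.dump({"label": self.label, "config": asdict(self.config)},
                      fh, indent=2)
        import pandas as pd
        pd.DataFrame(self.history).to_csv(
            os.path.join(out_dir, "history.csv"), index=False)

    @classmethod
    def load(cls, out_dir: str | os.PathLike) -> "GanBundle":
        import pandas as pd
        with open(os.path.join(out_dir, "meta.json")) as fh:
            meta = json.load(fh)
        cfg = GanConfig(**meta["config"])
        gen = build_generator(cfg)
        disc = build_discriminator(cfg)
        gen.load(os.path.join(out_dir, "generator.npz"))
        disc.load(os.path.join(out_dir, "discriminator.npz"))
        hist = pd.read_csv(os.path.join(out_dir, "history.csv"))
        return cls(generator=gen, discriminator=disc, label=meta["label"],
                   config=cfg, history=hist.to_dict("records"))


@dataclass
class SyntheticLibrary:
    """GAN-sampled images, balanced across classes."""

    images: list[LabeledImage]
    per_class_count: int

    def __post_init__(self):
        counts = {c: sum(im.label == c for im in self.images) for c in CLASSES}
        if any(v != self.per_class_count for v in counts.values()):
            raise ValueError(f"unbalanced synthetic library: {counts}")


# ---------------------------------------------------------------------------
# architecture

def build_generator(config: GanConfig,
                    rng: np.random.Generator | None = None) -> Sequential:
    """Latent (latent_dim,) -> (channels, S, S) image in [-1,1].

    Linear projection to an (S/16, S/16) feature map, then exactly four
    transposed convolutions (kernel 4, stride 2, pad 1), batch norm and ReLU
    between layers, Tanh at the output.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    s0 = config.image_size // 16
    w = config.width
    return Sequential([
        Linear(config.latent_dim, w * s0 * s0, rng, w_std=0.02),
        Reshape((w, s0, s0)),
        BatchNorm2d(w), ReLU(),
        ConvTranspose2d(w, w // 2, 4, 2, 1, rng), BatchNorm2d(w // 2), ReLU(),
        ConvTranspose2d(w // 2, w // 4, 4, 2, 1, rng), BatchNorm2d(w // 4),
        ReLU(),
        ConvTranspose2d(w // 4, w // 8, 4, 2, 1, rng), BatchNorm2d(w // 8),
        ReLU(),
        ConvTranspose2d(w // 8, config.channels, 4, 2, 1, rng), Tanh(),
    ])


def build_discriminator(config: GanConfig,
                        rng: np.random.Generator | None = None) -> Sequential:
    """(channels, S, S) image -> probability of being real, in (0,1).

    Four stride-2 convolutions mirroring the generator, LeakyReLU(0.2)
    activations with batch norm after the first layer, Sigmoid head.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    s0 = config.image_size // 16
    w = config.width
    return Sequential([
        Conv2d(config.channels, w // 8, 4, 2, 1, rng, w_std=0.02),
        LeakyReLU(0.2),
        Conv2d(w // 8, w // 4, 4, 2, 1, rng, w_std=0.02), BatchNorm2d(w // 4),
        LeakyReLU(0.2),
        Conv2d(w // 4, w // 2, 4, 2, 1, rng, w_std=0.02), BatchNorm2d(w // 2),
        LeakyReLU(0.2),
        Conv2d(w // 2, w, 4, 2, 1, rng, w_std=0.02), BatchNorm2d(w),
        LeakyReLU(0.2),
        Flatten(), Linear(w * s0 * s0, 1, rng, w_std=0.02), Sigmoid(),
    ])


def gan_losses(d_real: np.ndarray, d_fake: np.ndarray
               ) -> tuple[float, float]:
    """Closed-form adversarial losses from discriminator outputs.

    discriminator_loss = -mean(log d_real + log(1 - d_fake)); minimizing it
    maximizes the minimax objective over the discriminator. generator_loss is
    the non-saturating -mean(log d_fake).
    """
    d_real = np.asarray(d_real, dtype=np.float64).ravel()
    d_fake = np.asarray(d_fake, dtype=np.float64).ravel()
    if d_real.size == 0 or d_fake.size == 0:
        raise ValueError("empty probability arrays")
    d_real = np.clip(d_real, _EPS, 1 - _EPS)
    d_fake = np.clip(d_fake, _EPS, 1 - _EPS)
    d_loss = -float(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake)))
    g_loss = -float(np.mean(np.log(d_fake)))
    return d_loss, g_loss


# ---------------------------------------------------------------------------
# estimator

class ImageGAN(BaseEstimator):
    """Unconditional GAN on a stack of same-class images.

    Parameters mirror :class:`GanConfig`. ``fit`` expects an (N, C, S, S)
    float array in [-1,1] (or a list of :class:`LabeledImage`, which will be
    cropped/resized and rescaled); ``sample`` draws new images.

    Attributes set by fit: ``generator_``, ``discriminator_``, ``history_``.
    """

    def __init__(self, learning_rate=2e-4, adam_beta1=0.5, adam_beta2=0.999,
                 batch_size=64, epochs=2000, image_size=128, latent_dim=64,
                 channels=3, width=256, seed=0, non_saturating=True,
                 augment=True, label_smoothing=0.0, checkpoint_every=0):
        self.learning_rate = learning_rate
        self.adam_beta1 = adam_beta1
        self.adam_beta2 = adam_beta2
        self.batch_size = batch_size
        self.epochs = epochs
        self.image_size = image_size
        self.latent_dim = latent_dim
        self.channels = channels
        self.width = width
        self.seed = seed
        self.non_saturating = non_saturating
        self.augment = augment
        self.label_smoothing = label_smoothing
        self.checkpoint_every = checkpoint_every

    def _config(self) -> GanConfig:
        return GanConfig(
            learning_rate=self.learning_rate, adam_beta1=self.adam_beta1,
            adam_beta2=self.adam_beta2, batch_size=self.batch_size,
            epochs=self.epochs, image_size=self.image_size,
            latent_dim=self.latent_dim, channels=self.channels,
            width=self.width, seed=self.seed,
            non_saturating=self.non_saturating,
            label_smoothing=self.label_smoothing)

    def fit(self, X, y=None):
        cfg = self._config()
        # keep the pool 25% larger than the model size so each batch can be
        # randomly cropped (then flipped), as in the acquisition pipeline
        pool = (int(round(cfg.image_size * 1.25)) if self.augment
                else cfg.image_size)
        X = prepare_real_images(X, pool, cfg.channels)
        rng = np.random.default_rng(cfg.seed)
        gen = build_generator(cfg, rng)
        disc = build_discriminator(cfg, rng)
        opt_g = Adam(gen, lr=cfg.learning_rate, beta1=cfg.adam_beta1,
                     beta2=cfg.adam_beta2)
        opt_d = Adam(disc, lr=cfg.learning_rate, beta1=cfg.adam_beta1,
                     beta2=cfg.adam_beta2)
        n = X.shape[0]
        bs = min(cfg.batch_size, n)
        history = []
        self.checkpoints_ = []   # (epoch, generator state) snapshots
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            d_losses, g_losses = [], []
            for start in range(0, n, bs):
                batch = X[order[start:start + bs]]
                if self.augment:
                    batch = _crop_batch(batch, cfg.image_size, rng)
                    batch = _flip_batch(batch, rng)
                m = batch.shape[0]
                # --- discriminator: ascend log D(x) + log(1 - D(G(z)))
                z = rng.standard_normal((m, cfg.latent_dim)).astype(np.float32)
                fake = gen.forward(z, train=True)
                disc.zero_grad()
                p_real = disc.forward(batch, train=True)
                pr = np.clip(p_real, _EPS, 1 - _EPS)
                s = cfg.label_smoothing
                disc.backward(
                    (-(1.0 - s) / (m * pr)
                     + s / (m * (1.0 - pr))).astype(np.float32))
                p_fake = disc.forward(fake, train=True)
                pf = np.clip(p_fake, _EPS, 1 - _EPS)
                disc.backward((1.0 / (m * (1.0 - pf))).astype(np.float32))
                opt_d.step()
                # --- generator
                z = rng.standard_normal((m, cfg.latent_dim)).astype(np.float32)
                fake = gen.forward(z, train=True)
                p_fake = disc.forward(fake, train=True)
                pf = np.clip(p_fake, _EPS, 1 - _EPS)
                if cfg.non_saturating:
                    dply = (-1.0 / (m * pf)).astype(np.float32)
                else:
                    dply = (1.0 / (m * (1.0 - pf))).astype(np.float32)
                disc.zero_grad()
                dx = disc.backward(dply)
                disc.zero_grad()     # generator step must not update D
                gen.zero_grad()
                gen.backward(dx)
                opt_g.step()
                d_l, g_l = gan_losses(p_real, p_fake)
                d_losses.append(d_l)
                g_losses.append(g_l)
            history.append({"epoch": epoch,
                            "d_loss": float(np.mean(d_losses)),
                            "g_loss": float(np.mean(g_losses))})
            if (self.checkpoint_every
                    and (epoch + 1) % self.checkpoint_every == 0):
                self.checkpoints_.append((epoch, gen.state_dict()))
        self.generator_ = gen
        self.discriminator_ = disc
        self.history_ = history
        return self

    def sample(self, n: int, seed: int | None = None) -> np.ndarray:
        """Draw n images (n, C, S, S) in [-1,1] in evaluation mode."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(self.seed if seed is None else seed)
        out = []
        for start in range(0, n, 64):
            m = min(64, n - start)
            z = rng.standard_normal((m, self.latent_dim)).astype(np.float32)
            out.append(self.generator_.forward(z, train=False))
        return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# functional wrappers

def _crop_batch(batch: np.ndarray, size: int,
                rng: np.random.Generator) -> np.ndarray:
    """Random size x size window per sample (no-op if already that size)."""
    h = batch.shape[2]
    if h == size:
        return batch
    tops = rng.integers(0, h - size + 1, batch.shape[0])
    lefts = rng.integers(0, h - size + 1, batch.shape[0])
    return np.stack([b[:, t:t + size, l:l + size]
                     for b, t, l in zip(batch, tops, lefts)])


def _flip_batch(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    flips = rng.random(batch.shape[0]) < 0.5
    if flips.any():
        batch = batch.copy()
        batch[flips] = batch[flips][..., ::-1]
    return batch


def prepare_real_images(images, image_size: int, channels: int = 3
                        ) -> np.ndarray:
    """Normalize training input to an (N, C, S, S) float32 array in [-1,1].

    Accepts an array already in model space, or LabeledImage objects in [0,1]
    storage space (resized with anti-aliasing as in the acquisition path).
    """
    from skimage.transform import resize

    from .phantom import to_model_space
    if isinstance(images, np.ndarray):
        if images.ndim != 4 or images.shape[1] != channels:
            raise ValueError(f"expected (N,{channels},H,W), got {images.shape}")
        X = images.astype(np.float32)
        if X.shape[2] != image_size:
            X = np.stack([
                resize(x, (channels, image_size, image_size),
                       preserve_range=True, anti_aliasing=True)
                for x in X]).astype(np.float32)
        return X
    if len(images) == 0:
        raise ValueError("need at least one training image")
    if hasattr(images[0], "frames"):        # VideoClip list
        from .video import clips_to_array
        return clips_to_array(images, image_size)
    labels = {im.label for im in images}
    if len(labels) > 1:
        raise ValueError(f"training images span multiple classes: {labels}")
    out = []
    for im in images:
        x = im.pixels
        if x.shape[1] != image_size or x.shape[2] != image_size:
            x = resize(x, (x.shape[0], image_size, image_size),
                       preserve_range=True, anti_aliasing=True)
        out.append(to_model_space(x))
    return np.stack(out).astype(np.float32)


def train_image_gan(images: list[LabeledImage],
                    config: GanConfig | None = None) -> GanBundle:
    """Train one per-class GAN and return its bundle with loss history."""
    config = config if config is not None else GanConfig()
    if len(images) == 0:
        raise ValueError("need at least one training image")
    labels = {im.label for im in images}
    if len(labels) > 1:
        raise ValueError(f"training images span multiple classes: {labels}")
    est = ImageGAN(**{k: getattr(config, k) for k in (
        "learning_rate", "adam_beta1", "adam_beta2", "batch_size", "epochs",
        "image_size", "latent_dim", "channels", "width", "seed",
        "non_saturating", "label_smoothing", "checkpoint_every")})
    est.fit(images)
    return GanBundle(generator=est.generator_,
                     discriminator=est.discriminator_,
                     label=images[0].label, config=config,
                     history=est.history_)


def sample_synthetic_images(bundle: GanBundle, n: int, seed: int = 0,
                            out_size: int | None = None
                            ) -> list[LabeledImage]:
    """Sample n synthetic images from a bundle, labeled with its class.

    Images come back in [0,1] storage space (8-bit quantized); ``out_size``
    optionally resizes, e.g. up to the 128 px classifier input resolution
    when the GAN was trained smaller.
    """
    from skimage.transform import resize

    from .phantom import _quantize, to_unit_range
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = bundle.config
    rng = np.random.default_rng(seed)
    images = []
    for start in range(0, n, 64):
        m = min(64, n - start)
        z = rng.standard_normal((m, cfg.latent_dim)).astype(np.float32)
        raw = bundle.generator.forward(z, train=False)
        for x in raw:
            u = to_unit_range(x)
            if out_size is not None and out_size != u.shape[1]:
                u = resize(u, (u.shape[0], out_size, out_size),
                           preserve_range=True, anti_aliasing=True)
            images.append(LabeledImage(
                pixels=_quantize(u), label=bundle.label, domain="seen",
                provenance="gan"))
    return images


def synthesize_class_library(bundles: dict[str, GanBundle], per_class: int,
                             seed: int = 0, out_size: int | None = 128
                             ) -> SyntheticLibrary:
    """Balanced per-class synthetic library (default 320/class -> 960)."""
    missing = [c for c in CLASSES if c not in bundles]
    if missing:
        raise ValueError(f"missing bundles for classes: {missing}")
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    class_seeds = ss.generate_state(len(CLASSES)) % (2 ** 31)
    images = []
    for c, s in zip(CLASSES, class_seeds):
        images.extend(sample_synthetic_images(bundles[c], per_class,
                                              seed=int(s), out_size=out_size))
    return SyntheticLibrary(images=images, per_class_count=per_class)
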