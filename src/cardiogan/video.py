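"""Temporal GAN for 5-frame beating-cell clips.

The five frames of a clip are modeled as the five channels of a single 2-D
generator output of shape (5, 64, 64) — exactly the tensor contract of the
study — so no recurrent or 3-D convolution machinery is involved. The
generator projects the 64-dim latent to a 4x4 map and upsamples through four
transposed convolutions; the discriminator mirrors it and scores whether an
input (5,64,64) stack is a genuine beating sequence.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .gan import GanBundle, GanConfig, ImageGAN
from .phantom import CLIP_FPS, VideoClip, to_model_space, to_unit_range


@dataclass
class VideoGanConfig(GanConfig):
    """Image-GAN config fixed to the (5,64,64) clip contract."""

    image_size: int = 64
    channels: int = 5

    def __post_init__(self):
        super().__post_init__()
        if self.channels != 5:
            raise ValueError("video GAN output is fixed at 5 frames")


class VideoGAN(ImageGAN):
    """GAN over clips; inherits the training loop with clip-shaped tensors."""

    def __init__(self, learning_rate=2e-4, adam_beta1=0.5, adam_beta2=0.999,
                 batch_size=64, epochs=2000, image_size=64, latent_dim=64,
                 width=256, seed=0, non_saturating=True, augment=True,
                 label_smoothing=0.0, checkpoint_every=0):
        super().__init__(
            learning_rate=learning_rate, adam_beta1=adam_beta1,
            adam_beta2=adam_beta2, batch_size=batch_size, epochs=epochs,
            image_size=image_size, latent_dim=latent_dim, channels=5,
            width=width, seed=seed, non_saturating=non_saturating,
            augment=augment, label_smoothing=label_smoothing,
            checkpoint_every=checkpoint_every)


def build_video_generator(config: VideoGanConfig | None = None,
                          rng: np.random.Generator | None = None):
    from .gan import build_generator
    return build_generator(config or VideoGanConfig(), rng)


def build_video_discriminator(config: VideoGanConfig | None = None,
                              rng: np.random.Generator | None = None):
    from .gan import build_discriminator
    return build_discriminator(config or VideoGanConfig(), rng)


def clips_to_array(clips: list[VideoClip], size: int) -> np.ndarray:
    """Clips in [0,1] -> (N,5,size,size) float32 in [-1,1]."""
    from skimage.transform import resize
    if len(clips) == 0:
        raise ValueError("need at least one clip")
    out = []
    for clip in clips:
        f = clip.frames
        if f.shape[1] != size:
            f = resize(f, (f.shape[0], size, size), preserve_range=True,
                       anti_aliasing=True)
        out.append(to_model_space(f))
    return np.stack(out).astype(np.float32)


def train_video_gan(clips: list[VideoClip],
                    config: VideoGanConfig | None = None) -> GanBundle:
    """Train the temporal GAN on beating clips; same contract as the
    image-GAN trainer (per-epoch loss history, deterministic in the seed)."""
    config = config if config is not None else VideoGanConfig()
    est = VideoGAN(**{k: getattr(config, k) for k in (
        "learning_rate", "adam_beta1", "adam_beta2", "batch_size", "epochs",
        "image_size", "latent_dim", "width", "seed", "non_saturating",
        "label_smoothing", "checkpoint_every")})
    pool = int(round(config.image_size * 1.25))
    est.fit(clips_to_array(clips, pool))
    return GanBundle(generator=est.generator_,
                     discriminator=est.discriminator_,
                     label="clip", config=config, history=est.history_)


def sample_clips(bundle: GanBundle, n: int, seed: int = 0
                 ) -> list[VideoClip]:
    """Draw n synthetic clips in [0,1] storage space."""
    if n < 1:
        raise ValueError("n must be >= 1")
    from .phantom import _quantize
    rng = np.random.default_rng(seed)
    clips = []
    for start in range(0, n, 64):
        m = min(64, n - start)
        z = rng.standard_normal((m, bundle.config.latent_dim)) \
            .astype(np.float32)
        raw = bundle.generator.forward(z, train=False)
        for x in raw:
            clips.append(VideoClip(frames=_quantize(to_unit_range(x)),
                                   provenance="gan"))
    return clips


def clip_to_video_file(clip: VideoClip, path: str | os.PathLike,
                       gif: bool = True) -> list[str]:
    """Write a clip as 5 grayscale PNG frames (plus an optional GIF).

    The PNG path round-trips losslessly (frames are stored 8-bit). Returns
    the list of files written; the GIF plays at the clip's native frame
    rate (5 frames at 5 FPS = 1.0 s).
    """
    import imageio.v3 as iio
    path = str(path)
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    u8 = np.round(np.clip(clip.frames, 0, 1) * 255).astype(np.uint8)
    written = []
    for t, frame in enumerate(u8):
        fn = f"{path}_f{t}.png"
        iio.imwrite(fn, frame)
        written.append(fn)
    if gif:
        fn = f"{path}.gif"
        iio.imwrite(fn, u8, duration=1000.0 / clip.fps, loop=0)
        written.append(fn)
    return written


def read_clip(path_prefix: str | os.PathLike, fps: float = CLIP_FPS,
              provenance: str = "phantom") -> VideoClip:
    """Read back a clip written by :func:`clip_to_video_file`."""
    import imageio.v3 as iio
    frames = [iio.imread(f"{path_prefix}_f{t}.png") for t in range(5)]
    arr = np.stack(frames).astype(np.float32) / 255.0
    return VideoClip(frames=arr, fps=fps, provenance=provenance)
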