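"""Procedural phantom microscopy: cell-field images and beating-cell clips.

Real recordings of hiPSC-derived cardiomyocytes cannot be redistributed, so
this module generates stand-in data with the same statistical handles the
real data exhibits: maturation stage controls cell density, cell area,
elongation and alignment (day-2 cultures are sparse fields of small round
cells; day-14 cultures are dense fields of large elongated cells), and a
second acquisition batch ("unseen" domain) is emulated by shifting every
generator parameter mean by a fixed number of its own standard deviations.

Cells are textured ellipses with von-Mises-distributed orientations composed
over a noisy background; fields are rendered at the native 300x300 RGB
acquisition size and resized downstream. Beating clips are single centred
cells whose boundary contracts radially toward the centroid and relaxes
again, with the contraction profile (0, A/2, A, A/2, 0) pixels over five
frames at 5 FPS.

Every generator is a pure function of its parameters and seed: rendering
twice with identical arguments yields bitwise-identical pixels (pixels are
quantized to 8-bit levels at render time so disk round-trips are lossless).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

CLASSES = ("day2", "day6", "day14")
DOMAINS = ("seen", "unseen")
NATIVE_SIZE = (300, 300)
CLIP_FRAMES = 5
CLIP_SIZE = 64
CLIP_FPS = 5.0

# slight per-channel tint so phantom fields are genuinely RGB
_CHANNEL_GAIN = np.array([1.0, 0.97, 0.92], dtype=np.float32)


def _quantize(x: np.ndarray) -> np.ndarray:
    """Snap [0,1] floats to the 8-bit grid used for PNG storage."""
    return (np.round(np.clip(x, 0.0, 1.0) * 255.0) / 255.0).astype(np.float32)


@dataclass(frozen=True)
class PhantomParams:
    """Morphology and imaging parameters for one maturation-stage preset.

    Areas are in px^2 at the native 300x300 render; intensities and noise are
    on the [0,1] pixel scale; ``alignment_kappa`` is the von Mises
    concentration of cell orientations (0 = isotropic).
    """

    cell_density: float          # expected cells per field
    cell_area_range: tuple[float, float]
    elongation_range: tuple[float, float]   # major/minor axis ratio, >= 1
    alignment_kappa: float
    intensity_fg: float
    intensity_bg: float
    noise_sd: float
    texture_scale: float         # px, length scale of within-cell modulation

    def __post_init__(self):
        lo, hi = self.cell_area_range
        elo, ehi = self.elongation_range
        if lo <= 0 or hi < lo:
            raise ValueError("cell_area_range must satisfy 0 < min <= max")
        if elo < 1 or ehi < elo:
            raise ValueError("elongation_range must satisfy 1 <= min <= max")
        if self.alignment_kappa < 0:
            raise ValueError("alignment_kappa must be >= 0")
        for name in ("intensity_fg", "intensity_bg", "noise_sd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.cell_density < 0:
            raise ValueError("cell_density must be >= 0")
        if self.texture_scale <= 0:
            raise ValueError("texture_scale must be > 0")

    @property
    def area_mean(self) -> float:
        return 0.5 * (self.cell_area_range[0] + self.cell_area_range[1])

    @property
    def elongation_mean(self) -> float:
        return 0.5 * (self.elongation_range[0] + self.elongation_range[1])


@dataclass
class LabeledImage:
    """One (3,H,W) image in [0,1] with its class/domain/provenance tags."""

    pixels: np.ndarray
    label: str
    domain: str
    provenance: str = "phantom"
    seed: int | None = None

    def __post_init__(self):
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}")
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.pixels.ndim != 3 or self.pixels.shape[0] != 3:
            raise ValueError(f"pixels must be (3,H,W), got {self.pixels.shape}")


@dataclass
class VideoClip:
    """Five consecutive (64,64) grayscale frames of one beating cell, 5 FPS."""

    frames: np.ndarray
    fps: float = CLIP_FPS
    provenance: str = "phantom"
    amplitude: float | None = None   # ground-truth peak contraction, px

    def __post_init__(self):
        if self.frames.ndim != 3 or self.frames.shape[0] != CLIP_FRAMES:
            raise ValueError(
                f"frames must be ({CLIP_FRAMES},H,W), got {self.frames.shape}")
        if self.frames.shape[1] != self.frames.shape[2]:
            raise ValueError("frames must be square")


@dataclass
class PhantomImageSet:
    images: list[LabeledImage]
    per_class_counts: dict[str, dict[str, int]]   # domain -> class -> count
    seed: int

    def subset(self, domain: str | None = None,
               label: str | None = None) -> list[LabeledImage]:
        return [im for im in self.images
                if (domain is None or im.domain == domain)
                and (label is None or im.label == label)]


# ---------------------------------------------------------------------------
# presets

def make_class_presets(difficulty: float = 0.5) -> dict[str, PhantomParams]:
    """Presets for the three maturation stages.

    ``difficulty`` in [0,1] pulls the day-2 and day-6 morphology toward each
    other (their feature clusters overlap in the real data, while day 14 is
    well separated). At 0 the day-2/day-6 area ranges are disjoint; at 1 they
    overlap over most of the day-2 interval.
    """
    if not 0.0 <= difficulty <= 1.0:
        raise ValueError(f"difficulty must be in [0,1], got {difficulty}")
    d = float(difficulty)
    noise = 0.02 + 0.02 * d
    # areas are sized so cells remain resolved after the 300 -> 128 resize:
    # day-2 cells span ~40 px, day-14 cells ~100 px at native scale, and the
    # day-14 field is near-confluent
    day2 = PhantomParams(
        cell_density=7.0,
        cell_area_range=(1200.0, 2600.0),
        elongation_range=(1.0, 1.5),
        alignment_kappa=0.5,
        intensity_fg=0.55, intensity_bg=0.15,
        noise_sd=noise, texture_scale=6.0)
    day6 = PhantomParams(
        cell_density=13.0 - 4.0 * d,
        cell_area_range=(3000.0 - 1700.0 * d, 5200.0),
        elongation_range=(1.5 - 0.4 * d, 2.5),
        alignment_kappa=1.5,
        intensity_fg=0.60 - 0.03 * d, intensity_bg=0.15,
        noise_sd=noise, texture_scale=6.0)
    day14 = PhantomParams(
        cell_density=22.0,
        cell_area_range=(6000.0, 9000.0),
        elongation_range=(3.0, 5.0),
        alignment_kappa=4.0,
        intensity_fg=0.70, intensity_bg=0.15,
        noise_sd=noise, texture_scale=6.0)
    return {"day2": day2, "day6": day6, "day14": day14}


def shift_params(params: PhantomParams, n_sd: float) -> PhantomParams:
    """Mean-shift every parameter by ``n_sd`` of its own spread, one direction.

    Models a second culture batch on another scaffold: faster growth (denser
    fields of larger, more elongated cells, moving each class toward the
    morphology of the next timepoint), a slightly brighter background and
    slightly more sensor noise. The per-parameter spreads are 35% relative
    for the count and areas (batch-to-batch growth variability), uniform SD
    ((max-min)/sqrt(12)) for elongation, and fixed nominal SDs for the
    imaging parameters.
    """
    if n_sd < 0:
        raise ValueError("n_sd must be >= 0")
    if n_sd == 0:
        return params
    a_lo, a_hi = params.cell_area_range
    a_sd = 0.35 * params.area_mean
    e_lo, e_hi = params.elongation_range
    e_sd = (e_hi - e_lo) / np.sqrt(12.0)
    return dataclasses.replace(
        params,
        cell_density=params.cell_density * (1.0 + 0.35 * n_sd),
        cell_area_range=(a_lo + n_sd * a_sd, a_hi + n_sd * a_sd),
        elongation_range=(e_lo + n_sd * e_sd, e_hi + n_sd * e_sd),
        intensity_bg=float(np.clip(params.intensity_bg + 0.03 * n_sd, 0, 1)),
        noise_sd=float(np.clip(params.noise_sd + 0.02 * n_sd, 0, 1)),
    )


# ---------------------------------------------------------------------------
# rendering

def _sample_cells(params: PhantomParams, shape: tuple[int, int],
                  rng: np.random.Generator) -> list[tuple]:
    """Draw (cy, cx, area, elongation, theta) for a Poisson number of cells."""
    n = rng.poisson(params.cell_density)
    cells = []
    for _ in range(n):
        cy = rng.uniform(0, shape[0])
        cx = rng.uniform(0, shape[1])
        area = rng.uniform(*params.cell_area_range)
        elong = rng.uniform(*params.elongation_range)
        if params.alignment_kappa > 0:
            theta = rng.vonmises(0.0, params.alignment_kappa) / 2.0
        else:
            theta = rng.uniform(-np.pi / 2, np.pi / 2)
        cells.append((cy, cx, area, elong, theta))
    return cells


def _paint_ellipse(canvas: np.ndarray, cy: float, cx: float, area: float,
                   elong: float, theta: float, value: float | np.ndarray):
    """Max-compose one rotated ellipse of the given area onto ``canvas``."""
    b = np.sqrt(area / (np.pi * elong))   # semi-minor
    a = elong * b                         # semi-major
    h, w = canvas.shape
    y0, y1 = int(max(0, np.floor(cy - a))), int(min(h, np.ceil(cy + a) + 1))
    x0, x1 = int(max(0, np.floor(cx - a))), int(min(w, np.ceil(cx + a) + 1))
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    patch = canvas[y0:y1, x0:x1]
    val = value[y0:y1, x0:x1] if isinstance(value, np.ndarray) else value
    np.copyto(patch, np.maximum(patch, val), where=mask)


def _texture_field(shape: tuple[int, int], scale: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean modulation field with unit-ish amplitude."""
    raw = rng.normal(0.0, 1.0, shape)
    sm = ndimage.gaussian_filter(raw, sigma=scale)
    sd = sm.std()
    return (sm / sd if sd > 0 else sm).astype(np.float32)


def render_cell_field(params: PhantomParams,
                      size: tuple[int, int] = NATIVE_SIZE,
                      seed: int = 0,
                      label: str = "day2",
                      domain: str = "seen",
                      cells: list[tuple] | None = None) -> LabeledImage:
    """Render one phantom microscopy field.

    ``cells`` may be given explicitly as (cy, cx, area, elongation, theta)
    tuples; otherwise a Poisson(cell_density) number is sampled. The result is
    deterministic in (params, size, seed, cells).
    """
    h, w = size
    if h < 64 or w < 64:
        raise ValueError(f"field size must be at least 64x64, got {size}")
    rng = np.random.default_rng(seed)
    if cells is None:
        cells = _sample_cells(params, (h, w), rng)
    base = np.full((h, w), params.intensity_bg, dtype=np.float32)
    if cells:
        tex = _texture_field((h, w), params.texture_scale, rng)
        fg = np.clip(params.intensity_fg * (1.0 + 0.25 * tex), 0.0, 1.0)
        for (cy, cx, area, elong, theta) in cells:
            _paint_ellipse(base, cy, cx, area, elong, theta, fg)
    img = base[None, :, :] * _CHANNEL_GAIN[:, None, None]
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    return LabeledImage(pixels=_quantize(img), label=label, domain=domain,
                        provenance="phantom", seed=seed)


def make_image_dataset(presets: dict[str, PhantomParams],
                       n_per_class: int | dict[str, int],
                       unseen_shift: float = 0.0,
                       seed: int = 0,
                       size: tuple[int, int] = NATIVE_SIZE) -> PhantomImageSet:
    """Balanced seen + unseen phantom image set.

    For each class, ``n_per_class`` seen images are drawn from its preset and
    the same number of unseen images from the preset mean-shifted by
    ``unseen_shift`` standard deviations (see :func:`shift_params`).
    """
    if not presets:
        raise ValueError("presets must not be empty")
    if unseen_shift < 0:
        raise ValueError("unseen_shift must be >= 0")
    counts = ({c: int(n_per_class) for c in presets}
              if isinstance(n_per_class, int) else dict(n_per_class))
    if any(v < 1 for v in counts.values()):
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    images: list[LabeledImage] = []
    per_class: dict[str, dict[str, int]] = {d: {} for d in DOMAINS}
    for label in presets:
        base = presets[label]
        for domain in DOMAINS:
            p = base if domain == "seen" else shift_params(base, unseen_shift)
            child = np.random.SeedSequence(
                entropy=ss.entropy,
                spawn_key=(CLASSES.index(label), DOMAINS.index(domain)))
            img_seeds = child.generate_state(counts[label]) % (2 ** 31)
            for s in img_seeds:
                images.append(render_cell_field(
                    p, size=size, seed=int(s), label=label, domain=domain))
            per_class[domain][label] = counts[label]
    return PhantomImageSet(images=images, per_class_counts=per_class,
                           seed=seed)


# ---------------------------------------------------------------------------
# beating clips

def contraction_profile(amplitude: float,
                        n_frames: int = CLIP_FRAMES) -> np.ndarray:
    """Radial boundary displacement (px) per frame: relax -> peak -> relax."""
    half = (n_frames - 1) / 2.0
    t = np.arange(n_frames)
    return amplitude * (1.0 - np.abs(t - half) / half)


def _render_beating_frame(c: float, params: PhantomParams, frame_size: int,
                          radius: float, elong: float, tex: np.ndarray,
                          noise: np.ndarray | None) -> np.ndarray:
    """One frame of a centred cell contracted inward by ``c`` pixels.

    The cell is an ellipse with a bright membrane rim and a textured interior;
    the texture contracts with the cell (material motion), so block matching
    sees genuine radial displacement.
    """
    h = w = frame_size
    cy = cx = (frame_size - 1) / 2.0
    s = max(1.0 - c / radius, 0.05)     # isotropic contraction factor
    a = radius * np.sqrt(elong) * s
    b = radius / np.sqrt(elong) * s
    yy, xx = np.mgrid[0:h, 0:w]
    u = (xx - cx) / a
    v = (yy - cy) / b
    r2 = u ** 2 + v ** 2
    inside = r2 <= 1.0
    # sample the texture in material coordinates so it moves with the tissue
    ty = np.clip((yy - cy) / s + cy, 0, h - 1)
    tx = np.clip((xx - cx) / s + cx, 0, w - 1)
    tex_warp = ndimage.map_coordinates(tex, [ty, tx], order=1)
    interior = params.intensity_fg * (1.0 + 0.30 * tex_warp)
    rim = (r2 > 0.72) & inside
    img = np.full((h, w), params.intensity_bg, dtype=np.float32)
    img[inside] = interior[inside]
    img[rim] = np.clip(params.intensity_fg * 1.55, 0.0, 1.0)
    if noise is not None:
        img = img + noise
    return img


def render_beating_clip(params: PhantomParams, amplitude: float,
                        seed: int = 0, frame_size: int = CLIP_SIZE,
                        radius: float | None = None) -> VideoClip:
    """Five-frame clip of one centred cell beating once at 5 FPS."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    radius = radius if radius is not None else 0.30 * frame_size
    elong = min(params.elongation_mean, 1.3)
    tex = _texture_field((frame_size, frame_size),
                         max(params.texture_scale / 2.0, 1.5), rng)
    prof = contraction_profile(amplitude)
    frames = np.empty((CLIP_FRAMES, frame_size, frame_size), dtype=np.float32)
    for t, c in enumerate(prof):
        noise = (rng.normal(0.0, params.noise_sd,
                            (frame_size, frame_size)).astype(np.float32)
                 if params.noise_sd > 0 else None)
        frames[t] = _render_beating_frame(float(c), params, frame_size,
                                          radius, elong, tex, noise)
    return VideoClip(frames=_quantize(frames), provenance="phantom",
                     amplitude=amplitude)


def render_beating_sequence(params: PhantomParams, amplitude: float,
                            duration_s: float, period_s: float = 1.0,
                            fps: float = CLIP_FPS, seed: int = 0,
                            frame_size: int = CLIP_SIZE) -> np.ndarray:
    """Periodic beating over ``duration_s`` seconds; one beat per period.

    Returns an (n_frames, H, W) array; each period repeats the five-point
    contraction profile so the sequence is suitable for peak-based motion
    quantification over longer windows (e.g. the 20 s normalization window).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    radius = 0.30 * frame_size
    elong = min(params.elongation_mean, 1.3)
    tex = _texture_field((frame_size, frame_size),
                         max(params.texture_scale / 2.0, 1.5), rng)
    n = int(round(duration_s * fps))
    per = period_s * fps
    frames = np.empty((n, frame_size, frame_size), dtype=np.float32)
    for t in range(n):
        phase = (t % per) / per                      # in [0,1)
        c = amplitude * (1.0 - abs(2.0 * phase - 1.0))
        noise = (rng.normal(0.0, params.noise_sd,
                            (frame_size, frame_size)).astype(np.float32)
                 if params.noise_sd > 0 else None)
        frames[t] = _render_beating_frame(float(c), params, frame_size,
                                          radius, elong, tex, noise)
    return _quantize(frames)


def make_clip_dataset(params: PhantomParams, n_clips: int, seed: int = 0,
                      amplitude_range: tuple[float, float] = (2.0, 5.0),
                      frame_size: int = CLIP_SIZE) -> list[VideoClip]:
    """Clips with contraction amplitudes drawn uniformly from a range."""
    if n_clips < 1:
        raise ValueError("n_clips must be >= 1")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    amps = rng.uniform(*amplitude_range, size=n_clips)
    clip_seeds = ss.generate_state(n_clips) % (2 ** 31)
    return [render_beating_clip(params, float(a), seed=int(s),
                                frame_size=frame_size)
            for a, s in zip(amps, clip_seeds)]


# ---------------------------------------------------------------------------
# pixel-space conversions shared across the pipeline

def to_model_space(x: np.ndarray) -> np.ndarray:
    """[0,1] storage scale -> [-1,1] model scale (Tanh output range)."""
    return (x.astype(np.float32) * 2.0 - 1.0)


def to_unit_range(x: np.ndarray) -> np.ndarray:
    """[-1,1] model scale -> [0,1] storage scale."""
    return np.clip((x.astype(np.float32) + 1.0) / 2.0, 0.0, 1.0)
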