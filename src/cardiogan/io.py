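"""Dataset I/O: PNG images + CSV manifests, clip frame sequences, reports.

The on-disk dataset format is a directory of 8-bit RGB PNGs plus a
``manifest.csv`` with columns (filename, label, domain, provenance, seed).
Pixels are stored quantized, so write -> read round-trips are exact against
the in-memory [0,1] arrays produced by the generators.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import CLASSES, DOMAINS, LabeledImage, VideoClip

logger = logging.getLogger("cardiogan")

MANIFEST_COLUMNS = ("filename", "label", "domain", "provenance", "seed")
FORMAT_VERSION = 1


def write_image_dataset(images: list[LabeledImage],
                        root: str | os.PathLike,
                        prefix: str = "img") -> Path:
    """Write images and manifest under ``root``; returns the manifest path."""
    import imageio.v3 as iio
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, im in enumerate(images):
        fn = f"{prefix}_{i:05d}.png"
        u8 = np.round(np.clip(im.pixels, 0, 1) * 255).astype(np.uint8)
        iio.imwrite(root / fn, u8.transpose(1, 2, 0))
        rows.append({"filename": fn, "label": im.label, "domain": im.domain,
                     "provenance": im.provenance,
                     "seed": -1 if im.seed is None else im.seed})
    df = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    df.attrs["format_version"] = FORMAT_VERSION
    manifest = root / "manifest.csv"
    df.to_csv(manifest, index=False)
    return manifest


def read_dataset(manifest_path: str | os.PathLike) -> list[LabeledImage]:
    """Load a PNG+manifest dataset back into [0,1] LabeledImages.

    Raises a validation error naming the offending row for unknown labels or
    missing files; an empty manifest returns an empty list with a warning.
    """
    import imageio.v3 as iio
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path)
    missing_cols = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"manifest missing columns: {sorted(missing_cols)}")
    if len(df) == 0:
        logger.warning("empty manifest: %s", manifest_path)
        return []
    root = manifest_path.parent
    images = []
    for i, row in df.iterrows():
        if row["label"] not in CLASSES:
            raise ValueError(
                f"manifest row {i}: unknown label {row['label']!r}")
        if row["domain"] not in DOMAINS:
            raise ValueError(
                f"manifest row {i}: unknown domain {row['domain']!r}")
        path = root / row["filename"]
        if not path.exists():
            raise FileNotFoundError(f"manifest row {i}: missing file {path}")
        arr = iio.imread(path).astype(np.float32) / 255.0
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        seed = int(row["seed"])
        images.append(LabeledImage(
            pixels=np.ascontiguousarray(arr.transpose(2, 0, 1)),
            label=row["label"], domain=row["domain"],
            provenance=row["provenance"],
            seed=None if seed < 0 else seed))
    return images


def write_clip_dataset(clips: list[VideoClip], root: str | os.PathLike,
                       gif: bool = False) -> Path:
    """Write clips as frame sequences plus a manifest; returns manifest path."""
    from .video import clip_to_video_file
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, clip in enumerate(clips):
        prefix = root / f"clip_{i:04d}"
        clip_to_video_file(clip, prefix, gif=gif)
        rows.append({"prefix": f"clip_{i:04d}", "fps": clip.fps,
                     "provenance": clip.provenance,
                     "amplitude": (np.nan if clip.amplitude is None
                                   else clip.amplitude)})
    manifest = root / "clips.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_clip_dataset(manifest_path: str | os.PathLike) -> list[VideoClip]:
    from .video import read_clip
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    clips = []
    for _, row in df.iterrows():
        clip = read_clip(manifest_path.parent / row["prefix"],
                         fps=row["fps"], provenance=row["provenance"])
        if not np.isnan(row.get("amplitude", np.nan)):
            clip.amplitude = float(row["amplitude"])
        clips.append(clip)
    return clips
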