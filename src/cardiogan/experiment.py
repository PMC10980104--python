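"""Experiment orchestration: config, seeding, the full pipeline, figures.

``run_experiment`` chains phantom generation -> per-class image GANs ->
synthetic library -> three-dataset assembly -> classifier training ->
domain evaluation, PCA fidelity, conventional baselines, and (optionally)
the video GAN and contractility quantification, writing every artifact
under one output directory. All randomness derives from a single global
seed via stage-keyed hashing, and re-running with an identical config and
seed reproduces byte-identical report files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classifier import (ClassifierConfig, CNNMaturationClassifier,
                         assemble_training_sets, images_to_arrays,
                         train_classifier)
from .evaluation import (evaluate_domains, pca_embed, pca_group_tags,
                         run_baselines)
from .gan import GanBundle, GanConfig, train_image_gan
from .io import write_clip_dataset, write_image_dataset
from .phantom import (CLASSES, make_class_presets, make_clip_dataset,
                      make_image_dataset)
from .video import VideoGanConfig, sample_clips, train_video_gan

logger = logging.getLogger("cardiogan")

STAGES = ("phantom", "extra_real", "gan_day2", "gan_day6", "gan_day14",
          "library", "clf_small_real", "clf_large_real", "clf_mixed",
          "baselines", "video_gan", "clips", "split")


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (stage-name-keyed SHA-256, < 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def set_global_seed(global_seed: int,
                    stages: tuple[str, ...] = STAGES) -> dict[str, int]:
    """Per-stage seed table for a run."""
    if global_seed < 0:
        raise ValueError("seed must be non-negative")
    return {stage: derive_seed(global_seed, stage) for stage in stages}


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one end-to-end run."""

    difficulty: float = 0.7
    unseen_shift: float = 1.0
    n_train_per_class: int = 60
    n_test_per_class: int = 40
    n_extra_real_per_class: int = 100
    synthetic_per_class: int = 100
    n_clips: int = 16
    baseline_cycles: int = 10
    include_video: bool = True
    make_figures: bool = True
    seed: int = 0
    out_dir: str = "runs/experiment"
    gan: GanConfig = field(default_factory=lambda: GanConfig(
        image_size=64, width=64, epochs=300, batch_size=16))
    video_gan: VideoGanConfig = field(default_factory=lambda: VideoGanConfig(
        image_size=64, width=32, epochs=150, batch_size=16))
    classifier: ClassifierConfig = field(
        default_factory=lambda: ClassifierConfig(epochs=8, batch_size=16))

    def __post_init__(self):
        if not 0 <= self.difficulty <= 1:
            raise ValueError("difficulty must be in [0,1]")
        if self.unseen_shift < 0:
            raise ValueError("unseen_shift must be >= 0")
        for name in ("n_train_per_class", "n_test_per_class",
                     "synthetic_per_class", "baseline_cycles"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw)
        if "gan" in raw and isinstance(raw["gan"], dict):
            raw["gan"] = GanConfig(**raw["gan"])
        if "video_gan" in raw and isinstance(raw["video_gan"], dict):
            raw["video_gan"] = VideoGanConfig(**raw["video_gan"])
        if "classifier" in raw and isinstance(raw["classifier"], dict):
            raw["classifier"] = ClassifierConfig(**raw["classifier"])
        return cls(**raw)


@dataclass
class RunRecord:
    config: dict
    seeds: dict[str, int]
    input_hash: str
    started: str
    finished: str
    artifacts: dict[str, str]
    reports: dict[str, dict]
    triplet_counts: dict[str, dict[str, int]]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _hash_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_experiment(config: ExperimentConfig) -> RunRecord:
    """Execute the full pipeline; artifacts land under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = set_global_seed(config.seed)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    artifacts: dict[str, str] = {}
    reports: dict[str, dict] = {}
    stage = "init"
    try:
        # ---- phantom data ------------------------------------------------
        stage = "phantom"
        logger.info("stage %s", stage)
        presets = make_class_presets(config.difficulty)
        n_total = config.n_train_per_class + config.n_test_per_class
        ds = make_image_dataset(presets, n_total,
                                unseen_shift=config.unseen_shift,
                                seed=seeds["phantom"])
        train, seen_test, unseen_test = [], [], []
        for c in CLASSES:
            s = ds.subset("seen", c)
            u = ds.subset("unseen", c)
            train += s[:config.n_train_per_class]
            seen_test += s[config.n_train_per_class:]
            unseen_test += u[config.n_train_per_class:]
        manifest = write_image_dataset(train, out / "data" / "train")
        artifacts["train_manifest"] = str(manifest)
        artifacts["seen_test_manifest"] = str(
            write_image_dataset(seen_test, out / "data" / "seen_test"))
        artifacts["unseen_test_manifest"] = str(
            write_image_dataset(unseen_test, out / "data" / "unseen_test"))
        input_hash = _hash_file(manifest)

        stage = "extra_real"
        extra = make_image_dataset(
            presets, config.n_extra_real_per_class, unseen_shift=0.0,
            seed=seeds["extra_real"]).subset("seen")

        # ---- per-class GANs and the synthetic library --------------------
        bundles: dict[str, GanBundle] = {}
        for c in CLASSES:
            stage = f"gan_{c}"
            logger.info("stage %s", stage)
            cfg = dataclasses.replace(config.gan, seed=seeds[stage])
            bundles[c] = train_image_gan(
                [im for im in train if im.label == c], cfg)
            bundles[c].save(out / "gan" / c)
            artifacts[f"gan_{c}"] = str(out / "gan" / c)
        stage = "library"
        from .gan import synthesize_class_library
        library = synthesize_class_library(
            bundles, config.synthetic_per_class, seed=seeds["library"],
            out_size=128)
        artifacts["synthetic_manifest"] = str(write_image_dataset(
            library.images, out / "data" / "synthetic"))

        # ---- three training datasets, three classifiers ------------------
        stage = "assemble"
        triplet = assemble_training_sets(train, extra, library)
        counts = triplet.counts()
        for name in ("small_real", "large_real", "mixed"):
            stage = f"clf_{name}"
            logger.info("stage %s", stage)
            cfg = dataclasses.replace(config.classifier, seed=seeds[stage])
            model = train_classifier(getattr(triplet, name), cfg)
            report = evaluate_domains(model, seen_test, unseen_test)
            reports[name] = report.to_dict()
            with open(out / f"report_{name}.json", "w") as fh:
                json.dump(reports[name], fh, indent=2, sort_keys=True)
            artifacts[f"report_{name}"] = str(out / f"report_{name}.json")
            import pandas as pd
            pd.DataFrame(model.history_).to_csv(
                out / f"history_{name}.csv", index=False)
            if name == "mixed" and config.make_figures:
                _trained_mixed = model

        # ---- PCA fidelity ------------------------------------------------
        stage = "pca"
        logger.info("stage %s", stage)
        pca_imgs = train + library.images + unseen_test
        pca = pca_embed(pca_imgs, n_components=2,
                        groups=pca_group_tags(pca_imgs))
        np.savez(out / "pca_scores.npz", scores=pca.scores,
                 groups=pca.groups,
                 explained=pca.explained_variance_ratio)
        reports["pca_explained_variance"] = {
            "ratios": pca.explained_variance_ratio.tolist()}

        # ---- conventional baselines --------------------------------------
        stage = "baselines"
        logger.info("stage %s", stage)
        baselines = run_baselines(triplet.mixed, seen_test, unseen_test,
                                  cycles=config.baseline_cycles,
                                  seed=seeds["baselines"])
        baselines.records.to_csv(out / "baselines.csv", index=False)
        artifacts["baselines"] = str(out / "baselines.csv")
        reports["baselines"] = {
            m: {k: float(v) for k, v in row.items()}
            for m, row in baselines.records.groupby("method")[
                ["seen", "unseen", "pooled"]].mean().iterrows()}

        # ---- video branch ------------------------------------------------
        if config.include_video:
            stage = "clips"
            logger.info("stage %s", stage)
            clips = make_clip_dataset(presets["day6"], config.n_clips,
                                      seed=seeds["clips"])
            write_clip_dataset(clips, out / "data" / "clips")
            stage = "video_gan"
            logger.info("stage %s", stage)
            vcfg = dataclasses.replace(config.video_gan,
                                       seed=seeds["video_gan"])
            vbundle = train_video_gan(clips, vcfg)
            vbundle.save(out / "gan" / "video")
            fake_clips = sample_clips(vbundle, 4, seed=seeds["video_gan"])
            write_clip_dataset(fake_clips, out / "synthetic_clips", gif=True)
            artifacts["video_gan"] = str(out / "gan" / "video")

            stage = "contractility"
            from .motion import contractility_trace
            trace = contractility_trace(clips[0].frames, fps=clips[0].fps)
            reports["contractility_example"] = {
                "true_amplitude": clips[0].amplitude,
                "trace": trace.magnitudes.tolist(),
                "peak": (float(trace.peak_values.max())
                         if trace.peak_values.size else 0.0)}

        # ---- figures -----------------------------------------------------
        if config.make_figures:
            stage = "figures"
            logger.info("stage %s", stage)
            from .figures import figure_suite
            figs = figure_suite(
                out / "figures", train=train, library=library.images,
                unseen=unseen_test, pca=pca, reports=reports,
                model=_trained_mixed,
                clips=(clips if config.include_video else None),
                fake_clips=(fake_clips if config.include_video else None))
            artifacts.update(figs)
    except Exception as exc:
        raise RuntimeError(f"experiment failed at stage {stage!r}: {exc}") \
            from exc

    record = RunRecord(
        config=asdict(config), seeds=seeds, input_hash=input_hash,
        started=started, finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        artifacts=artifacts, reports=reports, triplet_counts=counts)
    record.to_json(out / "run_record.json")
    return record


def augmentation_benefit_experiment(
        difficulty: float = 0.7,
        unseen_shift: float = 1.0,
        n_train_per_class: int = 60,
        n_test_per_class: int = 40,
        synthetic_per_class: int = 100,
        gan_epochs: int = 300,
        clf_epochs: int = 8,
        clf_batch_size: int = 16,
        gan_image_size: int = 64,
        gan_width: int = 64,
        gan_batch_size: int = 16,
        classifier_seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
        data_seed: int = 77) -> dict:
    """Quantify the generalization gain from mixing GAN images into training.

    The phantom conditions deliberately stress the classifier: day-2/day-6
    morphology overlaps (difficulty) and the unseen domain is a one-SD batch
    shift. One GAN per class is trained on the small real set, a synthetic
    library is sampled, and for each classifier seed the small-real and
    mixed (real + synthetic) classifiers are trained identically and scored
    on both domains. Returns per-seed accuracies plus medians; the
    ``unseen_gain`` entries are (mixed - small_real) unseen accuracy.
    """
    from .gan import synthesize_class_library

    presets = make_class_presets(difficulty)
    ds = make_image_dataset(presets, n_train_per_class + n_test_per_class,
                            unseen_shift=unseen_shift, seed=data_seed)
    train, seen_test, unseen_test = [], [], []
    for c in CLASSES:
        s = ds.subset("seen", c)
        u = ds.subset("unseen", c)
        train += s[:n_train_per_class]
        seen_test += s[n_train_per_class:]
        unseen_test += u[n_train_per_class:]

    bundles = {}
    for i, c in enumerate(CLASSES):
        cfg = GanConfig(image_size=gan_image_size, width=gan_width,
                        epochs=gan_epochs, batch_size=gan_batch_size,
                        seed=100 + i)
        bundles[c] = train_image_gan([im for im in train if im.label == c],
                                     cfg)
    library = synthesize_class_library(bundles, synthetic_per_class,
                                       seed=200, out_size=128)

    Xs, ys = images_to_arrays(train)
    Xm, ym = images_to_arrays(train + library.images)
    Xse, yse = images_to_arrays(seen_test)
    Xun, yun = images_to_arrays(unseen_test)

    per_seed = []
    for seed in classifier_seeds:
        rows = {}
        for name, (X, y) in (("small_real", (Xs, ys)), ("mixed", (Xm, ym))):
            model = CNNMaturationClassifier(
                epochs=clf_epochs, batch_size=clf_batch_size,
                seed=seed).fit(X, y)
            rows[f"{name}_seen"] = float((model.predict(Xse) == yse).mean())
            rows[f"{name}_unseen"] = float((model.predict(Xun) == yun).mean())
        rows["unseen_gain"] = rows["mixed_unseen"] - rows["small_real_unseen"]
        per_seed.append(rows)
    medians = {k: float(np.median([r[k] for r in per_seed]))
               for k in per_seed[0]}
    return {"per_seed": per_seed, "medians": medians}
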