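"""Qualitative figure suite: real/synthetic panels, clip strips, PCA plots,
feature maps and confusion heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import feature_maps
from .phantom import CLASSES


def _grid(ax_row, images, title=None):
    for ax, im in zip(ax_row, images):
        arr = np.transpose(np.clip(im, 0, 1), (1, 2, 0))
        ax.imshow(arr)
        ax.set_xticks([])
        ax.set_yticks([])
    if title:
        ax_row[0].set_ylabel(title, fontsize=9)


def real_vs_synthetic_panel(path, train, library, n=4):
    fig, axes = plt.subplots(6, n, figsize=(2 * n, 12))
    for i, c in enumerate(CLASSES):
        real = [im.pixels for im in train if im.label == c][:n]
        fake = [im.pixels for im in library if im.label == c][:n]
        _grid(axes[2 * i], real, f"real {c}")
        _grid(axes[2 * i + 1], fake, f"synthetic {c}")
    fig.suptitle("Phantom vs GAN-synthetic cell fields")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def clip_strip(path, clips, fake_clips, n_frames=5):
    rows = []
    if clips:
        rows.append(("real clip", clips[0].frames))
    if fake_clips:
        rows.append(("synthetic clip", fake_clips[0].frames))
    if not rows:
        return
    fig, axes = plt.subplots(len(rows), n_frames,
                             figsize=(2 * n_frames, 2 * len(rows)),
                             squeeze=False)
    for r, (name, frames) in enumerate(rows):
        for t in range(n_frames):
            axes[r][t].imshow(frames[t], cmap="gray", vmin=0, vmax=1)
            axes[r][t].set_xticks([]); axes[r][t].set_yticks([])
            axes[r][t].set_title(f"{t / 5.0:.1f}s", fontsize=8)
        axes[r][0].set_ylabel(name, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def pca_scatter(path, pca):
    fig, ax = plt.subplots(figsize=(7, 6))
    for tag in sorted(set(pca.groups)):
        sel = pca.groups == tag
        ax.scatter(pca.scores[sel, 0], pca.scores[sel, 1], s=8, alpha=0.6,
                   label=tag)
    ax.set_xlabel(f"PC1 ({pca.explained_variance_ratio[0]:.0%} var)")
    ax.set_ylabel(f"PC2 ({pca.explained_variance_ratio[1]:.0%} var)")
    ax.legend(fontsize=7, markerscale=1.5)
    ax.set_title("PCA of real, synthetic and unseen image features")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def pca_hex(path, pca):
    tags = sorted(set(pca.groups))
    fig, axes = plt.subplots(1, len(tags), figsize=(3 * len(tags), 3),
                             squeeze=False)
    for ax, tag in zip(axes[0], tags):
        sel = pca.groups == tag
        if sel.sum() >= 3:
            ax.hexbin(pca.scores[sel, 0], pca.scores[sel, 1], gridsize=14,
                      cmap="viridis", mincnt=1)
        ax.set_title(tag, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def feature_map_panel(path, model, images_by_class):
    fig, axes = plt.subplots(len(images_by_class), 5,
                             figsize=(10, 2 * len(images_by_class)),
                             squeeze=False)
    for r, (label, img) in enumerate(images_by_class):
        axes[r][0].imshow(np.transpose(np.clip(img, 0, 1), (1, 2, 0)))
        axes[r][0].set_ylabel(label, fontsize=9)
        maps = feature_maps(model, img * 2.0 - 1.0)
        for k in range(4):
            axes[r][k + 1].imshow(maps[k], cmap="inferno", vmin=0, vmax=1)
            axes[r][k + 1].set_title(f"filter {k + 1}", fontsize=8)
        for ax in axes[r]:
            ax.set_xticks([]); ax.set_yticks([])
    fig.suptitle("Last-conv-layer feature maps")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def confusion_heatmap(path, report: dict, title: str):
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, key in zip(axes, ("confusion_seen", "confusion_unseen")):
        cm = np.array(report[key]["counts"], dtype=float)
        norm = cm / np.maximum(cm.sum(axis=1, keepdims=True), 1)
        im = ax.imshow(norm, cmap="Blues", vmin=0, vmax=1)
        labels = report[key]["labels"]
        ax.set_xticks(range(3), labels)
        ax.set_yticks(range(3), labels)
        ax.set_xlabel("predicted"); ax.set_ylabel("true")
        ax.set_title(key.replace("confusion_", "") + " domain")
        for i in range(3):
            for j in range(3):
                ax.text(j, i, f"{norm[i, j]:.2f}", ha="center", va="center",
                        fontsize=8,
                        color="white" if norm[i, j] > 0.5 else "black")
    fig.suptitle(title)
    fig.colorbar(im, ax=axes, shrink=0.8)
    fig.savefig(path, dpi=110)
    plt.close(fig)


def figure_suite(out_dir, train, library, unseen, pca, reports, model,
                 clips=None, fake_clips=None) -> dict[str, str]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    real_vs_synthetic_panel(out / "real_vs_synthetic.png", train, library)
    paths["fig_real_vs_synthetic"] = str(out / "real_vs_synthetic.png")
    if clips is not None:
        clip_strip(out / "clip_strip.png", clips, fake_clips)
        paths["fig_clip_strip"] = str(out / "clip_strip.png")
    pca_scatter(out / "pca_scatter.png", pca)
    paths["fig_pca_scatter"] = str(out / "pca_scatter.png")
    pca_hex(out / "pca_hex.png", pca)
    paths["fig_pca_hex"] = str(out / "pca_hex.png")
    imgs = [(c, next(im.pixels for im in train if im.label == c))
            for c in CLASSES]
    feature_map_panel(out / "feature_maps.png", model, imgs)
    paths["fig_feature_maps"] = str(out / "feature_maps.png")
    for name in ("small_real", "large_real", "mixed"):
        if name in reports:
            confusion_heatmap(out / f"heatmap_{name}.png", reports[name],
                              f"Prediction heatmaps - {name} training")
            paths[f"fig_heatmap_{name}"] = str(out / f"heatmap_{name}.png")
    return paths
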