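"""Domain-generalization evaluation, distribution fidelity and baselines.

Covers the quantitative readouts of the study design: seen/unseen-domain
accuracies with per-class confusion matrices, PCA of real vs synthetic vs
unseen image features, conventional-ML baselines (SVM, random forest, KNN,
Gaussian naive Bayes) repeated over cycles, ablation classifier variants,
and feature-map visualization of the last conv layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import CNNMaturationClassifier, images_to_arrays
from .phantom import CLASSES, LabeledImage

BASELINE_METHODS = ("svm", "random_forest", "knn", "naive_bayes")


@dataclass
class ConfusionMatrix:
    """3x3 counts; true class by row, predicted class by column."""

    counts: np.ndarray
    labels: tuple[str, ...] = CLASSES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected {(k, k)} counts, got "
                             f"{self.counts.shape}")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def row_normalized(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            return np.where(sums > 0, self.counts / sums, 0.0)

    def to_dict(self) -> dict:
        return {"labels": list(self.labels),
                "counts": self.counts.tolist()}


@dataclass
class DomainReport:
    """Seen/unseen/pooled accuracies plus per-domain confusion matrices."""

    seen_accuracy: float
    unseen_accuracy: float
    pooled_accuracy: float
    mean_accuracy: float          # plain average of the two domain accuracies
    confusion_seen: ConfusionMatrix
    confusion_unseen: ConfusionMatrix
    n_seen: int
    n_unseen: int

    def to_dict(self) -> dict:
        return {
            "seen_accuracy": self.seen_accuracy,
            "unseen_accuracy": self.unseen_accuracy,
            "pooled_accuracy": self.pooled_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "n_seen": self.n_seen, "n_unseen": self.n_unseen,
            "confusion_seen": self.confusion_seen.to_dict(),
            "confusion_unseen": self.confusion_unseen.to_dict(),
        }


@dataclass
class PcaResult:
    loadings: np.ndarray            # (n_components, n_features), orthonormal
    scores: np.ndarray              # (n_samples, n_components)
    explained_variance_ratio: np.ndarray
    groups: np.ndarray              # per-sample tags, e.g. "real-seen:day2"


@dataclass
class BaselineReport:
    """Per-method, per-cycle seen/unseen/pooled accuracies."""

    records: pd.DataFrame           # columns: method, cycle, seen, unseen, pooled
    cycles: int

    def summary(self) -> pd.DataFrame:
        return (self.records.groupby("method")[["seen", "unseen", "pooled"]]
                .agg(["mean", "std"]))


# ---------------------------------------------------------------------------
# accuracy bookkeeping

def confusion(true_labels, predicted_labels,
              labels: tuple[str, ...] = CLASSES) -> ConfusionMatrix:
    """Count (true, predicted) pairs in a fixed class order."""
    from sklearn.metrics import confusion_matrix as sk_confusion
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label lists must have equal length")
    unknown = set(true_labels) | set(predicted_labels)
    unknown -= set(labels)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    counts = sk_confusion(true_labels, predicted_labels, labels=list(labels))
    return ConfusionMatrix(counts=counts, labels=labels)


def evaluate_domains(model, seen_test, unseen_test) -> DomainReport:
    """Accuracy and confusion on the seen and unseen test sets.

    ``model`` is anything with a ``predict`` over (N,3,H,W) arrays;
    test sets are LabeledImage lists or (X, y) tuples.
    """
    def _xy(ds):
        if isinstance(ds, tuple):
            return ds
        return images_to_arrays(ds)

    Xs, ys = _xy(seen_test)
    Xu, yu = _xy(unseen_test)
    if len(ys) == 0 or len(yu) == 0:
        raise ValueError("test sets must be non-empty")
    ps = model.predict(Xs)
    pu = model.predict(Xu)
    cs, cu = confusion(ys, ps), confusion(yu, pu)
    correct = np.trace(cs.counts) + np.trace(cu.counts)
    n = cs.total + cu.total
    return DomainReport(
        seen_accuracy=cs.accuracy, unseen_accuracy=cu.accuracy,
        pooled_accuracy=float(correct / n),
        mean_accuracy=float((cs.accuracy + cu.accuracy) / 2.0),
        confusion_seen=cs, confusion_unseen=cu,
        n_seen=cs.total, n_unseen=cu.total)


# ---------------------------------------------------------------------------
# PCA fidelity

def featurize(images, size: int = 32) -> np.ndarray:
    """Shared low-dimensional featurization: grayscale, resize, flatten.

    Used for both the PCA fidelity analysis and the conventional-ML
    baselines so all distribution comparisons see identical features.
    """
    from skimage.transform import resize
    if not isinstance(images, np.ndarray):
        images, _ = images_to_arrays(images, size=128)
    n = images.shape[0]
    gray = images.mean(axis=1)
    if gray.shape[1] != size:
        gray = np.stack([resize(g, (size, size), preserve_range=True,
                                anti_aliasing=True) for g in gray])
    return gray.reshape(n, -1).astype(np.float64)


def pca_embed(images, n_components: int = 2, groups=None,
              featurized: bool = False) -> PcaResult:
    """Project image features onto their top principal components."""
    from sklearn.decomposition import PCA
    X = np.asarray(images, dtype=np.float64) if featurized else \
        featurize(images)
    n = X.shape[0]
    if n_components >= n:
        raise ValueError(
            f"n_components={n_components} needs more than {n} samples")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    groups = (np.asarray(groups) if groups is not None
              else np.array(["all"] * n))
    if groups.shape[0] != n:
        raise ValueError("groups length mismatch")
    return PcaResult(loadings=pca.components_, scores=scores,
                     explained_variance_ratio=pca.explained_variance_ratio_,
                     groups=groups)


def pca_group_tags(images: list[LabeledImage]) -> np.ndarray:
    """Standard group tags: provenance/domain x class."""
    tags = []
    for im in images:
        prov = "synthetic" if im.provenance == "gan" else f"real-{im.domain}"
        tags.append(f"{prov}:{im.label}")
    return np.array(tags)


# ---------------------------------------------------------------------------
# conventional-ML baselines

def _make_baseline(method: str, seed: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    if method == "svm":
        return SVC(kernel="rbf", random_state=seed)
    if method == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if method == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if method == "naive_bayes":
        return GaussianNB()
    raise ValueError(f"unknown baseline {method!r}")


def run_baselines(train_set, seen_test, unseen_test, cycles: int = 10,
                  seed: int = 0) -> BaselineReport:
    """Fit each conventional method ``cycles`` times (re-seeded) and score.

    All methods see the same 32x32-grayscale pixel features. Deterministic
    methods (KNN, naive Bayes, and SVM at fixed seed) repeat identically
    across cycles; the repeats quantify the stochastic ones, mirroring the
    10-cycle repetition of the study.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    Xtr = featurize(train_set)
    ytr = np.array([im.label for im in train_set]) \
        if not isinstance(train_set, tuple) else None
    if ytr is None:
        Xtr, ytr = featurize(train_set[0]), train_set[1]
    Xs = featurize(seen_test)
    ys = np.array([im.label for im in seen_test])
    Xu = featurize(unseen_test)
    yu = np.array([im.label for im in unseen_test])
    if not (len(ytr) and len(ys) and len(yu)):
        raise ValueError("datasets must be non-empty")
    rows = []
    ss = np.random.SeedSequence(seed)
    cycle_seeds = ss.generate_state(cycles) % (2 ** 31)
    for cycle, cseed in enumerate(cycle_seeds):
        for method in BASELINE_METHODS:
            est = _make_baseline(method, int(cseed))
            est.fit(Xtr, ytr)
            acc_s = float((est.predict(Xs) == ys).mean())
            acc_u = float((est.predict(Xu) == yu).mean())
            pooled = (acc_s * len(ys) + acc_u * len(yu)) / (len(ys) + len(yu))
            rows.append({"method": method, "cycle": cycle, "seen": acc_s,
                         "unseen": acc_u, "pooled": pooled})
    return BaselineReport(records=pd.DataFrame(rows), cycles=cycles)


# ---------------------------------------------------------------------------
# ablations and interpretation

def build_ablation_model(name: str, seed: int = 0,
                         **train_params) -> CNNMaturationClassifier:
    """Untrained classifier estimator with an ablation architecture.

    ``name`` is one of fc_only / small_cnn / disc_like (or proposed).
    """
    if name not in ("proposed", "fc_only", "small_cnn", "disc_like"):
        raise ValueError(f"unknown ablation model {name!r}")
    return CNNMaturationClassifier(architecture=name, seed=seed,
                                   **train_params)


def feature_maps(model: CNNMaturationClassifier, image: np.ndarray
                 ) -> np.ndarray:
    """Per-channel activation maps of the last conv stage, in [0,1].

    Returns (4, 12, 12) maps for the proposed architecture (the activation
    entering the fully-connected head), min-max normalized per channel.
    """
    if getattr(model, "architecture", None) != "proposed":
        raise ValueError("feature maps are defined for the proposed "
                         "conv architecture only")
    from .classifier import center_crop
    from .nn import Flatten
    x = np.asarray(image, dtype=np.float32)
    if x.ndim != 3 or x.shape[0] != 3:
        raise ValueError(f"image must be (3,H,W), got {x.shape}")
    if x.shape[1] > 96:
        x = center_crop(x, 96)
    h = x[None]
    for layer in model.net_.layers:
        if isinstance(layer, Flatten):
            break
        h = layer.forward(h, train=False)
    maps = h[0]
    lo = maps.min(axis=(1, 2), keepdims=True)
    hi = maps.max(axis=(1, 2), keepdims=True)
    rng_ = np.where(hi - lo > 0, hi - lo, 1.0)
    return ((maps - lo) / rng_).astype(np.float32)
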