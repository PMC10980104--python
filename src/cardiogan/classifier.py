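"""Maturation-stage CNN classifier and training-set assembly.

The classifier is three conv layers (kernel 3; output channels 32, 16, 4),
each followed by an overlapping 4x4 max pool with stride 2 and padding 1
(halving the spatial size, so 96 -> 48 -> 24 -> 12), then two fully
connected layers (576 -> 64 -> 3) and a softmax. Training samples a random
96x96 crop (with random horizontal flip) from each 128x128 image every
epoch; evaluation uses the deterministic center crop. Optimized with Adam
(lr 5e-4, betas (0.9, 0.999)), batch 64, cross-entropy plus an L2 weight
penalty.

Three training datasets quantify the value of synthetic data: the small real
set the GAN was trained on, a larger real set, and the small real set mixed
with the GAN's synthetic library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .gan import SyntheticLibrary
from .nn import (Adam, Conv2d, Flatten, LeakyReLU, Linear, MaxPool2d, ReLU,
                 Sequential)
from .phantom import CLASSES, LabeledImage, to_model_space

CROP = 96
ABLATION_NAMES = ("proposed", "fc_only", "small_cnn", "disc_like")

# flattened dimension entering the first fully-connected layer, per model
_FLATTEN_DIMS = {
    "proposed": 4 * 12 * 12,        # conv shapes (32,48,48),(16,24,24),(4,12,12)
    "fc_only": 3 * 96 * 96,         # raw pixels, 27648
    "small_cnn": 4 * 8 * 8,         # conv shapes (16,32,32),(4,8,8)
    "disc_like": 4 * 16 * 16,       # same conv stack applied to 128px input
}


@dataclass
class ClassifierSpec:
    """Architecture contract for the proposed classifier."""

    input_shape: tuple[int, int, int] = (3, CROP, CROP)
    conv_channels: tuple[int, ...] = (32, 16, 4)
    kernel_size: int = 3
    activation_shapes: tuple[tuple[int, int, int], ...] = (
        (32, 48, 48), (16, 24, 24), (4, 12, 12))
    fc_sizes: tuple[int, ...] = (576, 64, 3)

    def __post_init__(self):
        c, h, w = self.activation_shapes[-1]
        if c * h * w != self.fc_sizes[0]:
            raise ValueError("flattened conv output must match first FC size")


@dataclass
class ClassifierConfig:
    learning_rate: float = 5e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    batch_size: int = 64
    epochs: int = 1000
    weight_penalty: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.adam_beta1, self.adam_beta2) <= 0:
            raise ValueError("learning rate and betas must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.weight_penalty < 0:
            raise ValueError("weight_penalty must be >= 0")


@dataclass
class TrainSetTriplet:
    """The three classifier training datasets."""

    small_real: list[LabeledImage]
    large_real: list[LabeledImage]
    mixed: list[LabeledImage]

    def counts(self) -> dict[str, dict[str, int]]:
        out = {}
        for name in ("small_real", "large_real", "mixed"):
            imgs = getattr(self, name)
            out[name] = {c: sum(im.label == c for im in imgs) for c in CLASSES}
            out[name]["total"] = len(imgs)
        return out


# ---------------------------------------------------------------------------
# architectures

def build_cnn_classifier(spec: ClassifierSpec | None = None,
                         rng: np.random.Generator | None = None
                         ) -> Sequential:
    """The proposed 3-conv + 2-FC network (logit output; softmax applied by
    the loss / predict path)."""
    spec = spec if spec is not None else ClassifierSpec()
    rng = rng if rng is not None else np.random.default_rng(0)
    c1, c2, c3 = spec.conv_channels
    k = spec.kernel_size
    return Sequential([
        Conv2d(3, c1, k, 1, 1, rng), ReLU(), MaxPool2d(4, 2, 1),
        Conv2d(c1, c2, k, 1, 1, rng), ReLU(), MaxPool2d(4, 2, 1),
        Conv2d(c2, c3, k, 1, 1, rng), ReLU(), MaxPool2d(4, 2, 1),
        Flatten(),
        Linear(spec.fc_sizes[0], spec.fc_sizes[1], rng), ReLU(),
        Linear(spec.fc_sizes[1], spec.fc_sizes[2], rng),
    ])


def _build_fc_only(rng) -> Sequential:
    sizes = (27648, 4096, 1024, 256, 64, 3)
    layers = [Flatten()]
    for a, b in zip(sizes[:-1], sizes[1:]):
        layers += [Linear(a, b, rng), ReLU()]
    layers.pop()          # no activation after the final logits
    return Sequential(layers)


def _build_small_cnn(rng) -> Sequential:
    # 96 -> (conv k3 pad1, pool 3/3) -> 32 -> (conv, pool 4/4) -> 8
    return Sequential([
        Conv2d(3, 16, 3, 1, 1, rng), ReLU(), MaxPool2d(3, 3, 0),
        Conv2d(16, 4, 3, 1, 1, rng), ReLU(), MaxPool2d(4, 4, 0),
        Flatten(), Linear(256, 32, rng), ReLU(), Linear(32, 3, rng),
    ])


def _build_disc_like(rng) -> Sequential:
    # discriminator-style: full 128px input, halving conv+pool stages
    return Sequential([
        Conv2d(3, 32, 3, 1, 1, rng), LeakyReLU(0.2), MaxPool2d(4, 2, 1),
        Conv2d(32, 16, 3, 1, 1, rng), LeakyReLU(0.2), MaxPool2d(4, 2, 1),
        Conv2d(16, 4, 3, 1, 1, rng), LeakyReLU(0.2), MaxPool2d(4, 2, 1),
        Flatten(), Linear(4 * 16 * 16, 64, rng), ReLU(), Linear(64, 3, rng),
    ])


def build_model(name: str, rng: np.random.Generator | None = None
                ) -> Sequential:
    """Build the proposed classifier or one of the ablation architectures."""
    rng = rng if rng is not None else np.random.default_rng(0)
    if name == "proposed":
        return build_cnn_classifier(rng=rng)
    if name == "fc_only":
        return _build_fc_only(rng)
    if name == "small_cnn":
        return _build_small_cnn(rng)
    if name == "disc_like":
        return _build_disc_like(rng)
    raise ValueError(f"unknown model {name!r}; choose from {ABLATION_NAMES}")


def flatten_feature_dim(model_name: str) -> int:
    """Flattened dimension entering the first fully-connected layer."""
    if model_name not in _FLATTEN_DIMS:
        raise ValueError(
            f"unknown model {model_name!r}; choose from {ABLATION_NAMES}")
    return _FLATTEN_DIMS[model_name]


def model_input_size(name: str) -> int:
    return 128 if name == "disc_like" else CROP


# ---------------------------------------------------------------------------
# augmentation

def random_crop_flip(image: np.ndarray, seed: int | np.random.Generator,
                     crop: int = CROP) -> np.ndarray:
    """Random crop + horizontal flip of one (C,H,W) image, for training."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    c, h, w = image.shape
    if h < crop or w < crop:
        raise ValueError(f"input {image.shape} smaller than crop {crop}")
    top = int(rng.integers(0, h - crop + 1))
    left = int(rng.integers(0, w - crop + 1))
    out = image[:, top:top + crop, left:left + crop]
    if rng.random() < 0.5:
        out = out[:, :, ::-1]
    return np.ascontiguousarray(out)


def center_crop(image: np.ndarray, crop: int = CROP) -> np.ndarray:
    """Deterministic evaluation crop."""
    c, h, w = image.shape
    if h < crop or w < crop:
        raise ValueError(f"input {image.shape} smaller than crop {crop}")
    top, left = (h - crop) // 2, (w - crop) // 2
    return np.ascontiguousarray(image[:, top:top + crop, left:left + crop])


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# dataset assembly

def assemble_training_sets(small_real: list[LabeledImage],
                           extra_real: list[LabeledImage],
                           synthetic: SyntheticLibrary | list[LabeledImage]
                           ) -> TrainSetTriplet:
    """Build the three-dataset design.

    * ``small_real``: the GAN's own training set (e.g. 691 images);
    * ``large_real``: small_real plus extra real images (e.g. +960 -> 1651);
    * ``mixed``: small_real plus the synthetic library (e.g. +960 -> 1651).
    """
    syn_images = (synthetic.images if isinstance(synthetic, SyntheticLibrary)
                  else list(synthetic))
    for name, imgs in (("small_real", small_real), ("extra_real", extra_real),
                       ("synthetic", syn_images)):
        bad = [im.label for im in imgs if im.label not in CLASSES]
        if bad:
            raise ValueError(f"{name} contains unknown labels: {set(bad)}")
    if small_real and syn_images:
        if {im.label for im in syn_images} - {im.label for im in small_real}:
            raise ValueError("synthetic classes not present in small_real")
    return TrainSetTriplet(
        small_real=list(small_real),
        large_real=list(small_real) + list(extra_real),
        mixed=list(small_real) + syn_images,
    )


# ---------------------------------------------------------------------------
# estimator

class CNNMaturationClassifier(ClassifierMixin, BaseEstimator):
    """CNN classifier over maturation stages, scikit-learn style.

    ``fit`` accepts X as an (N, 3, H, W) float array in [-1,1] model space
    with H, W >= the crop size (random 96x96 crops are drawn each epoch when
    the input is larger), plus y as string or integer labels. ``architecture``
    selects the proposed model or an ablation variant.

    Attributes set by fit: ``net_``, ``classes_``, ``history_``.
    """

    def __init__(self, learning_rate=5e-4, adam_beta1=0.9, adam_beta2=0.999,
                 batch_size=64, epochs=1000, weight_penalty=1e-4, seed=0,
                 architecture="proposed"):
        self.learning_rate = learning_rate
        self.adam_beta1 = adam_beta1
        self.adam_beta2 = adam_beta2
        self.batch_size = batch_size
        self.epochs = epochs
        self.weight_penalty = weight_penalty
        self.seed = seed
        self.architecture = architecture

    # -- data handling ------------------------------------------------------
    def _validate(self, X, y=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[1] != 3:
            raise ValueError(f"X must be (N,3,H,W), got {X.shape}")
        if y is not None:
            y = np.asarray(y)
            if y.shape[0] != X.shape[0]:
                raise ValueError("X and y length mismatch")
        return X, y

    def _input_size(self) -> int:
        return model_input_size(self.architecture)

    def fit(self, X, y):
        ClassifierConfig(
            learning_rate=self.learning_rate, adam_beta1=self.adam_beta1,
            adam_beta2=self.adam_beta2, batch_size=self.batch_size,
            epochs=self.epochs, weight_penalty=self.weight_penalty,
            seed=self.seed)
        X, y = self._validate(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes to train")
        rng = np.random.default_rng(self.seed)
        net = build_model(self.architecture, rng)
        opt = Adam(net, lr=self.learning_rate, beta1=self.adam_beta1,
                   beta2=self.adam_beta2, eps=1e-8,
                   weight_decay=self.weight_penalty)
        size = self._input_size()
        n = X.shape[0]
        bs = min(self.batch_size, n)
        history = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                if X.shape[2] > size:
                    batch = np.stack([random_crop_flip(X[i], rng, size)
                                      for i in idx])
                else:
                    batch = X[idx]
                labels = y_idx[idx]
                logits = net.forward(batch, train=True)
                probs = softmax(logits)
                m = len(idx)
                losses.append(-float(np.mean(np.log(
                    np.clip(probs[np.arange(m), labels], 1e-12, None)))))
                correct += int((probs.argmax(axis=1) == labels).sum())
                dlogits = probs.copy()
                dlogits[np.arange(m), labels] -= 1.0
                net.zero_grad()
                net.backward((dlogits / m).astype(np.float32))
                opt.step()
            history.append({"epoch": epoch,
                            "loss": float(np.mean(losses)),
                            "train_accuracy": correct / n})
        self.net_ = net
        self.history_ = history
        return self

    # -- inference ----------------------------------------------------------
    def _prepare_eval(self, X):
        X, _ = self._validate(X)
        size = self._input_size()
        if X.shape[2] < size:
            raise ValueError(f"images smaller than model input {size}")
        if X.shape[2] > size:
            X = np.stack([center_crop(x, size) for x in X])
        return X

    def predict_proba(self, X):
        X = self._prepare_eval(X)
        out = []
        for start in range(0, X.shape[0], 256):
            logits = self.net_.forward(X[start:start + 256], train=False)
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


# ---------------------------------------------------------------------------
# functional wrappers

def images_to_arrays(images: list[LabeledImage], size: int = 128
                     ) -> tuple[np.ndarray, np.ndarray]:
    """LabeledImages in [0,1] -> ((N,3,size,size) in [-1,1], labels)."""
    from skimage.transform import resize
    xs, ys = [], []
    for im in images:
        x = im.pixels
        if x.shape[1] != size or x.shape[2] != size:
            x = resize(x, (x.shape[0], size, size), preserve_range=True,
                       anti_aliasing=True)
        xs.append(to_model_space(x))
        ys.append(im.label)
    return np.stack(xs).astype(np.float32), np.array(ys)


def train_classifier(dataset: list[LabeledImage],
                     config: ClassifierConfig | None = None,
                     architecture: str = "proposed"
                     ) -> CNNMaturationClassifier:
    """Train on a labeled image list; returns the fitted estimator
    (its ``history_`` holds per-epoch loss and training accuracy)."""
    config = config if config is not None else ClassifierConfig()
    X, y = images_to_arrays(dataset, size=128)
    est = CNNMaturationClassifier(
        learning_rate=config.learning_rate, adam_beta1=config.adam_beta1,
        adam_beta2=config.adam_beta2, batch_size=config.batch_size,
        epochs=config.epochs, weight_penalty=config.weight_penalty,
        seed=config.seed, architecture=architecture)
    return est.fit(X, y)


def predict_proba(model: CNNMaturationClassifier, images) -> np.ndarray:
    """Probability simplex vectors for LabeledImages or an (N,3,H,W) array."""
    if not isinstance(images, np.ndarray):
        images, _ = images_to_arrays(images, size=128)
    return model.predict_proba(images)
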