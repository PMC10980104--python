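"""CNN classifier: architecture shapes, augmentation, dataset assembly."""

import numpy as np
import pytest

from cardiogan.classifier import (ABLATION_NAMES, ClassifierConfig,
                                  ClassifierSpec, CNNMaturationClassifier,
                                  assemble_training_sets,
                                  build_cnn_classifier, build_model,
                                  center_crop, flatten_feature_dim,
                                  random_crop_flip, softmax)
from cardiogan.nn import Flatten, Linear, MaxPool2d
from cardiogan.phantom import LabeledImage


def _dummy_images(label, n, value=0.5, size=8):
    px = np.full((3, size, size), value, dtype=np.float32)
    return [LabeledImage(pixels=px, label=label, domain="seen")
            for _ in range(n)]


class TestArchitecture:
    def test_stagewise_activation_shapes_match_the_printed_table(self, rng):
        net = build_cnn_classifier()
        x = rng.normal(size=(2, 3, 96, 96)).astype(np.float32)
        shapes = []
        h = x
        for layer in net.layers:
            h = layer.forward(h, train=False)
            if isinstance(layer, MaxPool2d):
                shapes.append(h.shape[1:])
        assert shapes == [(32, 48, 48), (16, 24, 24), (4, 12, 12)]
        assert h.shape == (2, 3)

    def test_probabilities_form_a_simplex(self, rng):
        net = build_cnn_classifier()
        x = rng.normal(size=(4, 3, 96, 96)).astype(np.float32)
        probs = softmax(net.forward(x, train=False))
        assert probs.shape == (4, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_flattened_dimensions_per_model(self):
        assert flatten_feature_dim("proposed") == 576       # 4*12*12
        assert flatten_feature_dim("fc_only") == 27648      # 3*96*96
        assert flatten_feature_dim("small_cnn") == 256      # 4*8*8
        assert flatten_feature_dim("disc_like") == 1024     # 4*16*16
        with pytest.raises(ValueError):
            flatten_feature_dim("resnet")

    @pytest.mark.parametrize("name", ABLATION_NAMES)
    def test_every_model_emits_three_class_logits(self, name, rng):
        net = build_model(name, rng)
        size = 128 if name == "disc_like" else 96
        x = rng.normal(size=(2, 3, size, size)).astype(np.float32)
        probs = softmax(net.forward(x, train=False))
        assert probs.shape == (2, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_fc_only_first_layer_consumes_raw_pixels(self, rng):
        net = build_model("fc_only", rng)
        first_linear = next(l for l in net.layers if isinstance(l, Linear))
        assert first_linear.params["W"].shape[0] == 27648

    def test_small_cnn_last_conv_activation_shape(self, rng):
        net = build_model("small_cnn", rng)
        h = rng.normal(size=(1, 3, 96, 96)).astype(np.float32)
        for layer in net.layers:
            if isinstance(layer, Flatten):
                break
            h = layer.forward(h, train=False)
        assert h.shape[1:] == (4, 8, 8)

    def test_spec_validates_flatten_consistency(self):
        with pytest.raises(ValueError):
            ClassifierSpec(fc_sizes=(500, 64, 3))


class TestAugmentation:
    def test_crop_is_a_subwindow_with_intact_channels(self, rng):
        img = rng.random((3, 128, 128)).astype(np.float32)
        out = random_crop_flip(img, seed=3)
        assert out.shape == (3, 96, 96)
        # every cropped row exists somewhere in the source (possibly flipped)
        row = out[0, 0]
        found = any(
            np.array_equal(row, img[0, i, j:j + 96]) or
            np.array_equal(row, img[0, i, j:j + 96][::-1])
            for i in range(128) for j in range(33))
        assert found

    def test_fixed_seed_reproduces_the_crop(self, rng):
        img = rng.random((3, 128, 128)).astype(np.float32)
        assert np.array_equal(random_crop_flip(img, seed=9),
                              random_crop_flip(img, seed=9))

    def test_constant_image_stays_constant(self):
        img = np.full((3, 128, 128), 0.25, dtype=np.float32)
        out = random_crop_flip(img, seed=0)
        assert np.all(out == 0.25)

    def test_undersized_input_rejected(self, rng):
        with pytest.raises(ValueError):
            random_crop_flip(rng.random((3, 64, 64)).astype(np.float32), 0)

    def test_center_crop_is_deterministic_and_centered(self, rng):
        img = rng.random((3, 128, 128)).astype(np.float32)
        out = center_crop(img, 96)
        assert np.array_equal(out, img[:, 16:112, 16:112])


class TestAssembly:
    def test_study_sized_totals(self):
        small = (_dummy_images("day2", 229) + _dummy_images("day6", 227)
                 + _dummy_images("day14", 235))                    # 691
        extra = [im for c in ("day2", "day6", "day14")
                 for im in _dummy_images(c, 320)]                  # 960
        synthetic = [LabeledImage(pixels=im.pixels, label=im.label,
                                  domain="seen", provenance="gan")
                     for im in extra]
        triplet = assemble_training_sets(small, extra, synthetic)
        counts = triplet.counts()
        assert counts["small_real"]["total"] == 691
        assert counts["large_real"]["total"] == 1651
        assert counts["mixed"]["total"] == 1651
        assert len(triplet.mixed) == len(triplet.small_real) + len(synthetic)

    def test_empty_synthetic_reduces_mixed_to_small_real(self):
        small = _dummy_images("day2", 2) + _dummy_images("day6", 2)
        triplet = assemble_training_sets(small, [], [])
        assert triplet.mixed == triplet.small_real

    def test_unknown_label_rejected(self):
        bad = [LabeledImage(pixels=np.zeros((3, 4, 4), np.float32),
                            label="day2", domain="seen")]
        object.__setattr__(bad[0], "label", "day9")
        with pytest.raises(ValueError):
            assemble_training_sets(bad, [], [])


class TestTraining:
    def test_defaults_follow_the_training_setup(self):
        cfg = ClassifierConfig()
        assert cfg.learning_rate == 5e-4
        assert (cfg.adam_beta1, cfg.adam_beta2) == (0.9, 0.999)
        assert cfg.batch_size == 64
        assert cfg.epochs == 1000

    def test_separable_intensity_classes_reach_full_training_accuracy(self,
                                                                      rng):
        levels = {"day2": -0.6, "day6": 0.0, "day14": 0.6}
        X, y = [], []
        for label, lv in levels.items():
            X.append(np.full((10, 3, 96, 96), lv, np.float32)
                     + rng.normal(0, 0.05, (10, 3, 96, 96)).astype(np.float32))
            y += [label] * 10
        X = np.concatenate(X)
        clf = CNNMaturationClassifier(epochs=40, batch_size=8, seed=0)
        clf.fit(X, np.array(y))
        assert max(h["train_accuracy"] for h in clf.history_) == 1.0
        assert len(clf.history_) == 40

    def test_single_class_dataset_rejected(self, rng):
        X = rng.random((4, 3, 96, 96)).astype(np.float32)
        with pytest.raises(ValueError):
            CNNMaturationClassifier(epochs=1).fit(X, np.array(["day2"] * 4))

    def test_predict_proba_is_deterministic_and_row_consistent(self, rng):
        X = rng.random((8, 3, 96, 96)).astype(np.float32) * 2 - 1
        y = np.array(["day2"] * 4 + ["day14"] * 4)
        clf = CNNMaturationClassifier(epochs=2, batch_size=4, seed=0).fit(X, y)
        dup = np.concatenate([X[:2], X[:2]])
        p = clf.predict_proba(dup)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.array_equal(p[:2], p[2:])
        assert len(clf.predict(X)) == 8

    def test_sklearn_param_interface_round_trips(self):
        clf = CNNMaturationClassifier(epochs=7, seed=3)
        params = clf.get_params()
        assert params["epochs"] == 7
        clone = CNNMaturationClassifier(**params)
        assert clone.get_params() == params
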