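"""Evaluation: confusion bookkeeping, PCA oracle, baselines, feature maps."""

import numpy as np
import pytest

from cardiogan.evaluation import (BASELINE_METHODS, build_ablation_model,
                                  confusion, evaluate_domains, feature_maps,
                                  pca_embed, run_baselines)
from cardiogan.classifier import CNNMaturationClassifier
from cardiogan.phantom import (CLASSES, make_class_presets,
                               make_image_dataset)


class _OracleModel:
    """Predicts the label encoded in each image's mean intensity."""

    def predict(self, X):
        means = np.asarray(X).mean(axis=(1, 2, 3))
        return np.array([CLASSES[int(round(m))] for m in means])


class _ConstantModel:
    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.array([self.label] * len(X))


def _encoded_set(labels, size=96):
    X = np.stack([np.full((3, size, size), float(CLASSES.index(c)),
                          np.float32) for c in labels])
    return X, np.array(labels)


class TestConfusion:
    def test_perfect_predictions_fill_the_diagonal(self):
        cm = confusion(["day2", "day6", "day14"], ["day2", "day6", "day14"])
        assert np.array_equal(cm.counts, np.eye(3, dtype=int))
        assert cm.accuracy == 1.0

    def test_systematic_error_fills_one_off_diagonal_cell(self):
        cm = confusion(["day2", "day2"], ["day6", "day6"])
        assert cm.counts[0, 1] == 2
        assert cm.counts.sum() == 2
        assert cm.accuracy == 0.0

    def test_total_count_conservation(self, rng):
        true = rng.choice(CLASSES, size=50)
        pred = rng.choice(CLASSES, size=50)
        assert confusion(true, pred).total == 50

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["day2"], ["day9"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(["day2"], ["day2", "day6"])


class TestDomainReport:
    def test_oracle_model_scores_one_everywhere(self):
        seen = _encoded_set(["day2", "day6", "day14"] * 2)
        unseen = _encoded_set(["day2", "day14"] * 2)
        rep = evaluate_domains(_OracleModel(), seen, unseen)
        assert rep.seen_accuracy == rep.unseen_accuracy == 1.0
        assert rep.pooled_accuracy == 1.0

    def test_constant_model_on_balanced_sets_scores_one_third(self):
        seen = _encoded_set(["day2", "day6", "day14"] * 4)
        rep = evaluate_domains(_ConstantModel("day2"), seen, seen)
        assert rep.seen_accuracy == pytest.approx(1 / 3)

    def test_pooled_accuracy_is_sample_weighted(self):
        # 10/10 correct on seen, 5/10 on unseen -> pooled 15/20
        seen = _encoded_set(["day2"] * 10)
        unseen_labels = ["day2"] * 5 + ["day6"] * 5
        unseen = _encoded_set(["day2"] * 10)[0], np.array(unseen_labels)
        rep = evaluate_domains(_ConstantModel("day2"), seen, unseen)
        assert rep.pooled_accuracy == pytest.approx(0.75)
        assert rep.mean_accuracy == pytest.approx(0.75)
        total = (rep.confusion_seen.counts.sum()
                 + rep.confusion_unseen.counts.sum())
        assert total == 20

    def test_empty_test_set_rejected(self):
        seen = _encoded_set(["day2", "day6"])
        with pytest.raises(ValueError):
            evaluate_domains(_OracleModel(), seen, (seen[0][:0], seen[1][:0]))


class TestPca:
    def test_scores_are_centered(self, rng):
        X = rng.random((20, 16))
        res = pca_embed(X, n_components=3, featurized=True)
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-8)

    def test_matches_bruteforce_eigendecomposition(self, rng):
        # independent oracle: eigenvectors of the covariance matrix
        X = rng.random((20, 16))
        res = pca_embed(X, n_components=4, featurized=True)
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (len(X) - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for k in range(4):
            v = res.loadings[k]
            ref = evecs[:, k]
            sign = np.sign(v @ ref) or 1.0
            assert np.allclose(v, sign * ref, atol=1e-8)
            assert np.allclose(np.abs(Xc @ ref), np.abs(res.scores[:, k]),
                               atol=1e-8)
        assert np.allclose(res.explained_variance_ratio[:4],
                           evals[:4] / np.trace(cov), atol=1e-8)

    def test_loadings_are_orthonormal(self, rng):
        res = pca_embed(rng.random((30, 25)), n_components=5,
                        featurized=True)
        gram = res.loadings @ res.loadings.T
        assert np.allclose(gram, np.eye(5), atol=1e-8)

    def test_variance_ratios_nonincreasing_and_bounded(self, rng):
        res = pca_embed(rng.random((30, 25)), n_components=5,
                        featurized=True)
        r = res.explained_variance_ratio
        assert np.all(np.diff(r) <= 1e-12)
        assert r.sum() <= 1.0 + 1e-12

    def test_two_components_per_sample(self, rng):
        res = pca_embed(rng.random((10, 9)), n_components=2, featurized=True)
        assert res.scores.shape == (10, 2)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_embed(rng.random((5, 9)), n_components=5, featurized=True)


class TestBaselines:
    @pytest.fixture(scope="class")
    def tiny_phantom_split(self):
        presets = make_class_presets(0.0)
        ds = make_image_dataset(presets, 20, unseen_shift=0.5, seed=3)
        train, seen, unseen = [], [], []
        for c in CLASSES:
            s = ds.subset("seen", c)
            train += s[:12]
            seen += s[12:]
            unseen += ds.subset("unseen", c)[12:]
        return train, seen, unseen

    def test_report_covers_all_methods_and_cycles(self, tiny_phantom_split):
        train, seen, unseen = tiny_phantom_split
        rep = run_baselines(train, seen, unseen, cycles=2, seed=0)
        assert len(rep.records) == 4 * 2
        assert set(rep.records["method"]) == set(BASELINE_METHODS)
        assert rep.records[["seen", "unseen", "pooled"]].min().min() >= 0
        assert rep.records[["seen", "unseen", "pooled"]].max().max() <= 1

    def test_default_cycle_count_is_ten(self, tiny_phantom_split):
        train, seen, unseen = tiny_phantom_split
        rep = run_baselines(train[:6] + train[12:18] + train[24:30],
                            seen, unseen, seed=0)
        assert rep.cycles == 10

    def test_every_method_beats_chance_on_separable_phantoms(
            self, tiny_phantom_split):
        train, seen, unseen = tiny_phantom_split
        rep = run_baselines(train, seen, unseen, cycles=3, seed=0)
        med = rep.records.groupby("method")["seen"].median()
        assert (med > 1 / 3).all()

    def test_invalid_cycles_rejected(self, tiny_phantom_split):
        train, seen, unseen = tiny_phantom_split
        with pytest.raises(ValueError):
            run_baselines(train, seen, unseen, cycles=0)


class TestFeatureMaps:
    @pytest.fixture(scope="class")
    def trained(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([
            np.full((4, 3, 96, 96), -0.5, np.float32),
            np.full((4, 3, 96, 96), 0.5, np.float32)])
        X += rng.normal(0, 0.05, X.shape).astype(np.float32)
        y = np.array(["day2"] * 4 + ["day14"] * 4)
        return CNNMaturationClassifier(epochs=1, batch_size=4,
                                       seed=0).fit(X, y)

    def test_four_normalized_maps_of_the_final_grid(self, trained, rng):
        maps = feature_maps(trained, rng.random((3, 96, 96))
                            .astype(np.float32))
        assert maps.shape == (4, 12, 12)
        assert maps.min() >= 0.0 and maps.max() <= 1.0

    def test_larger_inputs_are_center_cropped(self, trained, rng):
        maps = feature_maps(trained, rng.random((3, 128, 128))
                            .astype(np.float32))
        assert maps.shape == (4, 12, 12)

    def test_non_conv_model_rejected(self, rng):
        X = np.concatenate([np.full((2, 3, 96, 96), -0.5, np.float32),
                            np.full((2, 3, 96, 96), 0.5, np.float32)])
        y = np.array(["day2", "day2", "day14", "day14"])
        fc = build_ablation_model("fc_only", epochs=1, batch_size=2)
        fc.fit(X, y)
        with pytest.raises(ValueError):
            feature_maps(fc, X[0])

    def test_unknown_ablation_name_rejected(self):
        with pytest.raises(ValueError):
            build_ablation_model("vgg")
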