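"""Normalisation, SVM training, cross-validation and metric computation."""

import numpy as np
import pytest

from nirscomp import ClassifierConfig, CompensationSVM, Normalizer, evaluate_metrics
from nirscomp.exceptions import ConfigurationError, TrainingError
from nirscomp.recording import CLASSES


def blobs(rng, n_per_class=50, spread=0.05):
    """Four well-separated Gaussian blobs in 2-D, labelled NC/LF/TR/SE."""
    centers = {"NC": (0, 0), "LF": (3, 0), "TR": (0, 3), "SE": (3, 3)}
    X, y = [], []
    for label, c in centers.items():
        X.append(rng.normal(c, spread, size=(n_per_class, 2)))
        y += [label] * n_per_class
    return np.vstack(X), np.array(y)


class TestNormalizer:
    def test_zscore_train_stats(self, rng):
        X = rng.normal(3.0, 2.0, size=(200, 5))
        norm = Normalizer("zscore").fit(X)
        Z = norm.apply(X)
        assert np.max(np.abs(Z.mean(axis=0))) < 1e-9
        np.testing.assert_allclose(Z.std(axis=0), 1.0, rtol=1e-9)

    def test_constant_feature_maps_to_zero(self, rng):
        X = rng.normal(size=(50, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning):
            norm = Normalizer("zscore").fit(X)
        assert np.all(norm.apply(X)[:, 1] == 0.0)

    def test_affine_inverse_round_trip(self, rng):
        X = rng.normal(size=(40, 6))
        norm = Normalizer("minmax").fit(X)
        np.testing.assert_allclose(norm.inverse(norm.apply(X)), X, atol=1e-10)


class TestTraining:
    def test_separable_blobs_training_accuracy(self, rng):
        X, y = blobs(rng)
        fitted = CompensationSVM(X, y).fit()
        assert fitted.training_accuracy == 1.0

    def test_xor_rbf_sanity(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array(["NC", "NC", "LF", "LF"])
        fitted = CompensationSVM(X, y, ClassifierConfig(C=10.0, folds=2)).fit()
        assert np.all(fitted.predict(X) == y)

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError):
            CompensationSVM(np.zeros((10, 2)), np.array(["NC"] * 10))

    def test_unknown_label_rejected(self):
        with pytest.raises(TrainingError):
            CompensationSVM(np.zeros((4, 2)), np.array(["NC", "LF", "UD", "SE"]))


class TestCrossValidation:
    def test_separable_features_perfect_accuracy(self, rng):
        X, y = blobs(rng)
        rep = CompensationSVM(X, y).crossvalidate()
        assert rep.accuracy == 1.0
        assert np.all(rep.confusion == np.diag([50, 50, 50, 50]))

    def test_permuted_labels_fall_to_chance(self, rng):
        X, y = blobs(rng, n_per_class=100)
        yp = rng.permutation(y)
        rep = CompensationSVM(X, yp, ClassifierConfig(folds=5)).crossvalidate()
        assert 0.25 - 0.08 < rep.accuracy < 0.25 + 0.08

    def test_fold_sizes_balanced_per_class(self, rng):
        X, y = blobs(rng, n_per_class=53)
        rep = CompensationSVM(X, y).crossvalidate()
        for d in rep.fold_details:
            labels = y[d["test_indices"]]
            counts = [int(np.sum(labels == c)) for c in CLASSES]
            assert max(counts) - min(counts) <= 1

    def test_deterministic_under_seed(self, rng):
        X, y = blobs(rng, spread=1.0)
        cfg = ClassifierConfig(seed=3)
        a = CompensationSVM(X, y, cfg).crossvalidate().to_dict()
        b = CompensationSVM(X, y, cfg).crossvalidate().to_dict()
        assert a == b

    def test_folds_exceeding_rows_rejected(self, rng):
        X = rng.normal(size=(6, 2))
        y = np.array(["NC", "LF", "TR", "SE", "NC", "LF"])
        with pytest.raises(TrainingError):
            CompensationSVM(X, y, ClassifierConfig(folds=10)).crossvalidate()

    def test_no_leakage_through_normalisation(self, rng):
        """An extreme outlier confined to held-out rows must not move the
        training-side normalisation parameters of its fold."""
        X, y = blobs(rng)
        cfg = ClassifierConfig(folds=4, seed=0)
        base = CompensationSVM(X, y, cfg).crossvalidate()
        # find the fold holding row 0 out, then poison that row only
        fold_of_row0 = next(
            i for i, d in enumerate(base.fold_details) if 0 in d["test_indices"]
        )
        X2 = X.copy()
        X2[0] = 1e6
        poisoned = CompensationSVM(X2, y, cfg).crossvalidate()
        np.testing.assert_allclose(
            poisoned.fold_details[fold_of_row0]["norm_shift"],
            base.fold_details[fold_of_row0]["norm_shift"],
            atol=1e-12,
        )
        np.testing.assert_allclose(
            poisoned.fold_details[fold_of_row0]["norm_scale"],
            base.fold_details[fold_of_row0]["norm_scale"],
            atol=1e-12,
        )

    def test_trial_level_split_keeps_trials_together(self, rng):
        X, y = blobs(rng, n_per_class=40)
        trials = np.array([f"{lbl}_{i // 10}" for i, lbl in enumerate(y)])
        cfg = ClassifierConfig(folds=4, split_unit="trial")
        rep = CompensationSVM(X, y, cfg, trial_ids=trials).crossvalidate()
        seen = {}
        for k, d in enumerate(rep.fold_details):
            for t in set(trials[d["test_indices"]]):
                assert t not in seen, "trial split across folds"
                seen[t] = k
        assert set(seen) == set(trials)


class TestMetrics:
    def test_perfect_diagonal(self):
        m = evaluate_metrics(np.diag([10, 10, 10, 10]))
        assert m["accuracy"] == 1.0
        assert m["macro_f1"] == 1.0
        assert all(v["f1"] == 1.0 for v in m["per_class"].values())

    def test_two_class_hand_computation(self):
        cm = np.zeros((4, 4), dtype=int)
        cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1] = 9, 1, 1, 9
        with pytest.warns(UserWarning):
            m = evaluate_metrics(cm)
        assert m["per_class"]["NC"]["precision"] == pytest.approx(0.9)
        assert m["per_class"]["NC"]["recall"] == pytest.approx(0.9)
        assert m["per_class"]["LF"]["f1"] == pytest.approx(0.9)

    def test_degenerate_all_zero(self):
        with pytest.warns(UserWarning):
            m = evaluate_metrics(np.zeros((4, 4), dtype=int))
        assert m["accuracy"] == 0.0
        assert m["macro_f1"] == 0.0

    def test_negative_entries_rejected(self):
        cm = np.diag([1, 1, 1, -1])
        with pytest.raises(ConfigurationError):
            evaluate_metrics(cm)

    def test_f1_is_harmonic_mean(self, rng):
        cm = rng.integers(0, 30, size=(4, 4))
        with np.errstate(all="ignore"):
            m = evaluate_metrics(cm)
        for c in CLASSES:
            p, r, f = (m["per_class"][c][k] for k in ("precision", "recall", "f1"))
            if p + r > 0:
                assert f == pytest.approx(2 * p * r / (p + r), rel=1e-9)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        ClassifierConfig(C=0.0)
    with pytest.raises(ConfigurationError):
        ClassifierConfig(folds=1)
    with pytest.raises(ConfigurationError):
        ClassifierConfig(gamma_rule="fixed")
    assert ClassifierConfig(gamma_rule="fixed", gamma_value=0.1).gamma == 0.1
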