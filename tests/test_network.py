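"""The dense classifier: architecture, training behaviour, determinism."""

import numpy as np
import pytest

from scfsnn import DenseClassifier, NetConfig, accuracy, build_model


@pytest.fixture
def cfg():
    return NetConfig(dtype="float64")


def separable_problem(rng, n=200, p=5):
    X = rng.normal(size=(n, p))
    y = (X[:, 0] + X[:, 1] > 0).astype(int)
    return X, y


class TestArchitecture:
    def test_layer_widths(self, cfg, rng):
        model = DenseClassifier(10, 2, cfg, rng)
        assert model.params["W0"].shape == (10, 256)
        assert model.params["W1"].shape == (256, 128)
        assert model.params["W2"].shape == (128, 2)

    def test_softmax_rows_sum_to_one(self, cfg, rng):
        model = DenseClassifier(7, 3, cfg, rng)
        probs = model.predict_proba(rng.normal(size=(11, 7)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs > 0) and np.all(probs < 1)

    def test_same_seed_identical_initial_weights(self, cfg):
        a = build_model(6, 2, cfg, seed=4)
        b = build_model(6, 2, cfg, seed=4)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_invalid_sizes_rejected(self, cfg, rng):
        with pytest.raises(ValueError):
            DenseClassifier(0, 2, cfg, rng)
        with pytest.raises(ValueError):
            DenseClassifier(3, 1, cfg, rng)


class TestTraining:
    def test_separable_toy_fits_within_30_epochs(self, cfg, rng):
        X, y = separable_problem(rng)
        model = DenseClassifier(5, 2, cfg, rng)
        model.fit_epochs(X, y, 30)
        assert accuracy(model, X, y) > 0.95

    def test_zero_epochs_leaves_model_unchanged(self, cfg, rng):
        X, y = separable_problem(rng, n=50)
        model = DenseClassifier(5, 2, cfg, rng)
        before = {k: v.copy() for k, v in model.params.items()}
        model.fit_epochs(X, y, 0)
        for k, v in model.params.items():
            np.testing.assert_array_equal(v, before[k])

    def test_loss_decreases_on_separable_toy(self, cfg, rng):
        X, y = separable_problem(rng)
        model = DenseClassifier(5, 2, cfg, rng)
        losses = model.fit_epochs(X, y, 12)
        assert np.mean(losses[-3:]) < np.mean(losses[:3])

    def test_no_signal_control_near_majority_rate(self, cfg, rng):
        """Label-permuted data: held-out accuracy stays near the majority rate."""
        X = rng.normal(size=(300, 8))
        y = rng.permutation(np.repeat([0, 1], 150))
        model = DenseClassifier(8, 2, cfg, rng)
        model.fit_epochs(X[:200], y[:200], 20)
        acc = accuracy(model, X[200:], y[200:])
        assert abs(acc - 0.5) < 0.15


class TestEvalDeterminism:
    def test_repeated_predict_bitwise_identical(self, cfg, rng):
        X, y = separable_problem(rng, n=64)
        model = DenseClassifier(5, 2, cfg, rng)
        model.fit_epochs(X, y, 3)
        p1 = model.predict_proba(X)
        p2 = model.predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_input_gradients_deterministic(self, cfg, rng):
        X, y = separable_problem(rng, n=32)
        model = DenseClassifier(5, 2, cfg, rng)
        model.fit_epochs(X, y, 2)
        np.testing.assert_array_equal(
            model.input_gradients(X, y), model.input_gradients(X, y)
        )


class TestFeatureDropping:
    def test_dropping_matches_zero_masked_predictions(self, cfg, rng):
        """Slicing the first layer equals zeroing the dropped input columns."""
        X, y = separable_problem(rng, n=80, p=6)
        model = DenseClassifier(6, 2, cfg, rng)
        model.fit_epochs(X, y, 3)
        keep = np.array([0, 2, 3, 5])
        X_masked = X.copy()
        X_masked[:, [1, 4]] = 0.0
        expected = model.predict_proba(X_masked)
        model.drop_features(keep)
        got = model.predict_proba(X[:, keep])
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestPersistence:
    def test_save_load_round_trip(self, cfg, rng, tmp_path):
        X, y = separable_problem(rng, n=60)
        model = DenseClassifier(5, 2, cfg, rng)
        model.fit_epochs(X, y, 2)
        path = tmp_path / "model.npz"
        model.save(path)
        clone = DenseClassifier.load(path)
        np.testing.assert_array_equal(model.predict_proba(X), clone.predict_proba(X))


class TestAccuracy:
    def test_hand_built_two_thirds(self, cfg, rng):
        model = DenseClassifier(2, 2, cfg, rng)
        X = rng.normal(size=(3, 2))
        probs = model.predict_proba(X)
        pred = probs.argmax(axis=1)
        y = pred.copy()
        y[0] = 1 - y[0]  # break one match
        assert accuracy(model, X, y) == pytest.approx(2 / 3)
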