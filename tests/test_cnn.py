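"""Dilated-CNN classifier: preprocessing, architecture, training, prediction.

The backward pass is validated against central-difference numerical
gradients on a miniature configuration; learning behavior is checked on
small separable synthetic data.
"""

import dataclasses

import numpy as np
import pytest

from oxirelax import (AcquisitionConfig, ModelConfig, build_model,
                      generate_dataset, predict, preprocess, train)
from oxirelax.cnn import _backward, _forward, predict_proba
from oxirelax.errors import (ConfigurationError, DegenerateInputError,
                             InvalidInputError)

SMALL = ModelConfig(target_len=128, epochs=25, seed=0)


@pytest.fixture(scope="module")
def separable_data():
    """Noiseless, widely separated curves: a learning sanity oracle."""
    acq = AcquisitionConfig(n_echoes=512, noise_sigma=0.0)
    recs = generate_dataset(30, (1 / 3, 1 / 3, 1 / 3), acq, seed=5)
    X = np.stack([preprocess(r.curve, SMALL.target_len) for r in recs])
    y = np.array([int(r.true_class) for r in recs])
    return X, y


class TestPreprocess:
    def test_minmax_contract(self, rng):
        x = preprocess(rng.normal(size=700), 128)
        assert x.shape == (128,)
        assert x.min() == 0.0 and x.max() == 1.0

    def test_identity_length_rescales_only(self, rng):
        raw = rng.normal(size=128)
        x = preprocess(raw, 128)
        expected = (raw - raw.min()) / (raw.max() - raw.min())
        np.testing.assert_allclose(x, expected, rtol=1e-6)

    def test_pooled_monoexponential_still_strictly_decreasing(self):
        t = 8e-4 * np.arange(1, 2049)
        x = preprocess(np.exp(-t / 0.1), 512)
        assert np.all(np.diff(x) < 0)

    def test_upsampling_short_curves(self):
        x = preprocess(np.linspace(1, 0, 64), 128)
        assert x.shape == (128,)
        assert x[0] == 1.0 and x[-1] == 0.0

    def test_constant_curve_rejected(self):
        with pytest.raises(DegenerateInputError):
            preprocess(np.ones(100), 64)


class TestBuildModel:
    def test_output_width_and_param_count(self):
        model = build_model(ModelConfig())
        assert model.weights["out_W"].shape[1] == 3
        assert model.n_parameters == sum(w.size for w in model.weights.values())

    def test_softmax_simplex(self, rng):
        model = build_model(SMALL)
        probs = _forward(model, rng.uniform(0, 1, (8, 128)).astype(np.float32))
        assert probs.shape == (8, 3)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_receptive_field_exceeding_input_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(target_len=64)  # default receptive field is 121

    def test_relu_dead_zone(self, rng):
        """Inputs differing only where every first-layer channel is inactive
        produce identical outputs."""
        model = build_model(SMALL)
        # force all first-layer pre-activations negative for non-negative input
        model.weights["conv0_W"] = -np.abs(model.weights["conv0_W"]) - 0.01
        model.weights["conv0_b"][:] = 0.0
        a = rng.uniform(0.1, 1, (1, 128)).astype(np.float32)
        b = rng.uniform(0.1, 1, (1, 128)).astype(np.float32)
        np.testing.assert_array_equal(_forward(model, a), _forward(model, b))

    def test_config_consistency_checks(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(n_conv_layers=3)
        with pytest.raises(ConfigurationError):
            ModelConfig(kernel_size=8)


def test_backward_matches_numerical_gradient(rng):
    cfg = ModelConfig(n_conv_layers=2, filters_per_layer=(3, 4), kernel_size=3,
                      dilation_rates=(1, 2), dense_units=5, target_len=20, seed=0)
    model = build_model(cfg)
    model.weights = {k: v.astype(np.float64) for k, v in model.weights.items()}
    X = rng.uniform(0, 1, (4, 20))
    y = np.array([0, 1, 2, 1])
    onehot = np.eye(3)[y]
    sw = np.ones(4)

    probs, cache = _forward(model, X, want_cache=True)
    grads = _backward(model, cache, probs, onehot, sw)

    def loss():
        p = _forward(model, X)
        return -np.mean(np.log(p[np.arange(4), y]))

    eps = 1e-6
    for key in ("conv0_W", "conv1_W", "dense_W", "out_W", "conv1_b"):
        W = model.weights[key]
        flat = W.reshape(-1)
        picks = rng.choice(flat.size, size=min(10, flat.size), replace=False)
        for i in picks:
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss()
            flat[i] = orig - eps
            lm = loss()
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[key].reshape(-1)[i] == pytest.approx(num, rel=1e-4, abs=1e-9)


class TestTrain:
    def test_separable_data_memorized(self, separable_data):
        X, y = separable_data
        cfg = dataclasses.replace(SMALL, epochs=50, val_fraction=0.2)
        model = train(X, y, cfg)
        assert model.training_history["train_acc"][-1] >= 0.95
        # training curves recorded for every epoch
        assert len(model.training_history["val_loss"]) == 50
        # memorization sanity: training curves get their own labels back
        pred = predict_proba(model, X).argmax(axis=1)
        assert np.mean(pred == y) >= 0.95

    def test_seeded_determinism(self, separable_data):
        X, y = separable_data
        cfg = dataclasses.replace(SMALL, epochs=5)
        h1 = train(X, y, cfg).training_history
        h2 = train(X, y, cfg).training_history
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_acc"] == h2["val_acc"]

    def test_single_class_rejected(self, separable_data):
        X, _ = separable_data
        with pytest.raises(InvalidInputError):
            train(X, np.zeros(len(X), dtype=int), SMALL)

    def test_input_length_robustness(self, separable_data):
        """One model classifies curves of 1,024 / 2,048 / 16,384 echoes."""
        X, y = separable_data
        model = train(X, y, dataclasses.replace(SMALL, epochs=40))
        t2 = 0.18  # a clearly non-oxidized, slow-relaxing sample
        for n_echoes in (1024, 2048, 16384):
            t = 2 * 4.0e-4 * np.arange(1, n_echoes + 1)
            label, prob = predict(model, np.exp(-t / t2))
            assert label in ("Good", "Fair", "Bad")
            assert 1 / 3 <= prob <= 1.0


class TestPredict:
    def test_probability_range(self, separable_data):
        X, y = separable_data
        model = train(X, y, dataclasses.replace(SMALL, epochs=3))
        _, prob = predict(model, X[0])
        assert 1 / 3 <= prob <= 1.0

    def test_uniform_tie_breaks_to_first_class(self):
        model = build_model(SMALL)
        # zero the head: logits identical -> exactly uniform softmax
        model.weights["out_W"][:] = 0.0
        model.weights["out_b"][:] = 0.0
        label, prob = predict(model, np.linspace(1, 0, 128))
        assert label == model.class_order[0]
        assert prob == pytest.approx(1 / 3)

    def test_save_load_roundtrip(self, separable_data, tmp_path):
        X, y = separable_data
        from oxirelax import TrainedModel
        model = train(X, y, dataclasses.replace(SMALL, epochs=3))
        model.save(tmp_path / "m")
        loaded = TrainedModel.load(tmp_path / "m")
        assert loaded.config == model.config
        np.testing.assert_array_equal(
            predict_proba(loaded, X[:5]), predict_proba(model, X[:5]))
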