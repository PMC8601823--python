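"""Patch CNN: architecture, loss, gradients, training schedule, checkpoints."""

import numpy as np
import pytest

from alrls.cnn import (
    CNNSpec,
    LabeledPatchSet,
    TrainingConfig,
    accuracy,
    build_model,
    load_checkpoint,
    loss,
    loss_and_grads,
    predict_batch,
    save_checkpoint,
    train,
)

TINY = CNNSpec(d1=2, d2=2, fc1=8, fc2=5)


def separable_patches(n_per_class, seed=0):
    """Trivially separable synthetic classes: dark vs bright patches."""
    rng = np.random.default_rng(seed)
    dark = np.clip(rng.normal(0.25, 0.05, size=(n_per_class, 32, 32)), 0, 1)
    bright = np.clip(rng.normal(0.75, 0.05, size=(n_per_class, 32, 32)), 0, 1)
    X = np.concatenate([dark, bright])
    y = np.repeat([0, 1], n_per_class)
    return LabeledPatchSet(X=X, y=y)


class TestArchitecture:
    def test_seeded_build_is_deterministic(self):
        a = build_model(TINY, seed=3)
        b = build_model(TINY, seed=3)
        for key in a.params:
            np.testing.assert_array_equal(a.params[key], b.params[key])

    def test_default_flatten_feeds_first_fc_layer(self):
        spec = CNNSpec()
        assert spec.computed_flatten() == 1600
        assert spec.fc1 == 1600

    def test_mismatched_flatten_rejected(self):
        with pytest.raises(ValueError, match="flatten"):
            CNNSpec(flatten_size=999).validate()

    def test_forward_on_zero_image_is_valid_softmax(self):
        m = build_model(TINY, seed=0)
        m.step = 1  # mark trained for inference
        probs = predict_batch(m, np.zeros((1, 32, 32)))
        assert np.all(np.isfinite(probs))
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)


class TestLoss:
    def test_uniform_prediction_value(self):
        m = build_model(TINY, seed=0)
        for key in m.params:
            m.params[key] = np.zeros_like(m.params[key])
        m.params["bn1_gamma"] = np.ones_like(m.params["bn1_gamma"])
        m.params["bn2_gamma"] = np.ones_like(m.params["bn2_gamma"])
        batch = LabeledPatchSet(X=np.zeros((1, 32, 32)), y=np.array([0]))
        assert loss(m, batch, eta=1.0) == pytest.approx(np.log(2.0), abs=1e-6)

    def test_l2_part_linear_in_eta(self):
        m = build_model(TINY, seed=1, dtype=np.float64)
        batch = separable_patches(2, seed=1).subset(np.arange(4))
        l0 = loss(m, batch, eta=0.0)
        l1 = loss(m, batch, eta=1.0)
        l2 = loss(m, batch, eta=2.0)
        assert l2 - l0 == pytest.approx(2 * (l1 - l0), rel=1e-9)

    def test_l2_equals_independent_sum_of_squares(self):
        from alrls.cnn import _L2_KEYS

        m = build_model(TINY, seed=2, dtype=np.float64)
        batch = separable_patches(2, seed=2).subset(np.arange(4))
        expected = 0.5 * sum(float((m.params[k] ** 2).sum()) for k in _L2_KEYS)
        assert loss(m, batch, eta=1.0) - loss(m, batch, eta=0.0) == pytest.approx(
            expected, rel=1e-9
        )


class TestGradients:
    def test_analytic_gradient_matches_central_differences(self):
        m = build_model(TINY, seed=0, dtype=np.float64)
        rng = np.random.default_rng(1)
        batch = LabeledPatchSet(X=rng.random((3, 32, 32)), y=np.array([0, 1, 0]))
        _, grads, _ = loss_and_grads(m, batch, eta=1.0, keep_prob=1.0)
        h = 1e-5
        for key, g in grads.items():
            flat = m.params[key].ravel()
            gflat = g.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + h
                lp = loss(m, batch, eta=1.0, keep_prob=1.0)
                flat[i] = orig - h
                lm = loss(m, batch, eta=1.0, keep_prob=1.0)
                flat[i] = orig
                numeric = (lp - lm) / (2 * h)
                denom = max(abs(numeric) + abs(gflat[i]), 1e-8)
                assert abs(numeric - gflat[i]) / denom < 1e-4, key


class TestTraining:
    def test_lr_schedule_decays_at_10000_step_boundaries(self):
        cfg = TrainingConfig(initial_lr=0.1)
        assert cfg.lr_at(0) == pytest.approx(0.1)
        assert cfg.lr_at(9999) == pytest.approx(0.1)
        assert cfg.lr_at(25000) == pytest.approx(0.1 * 0.9997**2)

    def test_separable_classes_reach_high_accuracy(self):
        data = separable_patches(150, seed=0)
        m = build_model(seed=0)
        m, log = train(m, data, TrainingConfig(max_steps=200, seed=0, log_every=200))
        assert log[-1]["val_accuracy"] >= 0.95

    def test_loss_trend_decreases(self):
        data = separable_patches(150, seed=3)
        losses = []
        m = build_model(seed=1)
        cfg = TrainingConfig(max_steps=1, seed=1, log_every=1)
        for _ in range(60):
            m, log = train(m, data, cfg)
            losses.append(log[-1]["train_loss"])
        assert np.mean(losses[-15:]) < np.mean(losses[:15])

    def test_same_seed_reproduces_weights(self):
        data = separable_patches(40, seed=2)
        runs = []
        for _ in range(2):
            m = build_model(TINY, seed=5)
            m, _ = train(m, data, TrainingConfig(max_steps=30, seed=5))
            runs.append(m)
        for key in runs[0].params:
            np.testing.assert_array_equal(runs[0].params[key], runs[1].params[key])
            np.testing.assert_array_equal(runs[0].shadow[key], runs[1].shadow[key])

    def test_single_class_data_rejected(self):
        X = np.zeros((10, 32, 32))
        with pytest.raises(ValueError):
            train(build_model(TINY, seed=0), LabeledPatchSet(X=X, y=np.zeros(10, dtype=int)))

    def test_inference_uses_shadow_weights_deterministically(self):
        data = separable_patches(40, seed=4)
        m = build_model(TINY, seed=0)
        m, _ = train(m, data, TrainingConfig(max_steps=20, seed=0))
        X = data.X[:5]
        np.testing.assert_array_equal(predict_batch(m, X), predict_batch(m, X))
        assert np.allclose(predict_batch(m, X).sum(axis=1), 1.0, atol=1e-6)


class TestCheckpoint:
    @pytest.fixture()
    def trained(self):
        m = build_model(TINY, seed=0)
        m, _ = train(m, separable_patches(40, seed=0), TrainingConfig(max_steps=20, seed=0))
        return m

    def test_round_trip_identical_predictions(self, trained, tmp_path, rng):
        probe = rng.random((4, 32, 32))
        save_checkpoint(trained, tmp_path / "ck")
        loaded = load_checkpoint(tmp_path / "ck")
        np.testing.assert_array_equal(predict_batch(trained, probe), predict_batch(loaded, probe))
        assert loaded.step == trained.step

    def test_corrupted_weights_error(self, trained, tmp_path):
        save_checkpoint(trained, tmp_path / "ck")
        (tmp_path / "ck.npz").write_bytes(b"not a zipfile")
        with pytest.raises(IOError):
            load_checkpoint(tmp_path / "ck")

    def test_sidecar_spec_mismatch_error(self, trained, tmp_path):
        import json

        save_checkpoint(trained, tmp_path / "ck")
        sidecar = json.loads((tmp_path / "ck.json").read_text())
        sidecar["spec"]["d1"] = 99
        (tmp_path / "ck.json").write_text(json.dumps(sidecar))
        with pytest.raises(IOError, match="shape"):
            load_checkpoint(tmp_path / "ck")

    def test_version_mismatch_error(self, trained, tmp_path):
        import json

        save_checkpoint(trained, tmp_path / "ck")
        sidecar = json.loads((tmp_path / "ck.json").read_text())
        sidecar["version"] = 999
        (tmp_path / "ck.json").write_text(json.dumps(sidecar))
        with pytest.raises(IOError, match="version"):
            load_checkpoint(tmp_path / "ck")
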