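"""The CNN+MLP patch classifier: construction, training, prediction,
checkpoints, determinism."""

import numpy as np
import pytest

from greenmap import (
    CLASS_ORDER,
    Manifest,
    SceneSpec,
    TrainingConfig,
    build_model,
    load_checkpoint,
    predict,
    retrain,
    save_checkpoint,
    train,
    write_scene,
)
from greenmap.model import DataError, load_manifest_arrays

TINY = dict(conv_filters=(8, 16), hidden_units=32)  # fast profile for unit tests


def tiny_config(**kwargs):
    defaults = dict(epochs=2, learning_rate=1e-3, seed=0, **TINY)
    defaults.update(kwargs)
    return TrainingConfig(**defaults)


@pytest.fixture(scope="module")
def tiny_manifest(tmp_path_factory):
    """24 labelled 24-px tiles (3 per class) on disk."""
    layout = [[CLASS_ORDER[(r * 8 + c) % 8] for c in range(8)] for r in range(3)]
    spec = SceneSpec(3, 8, tile_size=24, seed=42, class_layout=layout)
    _, manifest_path = write_scene(spec, tmp_path_factory.mktemp("tiny"))
    return Manifest.read_csv(manifest_path)


class TestBuildModel:
    def test_forward_shape_contract(self):
        model = build_model(TrainingConfig(), tile_size=200, n_classes=8)
        out = model.forward(np.zeros((2, 200, 200, 3)))
        assert out.shape == (2, 8)

    def test_same_seed_identical_parameters(self):
        a = build_model(tiny_config(seed=5), 24)
        b = build_model(tiny_config(seed=5), 24)
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            assert np.array_equal(wa, wb)

    def test_different_seed_different_parameters(self):
        a = build_model(tiny_config(seed=5), 24)
        b = build_model(tiny_config(seed=6), 24)
        assert any(not np.array_equal(wa, wb) for wa, wb in zip(a.get_weights(), b.get_weights()))

    def test_softmax_normalized(self, rng):
        model = build_model(tiny_config(), 24)
        probs = model.predict_proba(rng.random((4, 24, 24, 3)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_too_small_tile_rejected(self):
        with pytest.raises(ValueError):
            build_model(TrainingConfig(), tile_size=8)

    def test_defaults_match_shipped_profile(self):
        cfg = TrainingConfig()
        assert (cfg.batch_size, cfg.epochs, cfg.learning_rate) == (20, 200, 1e-2)
        assert (cfg.optimizer, cfg.loss, cfg.activation) == ("adam", "cross_entropy", "relu")
        assert (cfg.regularization, cfg.pooling, cfg.output_transfer) == ("none", "max", "linear")


class TestTrain:
    def test_history_one_entry_per_epoch(self, tiny_manifest):
        model = build_model(tiny_config(epochs=3), 24)
        _, history = train(model, tiny_manifest, tiny_config(epochs=3))
        assert [h["epoch"] for h in history] == [1, 2, 3]
        assert all(np.isfinite(h["loss"]) for h in history)

    def test_loss_decreases(self, tiny_manifest):
        cfg = tiny_config(epochs=10)
        model = build_model(cfg, 24)
        _, history = train(model, tiny_manifest, cfg)
        assert history[-1]["loss"] <= history[0]["loss"]

    def test_training_deterministic(self, tiny_manifest):
        runs = []
        for _ in range(2):
            cfg = tiny_config(epochs=2, seed=3)
            model = build_model(cfg, 24)
            model, _ = train(model, tiny_manifest, cfg)
            runs.append(model.get_weights())
        for wa, wb in zip(*runs):
            assert np.array_equal(wa, wb)

    def test_zero_epochs_disallowed(self):
        with pytest.raises(ValueError):
            TrainingConfig(epochs=0)

    def test_empty_manifest_is_data_error(self):
        model = build_model(tiny_config(), 24)
        with pytest.raises(DataError):
            train(model, Manifest.empty(), tiny_config())

    def test_unreadable_tile_is_data_error(self, tmp_path):
        manifest = Manifest.from_records(
            [{"tile_path": str(tmp_path / "missing.png"), "source_id": "s",
              "grid_row": 0, "grid_col": 0, "class_code": "H"}]
        )
        model = build_model(tiny_config(), 24)
        with pytest.raises(DataError, match="unreadable"):
            train(model, manifest, tiny_config())

    def test_max_steps_caps_optimiser_steps(self, tiny_manifest):
        cfg = tiny_config(epochs=10, max_steps=2, batch_size=20)
        model = build_model(cfg, 24)
        _, history = train(model, tiny_manifest, cfg)
        assert len(history) <= 2  # 24 tiles / batch 20 = 2 steps per epoch

    def test_balanced_scene_reaches_high_training_accuracy(self, scene_pair):
        """Separable-by-construction textures: a modest run fits the
        balanced training scene almost perfectly."""
        train_man, _ = scene_pair
        cfg = TrainingConfig(epochs=20, learning_rate=1e-3, seed=1)
        model = build_model(cfg, 32)
        _, history = train(model, train_man, cfg)
        assert history[-1]["accuracy"] >= 0.95


class TestPredictRetrain:
    def test_probability_vectors_sum_to_one(self, tiny_manifest):
        model = build_model(tiny_config(), 24)
        x, _ = load_manifest_arrays(tiny_manifest)
        results = predict(model, list(x * 255.0))
        for code, probs in results:
            assert code in CLASS_ORDER
            assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_forced_constant_output_layer(self, rng):
        model = build_model(tiny_config(), 24)
        head = model.layers[-1]
        head.w = np.zeros_like(head.w)
        head.b = np.zeros_like(head.b)
        head.b[CLASS_ORDER.index("UNH")] = 10.0
        results = predict(model, [rng.random((24, 24, 3)) * 255 for _ in range(5)])
        assert all(code == "UNH" for code, _ in results)

    def test_argmax_tie_broken_by_lowest_index(self, rng):
        model = build_model(tiny_config(), 24)
        head = model.layers[-1]
        head.w = np.zeros_like(head.w)
        head.b = np.zeros_like(head.b)  # all logits equal
        (code, probs), = predict(model, [rng.random((24, 24, 3)) * 255])
        assert code == CLASS_ORDER[0]
        assert np.allclose(probs, 1 / 8)

    def test_size_mismatch_rejected(self, rng):
        model = build_model(tiny_config(), 24)
        with pytest.raises(ValueError, match="size"):
            predict(model, [rng.random((32, 32, 3))])

    def test_retrain_with_zero_learning_rate_is_noop(self, tiny_manifest):
        cfg = tiny_config(epochs=2)
        model = build_model(cfg, 24)
        model, _ = train(model, tiny_manifest, cfg)
        before = model.get_weights()
        model, _ = retrain(model, tiny_manifest, tiny_config(epochs=1, learning_rate=0.0))
        for wa, wb in zip(before, model.get_weights()):
            assert np.array_equal(wa, wb)

    def test_retrain_warm_starts_from_given_parameters(self, tiny_manifest):
        cfg = tiny_config(epochs=2)
        model = build_model(cfg, 24)
        model, _ = train(model, tiny_manifest, cfg)
        fresh = build_model(cfg, 24)
        # warm start: retrained model must not equal a freshly initialised one
        model, _ = retrain(model, tiny_manifest, tiny_config(epochs=1))
        assert any(
            not np.array_equal(wa, wb)
            for wa, wb in zip(fresh.get_weights(), model.get_weights())
        )


class TestCheckpoints:
    def test_save_load_roundtrip(self, tmp_path, rng):
        cfg = tiny_config(seed=9)
        model = build_model(cfg, 24)
        save_checkpoint(model, tmp_path / "ckpt", cfg)
        loaded, loaded_cfg = load_checkpoint(tmp_path / "ckpt")
        assert loaded.class_order == model.class_order
        assert loaded.tile_size == 24
        assert loaded_cfg.seed == 9
        x = rng.random((3, 24, 24, 3))
        assert np.array_equal(model.forward(x), loaded.forward(x))

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = tiny_config(epochs=7, learning_rate=5e-4)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert TrainingConfig.from_yaml(tmp_path / "cfg.yaml") == cfg
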