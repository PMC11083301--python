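"""Segmentation network: contracts, masked loss, training behaviour."""

import numpy as np
import pytest

from marrowmeter import (
    ADIPOSE,
    HEMATO,
    IGNORE,
    LabelMask,
    ModelConfig,
    TileSpec,
    build_model,
    generate_tile,
    masked_loss,
    train_on_arrays,
)
from marrowmeter.model import Backbone, SegmentationModel


class TestBuildModel:
    def test_small_cnn_output_shape_and_softmax(self, rng):
        model = build_model(ModelConfig(input_size=64, seed=0))
        x = rng.integers(0, 255, (2, 64, 64, 3), dtype=np.uint8)
        probs = model.predict_proba(x)
        assert probs.shape == (2, 64, 64, 2)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-5)
        assert model.n_params() > 0

    def test_inception_backbone_matches_native_tile_size(self, rng):
        model = build_model(
            ModelConfig(backbone=Backbone.INCEPTIONV3_MIXED7, input_size=256, seed=0)
        )
        x = rng.integers(0, 255, (1, 256, 256, 3), dtype=np.uint8)
        probs = model.predict_proba(x)
        assert probs.shape == (1, 256, 256, 2)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-5)

    def test_incompatible_input_size_states_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(backbone=Backbone.INCEPTIONV3_MIXED7, input_size=100)
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(input_size=66)

    def test_n_classes_fixed_to_two(self):
        with pytest.raises(ValueError, match="n_classes"):
            ModelConfig(n_classes=3)


class TestMaskedLoss:
    def test_perfect_predictions_give_zero(self):
        labels = np.array([[HEMATO, ADIPOSE], [ADIPOSE, HEMATO]], dtype=np.uint8)
        probs = np.eye(2)[labels]
        assert masked_loss(probs, LabelMask(labels)) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_predictions_give_ln2(self, rng):
        labels = rng.integers(0, 3, (16, 16)).astype(np.uint8)
        probs = np.full((16, 16, 2), 0.5)
        assert masked_loss(probs, LabelMask(labels)) == pytest.approx(np.log(2), abs=1e-9)

    def test_relabelling_ignore_pixels_leaves_loss_unchanged(self, rng):
        labels = rng.integers(0, 3, (16, 16)).astype(np.uint8)
        probs = rng.dirichlet((1, 1), (16, 16))
        base = masked_loss(probs, labels)
        flipped = labels.copy()
        ignore = labels == IGNORE
        flipped[ignore] = rng.integers(0, 2, ignore.sum())
        # IGNORE pixels relabelled to tissue DO change the loss; what must
        # not change it is any prediction at the masked positions
        probs2 = probs.copy()
        probs2[ignore] = rng.dirichlet((1, 1), int(ignore.sum()))
        assert masked_loss(probs2, labels) == pytest.approx(base, abs=1e-12)

    def test_all_ignore_defined_zero_with_warning(self):
        labels = np.full((4, 4), IGNORE, dtype=np.uint8)
        with pytest.warns(UserWarning, match="IGNORE"):
            assert masked_loss(np.full((4, 4, 2), 0.5), labels) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            masked_loss(np.full((4, 4, 2), 0.5), np.zeros((5, 5), dtype=np.uint8))


class TestIgnoreMaskingGradients:
    def test_gradients_invariant_to_targets_at_masked_pixels(self):
        # the per-pixel target at an IGNORE position must never reach the
        # parameter gradients: scatter arbitrary one-hot targets at masked
        # positions and require bit-identical gradients
        rgb, mask = generate_tile(
            TileSpec(tile_size=64, target_cellularity=50, ignore_fraction=0.2, seed=7)
        )
        labels = mask.classes
        ignore = labels == IGNORE
        assert ignore.any()

        from marrowmeter import nn
        from marrowmeter.model import _one_hot_and_valid

        model = build_model(ModelConfig(input_size=64, epochs=1, seed=3))
        logits = model.forward_logits(rgb[None].astype(np.float32))
        probs = nn.softmax(logits)
        onehot, valid = _one_hot_and_valid(labels[None])

        def grads_for(target):
            dlogits = (probs - target) * valid[..., None] / valid.sum()
            assert (dlogits[0][ignore] == 0).all()  # masked pixels emit no signal
            model.net.backward(dlogits.astype(np.float32))
            return {qn: lay.grads[name].copy()
                    for qn, lay, name, _ in model.net.param_items()}

        ga = grads_for(onehot)
        rng = np.random.default_rng(0)
        relabelled = onehot.copy()
        relabelled[0][ignore] = np.eye(2, dtype=np.float32)[
            rng.integers(0, 2, int(ignore.sum()))
        ]
        gb = grads_for(relabelled)
        for qn in ga:
            np.testing.assert_array_equal(ga[qn], gb[qn])


class TestPredictTile:
    def test_wrong_tile_size_rejected(self, rng):
        model = build_model(ModelConfig(input_size=64, seed=0))
        with pytest.raises(ValueError, match="rgb_tile"):
            model.predict_tile(rng.integers(0, 255, (32, 32, 3), dtype=np.uint8))

    def test_prediction_deterministic(self, rng):
        model = build_model(ModelConfig(input_size=64, seed=0))
        tile = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
        assert model.predict_tile(tile) == model.predict_tile(tile)

    def test_argmax_tie_goes_to_hemato(self):
        # untrained zero-weight head emits exactly equal logits
        model = build_model(ModelConfig(input_size=64, seed=0))
        head = model.net.layers[-1]
        head.params["W"][:] = 0
        head.params["b"][:] = 0
        tile = np.full((64, 64, 3), 127, dtype=np.uint8)
        assert (model.predict_tile(tile).classes == HEMATO).all()

    def test_trained_model_segments_pure_adipose(self, trained_model):
        rgb, _ = generate_tile(
            TileSpec(tile_size=64, target_cellularity=0, ignore_fraction=0, seed=6)
        )
        pred = trained_model.predict_tile(rgb)
        assert (pred.classes == ADIPOSE).mean() >= 0.95


class TestTraining:
    def test_history_length_and_loss_trend_over_seeds(self, training_set):
        # 2 epochs on 20 tiles; loss must not increase in >=80% of 10 runs
        images, labels = training_set
        images, labels = images[:20], labels[:20]
        non_increasing = 0
        for seed in range(10):
            model = build_model(ModelConfig(input_size=64, epochs=2, seed=seed))
            _, hist = train_on_arrays(model, images, labels)
            assert len(hist.train_loss) == 2
            non_increasing += hist.train_loss[1] <= hist.train_loss[0]
        assert non_increasing >= 8

    def test_same_seed_same_data_identical_final_loss(self, training_set):
        images, labels = training_set
        losses = []
        for _ in range(2):
            model = build_model(ModelConfig(input_size=64, epochs=2, seed=5))
            _, hist = train_on_arrays(model, images[:10], labels[:10])
            losses.append(hist.train_loss[-1])
        assert losses[0] == losses[1]

    def test_fixture_training_reaches_high_masked_accuracy(self, trained):
        _, history = trained
        assert history.val_acc[-1] >= 0.95
        assert all(0 <= a <= 1 for a in history.train_acc)

    def test_loss_drops_tenfold_over_full_schedule(self, training_set):
        # full 25-epoch schedule on 100 fixture tiles: the loss trajectory
        # must fall at least tenfold from the first to the last epoch
        images, labels = training_set
        model = build_model(ModelConfig(input_size=64, epochs=25, seed=1))
        _, history = train_on_arrays(model, images[:100], labels[:100])
        assert history.train_loss[-1] <= history.train_loss[0] / 10

    def test_empty_training_set_rejected(self):
        model = build_model(ModelConfig(input_size=64, epochs=1, seed=0))
        with pytest.raises(ValueError, match="empty"):
            train_on_arrays(
                model,
                np.zeros((0, 64, 64, 3), dtype=np.uint8),
                np.zeros((0, 64, 64), dtype=np.uint8),
            )


class TestCheckpoint:
    def test_save_load_roundtrip_preserves_predictions(self, tmp_path, rng):
        model = build_model(ModelConfig(input_size=64, seed=2))
        path = model.save(tmp_path / "ckpt.npz")
        loaded = SegmentationModel.load(path)
        tile = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
        np.testing.assert_array_equal(
            model.predict_tile(tile).classes, loaded.predict_tile(tile).classes
        )
        assert loaded.config.input_size == 64
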