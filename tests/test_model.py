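"""Multi-slice model: shape ledger, training, calibration, persistence.

Training tests run the published architecture code at reduced canvas and
filter widths so they finish in seconds; the full-size shape contracts are
asserted separately (and in the acceptance suite) without training.
"""

import numpy as np
import pytest

import mstcell as M
from mstcell import nn
from mstcell.model import (FeatureExtractor, ModelConfig, build_multi_slice,
                           build_single_tensor, calibrate, load_extractor,
                           load_model, predict, prepare_inputs, train)
from mstcell.preprocess import make_slices
from tests.conftest import small_config


def _bundle(cfg, value=0.1):
    return make_slices(np.full((cfg.canvas_side, cfg.canvas_side, 3), value),
                       cfg.scale_mode)


class TestModelConfig:
    def test_published_shape_arithmetic(self):
        cfg = ModelConfig()
        assert cfg.branch_input_side == 256
        assert cfg.concat_channels == 640
        assert cfg.flatten_len == 32768
        ledger = cfg.shape_ledger()
        assert ledger["branch_output"] == (32, 32, 128)
        assert ledger["concat"] == (32, 32, 640)
        assert ledger["post_merge_pool"] == (16, 16, 128)
        assert ledger["flatten"] == (32768,)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(canvas_side=500)            # not divisible by 32
        with pytest.raises(ValueError):
            ModelConfig(dropout_rate=1.0)
        with pytest.raises(ValueError):
            ModelConfig(kernel=5)
        with pytest.raises(ValueError):
            ModelConfig(scale_mode="tanh")


class TestBuild:
    def test_shape_report_scaled(self):
        cfg = small_config()
        model = build_multi_slice(cfg)
        assert model.shape_report["concat"] == (4, 4, 160)
        assert model.shape_report["flatten"] == (128,)

    def test_single_tensor_variant(self):
        cfg = small_config()
        single = build_single_tensor(cfg)
        multi = build_multi_slice(cfg)
        assert single.n_branches == 1
        assert single.shape_report["flatten"] == (cfg.flatten_len,)
        assert single.n_parameters() < multi.n_parameters()

    def test_single_tensor_takes_one_input(self):
        cfg = small_config()
        single = build_single_tensor(cfg)
        s = cfg.canvas_side
        logits = single.forward([np.zeros((1, s, s, 3), np.float32)])
        assert logits.shape == (1, 4)
        with pytest.raises(ValueError):
            single.forward([np.zeros((1, s, s, 3))] * 5)

    def test_tied_branches_share_weights(self):
        cfg = small_config(tie_branch_weights=True)
        model = build_multi_slice(cfg)
        free = build_multi_slice(small_config())
        assert model.n_parameters() < free.n_parameters()
        assert model.branches[0].layers[0].W is model.branches[3].layers[0].W


class TestTrainContracts:
    def test_one_epoch_history_length(self):
        cfg = small_config(epochs=1)
        imgs = M.generate_dataset({c: 2 for c in M.CLASS_ORDER}, seed=1,
                                  canvas_side=cfg.canvas_side)
        x, y = prepare_inputs(imgs, cfg)
        model = build_multi_slice(cfg)
        model, hist = train(model, (x, y), cfg)
        assert len(hist) == 1
        assert np.isfinite(hist.train_loss[0])

    def test_same_seed_identical_first_epoch_loss(self):
        cfg = small_config(epochs=1)
        imgs = M.generate_dataset({c: 2 for c in M.CLASS_ORDER}, seed=1,
                                  canvas_side=cfg.canvas_side)
        x, y = prepare_inputs(imgs, cfg)
        losses = []
        for _ in range(2):
            model = build_multi_slice(cfg)
            _, hist = train(model, (x, y), cfg)
            losses.append(hist.train_loss[0])
        assert losses[0] == losses[1]

    def test_empty_split_rejected(self):
        cfg = small_config()
        model = build_multi_slice(cfg)
        with pytest.raises(ValueError):
            train(model, ([np.zeros((0, 64, 64, 3))] * 5, np.array([])), cfg)

    def test_end_to_end_synthetic_accuracy(self, trained_pipeline):
        """The CNN separates the four synthetic phenotypes on held-out data."""
        assert trained_pipeline.history.val_acc[-1] >= 0.90

    def test_augmentation_does_not_hurt(self):
        """Flip augmentation never costs more than noise in held-out accuracy."""
        accs = {}
        for augment in (False, True):
            per_seed = []
            for seed in (0, 1, 2):
                imgs = M.generate_dataset({c: 25 for c in M.CLASS_ORDER},
                                          seed=50 + seed, canvas_side=64)
                cfg = small_config(epochs=4, seed=seed)
                split = M.split_dataset(imgs, 0.7, 0.0, seed=seed,
                                        augment=augment)
                x_tr, y_tr = prepare_inputs(split.train, cfg)
                x_te, y_te = prepare_inputs(split.test, cfg)
                model = build_multi_slice(cfg)
                _, hist = train(model, (x_tr, y_tr, x_te, y_te), cfg)
                per_seed.append(hist.val_acc[-1])
            accs[augment] = np.mean(per_seed)
        assert accs[True] >= accs[False] - 0.05


class TestPredict:
    def test_probabilities_normalised(self, trained_pipeline):
        p = predict(trained_pipeline.model, _bundle(trained_pipeline.cfg))
        assert p.shape == (4,)
        assert abs(p.sum() - 1.0) < 1e-6
        assert (p >= 0).all()

    def test_zeroed_output_layer_uniform(self):
        cfg = small_config()
        model = build_multi_slice(cfg)
        model.dense2.W[...] = 0.0
        model.dense2.b[...] = 0.0
        p = predict(model, _bundle(cfg))
        np.testing.assert_allclose(p, 0.25, atol=1e-12)

    def test_scale_mode_mismatch_rejected(self, trained_pipeline):
        bundle = make_slices(np.full((64, 64, 3), 0.5), "zero_one")
        with pytest.raises(ValueError):
            predict(trained_pipeline.model, bundle)

    def test_dropout_inactive_at_inference(self, trained_pipeline):
        b = _bundle(trained_pipeline.cfg, 0.3)
        p1 = predict(trained_pipeline.model, b)
        p2 = predict(trained_pipeline.model, b)
        assert np.array_equal(p1, p2)

    def test_high_degree_rpe_recognised(self, trained_pipeline):
        """Held-out strongly pigmented RPE images classify as RPE."""
        imgs = [M.generate_image(M.PhenotypeSpec(
            M.CellClass.RPE, canvas_side=64, rpe_degree=0.9, seed=7000 + i))
            for i in range(20)]
        x, _ = prepare_inputs(imgs, trained_pipeline.cfg)
        probs = trained_pipeline.model.predict_proba(x)
        frac = (probs.argmax(axis=1)
                == M.CLASS_ORDER.index(M.CellClass.RPE)).mean()
        assert frac >= 0.90


class TestCalibrate:
    def test_feature_length_and_equality_with_flatten(self, trained_pipeline):
        cfg = trained_pipeline.cfg
        extractor = calibrate(trained_pipeline.model)
        b = _bundle(cfg, 0.2)
        feats = extractor(b)
        assert feats.shape == (1, cfg.flatten_len)
        trained_pipeline.model.forward(
            [np.asarray(a, np.float32) for a in
             ([b.macro[None]] + [q[None] for q in b.quadrants])], train=False)
        np.testing.assert_array_equal(feats,
                                      trained_pipeline.model._flat)

    def test_zero_input_finite(self, trained_pipeline):
        feats = calibrate(trained_pipeline.model)(
            _bundle(trained_pipeline.cfg, 0.0))
        assert np.isfinite(feats).all()

    def test_rejects_object_without_flatten(self):
        class NotAModel:
            pass
        with pytest.raises(ValueError):
            FeatureExtractor(NotAModel())


class TestPersistence:
    def test_checkpoint_round_trip(self, tmp_path, trained_pipeline):
        path = tmp_path / "model.npz"
        trained_pipeline.model.save(path)
        back = load_model(path)
        b = _bundle(trained_pipeline.cfg, 0.4)
        np.testing.assert_array_equal(predict(back, b),
                                      predict(trained_pipeline.model, b))

    def test_calibrated_file_strictly_smaller(self, tmp_path,
                                              trained_pipeline):
        mp, ep = tmp_path / "m.npz", tmp_path / "e.npz"
        trained_pipeline.model.save(mp)
        calibrate(trained_pipeline.model).save(ep)
        assert ep.stat().st_size < mp.stat().st_size
        ex = load_extractor(ep)
        b = _bundle(trained_pipeline.cfg, 0.4)
        np.testing.assert_allclose(ex(b),
                                   calibrate(trained_pipeline.model)(b),
                                   atol=1e-6)
        with pytest.raises(ValueError):
            load_model(ep)
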