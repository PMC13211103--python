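"""Detector assembly: pyramid contract, loss composition, decoding,
checkpoint round trips, training smoke."""

import numpy as np
import pytest

from stripedet import _tensor as T
from stripedet.detector import (Model, ModelConfig, ModelOutputs,
                                TrainingDivergedError, build_model,
                                decode_outputs, load_checkpoint, predict,
                                save_checkpoint, total_loss, train)
from stripedet.synthetic import SceneSpec, generate_dataset

TINY = ModelConfig(backbone_width=8, head_width=16)


class TestPyramidContract:
    @pytest.mark.parametrize("size,expected", [
        (640, (80, 40, 20, 10)),
        (320, (40, 20, 10, 5)),
        (128, (16, 8, 4, 2)),
    ])
    def test_level_sizes_and_channels(self, size, expected):
        model = build_model(TINY, seed=0)
        out = model(T.Tensor(np.zeros((1, 3, size, size))))
        for lvl, hw in zip(out.levels, expected):
            assert tuple(lvl.shape) == (1, 96, hw, hw)
        for stack, hw in zip(out.stacks, expected):
            assert tuple(stack.shape) == (1, 3, hw, hw)

    def test_indivisible_input_rejected(self):
        model = build_model(TINY, seed=0)
        with pytest.raises(ValueError):
            model(T.Tensor(np.zeros((1, 3, 100, 100))))

    def test_seeded_init_deterministic(self):
        m1 = build_model(TINY, seed=3)
        m2 = build_model(TINY, seed=3)
        for a, b in zip(m1.parameters(), m2.parameters()):
            assert np.array_equal(a.data, b.data)
        m3 = build_model(TINY, seed=4)
        assert any(not np.array_equal(a.data, c.data)
                   for a, c in zip(m1.parameters(), m3.parameters()))


class TestTotalLoss:
    def test_weighted_sum_values(self):
        cfg = ModelConfig()
        one = T.Tensor(1.0)
        assert total_loss(one, one, one, one, cfg).item() == pytest.approx(2.45)
        v = total_loss(T.Tensor(0.5), T.Tensor(0.8), T.Tensor(0.2),
                       T.Tensor(4.0), cfg)
        assert v.item() == pytest.approx(1.77)

    def test_zero_aux_reduces_to_detection(self):
        cfg = ModelConfig()
        v = total_loss(T.Tensor(0.7), T.Tensor(0.9), T.Tensor(0.0),
                       T.Tensor(0.0), cfg)
        assert v.item() == pytest.approx(1.6)

    def test_nan_component_aborts(self):
        with pytest.raises(TrainingDivergedError):
            total_loss(T.Tensor(float("nan")), T.Tensor(0.0), T.Tensor(0.0),
                       T.Tensor(0.0), ModelConfig())


def _craft_outputs(cfg, size, boxes_and_classes):
    """Hand-build head outputs encoding the given pixel boxes."""
    shapes = [(size // s, size // s) for s in cfg.strides]
    cls = [T.Tensor(np.full((1, cfg.num_classes) + s, -20.0)) for s in shapes]
    reg = [T.Tensor(np.zeros((1, 4) + s)) for s in shapes]
    from stripedet.trloss import assign_level
    for (box, cid, score_logit) in boxes_and_classes:
        lvl = assign_level(box, cfg.strides)
        stride = cfg.strides[lvl]
        cx = int((box[0] + box[2]) / 2 / stride)
        cy = int((box[1] + box[3]) / 2 / stride)
        ccx, ccy = (cx + 0.5) * stride, (cy + 0.5) * stride
        ltrb = np.array([ccx - box[0], ccy - box[1], box[2] - ccx, box[3] - ccy])
        cls[lvl].data[0, cid, cy, cx] = score_logit
        reg[lvl].data[0, :, cy, cx] = np.log(ltrb / (2 * stride))
    return ModelOutputs([], [], [], cls, reg)


class TestPredict:
    def test_score_threshold_one_empties_output(self, small_scene):
        model = build_model(TINY, seed=0)
        assert predict(model, small_scene.image, score_thr=1.0) == []

    def test_deterministic_for_fixed_weights(self, small_scene):
        model = build_model(TINY, seed=0)
        d1 = predict(model, small_scene.image, score_thr=0.05)
        d2 = predict(model, small_scene.image, score_thr=0.05)
        assert d1 == d2

    def test_decode_by_hand_two_disjoint_boxes_survive_nms(self):
        cfg = TINY
        boxes = [((8, 8, 60, 24), 0, 6.0), ((72, 80, 120, 100), 1, 5.0)]
        out = _craft_outputs(cfg, 128, boxes)
        dets = decode_outputs(out, cfg, (128, 128), score_thr=0.5, nms_iou=0.9)
        assert len(dets) == 2
        got = {d.class_id: d.box for d in dets}
        for (box, cid, _) in boxes:
            np.testing.assert_allclose(got[cid], box, atol=1e-6)

    def test_duplicate_top_box_suppressed(self):
        cfg = TINY
        out = _craft_outputs(cfg, 128, [((8, 8, 60, 24), 0, 6.0)])
        base = decode_outputs(out, cfg, (128, 128), 0.5, 0.5)
        # add an identical box at a neighbouring cell with a lower score
        out.cls[0].data[0, 0, 2, 5] = 4.0
        out.reg[0].data[0, :, 2, 5] = out.reg[0].data[0, :, 2, 4]
        dup = decode_outputs(out, cfg, (128, 128), 0.5, 0.99)
        assert len(base) == 1
        assert [d.box for d in dup[:1]] == [base[0].box]


@pytest.fixture(scope="module")
def tiny_dataset(tmp_path_factory):
    d = tmp_path_factory.mktemp("voc") / "data"
    spec = SceneSpec(image_size=128, n_objects=(2, 3), seed=1)
    generate_dataset(spec, 8, d, train_frac=1.0)
    return d


class TestTraining:
    def test_one_epoch_logs_finite_components(self, tiny_dataset):
        _, _, log = train(tiny_dataset, TINY, seed=0, epochs=1, batch_size=4,
                          use_icc=True, use_tr=True, optimizer="adam", lr=1e-3)
        entry = log[0]
        for key in ("L_cls", "L_loc", "L_inst", "L_cls_con", "L_TR", "L_total"):
            assert np.isfinite(entry[key])

    def test_disabled_aux_losses_logged_as_zero(self, tiny_dataset):
        _, _, log = train(tiny_dataset, TINY, seed=0, epochs=1, batch_size=4,
                          use_icc=False, use_tr=False, optimizer="adam",
                          lr=1e-3)
        assert log[0]["L_inst"] == log[0]["L_cls_con"] == log[0]["L_TR"] == 0.0

    def test_empty_dataset_rejected(self, tmp_path):
        generate_dataset(SceneSpec(image_size=128, seed=0), 0, tmp_path / "d")
        with pytest.raises(ValueError):
            train(tmp_path / "d", TINY, seed=0, epochs=1)

    def test_checkpoint_round_trip_preserves_predictions(self, tiny_dataset,
                                                         tmp_path,
                                                         small_scene):
        model, icc_mod, _ = train(tiny_dataset, TINY, seed=0, epochs=1,
                                  batch_size=4, use_icc=True, use_tr=True,
                                  optimizer="adam", lr=1e-3)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, TINY, path, icc_module=icc_mod)
        loaded, cfg, licc = load_checkpoint(path)
        assert cfg == TINY and licc is not None
        d1 = predict(model, small_scene.image, score_thr=0.05)
        d2 = predict(loaded, small_scene.image, score_thr=0.05)
        assert d1 == d2

    def test_training_determinism(self, tiny_dataset):
        _, _, log1 = train(tiny_dataset, TINY, seed=7, epochs=1, batch_size=4,
                           use_icc=False, use_tr=True, optimizer="adam",
                           lr=1e-3)
        _, _, log2 = train(tiny_dataset, TINY, seed=7, epochs=1, batch_size=4,
                           use_icc=False, use_tr=True, optimizer="adam",
                           lr=1e-3)
        assert log1 == log2
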