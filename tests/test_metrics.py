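"""Evaluation suite: hand-derived AP values, reference-evaluator
equivalence, ECS properties."""

import numpy as np
import pytest

from stripedet.metrics import (Detection, ar_bucket, average_precision,
                               bucketed_report, ecs, iou, map_suite)
from stripedet.reference import reference_map_suite
from stripedet.trloss import project_box


class TestIoU:
    def test_identical_and_disjoint(self):
        assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0
        assert iou((0, 0, 10, 10), (20, 20, 30, 30)) == 0.0

    def test_half_overlap_value(self):
        assert iou((0, 0, 10, 10), (5, 0, 15, 10)) == pytest.approx(50 / 150)

    def test_degenerate_box_warns_zero(self):
        with pytest.warns(UserWarning):
            assert iou((0, 0, 0, 10), (0, 0, 10, 10)) == 0.0


class TestArBucket:
    @pytest.mark.parametrize("box,bucket", [
        ((0, 0, 100, 100), "G1"),
        ((0, 0, 10, 100), "G4"),
        ((0, 0, 100, 20), "G3"),      # AR exactly 5: half-open boundary
        ((0, 0, 100, 40), "G2"),
        ((0, 0, 80, 10), "G4"),       # AR exactly 8
    ])
    def test_boundaries(self, box, bucket):
        assert ar_bucket(box) == bucket


class TestAveragePrecision:
    def test_perfect_single_detection(self):
        ap = average_precision([((0, 0, 10, 10), 0.9)], [(0, 0, 10, 10)], 0.5)
        assert ap == 1.0

    def test_missed_gt(self):
        assert average_precision([], [(0, 0, 10, 10)], 0.5) == 0.0

    def test_no_gt_excluded(self):
        assert average_precision([((0, 0, 10, 10), 0.9)], [], 0.5) is None

    def test_high_scoring_false_positive_halves_ap(self):
        # FP first, then a perfect match for one of two GTs:
        # 51 recall points at precision 0.5 -> 25.5 / 101
        dets = [((50, 50, 60, 60), 0.9), ((0, 0, 10, 10), 0.8)]
        gts = [(0, 0, 10, 10), (20, 20, 30, 30)]
        ap = average_precision(dets, gts, 0.5)
        assert ap == pytest.approx(51 * 0.5 / 101)

    def test_score_rescaling_invariance(self, rng):
        gts = [tuple(b) for b in [(0, 0, 10, 10), (30, 0, 44, 10),
                                  (0, 30, 10, 60)]]
        dets = [((1, 0, 11, 10), 0.7), ((29, 0, 45, 11), 0.4),
                ((50, 50, 60, 60), 0.6)]
        a = average_precision(dets, gts, 0.5)
        rescaled = [(b, 0.1 + 0.5 * s) for b, s in dets]  # monotone map
        assert average_precision(rescaled, gts, 0.5) == a

    def test_trailing_false_positive_never_raises_ap(self, rng):
        gts = [(0, 0, 10, 10)]
        dets = [((0, 0, 10, 10), 0.9)]
        base = average_precision(dets, gts, 0.5)
        worse = dets + [((40, 40, 50, 50), 0.1)]
        assert average_precision(worse, gts, 0.5) <= base


def _random_fixture(rng, n_images=3, n_classes=2, size=200):
    dets_pi, gts_pi = [], []
    for _ in range(n_images):
        n_gt = int(rng.integers(1, 5))
        boxes, labels = [], []
        for _ in range(n_gt):
            x, y = rng.uniform(0, size - 60, 2)
            w, h = rng.uniform(8, 60, 2)
            boxes.append((x, y, x + w, y + h))
            labels.append(int(rng.integers(0, n_classes)))
        dets = []
        for b, l in zip(boxes, labels):
            if rng.uniform() < 0.8:   # jittered true positive
                j = rng.uniform(-4, 4, 4)
                db = (b[0] + j[0], b[1] + j[1], b[2] + j[2], b[3] + j[3])
                dets.append(Detection(box=db, score=float(rng.uniform()),
                                      class_id=l))
        for _ in range(int(rng.integers(0, 3))):  # false positives
            x, y = rng.uniform(0, size - 40, 2)
            w, h = rng.uniform(5, 40, 2)
            dets.append(Detection(box=(x, y, x + w, y + h),
                                  score=float(rng.uniform()),
                                  class_id=int(rng.integers(0, n_classes))))
        dets_pi.append(dets)
        gts_pi.append((boxes, labels))
    return dets_pi, gts_pi


class TestMapSuite:
    def test_perfect_detections_score_one(self):
        gts = [([(0, 0, 20, 10), (40, 40, 60, 90)], [0, 1])]
        dets = [[Detection((0, 0, 20, 10), 0.9, 0),
                 Detection((40, 40, 60, 90), 0.8, 1)]]
        rep = map_suite(dets, gts, 2)
        assert rep.map == 1.0 and rep.ap50 == 1.0 and rep.ap75 == 1.0

    def test_map_is_class_mean(self):
        # class 0 perfectly detected, class 1 missed -> mAP = 0.5
        gts = [([(0, 0, 20, 10), (40, 40, 60, 90)], [0, 1])]
        dets = [[Detection((0, 0, 20, 10), 0.9, 0)]]
        rep = map_suite(dets, gts, 2)
        assert rep.map == pytest.approx(0.5)

    def test_ap50_at_least_ap75_and_map(self, rng):
        for _ in range(5):
            dets, gts = _random_fixture(rng)
            rep = map_suite(dets, gts, 2)
            assert rep.ap50 >= rep.ap75 - 1e-12
            assert rep.ap50 >= rep.map - 1e-12

    def test_matches_reference_evaluator(self, rng):
        for _ in range(25):
            dets, gts = _random_fixture(rng)
            rep = map_suite(dets, gts, 2)
            ref = reference_map_suite(dets, gts, 2)
            for fld in ("map", "ap50", "ap75"):
                assert getattr(rep, fld) == pytest.approx(getattr(ref, fld),
                                                          abs=1e-9)
            for fld in ("ap_small", "ap_medium", "ap_large"):
                a, b = getattr(rep, fld), getattr(ref, fld)
                assert (a is None) == (b is None)
                if a is not None:
                    assert a == pytest.approx(b, abs=1e-9)


class TestEcs:
    def test_uniform_map_gives_one(self):
        # the uniform-gate control emits constant 0.5 maps: exactly 1.0
        att = np.full((16, 16), 0.5)
        scores, mean = ecs(att, [(8, 8, 100, 40), (16, 40, 120, 64)], stride=8)
        assert scores == [1.0, 1.0] and mean == 1.0
        # arbitrary constant intensity: equal up to float rounding
        scores, mean = ecs(np.full((16, 16), 0.4), [(8, 8, 100, 40)], stride=8)
        assert mean == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        att = rng.uniform(0.1, 1.0, (16, 16))
        boxes = [(8, 8, 100, 40)]
        _, m1 = ecs(att, boxes, stride=8)
        _, m2 = ecs(att * 7.3, boxes, stride=8)
        assert m1 == pytest.approx(m2, rel=1e-12)

    def test_strip_enumeration_oracle(self):
        # intensity 2 exactly on the enumerated strip set, 1 elsewhere
        att = np.ones((16, 16))
        box = (16, 24, 104, 88)
        fx1, fy1, fx2, fy2 = project_box(box, 8, extent=(16, 16))
        strip = set()
        for y in range(fy1, fy2):
            for x in range(fx1, fx2):
                if (x - fx1 < 3 or fx2 - 1 - x < 3
                        or y - fy1 < 3 or fy2 - 1 - y < 3):
                    strip.add((y, x))
        for (y, x) in strip:
            att[y, x] = 2.0
        scores, _ = ecs(att, [box], stride=8)
        mu_g = att.mean()
        assert scores[0] == pytest.approx(2.0 / mu_g, rel=1e-12)

    def test_zero_map_rejected(self):
        with pytest.raises(ValueError):
            ecs(np.zeros((8, 8)), [(0, 0, 32, 32)], stride=8)

    def test_out_of_map_box_skipped_with_warning(self):
        att = np.ones((8, 8))
        with pytest.warns(UserWarning):
            scores, mean = ecs(att, [(640, 0, 700, 50)], stride=8)
        assert scores == [None] and np.isnan(mean)


class TestBucketedReport:
    def test_all_g1_leaves_other_buckets_absent(self):
        gts = [([(0, 0, 30, 30)], [0])]
        dets = [[Detection((0, 0, 30, 30), 0.9, 0)]]
        rep = bucketed_report(dets, gts, 1)
        assert set(rep.bucket_map) == {"G1"}

    def test_uniform_gates_give_unit_ecs_per_bucket(self):
        gts = [([(0, 0, 100, 10), (20, 20, 50, 50)], [0, 0])]
        dets = [[]]
        maps = [[np.full((s, s), 0.5) for s in (32, 16, 8, 4)]]
        rep = bucketed_report(dets, gts, 1, gate_maps_per_image=maps,
                              strides=(8, 16, 32, 64))
        assert all(v == pytest.approx(1.0) for v in rep.bucket_ecs.values())
        assert set(rep.bucket_ecs) == {"G1", "G4"}

    def test_bucket_ecs_matches_per_box_oracle(self, rng):
        boxes = [(0, 0, 100, 12), (30, 40, 80, 90)]
        gts = [(boxes, [0, 0])]
        maps = [[rng.uniform(0.2, 0.8, (s, s)) for s in (32, 16, 8, 4)]]
        rep = bucketed_report([[]], gts, 1, gate_maps_per_image=maps,
                              strides=(8, 16, 32, 64))
        from stripedet.trloss import assign_level
        for box in boxes:
            lvl = assign_level(box)
            per_box, _ = ecs(maps[0][lvl], [box], (8, 16, 32, 64)[lvl])
            assert rep.bucket_ecs[ar_bucket(box)] == pytest.approx(per_box[0])
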