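"""Contrastive objective: closed-form values, invariances, optimization."""

import math

import numpy as np
import pytest

from stripedet import _tensor as T
from stripedet.icc import (IccConfig, IccModule, ProjectionHead, roi_fuse,
                           supcon_loss)
from stripedet.nn import Adam
from stripedet.reference import roi_fuse_reference
from stripedet.voc_io import NormalizedBox


def _unit(i, d=16):
    v = np.zeros(d)
    v[i] = 1.0
    return v


class TestSupConLoss:
    def test_orthogonal_pair_closed_form(self):
        # anchors 0,1 each contribute -log(e / (e + 1)); anchor 2 skipped
        loss = supcon_loss([_unit(0), _unit(0), _unit(1)], [0, 0, 1], tau=1.0)
        assert loss.item() == pytest.approx(-math.log(math.e / (math.e + 1)),
                                            abs=1e-9)

    def test_identical_embeddings_closed_form(self):
        loss = supcon_loss([_unit(0)] * 3, [0, 0, 1], tau=1.0)
        assert loss.item() == pytest.approx(math.log(2.0), abs=1e-9)

    def test_all_distinct_labels_gives_zero(self):
        loss = supcon_loss([_unit(0), _unit(1), _unit(2)], [0, 1, 2], tau=0.5)
        assert loss.item() == 0.0

    def test_non_negative_random(self, rng):
        for _ in range(20):
            z = rng.normal(size=(6, 8))
            z /= np.linalg.norm(z, axis=1, keepdims=True)
            labels = rng.integers(0, 3, 6)
            assert supcon_loss(z, labels, tau=0.2).item() >= -1e-12

    def test_rotation_invariance(self, rng):
        z = rng.normal(size=(5, 8))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        labels = [0, 0, 1, 1, 2]
        q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        a = supcon_loss(z, labels, tau=0.3).item()
        b = supcon_loss(z @ q, labels, tau=0.3).item()
        assert a == pytest.approx(b, abs=1e-6)

    def test_permutation_invariance(self, rng):
        z = rng.normal(size=(6, 8))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        labels = np.array([0, 1, 0, 2, 1, 0])
        perm = rng.permutation(6)
        a = supcon_loss(z, labels, tau=0.4).item()
        b = supcon_loss(z[perm], labels[perm], tau=0.4).item()
        assert a == pytest.approx(b, abs=1e-9)

    def test_monotone_in_positive_similarity(self):
        # moving a positive pair closer never increases the loss
        prev = None
        for ang in np.linspace(1.2, 0.1, 8):
            z = np.stack([_unit(0, 4),
                          np.array([math.cos(ang), math.sin(ang), 0, 0]),
                          _unit(2, 4)])
            v = supcon_loss(z, [0, 0, 1], tau=0.5).item()
            if prev is not None:
                assert v <= prev + 1e-12
            prev = v

    def test_input_validation(self):
        with pytest.raises(ValueError):
            supcon_loss([_unit(0), _unit(1)], [0, 1], tau=0.0)
        with pytest.raises(ValueError):
            supcon_loss([_unit(0)], [0], tau=1.0)

    def test_literal_variant_penalizes_self_term(self):
        # with the self term in the denominator, even perfectly aligned
        # pairs keep a positive loss
        z = [_unit(0), _unit(0)]
        assert supcon_loss(z, [0, 0], tau=1.0).item() == pytest.approx(0.0)
        assert supcon_loss(z, [0, 0], tau=1.0, include_self=True).item() > 0.0


class TestRoiFuse:
    def test_equal_levels_collapse_to_single_pool(self, rng):
        f = T.Tensor(rng.normal(size=(1, 6, 8, 8)))
        boxes = [NormalizedBox(0.1, 0.2, 0.6, 0.9, label=0, instance_id=0)]
        fused = roi_fuse(f, f, boxes)
        single = T.roi_align(f, np.array([[0, 0.1, 0.2, 0.6, 0.9]]), 7)
        np.testing.assert_allclose(fused.data,
                                   single.mean(axis=(2, 3)).data, atol=1e-12)

    def test_constant_features_give_constant_vector(self):
        f3 = T.Tensor(np.full((1, 4, 8, 8), 2.5))
        f4 = T.Tensor(np.full((1, 4, 4, 4), 2.5))
        boxes = [NormalizedBox(0.2, 0.2, 0.8, 0.8, label=0, instance_id=0)]
        np.testing.assert_allclose(roi_fuse(f3, f4, boxes).data, 2.5)

    def test_matches_bilinear_oracle(self, rng):
        worst = 0.0
        for _ in range(5):
            f3 = rng.normal(size=(2, 5, 8, 8))
            f4 = rng.normal(size=(2, 5, 4, 4))
            rois = np.array([[0, 0.05, 0.1, 0.7, 0.9],
                             [1, 0.3, 0.25, 0.9, 0.6]])
            fused = roi_fuse(T.Tensor(f3), T.Tensor(f4), rois[:, 1:],
                             batch_idx=rois[:, 0].astype(int))
            worst = max(worst,
                        abs(fused.data - roi_fuse_reference(f3, f4, rois)).max())
        assert worst < 1e-4

    def test_degenerate_box_rejected(self, rng):
        f = T.Tensor(rng.normal(size=(1, 4, 8, 8)))
        with pytest.raises(ValueError):
            roi_fuse(f, f, [(0.5, 0.2, 0.5, 0.8)])


class TestHeadsAndCombination:
    def test_projection_is_unit_norm(self, rng):
        head = ProjectionHead(IccConfig(feature_dim=8, hidden_dim=16,
                                        embed_dim=12), rng=rng)
        z = head(T.Tensor(rng.normal(size=(5, 8))))
        np.testing.assert_allclose(np.linalg.norm(z.data, axis=1), 1.0,
                                   atol=1e-5)

    def test_zero_weight_constant_head(self, rng):
        cfg = IccConfig(feature_dim=8, hidden_dim=16, embed_dim=12)
        head = ProjectionHead(cfg, rng=rng)
        head.fc1.weight.data[...] = 0.0
        head.fc2.weight.data[...] = 0.0
        head.fc2.bias.data[...] = np.arange(1.0, 13.0)
        z1 = head(T.Tensor(rng.normal(size=(1, 8))))
        z2 = head(T.Tensor(rng.normal(size=(1, 8))))
        np.testing.assert_allclose(z1.data, z2.data, atol=1e-12)
        b = np.arange(1.0, 13.0)
        np.testing.assert_allclose(z1.data[0], b / np.linalg.norm(b), atol=1e-9)

    def test_combined_weighting_exact(self, rng):
        # L_ICC = 0.05 * L_inst + 0.3 * L_cls by direct enumeration of the
        # supervised contrastive terms over hand-set embeddings
        icc = IccModule(IccConfig(feature_dim=4, hidden_dim=8, embed_dim=6),
                        rng=rng)
        f3 = T.Tensor(rng.normal(size=(1, 4, 8, 8)))
        f4 = T.Tensor(rng.normal(size=(1, 4, 4, 4)))
        boxes1 = [NormalizedBox(0.1, 0.1, 0.4, 0.9, label=0, instance_id=0),
                  NormalizedBox(0.5, 0.2, 0.9, 0.5, label=1, instance_id=1),
                  NormalizedBox(0.2, 0.6, 0.8, 0.95, label=0, instance_id=2)]
        boxes2 = boxes1
        l_icc, l_inst, l_cls = icc.loss((f3, f4), (f3, f4), boxes1, boxes2)
        assert l_icc.item() == pytest.approx(
            0.05 * l_inst.item() + 0.3 * l_cls.item(), abs=1e-12)

        # independent enumeration of both branches
        zi, zc = icc.embed(f3, f4, boxes1)
        for tensor_z, labels, tau, expected in (
                (zi, [0, 1, 2, 0, 1, 2], icc.cfg.tau_inst, l_inst),
                (zc, [0, 1, 0, 0, 1, 0], icc.cfg.tau_cls, l_cls)):
            z = np.concatenate([tensor_z.data, tensor_z.data])
            n = len(labels)
            terms = []
            for i in range(n):
                pos = [j for j in range(n) if j != i and labels[j] == labels[i]]
                if not pos:
                    continue
                num = sum(math.exp(z[i] @ z[j] / tau) for j in pos)
                den = sum(math.exp(z[i] @ z[k] / tau) for k in range(n) if k != i)
                terms.append(-math.log(num / den))
            assert expected.item() == pytest.approx(np.mean(terms), abs=1e-9)

    def test_empty_boxes_give_zero(self, rng):
        icc = IccModule(IccConfig(feature_dim=4, hidden_dim=8, embed_dim=6),
                        rng=rng)
        f = T.Tensor(rng.normal(size=(1, 4, 8, 8)))
        l_icc, l_inst, l_cls = icc.loss((f, f), (f, f), [], [])
        assert l_icc.item() == l_inst.item() == l_cls.item() == 0.0

    def test_gradient_steps_reduce_loss(self, rng):
        # frozen features, trainable heads: optimization decreases L_ICC
        cfg = IccConfig(feature_dim=4, hidden_dim=8, embed_dim=6)
        icc = IccModule(cfg, rng=rng)
        f3 = T.Tensor(rng.normal(size=(1, 4, 8, 8)))
        f4 = T.Tensor(rng.normal(size=(1, 4, 4, 4)))
        boxes = [NormalizedBox(0.1, 0.1, 0.4, 0.9, label=0, instance_id=0),
                 NormalizedBox(0.5, 0.2, 0.9, 0.5, label=1, instance_id=1),
                 NormalizedBox(0.2, 0.6, 0.8, 0.95, label=0, instance_id=2)]
        opt = Adam(icc.parameters(), lr=1e-2)
        first = last = None
        for _ in range(200):
            l_icc, _, _ = icc.loss((f3, f4), (f3, f4), boxes, boxes)
            opt.zero_grad()
            l_icc.backward()
            opt.step()
            if first is None:
                first = l_icc.item()
            last = l_icc.item()
        assert last < first
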