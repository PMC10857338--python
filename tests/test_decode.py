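"""Decode pipeline: DFL expectation, box transform, NMS, full postprocess."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dod.decode import Detection, dfl_expect, distances_to_box, nms, postprocess
from dod.net import ModelConfig, RawPredictionSet


class TestDflExpect:
    def test_one_hot(self):
        logits = np.full(4, -30.0)
        logits[2] = 30.0
        assert dfl_expect(logits) == pytest.approx(2.0, abs=1e-9)

    def test_uniform(self):
        assert dfl_expect(np.zeros(4)) == pytest.approx(1.5)

    def test_symmetric_spikes(self):
        logits = np.full(4, -30.0)
        logits[0] = logits[3] = 5.0
        assert dfl_expect(logits) == pytest.approx(1.5, abs=1e-6)

    @given(st.lists(st.floats(-10, 10), min_size=4, max_size=4))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_range(self, logits):
        assert 0.0 <= dfl_expect(np.array(logits)) <= 3.0


class TestDistancesToBox:
    def test_zero_distances_collapse_to_center(self):
        box = distances_to_box(3, 2, 8, 0, 0, 0, 0)
        assert tuple(box) == (28.0, 20.0, 28.0, 20.0)

    def test_clipping(self):
        box = distances_to_box(0, 0, 8, 1, 1, 1, 1, image_size=(320, 320))
        assert tuple(box) == (0.0, 0.0, 12.0, 12.0)

    @given(
        l=st.floats(0, 3), r=st.floats(0, 3), t=st.floats(0, 3), b=st.floats(0, 3),
        col=st.integers(0, 30), row=st.integers(0, 30),
        stride=st.sampled_from([8, 16, 32]),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_width_height_identity(self, l, r, t, b, col, row, stride):
        box = distances_to_box(col, row, stride, l, r, t, b)
        assert box[2] - box[0] == pytest.approx((l + r) * stride, abs=1e-9)
        assert box[3] - box[1] == pytest.approx((t + b) * stride, abs=1e-9)


def brute_nms(dets, thr):
    """O(n^2) reference NMS."""
    from dod.assign_loss import iou

    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    keep, dead = [], set()
    for i in order:
        if i in dead:
            continue
        keep.append(i)
        for j in order:
            if j not in dead and j != i and dets[j].class_id == dets[i].class_id \
                    and iou(dets[i].box, dets[j].box) > thr:
                dead.add(j)
    return sorted(keep)


class TestNMS:
    def _random_dets(self, rng, n, nc=3):
        out = []
        for _ in range(n):
            x1, y1 = rng.uniform(0, 80, 2)
            w, h = rng.uniform(5, 40, 2)
            out.append(Detection((x1, y1, x1 + w, y1 + h), int(rng.integers(nc)),
                                 float(rng.uniform(0.05, 1)), 0.0))
        return out

    def test_single_unchanged(self):
        d = Detection((0, 0, 10, 10), 0, 0.8, 1.0)
        assert nms([d], 0.5) == [d]

    def test_identical_boxes_keep_highest(self):
        a = Detection((0, 0, 10, 10), 0, 0.9, 0.0)
        b = Detection((0, 0, 10, 10), 0, 0.8, 0.0)
        assert nms([b, a], 0.6) == [a]

    def test_different_classes_never_suppress(self):
        a = Detection((0, 0, 10, 10), 0, 0.9, 0.0)
        b = Detection((0, 0, 10, 10), 1, 0.8, 0.0)
        assert len(nms([a, b], 0.3)) == 2

    def test_matches_brute_force_on_random_boxes(self, rng):
        for _ in range(10):
            dets = self._random_dets(rng, 50)
            got = nms(dets, 0.5)
            ref = [dets[i] for i in brute_nms(dets, 0.5)]
            assert got == ref

    def test_output_subset_and_pairwise_bound(self, rng):
        dets = self._random_dets(rng, 40, nc=1)
        from dod.assign_loss import iou

        out = nms(dets, 0.45)
        assert all(d in dets for d in out)
        for i, a in enumerate(out):
            for b in out[i + 1:]:
                assert iou(a.box, b.box) <= 0.45 + 1e-12


def _raw_from_grids(cfg, box, cls, dep):
    return RawPredictionSet(box, cls, dep, tuple(cfg.strides), cfg.reg_max)


def _empty_grids(cfg, fill=-30.0):
    box, cls, dep = [], [], []
    for s in cfg.strides:
        g = cfg.input_size // s
        box.append(np.zeros((g, g, 4 * cfg.reg_max)))
        cls.append(np.full((g, g, cfg.num_classes), fill))
        dep.append(np.zeros((g, g)))
    return box, cls, dep


class TestPostprocess:
    cfg = ModelConfig(num_classes=3, input_size=64)

    def test_all_background_is_empty(self):
        raw = _raw_from_grids(self.cfg, *_empty_grids(self.cfg))
        assert postprocess(raw, 0.25, 0.6) == []

    def test_single_crafted_cell(self):
        box, cls, dep = _empty_grids(self.cfg)
        # level 0 (stride 8), cell row=2 col=3, one-hot distances l=r=t=b=1
        for side in range(4):
            box[0][2, 3, side * 4 + 1] = 30.0
        cls[0][2, 3, 1] = 2.0
        dep[0][2, 3] = 4.5
        raw = _raw_from_grids(self.cfg, box, cls, dep)
        dets = postprocess(raw, 0.25, 0.6, image_size=(64, 64))
        assert len(dets) == 1
        d = dets[0]
        assert d.class_id == 1
        assert d.confidence == pytest.approx(1 / (1 + np.exp(-2.0)), abs=1e-6)
        assert d.depth == pytest.approx(4.5)
        # center (3.5, 2.5)*8 = (28, 20); distances 1*8=8 px each side
        assert np.allclose(d.box, (20, 12, 36, 28), atol=1e-6)

    def test_fused_equals_step_by_step(self, rng):
        box, cls, dep = _empty_grids(self.cfg)
        for lvl in range(3):
            box[lvl] = rng.normal(size=box[lvl].shape)
            cls[lvl] = rng.normal(loc=-2, scale=2, size=cls[lvl].shape)
            dep[lvl] = rng.normal(size=dep[lvl].shape)
        raw = _raw_from_grids(self.cfg, box, cls, dep)
        got = postprocess(raw, 0.3, 0.5, image_size=(64, 64))
        # independent per-step pipeline
        from dod.decode import dfl_expect as dfe, distances_to_box as d2b

        cand = []
        for lvl, s in enumerate(self.cfg.strides):
            g = 64 // s
            for r in range(g):
                for c in range(g):
                    scores = 1 / (1 + np.exp(-cls[lvl][r, c]))
                    k = int(scores.argmax())
                    if scores[k] < 0.3:
                        continue
                    d = [dfe(box[lvl][r, c, i * 4:(i + 1) * 4]) for i in range(4)]
                    bx = d2b(c, r, s, d[0], d[1], d[2], d[3], image_size=(64, 64))
                    cand.append(Detection(tuple(bx), k, float(scores[k]),
                                          float(dep[lvl][r, c])))
        ref = nms(cand, 0.5)
        ref.sort(key=lambda d: -d.confidence)
        assert len(got) == len(ref)
        for a, b in zip(got, ref):
            assert a.class_id == b.class_id
            assert a.confidence == pytest.approx(b.confidence, rel=1e-9)
            assert np.allclose(a.box, b.box, atol=1e-9)

    def test_confidence_threshold_monotone(self, rng):
        box, cls, dep = _empty_grids(self.cfg)
        for lvl in range(3):
            cls[lvl] = rng.normal(size=cls[lvl].shape)
        raw = _raw_from_grids(self.cfg, box, cls, dep)
        counts = [len(postprocess(raw, c, 0.6)) for c in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_round_trip_encode_decode_all_strides(self):
        """A gt box encoded to exact cell distances decodes back exactly."""
        cfg = ModelConfig(num_classes=1, input_size=64)
        for lvl, s in enumerate(cfg.strides):
            g = 64 // s
            row, col = g // 2, g // 2
            cx, cy = (col + 0.5) * s, (row + 0.5) * s
            l, r, t, b = 0.75, 0.4375, 0.25, 0.4375  # box stays inside the image
            gt = (cx - l * s, cy - t * s, cx + r * s, cy + b * s)
            # encode: put the exact expectation into two bracketing bins
            box_g, cls_g, dep_g = _empty_grids(cfg)
            for side, d in enumerate((l, r, t, b)):
                lo = int(np.floor(d))
                w_hi = d - lo
                probs = np.full(cfg.reg_max, 1e-12)
                probs[lo] = 1 - w_hi
                probs[min(lo + 1, cfg.reg_max - 1)] += w_hi
                box_g[lvl][row, col, side * 4:(side + 1) * 4] = np.log(probs)
            cls_g[lvl][row, col, 0] = 8.0
            raw = _raw_from_grids(cfg, box_g, cls_g, dep_g)
            dets = postprocess(raw, 0.5, 0.6, image_size=(64, 64))
            assert len(dets) == 1
            assert np.allclose(dets[0].box, gt, atol=1e-6), (s, dets[0].box, gt)
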