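"""NMS variants vs brute-force references; decoding contract."""

import numpy as np
import pytest

from _oracles import brute_force_crop_first, brute_force_nms, random_detections
from weednet.boxes import generate_anchors
from weednet.postprocess import (
    Detection,
    NMSConfig,
    crop_first_nms,
    decode_detections,
    standard_nms,
)


class TestStandardNMS:
    def test_single_detection_survives(self):
        d = Detection(box=np.array([0.0, 0.0, 5.0, 5.0]), label="weed", score=0.7)
        assert standard_nms([d], 0.5) == [d]

    def test_coincident_boxes_keep_highest_score(self):
        box = np.array([0.0, 0.0, 10.0, 10.0])
        hi = Detection(box=box, label="weed", score=0.9)
        lo = Detection(box=box, label="weed", score=0.8)
        assert standard_nms([lo, hi], 0.5) == [hi]

    def test_disjoint_boxes_all_kept(self):
        dets = [
            Detection(box=np.array([20.0 * i, 0.0, 20.0 * i + 10, 10.0]), label="weed", score=s)
            for i, s in enumerate((0.3, 0.9, 0.5))
        ]
        out = standard_nms(dets, 0.5)
        assert {id(d) for d in out} == {id(d) for d in dets}
        assert [d.score for d in out] == sorted((d.score for d in dets), reverse=True)

    def test_mixed_labels_rejected(self):
        a = Detection(box=np.array([0.0, 0.0, 5.0, 5.0]), label="weed", score=0.5)
        b = Detection(box=np.array([0.0, 0.0, 5.0, 5.0]), label="sugarbeet", score=0.5)
        with pytest.raises(ValueError, match="mixed labels"):
            standard_nms([a, b], 0.5)

    def test_matches_brute_force_on_random_sets(self, rng):
        for trial in range(200):
            dets = random_detections(rng, int(rng.integers(0, 25)))
            thresh = float(rng.uniform(0.1, 0.9))
            got = standard_nms(dets, thresh)
            expected = brute_force_nms(dets, thresh)
            assert [id(d) for d in got] == [id(d) for d in expected]

    def test_order_invariance(self, rng):
        dets = random_detections(rng, 15)
        ref = standard_nms(dets, 0.5)
        for _ in range(5):
            perm = [dets[i] for i in rng.permutation(len(dets))]
            assert [id(d) for d in standard_nms(perm, 0.5)] == [id(d) for d in ref]


class TestCropFirstNMS:
    def crop(self, box, score=0.9):
        return Detection(box=np.asarray(box, float), label="sugarbeet", score=score)

    def weed(self, box, score=0.8):
        return Detection(box=np.asarray(box, float), label="weed", score=score)

    def test_overlapping_weed_removed_crop_kept(self):
        c = self.crop([0, 0, 10, 10])
        w = self.weed([0, 0, 10, 6])  # IoU 0.6
        assert crop_first_nms([c, w], 0.5) == [c]

    def test_low_overlap_weed_kept(self):
        c = self.crop([0, 0, 10, 10])
        w = self.weed([8, 8, 18, 18])
        assert crop_first_nms([c, w], 0.5) == [c, w]

    def test_no_crops_returns_weeds_unchanged(self):
        weeds = [self.weed([0, 0, 5, 5]), self.weed([1, 1, 6, 6])]
        assert crop_first_nms(weeds, 0.5) == weeds

    def test_matches_brute_force_on_random_mixed_sets(self, rng):
        for _ in range(200):
            dets = random_detections(rng, int(rng.integers(0, 25)), labels=("weed", "sugarbeet"))
            thresh = float(rng.uniform(0.1, 0.9))
            got = crop_first_nms(dets, thresh)
            assert [id(d) for d in got] == [id(d) for d in brute_force_crop_first(dets, thresh)]

    def test_invariants_on_random_sets(self, rng):
        for _ in range(100):
            dets = random_detections(rng, int(rng.integers(1, 25)), labels=("weed", "sugarbeet"))
            thresh = float(rng.uniform(0.0, 1.0))
            out = crop_first_nms(dets, thresh)
            # never grows; crop subset identical; weed count non-increasing
            assert len(out) <= len(dets)
            assert [id(d) for d in out if d.label == "sugarbeet"] == [
                id(d) for d in dets if d.label == "sugarbeet"
            ]
            assert sum(d.label == "weed" for d in out) <= sum(d.label == "weed" for d in dets)
            # idempotence
            assert [id(d) for d in crop_first_nms(out, thresh)] == [id(d) for d in out]

    def test_exclusive_threshold_is_identity_without_coincident_boxes(self, rng):
        dets = random_detections(rng, 20, labels=("weed", "sugarbeet"))
        assert crop_first_nms(dets, 1.0) == dets


class TestDecodeDetections:
    @pytest.fixture()
    def anchors(self):
        return generate_anchors((64, 64))

    def _raw(self, anchors, fill=-40.0):
        return [
            (np.full((len(a), 2), fill), np.zeros((len(a), 4))) for _, a in sorted(anchors.items())
        ]

    def test_all_logits_low_gives_empty(self, anchors):
        assert decode_detections(self._raw(anchors), anchors, NMSConfig()) == []

    def test_single_hot_anchor_decodes_to_its_box(self, anchors):
        raw = self._raw(anchors)
        raw[0][0][123, 1] = 40.0  # weed logit ~ p=1
        dets = decode_detections(raw, anchors, NMSConfig())
        assert len(dets) == 1
        assert dets[0].label == "weed"
        assert dets[0].score == pytest.approx(1.0)
        assert np.allclose(dets[0].box, anchors[3][123], atol=1e-5)

    def test_duplicates_collapse_to_one(self, anchors):
        from weednet.boxes import encode

        raw = self._raw(anchors)
        target = np.array([10.0, 10.0, 42.0, 42.0])
        # five anchors all regressed onto one object
        for idx in (40, 41, 50, 150, 160):
            raw[0][0][idx, 0] = 3.0
            raw[0][1][idx] = encode(target, anchors[3][idx])
        dets = decode_detections(raw, anchors, NMSConfig())
        assert len(dets) == 1
        assert np.allclose(dets[0].box, target, atol=1e-4)

    def test_length_mismatch_rejected(self, anchors):
        raw = self._raw(anchors)
        raw[0] = (raw[0][0][:-5], raw[0][1][:-5])
        with pytest.raises(ValueError, match="anchors"):
            decode_detections(raw, anchors, NMSConfig())

    def test_crop_first_flag_respected(self, anchors):
        from weednet.boxes import encode

        raw = self._raw(anchors)
        target = np.array([12.0, 12.0, 44.0, 44.0])
        raw[0][0][40, 0] = 5.0  # crop
        raw[0][1][40] = encode(target, anchors[3][40])
        raw[0][0][150, 1] = 4.0  # weed on the same spot
        raw[0][1][150] = encode(target, anchors[3][150])
        on = decode_detections(raw, anchors, NMSConfig(crop_first_enabled=True))
        off = decode_detections(raw, anchors, NMSConfig(crop_first_enabled=False))
        assert sorted(d.label for d in off) == ["sugarbeet", "weed"]
        assert [d.label for d in on] == ["sugarbeet"]
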