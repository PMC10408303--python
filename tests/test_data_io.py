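"""Annotation I/O, dataset split, preprocessing transforms."""

import numpy as np
import pytest

from weednet.data_io import (
    Annotation,
    AnnotationError,
    Sample,
    normalize_label,
    preprocess,
    random_flip,
    read_detection_records,
    read_voc_xml,
    split_dataset,
    write_detection_records,
    write_voc_xml,
)


def make_sample(n=2, image_size=(100, 80)):
    anns = [
        Annotation("sugarbeet", np.array([10.0, 20.0, 40.0, 60.0])),
        Annotation("weed", np.array([50.0, 5.0, 70.0, 25.0])),
    ][:n]
    return Sample(image=np.zeros((image_size[1], image_size[0], 3), np.uint8),
                  annotations=anns, image_id="s0", image_size=image_size)


class TestVocXml:
    def test_round_trip_preserves_labels_and_boxes(self, tmp_path):
        sample = make_sample()
        path = tmp_path / "s0.xml"
        write_voc_xml(sample, path)
        back = read_voc_xml(path)
        assert [a.label for a in back.annotations] == ["sugarbeet", "weed"]
        for a, b in zip(sample.annotations, back.annotations):
            assert np.allclose(a.box, b.box, atol=0.5)
        assert back.image_size == (100, 80)

    def test_object_count(self, tmp_path):
        path = tmp_path / "two.xml"
        write_voc_xml(make_sample(2), path)
        assert len(read_voc_xml(path).annotations) == 2
        write_voc_xml(make_sample(0), path)
        assert read_voc_xml(path).annotations == []

    def test_class_aliases_normalised(self):
        assert normalize_label("Sugar Beet") == "sugarbeet"
        assert normalize_label("crop") == "sugarbeet"
        assert normalize_label("WEED") == "weed"

    def test_unknown_class_rejected(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text(
            "<annotation><object><name>tree</name><bndbox>"
            "<xmin>1</xmin><ymin>1</ymin><xmax>5</xmax><ymax>5</ymax>"
            "</bndbox></object></annotation>"
        )
        with pytest.raises(AnnotationError, match="unknown class"):
            read_voc_xml(path)
        # explicit allow-list override accepts it
        assert read_voc_xml(path, allowed_classes=("tree",)).annotations[0].label == "tree"

    @pytest.mark.parametrize(
        "body, message",
        [
            ("<annotation><object><name>weed</name></object></annotation>", "bndbox"),
            (
                "<annotation><object><name>weed</name><bndbox>"
                "<xmin>1</xmin><ymin>1</ymin><xmax>5</xmax></bndbox></object></annotation>",
                "ymax",
            ),
            (
                "<annotation><object><name>weed</name><bndbox>"
                "<xmin>9</xmin><ymin>1</ymin><xmax>5</xmax><ymax>5</ymax>"
                "</bndbox></object></annotation>",
                "inverted",
            ),
            ("<annotation><object>", "malformed"),
        ],
    )
    def test_descriptive_parse_errors(self, tmp_path, body, message):
        path = tmp_path / "broken.xml"
        path.write_text(body)
        with pytest.raises(AnnotationError, match=message):
            read_voc_xml(path)


class TestSplit:
    def test_floor_arithmetic_100(self):
        samples = [make_sample() for _ in range(100)]
        split = split_dataset(samples, seed=5)
        assert (len(split.test), len(split.valid), len(split.train)) == (20, 8, 72)

    def test_deterministic_and_exact_partition(self):
        samples = [make_sample() for _ in range(37)]
        a = split_dataset(samples, seed=9)
        b = split_dataset(samples, seed=9)
        assert [id(s) for s in a.train] == [id(s) for s in b.train]
        ids = [id(s) for s in a.train + a.valid + a.test]
        assert sorted(ids) == sorted(id(s) for s in samples)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            split_dataset([make_sample(), make_sample()], seed=0)


class TestPreprocess:
    def test_resize_scales_boxes_by_axis_ratios(self):
        image = np.zeros((936, 1296, 3), np.uint8)
        anns = [Annotation("weed", np.array([129.6, 93.6, 648.0, 468.0]))]
        out, scaled = preprocess(image, anns, target_size=640)
        assert out.shape == (3, 640, 640)
        assert np.allclose(scaled[0].box, [64.0, 64.0, 320.0, 320.0])

    def test_identity_resize_keeps_boxes(self):
        image = np.zeros((640, 640, 3), np.uint8)
        anns = [Annotation("weed", np.array([10.0, 20.0, 30.0, 40.0]))]
        _, scaled = preprocess(image, anns, target_size=640)
        assert np.allclose(scaled[0].box, anns[0].box)

    def test_round_trip_restores_boxes(self):
        image = np.zeros((93, 129, 3), np.uint8)
        anns = [Annotation("weed", np.array([12.0, 9.0, 64.0, 46.0]))]
        _, fwd = preprocess(image, anns, target_size=640)
        small = np.zeros((640, 640, 3), np.uint8)
        # inverse per-axis scaling
        sx, sy = 129 / 640, 93 / 640
        back = fwd[0].box * np.array([sx, sy, sx, sy])
        assert np.allclose(back, anns[0].box, atol=1e-9)

    def test_letterbox_preserves_aspect_and_pads(self):
        image = np.zeros((50, 100, 3), np.uint8)
        image[:, :, 0] = 200  # red so padding (mean pixel) is detectable
        anns = [Annotation("weed", np.array([10.0, 10.0, 50.0, 40.0]))]
        out, scaled = preprocess(image, anns, target_size=200, normalize=False, letterbox=True)
        # uniform scale 2: boxes scale equally on both axes
        assert np.allclose(scaled[0].box, [20.0, 20.0, 100.0, 80.0])
        assert out.shape == (200, 200, 3)
        assert (out[:100, :, 0] == 200).all()  # content in the top band

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            preprocess(np.zeros((0, 5, 3), np.uint8), [])


class TestFlip:
    def test_probability_zero_is_identity(self, rng):
        image = rng.integers(0, 255, size=(20, 30, 3)).astype(np.uint8)
        anns = [Annotation("weed", np.array([2.0, 3.0, 8.0, 9.0]))]
        out, oanns = random_flip(image, anns, rng, p=0.0)
        assert out is image and oanns is anns

    def test_reflection_coordinates(self, rng):
        image = np.zeros((50, 100, 3), np.uint8)
        anns = [Annotation("weed", np.array([10.0, 0.0, 20.0, 10.0]))]
        out, oanns = random_flip(image, anns, rng, p=1.0)
        assert np.allclose(oanns[0].box, [80.0, 0.0, 90.0, 10.0])
        assert oanns[0].label == "weed"

    def test_double_flip_is_identity(self, rng):
        image = rng.integers(0, 255, size=(16, 24, 3)).astype(np.uint8)
        anns = [Annotation("sugarbeet", np.array([3.0, 4.0, 11.0, 12.0]))]
        once_img, once = random_flip(image, anns, rng, p=1.0)
        twice_img, twice = random_flip(once_img, once, rng, p=1.0)
        assert np.array_equal(twice_img, image)
        assert np.allclose(twice[0].box, anns[0].box)


class TestDetectionRecords:
    def test_round_trip(self, tmp_path):
        records = [
            {"image_id": "a", "label": "weed", "score": 0.75,
             "x_min": 1.0, "y_min": 2.0, "x_max": 3.5, "y_max": 4.25},
        ]
        path = tmp_path / "dets.tsv"
        write_detection_records(records, path)
        back = read_detection_records(path)
        assert back == records
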