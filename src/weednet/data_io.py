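"""Dataset I/O: Pascal-VOC XML annotations, split, and image preprocessing.

Annotations use the labelme-compatible VOC dialect (``object`` elements
with ``name`` and ``bndbox/xmin..ymax``).  XML coordinates are 1-based
integers by VOC convention and are converted to 0-based continuous pixel
coordinates internally.  Class names are normalised through an alias map
("sugar beet", "crop" -> "sugarbeet"); unknown names are rejected unless
an explicit allow-list is supplied.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .boxes import validate_boxes

#: Normalisation applied before the backbone (ImageNet statistics).
PIXEL_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
PIXEL_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

CLASS_ALIASES = {
    "sugarbeet": "sugarbeet",
    "sugar beet": "sugarbeet",
    "sugar_beet": "sugarbeet",
    "crop": "sugarbeet",
    "weed": "weed",
}


class AnnotationError(ValueError):
    """Raised for malformed or out-of-vocabulary annotation files."""


@dataclass(frozen=True)
class Annotation:
    label: str
    box: np.ndarray  # (4,) x_min, y_min, x_max, y_max; 0-based continuous

    def __post_init__(self):
        validate_boxes(self.box)


@dataclass
class Sample:
    """One image with its object annotations.

    ``image`` may be a file path (loaded lazily) or an in-memory HxWx3
    uint8 array; ``image_size`` is (width, height).
    """

    image: Path | np.ndarray
    annotations: list[Annotation]
    image_id: str = ""
    image_size: tuple[int, int] | None = None

    def load_pixels(self) -> np.ndarray:
        if isinstance(self.image, np.ndarray):
            return self.image
        with Image.open(self.image) as im:
            return np.asarray(im.convert("RGB"))


@dataclass(frozen=True)
class DatasetSplit:
    train: list[Sample]
    valid: list[Sample]
    test: list[Sample]
    seed: int


def normalize_label(name: str, allowed: tuple[str, ...] | None = None) -> str:
    key = name.strip().lower()
    if allowed is not None:
        if key in allowed:
            return key
        raise AnnotationError(f"unknown class name {name!r}; allowed: {sorted(allowed)}")
    if key not in CLASS_ALIASES:
        raise AnnotationError(
            f"unknown class name {name!r}; known aliases: {sorted(CLASS_ALIASES)}"
        )
    return CLASS_ALIASES[key]


def read_voc_xml(path, allowed_classes: tuple[str, ...] | None = None) -> Sample:
    """Parse one VOC-dialect annotation file into a :class:`Sample`.

    The returned sample's ``image`` is the path recorded in the file
    (resolved relative to the XML's directory) if present.
    """
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise AnnotationError(f"{path}: malformed XML ({exc})") from exc
    annotations = []
    for i, obj in enumerate(root.iter("object")):
        name_el = obj.find("name")
        if name_el is None or not (name_el.text or "").strip():
            raise AnnotationError(f"{path}: object {i} lacks a <name>")
        label = normalize_label(name_el.text, allowed_classes)
        bnd = obj.find("bndbox")
        if bnd is None:
            raise AnnotationError(f"{path}: object {i} ({label}) lacks a <bndbox>")
        coords = {}
        for key in ("xmin", "ymin", "xmax", "ymax"):
            el = bnd.find(key)
            if el is None or el.text is None:
                raise AnnotationError(f"{path}: object {i} ({label}) missing <{key}>")
            try:
                coords[key] = float(el.text)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: object {i} ({label}) has non-numeric <{key}>: {el.text!r}"
                ) from exc
        if coords["xmax"] < coords["xmin"] or coords["ymax"] < coords["ymin"]:
            raise AnnotationError(f"{path}: object {i} ({label}) has inverted coordinates")
        # 1-based inclusive pixel indices -> 0-based continuous boundaries
        box = np.array(
            [coords["xmin"] - 1.0, coords["ymin"] - 1.0, coords["xmax"], coords["ymax"]]
        )
        annotations.append(Annotation(label=label, box=box))
    size_el = root.find("size")
    image_size = None
    if size_el is not None:
        w, h = size_el.findtext("width"), size_el.findtext("height")
        if w and h:
            image_size = (int(w), int(h))
    filename = root.findtext("filename") or ""
    image = path.parent / filename if filename else path.with_suffix(".png")
    return Sample(
        image=image,
        annotations=annotations,
        image_id=path.stem,
        image_size=image_size,
    )


def write_voc_xml(sample: Sample, path) -> None:
    """Write a sample's annotations as VOC XML (integer, 1-based coords)."""
    path = Path(path)
    root = ET.Element("annotation")
    image_name = (
        Path(sample.image).name if not isinstance(sample.image, np.ndarray) else f"{sample.image_id}.png"
    )
    ET.SubElement(root, "filename").text = image_name
    if sample.image_size is not None:
        size = ET.SubElement(root, "size")
        ET.SubElement(size, "width").text = str(sample.image_size[0])
        ET.SubElement(size, "height").text = str(sample.image_size[1])
        ET.SubElement(size, "depth").text = "3"
    for ann in sample.annotations:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = ann.label
        bnd = ET.SubElement(obj, "bndbox")
        x1, y1, x2, y2 = (float(v) for v in ann.box)
        ET.SubElement(bnd, "xmin").text = str(int(round(x1)) + 1)
        ET.SubElement(bnd, "ymin").text = str(int(round(y1)) + 1)
        ET.SubElement(bnd, "xmax").text = str(int(round(x2)))
        ET.SubElement(bnd, "ymax").text = str(int(round(y2)))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode")


def split_dataset(samples: list[Sample], seed: int) -> DatasetSplit:
    """8:2 train+valid / test split, then 1/10 of the remainder as valid.

    Floor-based with a minimum of one sample per split; deterministic for
    a fixed seed; the three parts partition the input exactly.
    """
    samples = list(samples)
    n = len(samples)
    if n < 3:
        raise ValueError(f"need at least 3 samples to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = max(1, int(0.2 * n))
    remainder = n - n_test
    n_valid = max(1, int(0.1 * remainder))
    test = [samples[i] for i in order[:n_test]]
    valid = [samples[i] for i in order[n_test : n_test + n_valid]]
    train = [samples[i] for i in order[n_test + n_valid :]]
    return DatasetSplit(train=train, valid=valid, test=test, seed=seed)


def preprocess(
    image: np.ndarray,
    annotations: list[Annotation],
    target_size: int = 640,
    normalize: bool = True,
    letterbox: bool = False,
) -> tuple[np.ndarray, list[Annotation]]:
    """Resize to a ``target_size`` square and transform boxes to match.

    The default is a direct (aspect-distorting) resize with per-axis box
    scaling; ``letterbox=True`` preserves aspect with uniform scaling and
    pads the bottom/right with the mean pixel instead.  Returns the image
    as a float32 (3, S, S) tensor-ready array (scaled to [0, 1] and
    standardised unless ``normalize=False``, in which case the resized
    HxWx3 uint8 array is returned) and the transformed annotations.
    """
    h, w = image.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("cannot preprocess an empty image")
    if letterbox:
        scale = target_size / max(w, h)
        nw, nh = max(1, round(w * scale)), max(1, round(h * scale))
        small = np.asarray(Image.fromarray(image).resize((nw, nh), Image.BILINEAR))
        resized = np.full(
            (target_size, target_size, 3), image.mean(axis=(0, 1)), dtype=image.dtype
        )
        resized[:nh, :nw] = small
        sx = sy = scale
    else:
        resized = np.asarray(
            Image.fromarray(image).resize((target_size, target_size), Image.BILINEAR)
        )
        sx, sy = target_size / w, target_size / h
    scaled = [
        replace(ann, box=ann.box * np.array([sx, sy, sx, sy]))
        for ann in annotations
    ]
    if not normalize:
        return resized, scaled
    arr = resized.astype(np.float32) / 255.0
    arr = (arr - PIXEL_MEAN) / PIXEL_STD
    return np.ascontiguousarray(arr.transpose(2, 0, 1)), scaled


def random_flip(
    image: np.ndarray,
    annotations: list[Annotation],
    rng: np.random.Generator,
    p: float = 0.5,
) -> tuple[np.ndarray, list[Annotation]]:
    """Horizontal mirror with probability ``p``; x coordinates reflected."""
    if rng.random() >= p:
        return image, annotations
    w = image.shape[1]
    flipped = image[:, ::-1].copy()
    out = [
        replace(ann, box=np.array([w - ann.box[2], ann.box[1], w - ann.box[0], ann.box[3]]))
        for ann in annotations
    ]
    return flipped, out


def write_detection_records(records: list[dict], path) -> None:
    """Dump detection records as a tab-separated table."""
    cols = ("image_id", "label", "score", "x_min", "y_min", "x_max", "y_max")
    lines = ["\t".join(cols)]
    for r in records:
        lines.append("\t".join(str(r[c]) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")


def read_detection_records(path) -> list[dict]:
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0].split("\t")
    out = []
    for line in lines[1:]:
        vals = line.split("\t")
        rec = dict(zip(header, vals))
        for key in ("score", "x_min", "y_min", "x_max", "y_max"):
            rec[key] = float(rec[key])
        out.append(rec)
    return out
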