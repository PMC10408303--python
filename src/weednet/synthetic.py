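"""Synthetic top-down field scenes with per-object box annotations.

Scenes emulate the geometry of nadir field imagery over a row crop: a
textured brown soil background carrying two green plant classes that are
deliberately similar in colour but distinct in morphology and scale -
"sugarbeet" plants are large multi-lobed rosettes, "weed" plants are small
clusters of thin blades.  Every plant's tight bounding box (outermost
rendered pixel) and label are recorded, so a scene is a fully supervised
detection sample.  Rendering is completely determined by the spec's seed.

The generator is the fixture source for tests and the toy training runs;
it does not attempt photorealism (no perspective, shadows, occlusion or
illumination variation of real field data).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .boxes import iou_matrix
from .data_io import Annotation, Sample, write_voc_xml

_SOIL_BASE = np.array([112.0, 84.0, 58.0])
_CROP_COLOR = np.array([46.0, 108.0, 44.0])
_WEED_COLOR = np.array([74.0, 128.0, 56.0])


@dataclass(frozen=True)
class SceneSpec:
    """Scene recipe; sizes are radii in pixels of the plant footprint.

    ``max_overlap_iou`` bounds the pairwise IoU between the tight boxes of
    rendered plants; ``color_similarity`` in [0, 1] pulls the weed palette
    toward the crop palette (1 = identical colours, shape alone separates
    the classes).
    """

    image_size: int = 160
    n_crops: int = 2
    n_weeds: int = 3
    crop_radius: tuple[float, float] = (22.0, 31.0)
    weed_radius: tuple[float, float] = (15.0, 20.0)
    max_overlap_iou: float = 0.10
    background_noise: float = 7.0
    color_similarity: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32 pixels")
        if self.n_crops < 0 or self.n_weeds < 0:
            raise ValueError("object counts must be non-negative")
        if not 0.0 <= self.max_overlap_iou <= 1.0:
            raise ValueError("max_overlap_iou must lie in [0, 1]")


def _soil(size: int, noise: float, rng: np.random.Generator) -> np.ndarray:
    img = np.empty((size, size, 3))
    coarse = gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma=6.0)
    coarse = coarse / (np.abs(coarse).max() + 1e-9)
    grain = rng.normal(0.0, 1.0, (size, size))
    for c in range(3):
        img[:, :, c] = _SOIL_BASE[c] + 18.0 * coarse + noise * 0.35 * grain
    return img


def _rosette_mask(window, cx, cy, r, rng) -> np.ndarray:
    """Large multi-lobed rosette footprint (the crop class)."""
    yy, xx = window
    mask = np.zeros(yy.shape, dtype=bool)
    n_lobes = int(rng.integers(5, 9))
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    for k in range(n_lobes):
        theta = theta0 + 2.0 * np.pi * k / n_lobes + rng.normal(0.0, 0.06)
        a = r * 0.55 * rng.uniform(0.85, 1.05)
        b = r * 0.22 * rng.uniform(0.85, 1.15)
        lcx = cx + (r - a) * np.cos(theta)
        lcy = cy + (r - a) * np.sin(theta)
        dx, dy = xx - lcx, yy - lcy
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= (0.30 * r) ** 2
    return mask


def _blades_mask(window, cx, cy, r, rng) -> np.ndarray:
    """Small cluster of thin grass blades (the weed class)."""
    yy, xx = window
    mask = np.zeros(yy.shape, dtype=bool)
    n_blades = int(rng.integers(3, 6))
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    for k in range(n_blades):
        # each blade crosses the plant centre, like a grass tuft
        theta = theta0 + np.pi * k / n_blades + rng.normal(0.0, 0.18)
        a = r * rng.uniform(0.85, 1.0)
        b = max(1.1, r * 0.11)
        dx, dy = xx - cx, yy - cy
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= 2.25
    return mask


_SHAPES = {"sugarbeet": (_rosette_mask, 0.30), "weed": (_blades_mask, 0.18)}


def generate_scene(spec: SceneSpec) -> Sample:
    """Render one scene; fully determined by ``spec.seed``.

    Raises if the overlap policy cannot be satisfied within the retry
    budget (the spec asks for more plants than fit).
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    img = _soil(size, spec.background_noise, rng)
    weed_color = _WEED_COLOR + spec.color_similarity * (_CROP_COLOR - _WEED_COLOR)

    plan = [("sugarbeet", spec.crop_radius, _CROP_COLOR)] * spec.n_crops
    plan += [("weed", spec.weed_radius, weed_color)] * spec.n_weeds
    annotations: list[Annotation] = []
    placed: list[np.ndarray] = []
    budget = 60
    for label, (r_lo, r_hi), color in plan:
        mask_fn, shade_depth = _SHAPES[label]
        for _ in range(budget):
            r = rng.uniform(r_lo, r_hi)
            cx = rng.uniform(r + 1.0, size - r - 1.0)
            cy = rng.uniform(r + 1.0, size - r - 1.0)
            x0, x1 = max(0, int(cx - r - 2)), min(size, int(cx + r + 3))
            y0, y1 = max(0, int(cy - r - 2)), min(size, int(cy + r + 3))
            window = np.mgrid[y0:y1, x0:x1]
            mask = mask_fn(window, cx, cy, r, rng)
            ys, xs = np.nonzero(mask)
            box = np.array(
                [x0 + xs.min(), y0 + ys.min(), x0 + xs.max() + 1.0, y0 + ys.max() + 1.0]
            )
            if placed and iou_matrix(box[None], np.stack(placed)).max() > spec.max_overlap_iou:
                continue
            yy, xx = window
            dist = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
            shade = 1.0 - shade_depth * np.clip(dist / max(r, 1.0), 0.0, 1.0)
            texture = rng.normal(0.0, 6.0, mask.shape)
            patch = img[y0:y1, x0:x1]
            for c in range(3):
                layer = patch[:, :, c]
                layer[mask] = color[c] * shade[mask] + texture[mask]
            placed.append(box)
            annotations.append(Annotation(label=label, box=box))
            break
        else:
            raise ValueError(
                f"could not place {label!r} within the overlap policy "
                f"(iou <= {spec.max_overlap_iou}) after {budget} attempts"
            )
    pixels = np.clip(img, 0.0, 255.0).astype(np.uint8)
    return Sample(
        image=pixels,
        annotations=annotations,
        image_id=f"scene_{spec.seed:08d}",
        image_size=(size, size),
    )


def scene_seed(master_seed: int, index: int) -> int:
    """Deterministic per-scene seed derived from a master seed."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def generate_scenes(n_scenes: int, template: SceneSpec, seed: int) -> list[Sample]:
    """In-memory dataset of ``n_scenes`` scenes from one master seed."""
    return [
        generate_scene(replace(template, seed=scene_seed(seed, i))) for i in range(n_scenes)
    ]


def generate_dataset(
    n_scenes: int, template: SceneSpec, out_dir, seed: int
) -> list[tuple[Path, Path]]:
    """Write ``n_scenes`` PNG/XML pairs under ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = []
    for i in range(n_scenes):
        sample = generate_scene(replace(template, seed=scene_seed(seed, i)))
        png = out_dir / f"{sample.image_id}.png"
        xml = out_dir / f"{sample.image_id}.xml"
        Image.fromarray(sample.load_pixels()).save(png)
        write_voc_xml(sample, xml)
        pairs.append((png, xml))
    return pairs
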