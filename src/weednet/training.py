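"""Training loop, checkpoints, and model-level prediction/evaluation.

The trainer composes the pieces the library defines elsewhere: anchors and
delta encoding (``boxes``), focal + smooth-L1 objective with max-IoU
matching (``losses``), the warmup x cosine learning-rate curve
(``schedule``), detection decoding (``postprocess``) and VOC-style scoring
(``evaluation``).  Optimisation uses Adam; every source of randomness
(augmentation, shuffling, weight init) derives from the run config's seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .boxes import AnchorConfig, concat_anchors, generate_anchors
from .data_io import Annotation, Sample, preprocess, random_flip
from .evaluation import DEFAULT_IOU_THRESHOLD, EvalReport, GroundTruth, evaluate_detections
from .losses import FocalParams, detection_loss
from .model import CLASS_NAMES, Detector, ModelConfig, build_model
from .postprocess import Detection, NMSConfig, decode_detections
from .schedule import ScheduleConfig, lr_at


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a training run."""

    model: ModelConfig = field(default_factory=ModelConfig)
    nms: NMSConfig = field(default_factory=NMSConfig)
    focal: FocalParams = field(default_factory=FocalParams)
    image_size: int = 640
    batch_size: int = 8
    epochs: int = 20
    lr_init: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    flip_prob: float = 0.5
    eval_iou: float = DEFAULT_IOU_THRESHOLD
    seed: int = 0


def toy_run_config(epochs: int = 5, seed: int = 0) -> RunConfig:
    """CPU-scale benchmark configuration: tiny backbone, 160 px scenes.

    lr_init is raised to 2e-3 (a small net trained from random init) and
    beta2 lowered to 0.99 so the untuned warmup period 2/(1-beta2) = 200
    steps is commensurate with a run of a few hundred steps.
    """
    return RunConfig(
        model=ModelConfig(backbone="tiny", fpn_channels=64, head_convs=2),
        image_size=160,
        batch_size=8,
        epochs=epochs,
        lr_init=2e-3,
        beta2=0.99,
        seed=seed,
    )


@dataclass
class TrainResult:
    history: dict
    best_epoch: int
    best_map: float
    best_state: dict


def _label_indices(annotations: list[Annotation]) -> np.ndarray:
    return np.array([CLASS_NAMES.index(a.label) for a in annotations], dtype=np.int64)


def _prepare(sample: Sample, config: RunConfig, rng: np.random.Generator | None):
    pixels = sample.load_pixels()
    annotations = sample.annotations
    if rng is not None:
        pixels, annotations = random_flip(pixels, annotations, rng, config.flip_prob)
    image, annotations = preprocess(pixels, annotations, target_size=config.image_size)
    boxes = (
        np.stack([a.box for a in annotations]) if annotations else np.empty((0, 4))
    )
    return image, boxes, _label_indices(annotations)


def train(
    model: Detector,
    train_samples: list[Sample],
    valid_samples: list[Sample],
    config: RunConfig,
    verbose: bool = False,
) -> TrainResult:
    """Train ``model`` in place; returns per-epoch history and best weights.

    The best checkpoint is the epoch with maximal validation mAP.
    """
    if not train_samples:
        raise ValueError("training requires at least one sample")
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    anchors_by_level = generate_anchors((size, size), config.model.anchors)
    anchors_flat = concat_anchors(anchors_by_level)
    level_sizes = [len(anchors_by_level[lv]) for lv in sorted(anchors_by_level)]
    level_offsets = np.cumsum([0] + level_sizes)

    steps_per_epoch = math.ceil(len(train_samples) / config.batch_size)
    sched = ScheduleConfig(
        lr_init=config.lr_init,
        beta2=config.beta2,
        total_steps=config.epochs * steps_per_epoch,
    )
    optimizer = nn.Adam(model.parameters(), betas=(config.beta1, config.beta2))
    history: dict = {"epoch_loss": [], "valid_map": [], "lr": []}
    best = TrainResult(history=history, best_epoch=-1, best_map=-1.0, best_state={})
    step = 0
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(len(train_samples))
        epoch_losses: list[float] = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = [_prepare(train_samples[i], config, rng) for i in idx]
            images = np.stack([b[0] for b in batch])
            outputs = model(images)
            n = len(batch)
            cls_grads = [np.zeros(c.shape, dtype=np.float64) for c, _ in outputs]
            reg_grads = [np.zeros(r.shape, dtype=np.float64) for _, r in outputs]
            batch_loss = 0.0
            for i, (_, gt_boxes, gt_labels) in enumerate(batch):
                logits = np.concatenate([c.data[i] for c, _ in outputs])
                deltas = np.concatenate([r.data[i] for _, r in outputs])
                bundle, d_logits, d_deltas = detection_loss(
                    logits,
                    deltas,
                    anchors_flat,
                    gt_boxes,
                    gt_labels,
                    params=config.focal,
                    num_classes=config.model.num_classes,
                )
                batch_loss += bundle.total
                for lv, (lo, hi) in enumerate(zip(level_offsets[:-1], level_offsets[1:])):
                    cls_grads[lv][i] = d_logits[lo:hi] / n
                    reg_grads[lv][i] = d_deltas[lo:hi] / n
            batch_loss /= n
            epoch_losses.append(batch_loss)
            seeds = [(c, g) for (c, _), g in zip(outputs, cls_grads)]
            seeds += [(r, g) for (_, r), g in zip(outputs, reg_grads)]
            nn.backward_multi(seeds)
            optimizer.lr = lr_at(step, sched)
            history["lr"].append(optimizer.lr)
            optimizer.step()
            optimizer.zero_grad()
            step += 1
        epoch_loss = float(np.mean(epoch_losses))
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        report = evaluate_model(model, valid_samples, config) if valid_samples else None
        valid_map = report.map if report is not None else float("nan")
        history["epoch_loss"].append(epoch_loss)
        history["valid_map"].append(valid_map)
        if verbose:
            print(f"epoch {epoch + 1}/{config.epochs}  loss {epoch_loss:.4f}  mAP {valid_map:.3f}")
        if report is not None and valid_map > best.best_map:
            best.best_epoch = epoch
            best.best_map = valid_map
            best.best_state = model.state_dict()
    if best.best_epoch < 0:  # no validation set: keep final weights
        best.best_epoch = config.epochs - 1
        best.best_map = float("nan")
        best.best_state = model.state_dict()
    return best


def predict_image(
    model: Detector,
    pixels: np.ndarray,
    config: RunConfig,
    nms: NMSConfig | None = None,
) -> list[Detection]:
    """Detections for one HxWx3 image, in original pixel coordinates."""
    nms = nms if nms is not None else config.nms
    size = config.image_size
    model.eval()
    image, _ = preprocess(pixels, [], target_size=size)
    with nn.no_grad():
        outputs = model(image[None])
    raw = [(c.data[0], r.data[0]) for c, r in outputs]
    anchors = generate_anchors((size, size), config.model.anchors)
    dets = decode_detections(raw, anchors, nms, image_size=(size, size))
    h, w = pixels.shape[:2]
    sx, sy = w / size, h / size
    return [
        dataclasses.replace(d, box=d.box * np.array([sx, sy, sx, sy])) for d in dets
    ]


def evaluate_model(
    model: Detector,
    samples: list[Sample],
    config: RunConfig,
    nms: NMSConfig | None = None,
    iou_thresh: float | None = None,
) -> EvalReport:
    """Forward + post-process + VOC-style scoring over ``samples``."""
    detections: dict[str, list[Detection]] = {}
    ground_truths: list[GroundTruth] = []
    for k, sample in enumerate(samples):
        image_id = sample.image_id or f"sample_{k}"
        pixels = sample.load_pixels()
        detections[image_id] = predict_image(model, pixels, config, nms)
        for ann in sample.annotations:
            ground_truths.append(GroundTruth(image_id=image_id, box=ann.box, label=ann.label))
    return evaluate_detections(
        detections,
        ground_truths,
        iou_thresh=iou_thresh if iou_thresh is not None else config.eval_iou,
    )


# ---------------------------------------------------------------------------
# checkpoints and config serialisation


def run_config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def run_config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    model = d.get("model", {})
    if isinstance(model, dict):
        model = dict(model)
        anchors = model.get("anchors")
        if isinstance(anchors, dict):
            anchors = {
                k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in anchors.items()
            }
            model["anchors"] = AnchorConfig(**anchors)
        d["model"] = ModelConfig(**model)
    if isinstance(d.get("nms"), dict):
        d["nms"] = NMSConfig(**d["nms"])
    if isinstance(d.get("focal"), dict):
        d["focal"] = FocalParams(**d["focal"])
    return RunConfig(**d)


def save_checkpoint(model: Detector, config: RunConfig, path) -> None:
    """Weights + run config in one .npz archive."""
    payload = {f"state/{k}": v for k, v in model.state_dict().items()}
    payload["config_json"] = np.array(json.dumps(run_config_to_dict(config)))
    np.savez_compressed(Path(path), **payload)


def load_checkpoint(path) -> tuple[Detector, RunConfig]:
    with np.load(Path(path), allow_pickle=False) as archive:
        config = run_config_from_dict(json.loads(str(archive["config_json"])))
        state = {
            key[len("state/") :]: archive[key] for key in archive.files if key.startswith("state/")
        }
    model = build_model(config.model, seed=config.seed)
    model.load_state_dict(state)
    return model, config
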