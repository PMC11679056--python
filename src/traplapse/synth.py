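"""Synthetic fixtures: time-lapse scene sequences and multi-camera annotation sets.

These generators emulate the structure of a camera-trap deployment — a static
procedural background photographed hourly, day frames in colour and night
frames channel-equal (infrared), optional channelwise linear illumination
drift, and transient objects with known ground-truth boxes and change masks —
so every stage of the pipeline is testable without any real imagery.

What they do *not* emulate: photorealistic texture, weather, sensor noise
models, or the appearance statistics of real animals.  A green test on these
fixtures establishes algebraic and contract correctness, not field accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from traplapse.sequence import Modality
from traplapse.split import BoxAnnotation

#: Hourly cadence starting mid-morning, matching the deployment being emulated.
DEFAULT_START = datetime(2021, 6, 1, 8, 0, 0)


@dataclass
class ObjectSpec:
    """A transient object: shape, size, constant colour, and per-frame positions."""

    shape: str = "ellipse"  # "ellipse" or "rect"
    size: tuple[int, int] = (12, 8)  # (width, height) in pixels
    colour: tuple[float, float, float] = (0.9, 0.8, 0.2)
    schedule: dict[int, tuple[int, int]] = field(default_factory=dict)  # frame -> (cx, cy) px


@dataclass
class SceneConfig:
    """A stated synthetic world for one camera's time-lapse sequence."""

    width: int = 64
    height: int = 48
    n_frames: int = 16
    camera_id: str = "CAM"
    #: per-frame channelwise gains; None means no drift (all ones)
    illumination_drift: Sequence[tuple[float, float, float]] | None = None
    objects: list[ObjectSpec] = field(default_factory=list)
    night_frames: frozenset[int] = frozenset()
    noise_scale: float = 0.15
    start_time: datetime = DEFAULT_START
    interval: timedelta = timedelta(hours=1)
    seed: int = 0


@dataclass
class SyntheticFrame:
    image: np.ndarray  # (H, W, 3) float in [0, 1]
    timestamp: datetime
    filename: str
    boxes: list[tuple[int, int, int, int]]  # ground truth (x0, y0, x1, y1) px
    change_mask: np.ndarray  # (H, W) bool
    is_night: bool


def _procedural_background(cfg: SceneConfig) -> np.ndarray:
    """Seeded smooth noise plus a horizontal gradient; mid-intensity so drift stays in range."""
    rng = np.random.default_rng(cfg.seed)
    base = rng.uniform(0.0, 1.0, size=(cfg.height // 4 + 1, cfg.width // 4 + 1, 3))
    # bilinear upsample of coarse noise -> smooth texture
    img = np.array(
        Image.fromarray((base * 255).astype(np.uint8)).resize(
            (cfg.width, cfg.height), Image.BILINEAR
        ),
        dtype=np.float64,
    ) / 255.0
    gradient = np.linspace(0.0, 1.0, cfg.width)[None, :, None]
    img = 0.35 + cfg.noise_scale * (img - 0.5) + 0.15 * gradient
    return np.clip(img, 0.05, 0.85)


def _paint_object(img: np.ndarray, obj: ObjectSpec, cx: int, cy: int) -> tuple[int, int, int, int]:
    h, w = img.shape[:2]
    ow, oh = obj.size
    x0, x1 = max(0, cx - ow // 2), min(w, cx + (ow + 1) // 2)
    y0, y1 = max(0, cy - oh // 2), min(h, cy + (oh + 1) // 2)
    if obj.shape == "ellipse":
        yy, xx = np.mgrid[0:h, 0:w]
        mask = ((xx - cx) / max(ow / 2, 1)) ** 2 + ((yy - cy) / max(oh / 2, 1)) ** 2 <= 1.0
    else:
        mask = np.zeros((h, w), dtype=bool)
        mask[y0:y1, x0:x1] = True
    img[mask] = obj.colour
    ys, xs = np.nonzero(mask)  # tight half-open bbox of the painted pixels
    return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


def generate_scene_sequence(
    config: SceneConfig, out_dir: Path | str | None = None
) -> list[SyntheticFrame]:
    """Render the configured sequence; deterministic given ``config.seed``.

    Night frames are rendered exactly channel-equal (the greyscale mean
    replicated into all three channels).  When ``out_dir`` is given, frames
    are written as PNG files with filename-encoded timestamps
    (``{camera}_{YYYYMMDD}_{HHMMSS}.png``) plus a ``ground_truth.json``.
    """
    bg = _procedural_background(config)
    frames: list[SyntheticFrame] = []
    for i in range(config.n_frames):
        img = bg.copy()
        if config.illumination_drift is not None:
            gains = np.asarray(config.illumination_drift[i], dtype=np.float64)
            img = np.clip(img * gains[None, None, :], 0.0, 1.0)
        boxes = []
        change = np.zeros((config.height, config.width), dtype=bool)
        for obj in config.objects:
            if i in obj.schedule:
                cx, cy = obj.schedule[i]
                if not (0 <= cx < config.width and 0 <= cy < config.height):
                    raise ValueError(f"object centre ({cx}, {cy}) outside image bounds")
                before = img.copy()
                boxes.append(_paint_object(img, obj, cx, cy))
                change |= np.any(before != img, axis=2)
        is_night = i in config.night_frames
        if is_night:
            grey = img.mean(axis=2)
            img = np.repeat(grey[..., None], 3, axis=2)
        ts = config.start_time + i * config.interval
        frames.append(
            SyntheticFrame(
                image=img,
                timestamp=ts,
                filename=f"{config.camera_id}_{ts:%Y%m%d_%H%M%S}.png",
                boxes=boxes,
                change_mask=change,
                is_night=is_night,
            )
        )
    if out_dir is not None:
        _write_scene(frames, Path(out_dir))
    return frames


def _write_scene(frames: list[SyntheticFrame], out_dir: Path) -> None:
    import json

    out_dir.mkdir(parents=True, exist_ok=True)
    gt = {}
    for fr in frames:
        arr = np.round(fr.image * 255).astype(np.uint8)
        Image.fromarray(arr).save(out_dir / fr.filename)
        gt[fr.filename] = {
            "timestamp": fr.timestamp.isoformat(),
            "boxes": [list(b) for b in fr.boxes],
            "is_night": fr.is_night,
        }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1)


# --------------------------------------------------------------------------
# Annotation-set generator


@dataclass
class CameraAnnotationConfig:
    """Sampling law for one synthetic camera's annotations."""

    n_images: int = 200
    #: per-class Poisson mean of boxes per image
    class_means: dict[str, float] = field(default_factory=lambda: {"adult": 1.0})
    #: per-class log-normal (mu, sigma) of normalised box areas
    area_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"adult": (-5.5, 0.6)}
    )
    #: target fraction of each class's boxes that fall in day images
    day_fraction: dict[str, float] = field(default_factory=lambda: {"adult": 0.7})
    #: fraction of the camera's images captured in daylight
    day_image_fraction: float = 0.7


@dataclass
class SyntheticAnnotationConfig:
    """A stated multi-camera annotation world emulating a real deployment's tables."""

    cameras: dict[str, CameraAnnotationConfig]
    class_names: tuple[str, ...] = ("adult", "chick", "egg")
    seed: int = 0


def generate_annotation_dataset(
    config: SyntheticAnnotationConfig,
) -> tuple[list[BoxAnnotation], dict[str, tuple[str, Modality]]]:
    """Sample a multi-camera annotation set; deterministic given ``config.seed``.

    Each image is a day image with probability ``day_image_fraction``; boxes
    inherit their image's modality.  Per-image box counts are Poisson with a
    modality-conditional mean chosen so the expected fraction of a class's
    boxes falling in day images equals the configured per-class
    ``day_fraction``.  Normalised areas are log-normal, clipped to valid
    extents.  Returns annotations plus the image -> (camera, modality) index
    that :func:`~traplapse.split.camera_statistics` consumes.
    """
    rng = np.random.default_rng(config.seed)
    annotations: list[BoxAnnotation] = []
    image_index: dict[str, tuple[str, Modality]] = {}
    for cam_id in sorted(config.cameras):
        cam = config.cameras[cam_id]
        p_day_img = cam.day_image_fraction
        for i in range(cam.n_images):
            image_id = f"{cam_id}_{i:05d}"
            mod = Modality.DAY if rng.random() < p_day_img else Modality.NIGHT
            for cls in config.class_names:
                mean = cam.class_means.get(cls, 0.0)
                if mean <= 0:
                    continue
                f_day = cam.day_fraction.get(cls, 0.5)
                if mod is Modality.DAY:
                    mean_mod = mean * f_day / p_day_img if p_day_img > 0 else 0.0
                else:
                    mean_mod = mean * (1 - f_day) / (1 - p_day_img) if p_day_img < 1 else 0.0
                n_boxes = rng.poisson(mean_mod)
                mu, sg = cam.area_params.get(cls, (-5.5, 0.6))
                for _ in range(n_boxes):
                    area = float(np.clip(rng.lognormal(mu, sg), 1e-6, 0.9))
                    aspect = float(rng.uniform(0.6, 1.6))
                    w = min(float(np.sqrt(area * aspect)), 1.0)
                    h = min(area / w, 1.0)
                    cx = float(rng.uniform(w / 2, 1 - w / 2))
                    cy = float(rng.uniform(h / 2, 1 - h / 2))
                    annotations.append(
                        BoxAnnotation(
                            image_id=image_id,
                            camera_id=cam_id,
                            class_label=cls,
                            cx=cx,
                            cy=cy,
                            w=w,
                            h=h,
                            modality=mod,
                        )
                    )
            image_index[image_id] = (cam_id, mod)
    return annotations, image_index


def write_yolo_annotations(
    annotations: list[BoxAnnotation],
    image_index: dict[str, tuple[str, Modality]],
    out_dir: Path | str,
    class_names: Sequence[str],
) -> None:
    """Write one YOLO text file per image plus the image-index CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cls_idx = {c: i for i, c in enumerate(class_names)}
    by_image: dict[str, list[BoxAnnotation]] = {img: [] for img in image_index}
    for ann in annotations:
        by_image[ann.image_id].append(ann)
    for image_id, anns in by_image.items():
        with open(out_dir / f"{image_id}.txt", "w") as fh:
            for a in anns:
                fh.write(f"{cls_idx[a.class_label]} {a.cx:.6f} {a.cy:.6f} {a.w:.6f} {a.h:.6f}\n")
    with open(out_dir / "image_index.csv", "w") as fh:
        fh.write("image_id,camera_id,modality\n")
        for image_id in sorted(image_index):
            cam, mod = image_index[image_id]
            fh.write(f"{image_id},{cam},{mod.value}\n")
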