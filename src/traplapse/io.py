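"""Shared I/O: annotation readers, split manifests, run configuration, fitness metric."""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from traplapse.sequence import Modality
from traplapse.split import BoxAnnotation, CameraStats, PartitionResult


class AnnotationFormat(str, enum.Enum):
    YOLO_TXT = "yolo_txt"
    COCO_JSON = "coco_json"


@dataclass(frozen=True)
class FitnessInputs:
    """Detector evaluation metrics entering the model-selection fitness score."""

    map50: float
    map0595: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{f.name} must lie in [0, 1], got {v}")


def fitness_score(inputs: FitnessInputs) -> float:
    """Model-selection scalar: 0.1 * mAP@0.5 + 0.9 * mAP@0.05:0.95."""
    return 0.1 * inputs.map50 + 0.9 * inputs.map0595


# --------------------------------------------------------------------------
# Image index and annotation readers


def read_image_index(path: Path | str) -> dict[str, tuple[str, Modality]]:
    """CSV with columns image_id, camera_id, modality -> lookup dict."""
    index: dict[str, tuple[str, Modality]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            index[row["image_id"]] = (row["camera_id"], Modality(row["modality"]))
    return index


def _read_yolo(path: Path, index: Mapping[str, tuple[str, Modality]]) -> list[BoxAnnotation]:
    """One ``<image_id>.txt`` per image: ``class cx cy w h``, normalised centre format."""
    annotations: list[BoxAnnotation] = []
    files = sorted(path.glob("*.txt")) if path.is_dir() else [path]
    for f in files:
        image_id = f.stem
        if image_id not in index:
            raise ValueError(f"{f}: image {image_id!r} not present in the image index")
        cam, mod = index[image_id]
        with open(f) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) != 5:
                    raise ValueError(f"{f}:{lineno}: expected 5 fields, got {len(parts)}")
                try:
                    cls = str(int(parts[0]))
                    cx, cy, w, h = map(float, parts[1:])
                except ValueError as exc:
                    raise ValueError(f"{f}:{lineno}: malformed YOLO line {line!r}") from exc
                annotations.append(
                    BoxAnnotation(
                        image_id=image_id, camera_id=cam, class_label=cls,
                        cx=cx, cy=cy, w=w, h=h, modality=mod,
                    )
                )
    return annotations


def _read_coco(path: Path, index: Mapping[str, tuple[str, Modality]]) -> list[BoxAnnotation]:
    """COCO JSON with pixel ``bbox = [x, y, w, h]`` (corner + size, 0-based,
    half-open) converted to normalised centre format."""
    with open(path) as fh:
        doc = json.load(fh)
    images = {img["id"]: img for img in doc["images"]}
    categories = {c["id"]: c["name"] for c in doc.get("categories", [])}
    annotations: list[BoxAnnotation] = []
    for i, ann in enumerate(doc["annotations"]):
        img = images.get(ann["image_id"])
        if img is None:
            raise ValueError(f"{path}: annotation {i} references unknown image id {ann['image_id']}")
        image_id = Path(img.get("file_name", str(img["id"]))).stem
        if image_id not in index:
            raise ValueError(f"{path}: image {image_id!r} not present in the image index")
        cam, mod = index[image_id]
        x, y, w, h = ann["bbox"]
        W, H = img["width"], img["height"]
        annotations.append(
            BoxAnnotation(
                image_id=image_id,
                camera_id=cam,
                class_label=categories.get(ann["category_id"], str(ann["category_id"])),
                cx=(x + w / 2) / W,
                cy=(y + h / 2) / H,
                w=w / W,
                h=h / H,
                modality=mod,
            )
        )
    return annotations


def read_annotations(
    path: Path | str,
    format: AnnotationFormat | str,
    image_index: Mapping[str, tuple[str, Modality]] | Path | str,
) -> list[BoxAnnotation]:
    """Read YOLO-text or COCO-JSON annotations joined with the image index.

    Images present in the index but absent from the annotation files (or with
    empty files) simply contribute zero boxes; they still count toward
    per-camera image totals downstream.
    """
    if not isinstance(image_index, Mapping):
        image_index = read_image_index(image_index)
    fmt = AnnotationFormat(format)
    path = Path(path)
    if fmt is AnnotationFormat.YOLO_TXT:
        return _read_yolo(path, image_index)
    return _read_coco(path, image_index)


# --------------------------------------------------------------------------
# Split manifest


def _stats_to_dict(s: CameraStats) -> dict:
    return {
        "camera_id": s.camera_id,
        "n_images": s.n_images,
        "class_counts": dict(s.class_counts),
        "size_class_counts": {f"{c}|{sz}": v for (c, sz), v in s.size_class_counts.items()},
        "day_counts": dict(s.day_counts),
        "night_counts": dict(s.night_counts),
    }


def write_split_manifest(
    result: PartitionResult,
    stats: Sequence[CameraStats],
    path: Path | str,
    image_lists: Mapping[str, Sequence[str]] | None = None,
) -> None:
    """JSON manifest of a partition: assignment, objective terms, subset totals."""
    by_cam = {s.camera_id: s for s in stats}
    subset_images = {
        sub: sum(by_cam[c].n_images for c in result.cameras(sub)) for sub in ("train", "val", "test")
    }
    doc = {
        "assignment": dict(sorted(result.assignment.items())),
        "sigma_n2": result.sigma_n2,
        "sigma_s2": result.sigma_s2,
        "sigma_r2": result.sigma_r2,
        "objective": result.objective,
        "subset_image_counts": subset_images,
        "camera_stats": [_stats_to_dict(s) for s in stats],
    }
    if image_lists is not None:
        doc["image_lists"] = {k: sorted(v) for k, v in image_lists.items()}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_split_manifest(path: Path | str) -> PartitionResult:
    with open(path) as fh:
        doc = json.load(fh)
    return PartitionResult(
        assignment=doc["assignment"],
        sigma_n2=doc["sigma_n2"],
        sigma_s2=doc["sigma_s2"],
        sigma_r2=doc["sigma_r2"],
        objective=doc["objective"],
    )


# --------------------------------------------------------------------------
# Run configuration


_CONFIG_KEYS = {
    "window", "min_window", "grey_tolerance", "night_window", "colour_correction",
    "filename_pattern", "timestamp_source", "subset_sizes", "forced", "max_fraction",
    "seed", "out_dir", "h_gain", "s_gain", "v_gain",
}

_CONFIG_DEFAULTS = {
    "window": 12,
    "min_window": 1,
    "grey_tolerance": 2.0,
    "night_window": "18:00-06:00",
    "colour_correction": True,
    "filename_pattern": None,
    "timestamp_source": "filename_pattern",
    "subset_sizes": [6, 2, 2],
    "forced": {},
    "max_fraction": 0.25,
    "seed": 0,
    "out_dir": None,
    "h_gain": 0.015,
    "s_gain": 0.7,
    "v_gain": 0.4,
}


@dataclass
class RunConfig:
    """The union of all module configuration, YAML-round-trippable.

    Unknown keys are rejected so typos fail loudly rather than silently
    reverting to defaults.
    """

    values: dict

    def __post_init__(self):
        unknown = set(self.values) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(_CONFIG_DEFAULTS)
        merged.update(self.values)
        self.values = merged

    def __getitem__(self, key: str):
        return self.values[key]

    def night_window_times(self):
        from datetime import time

        start, end = self.values["night_window"].split("-")
        h1, m1 = map(int, start.split(":"))
        h2, m2 = map(int, end.split(":"))
        return (time(h1, m1), time(h2, m2))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            values = yaml.safe_load(fh) or {}
        return cls(values=values)

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.values, fh)
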