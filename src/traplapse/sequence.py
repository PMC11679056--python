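"""Sequence indexing: ordering frames, day/night labelling, background-frame selection.

A camera's time-lapse output is a totally ordered sequence of frames.  Each
frame belongs to one of two *modalities* — colour daylight imagery or
infrared night imagery (channel-equal greyscale) — and the background model
for a frame is built only from prior frames of the same modality.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, time
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger(__name__)

#: EXIF tag ids: DateTimeOriginal lives in the Exif IFD, DateTime at top level.
_EXIF_IFD = 0x8769
_TAG_DATETIME_ORIGINAL = 36867
_TAG_DATETIME = 306

#: IR frames are stored with R=G=B; tolerance in 8-bit intensity units.
DEFAULT_GREY_TOLERANCE = 2.0

#: Night window: hours in [start, end) wrapping midnight count as night.
DEFAULT_NIGHT_WINDOW = (time(18, 0), time(6, 0))


class Modality(str, enum.Enum):
    DAY = "day"
    NIGHT = "night"


class TimestampSource(str, enum.Enum):
    EXIF = "exif"
    FILENAME_PATTERN = "filename_pattern"


class BackgroundUnavailable(RuntimeError):
    """Raised when a frame has no usable same-modality history."""


@dataclass(frozen=True)
class FrameRecord:
    """One time-lapse frame with its position in the camera's sequence."""

    frame_id: str
    camera_id: str
    path: Path
    timestamp: datetime
    modality: Modality
    index_in_sequence: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "frame_id": self.frame_id,
                "camera_id": self.camera_id,
                "path": str(self.path),
                "timestamp": self.timestamp.isoformat(),
                "modality": self.modality.value,
                "index_in_sequence": self.index_in_sequence,
            }
        )

    @classmethod
    def from_json(cls, line: str) -> "FrameRecord":
        d = json.loads(line)
        return cls(
            frame_id=d["frame_id"],
            camera_id=d["camera_id"],
            path=Path(d["path"]),
            timestamp=datetime.fromisoformat(d["timestamp"]),
            modality=Modality(d["modality"]),
            index_in_sequence=int(d["index_in_sequence"]),
        )


@dataclass
class SequenceIndex:
    """Time-ordered frames of a single camera."""

    camera_id: str
    frames: list[FrameRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def write_manifest(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            for fr in self.frames:
                fh.write(fr.to_json() + "\n")

    @classmethod
    def read_manifest(cls, path: Path | str) -> "SequenceIndex":
        frames = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    frames.append(FrameRecord.from_json(line))
        camera_id = frames[0].camera_id if frames else ""
        return cls(camera_id=camera_id, frames=frames)


def _in_night_window(ts: datetime, window: tuple[time, time]) -> bool:
    start, end = window
    t = ts.time()
    if start <= end:
        return start <= t < end
    return t >= start or t < end  # window wraps midnight


def classify_modality(
    image: np.ndarray,
    timestamp: datetime,
    grey_tolerance: float = DEFAULT_GREY_TOLERANCE,
    night_window: tuple[time, time] = DEFAULT_NIGHT_WINDOW,
) -> Modality:
    """Label a frame DAY or NIGHT.

    Infrared night frames are stored channel-equal, so the measured test —
    ``max over pixels of max(|R-G|, |G-B|) <= grey_tolerance`` — takes
    precedence: cameras switch sensor on measured light, not on the clock.
    Colour frames fall back to the clock rule: night iff the local time lies
    in ``night_window`` (default 18:00–06:00, the approximate IR window of
    the target deployment).

    Parameters
    ----------
    image : (H, W, 3) array
        Decoded frame; uint8 or float.  ``grey_tolerance`` is interpreted on
        the 0–255 scale, and rescaled automatically for unit-interval floats.
    timestamp : datetime
        Local camera time.
    grey_tolerance : float
        Maximum channel disagreement (8-bit units) still counted as greyscale.
    """
    if grey_tolerance < 0:
        raise ValueError("grey_tolerance must be >= 0")
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {arr.shape}")
    tol = grey_tolerance
    if np.issubdtype(arr.dtype, np.floating) and arr.max() <= 1.0 + 1e-9:
        tol = grey_tolerance / 255.0
    arr = arr.astype(np.float64)
    rg = np.abs(arr[..., 0] - arr[..., 1])
    gb = np.abs(arr[..., 1] - arr[..., 2])
    if max(rg.max(initial=0.0), gb.max(initial=0.0)) <= tol:
        return Modality.NIGHT
    return Modality.NIGHT if _in_night_window(timestamp, night_window) else Modality.DAY


def _exif_timestamp(path: Path) -> datetime:
    with Image.open(path) as img:
        exif = img.getexif()
        raw = exif.get_ifd(_EXIF_IFD).get(_TAG_DATETIME_ORIGINAL) or exif.get(_TAG_DATETIME)
    if not raw:
        raise ValueError(f"no EXIF timestamp in {path}")
    return datetime.strptime(str(raw), "%Y:%m:%d %H:%M:%S")


def _filename_timestamp(path: Path, pattern: str) -> datetime:
    try:
        return datetime.strptime(path.stem, pattern)
    except ValueError as exc:
        raise ValueError(f"cannot parse timestamp from {path.name!r} with pattern {pattern!r}") from exc


def index_sequence(
    image_paths: Sequence[Path | str],
    camera_id: str,
    timestamp_source: TimestampSource | str = TimestampSource.FILENAME_PATTERN,
    filename_pattern: str | None = None,
    grey_tolerance: float = DEFAULT_GREY_TOLERANCE,
    night_window: tuple[time, time] = DEFAULT_NIGHT_WINDOW,
) -> SequenceIndex:
    """Build a :class:`SequenceIndex` from image files of one camera.

    Frames are sorted ascending by capture timestamp (ties broken by path,
    lexicographically, for determinism) and each is labelled DAY or NIGHT via
    :func:`classify_modality`.  Unreadable images are skipped with a logged
    warning; an unparseable timestamp is a hard error naming the file.
    """
    timestamp_source = TimestampSource(timestamp_source)
    if timestamp_source is TimestampSource.FILENAME_PATTERN and not filename_pattern:
        raise ValueError("filename_pattern is required with FILENAME_PATTERN timestamp source")

    entries: list[tuple[datetime, str, Path, np.ndarray]] = []
    for p in image_paths:
        p = Path(p)
        try:
            with Image.open(p) as img:
                arr = np.asarray(img.convert("RGB"))
        except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
            logger.warning("skipping unreadable image %s: %s", p, exc)
            continue
        if timestamp_source is TimestampSource.EXIF:
            ts = _exif_timestamp(p)
        else:
            ts = _filename_timestamp(p, filename_pattern)  # type: ignore[arg-type]
        entries.append((ts, str(p), p, arr))

    entries.sort(key=lambda e: (e[0], e[1]))
    frames = [
        FrameRecord(
            frame_id=path.stem,
            camera_id=camera_id,
            path=path,
            timestamp=ts,
            modality=classify_modality(arr, ts, grey_tolerance, night_window),
            index_in_sequence=i,
        )
        for i, (ts, _, path, arr) in enumerate(entries)
    ]
    return SequenceIndex(camera_id=camera_id, frames=frames)


def select_background_frames(
    index: SequenceIndex,
    current: FrameRecord,
    count: int = 12,
    min_count: int = 1,
) -> list[FrameRecord]:
    """Pick the background window for ``current``: its most recent
    same-modality predecessors.

    Returns up to ``count`` frames, most recent first.  Near the start of a
    sequence fewer may exist; all available ones are returned provided at
    least ``min_count``, otherwise :class:`BackgroundUnavailable` is raised.
    """
    if not any(f.frame_id == current.frame_id for f in index.frames):
        raise ValueError(f"frame {current.frame_id!r} does not belong to the index")
    prior = [
        f
        for f in index.frames
        if f.index_in_sequence < current.index_in_sequence and f.modality is current.modality
    ]
    prior.sort(key=lambda f: f.index_in_sequence, reverse=True)
    selected = prior[:count]
    if len(selected) < min_count:
        raise BackgroundUnavailable(
            f"frame {current.frame_id!r}: {len(selected)} prior {current.modality.value} "
            f"frames available, {min_count} required"
        )
    return selected


def load_frame(record: FrameRecord) -> np.ndarray:
    """Decode a frame to unit-interval float RGB (H, W, 3)."""
    with Image.open(record.path) as img:
        return np.asarray(img.convert("RGB"), dtype=np.float64) / 255.0


def iter_sequences(
    root: Path | str,
    timestamp_source: TimestampSource | str = TimestampSource.FILENAME_PATTERN,
    filename_pattern: str | None = None,
    **kwargs,
) -> Iterable[SequenceIndex]:
    """Index every camera subdirectory of ``root`` (one directory per camera)."""
    root = Path(root)
    for cam_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        paths = sorted(
            p for p in cam_dir.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
        )
        pattern = filename_pattern
        if pattern and "{camera}" in pattern:
            pattern = pattern.replace("{camera}", cam_dir.name)
        yield index_sequence(
            paths, cam_dir.name, timestamp_source, filename_pattern=pattern, **kwargs
        )
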