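"""Frame ingestion, frame-rate decimation, cropping and annotation I/O.

Meal videos are recorded at a native frame rate (30 fps in the study design
this package targets) and decimated to a working rate — 6 fps by default,
comfortably above twice the ~2 Hz upper bound of human chewing frequency.
All downstream indices live in the *retained* (down-sampled) frame space;
timestamps are always derived from the native-stream index so they remain
comparable to annotations made on the full-rate video.

Coordinate conventions: 0-based, (row, column); rectangles are half-open,
``[y, y+h) x [x, x+w)``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize as _skimage_resize

__all__ = [
    "FrameSequence",
    "AnnotationRecord",
    "InputError",
    "ConfigError",
    "ParseError",
    "load_frames",
    "frames_from_arrays",
    "to_grayscale",
    "resize",
    "read_annotations",
    "write_annotations",
    "write_summary",
    "read_summary",
]

#: ITU-R BT.601 luma weights for RGB -> grayscale conversion.
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])

SUMMARY_SCHEMA_VERSION = 1

_IMAGE_EXTS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}
_VIDEO_EXTS = {".mp4", ".avi", ".mov", ".mkv"}


class InputError(ValueError):
    """Unreadable or malformed input data."""


class ConfigError(ValueError):
    """A configuration value outside its documented range."""


class ParseError(ValueError):
    """An annotation or summary file that does not match the schema."""


@dataclass
class FrameSequence:
    """A time-ordered stack of frames at a declared (possibly decimated) rate.

    Attributes
    ----------
    frames
        List of 2-D grayscale or 3-D color intensity arrays, all sharing one
        height/width.
    frame_index
        Index of each frame in the down-sampled stream (0, 1, 2, ...).
    source_index
        Index of each frame in the native stream; timestamps derive from this.
    fps
        Frame rate of the down-sampled stream.
    native_fps
        Frame rate of the source. ``native_fps % fps == 0`` whenever
        decimation was applied.
    """

    frames: list[np.ndarray]
    frame_index: list[int]
    source_index: list[int]
    fps: float
    native_fps: float

    def __post_init__(self) -> None:
        n = len(self.frames)
        if len(self.frame_index) != n or len(self.source_index) != n:
            raise InputError("frames, frame_index and source_index must align")
        if self.frame_index != list(range(self.frame_index[0] if n else 0,
                                          (self.frame_index[0] if n else 0) + n)):
            # strictly increasing by construction; allow only 0-based contiguous
            if n and (self.frame_index[0] != 0
                      or any(b - a != 1 for a, b in zip(self.frame_index, self.frame_index[1:]))):
                raise InputError("frame_index must start at 0 and increase by 1")
        if n:
            shapes = {f.shape[:2] for f in self.frames}
            if len(shapes) != 1:
                raise InputError("all frames must share one height/width")
        if self.fps <= 0 or self.native_fps <= 0:
            raise ConfigError("frame rates must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    def timestamp(self, i: int) -> float:
        """Time in seconds of retained frame ``i``, exact in the native stream."""
        return self.source_index[i] / self.native_fps

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape[:2]


@dataclass
class AnnotationRecord:
    """Manually annotated bite timestamps and chew counts for one meal."""

    bite_times: list[float]
    chew_count_total: int
    chew_counts_per_segment: list[int] | None = None
    subject_id: str = ""
    meal_id: str = ""

    def __post_init__(self) -> None:
        if any(b < a for a, b in zip(self.bite_times, self.bite_times[1:])):
            raise ParseError("bite_times must be sorted ascending")
        if self.chew_count_total < 0:
            raise ParseError("chew_count_total must be nonnegative")
        if self.chew_counts_per_segment is not None:
            if any(c < 0 for c in self.chew_counts_per_segment):
                raise ParseError("chew_counts_per_segment entries must be nonnegative")
            if sum(self.chew_counts_per_segment) != self.chew_count_total:
                raise ParseError(
                    "chew_count_total must equal the sum of chew_counts_per_segment "
                    f"({self.chew_count_total} != {sum(self.chew_counts_per_segment)})"
                )


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an RGB frame to single-channel luma (BT.601 weights).

    Output is float64 in the source intensity range; a uint8 input in
    [0, 255] yields values in [0, 255].
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise InputError(f"expected an RGB frame with 3 channels, got shape {frame.shape}")
    return frame.astype(np.float64) @ GRAY_WEIGHTS


def resize(frame: np.ndarray, height: int, width: int) -> np.ndarray:
    """Bilinearly resize a grayscale frame to ``(height, width)``.

    A same-shape request returns the input values unchanged.
    """
    if height <= 0 or width <= 0:
        raise ConfigError("resize dimensions must be positive")
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape == (height, width):
        return frame.copy()
    return _skimage_resize(frame, (height, width), order=1, mode="edge",
                           anti_aliasing=False, preserve_range=True)


def _crop(frame: np.ndarray, rect: tuple[int, int, int, int]) -> np.ndarray:
    x, y, w, h = rect
    if x < 0 or y < 0 or w <= 0 or h <= 0 or y + h > frame.shape[0] or x + w > frame.shape[1]:
        raise ConfigError(
            f"crop rectangle (x={x}, y={y}, w={w}, h={h}) out of bounds for frame {frame.shape[:2]}"
        )
    return frame[y:y + h, x:x + w]


def frames_from_arrays(arrays: Sequence[np.ndarray], native_fps: float,
                       target_fps: float | None = None,
                       crop_rect: tuple[int, int, int, int] | None = None) -> FrameSequence:
    """Build a :class:`FrameSequence` from in-memory frames, decimating to
    ``target_fps`` (keep native frame 0, then every k-th) and optionally
    pre-cropping each retained frame."""
    if target_fps is None:
        target_fps = native_fps
    if target_fps <= 0:
        raise ConfigError("target_fps must be positive")
    if target_fps > native_fps:
        raise ConfigError(f"target_fps {target_fps} exceeds native fps {native_fps}")
    ratio = native_fps / target_fps
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9:
        raise ConfigError(
            f"native fps {native_fps} is not an integer multiple of target fps {target_fps}"
        )
    frames, fidx, sidx = [], [], []
    for j, src in enumerate(range(0, len(arrays), k)):
        f = np.asarray(arrays[src])
        if crop_rect is not None:
            f = _crop(f, crop_rect)
        frames.append(f)
        fidx.append(j)
        sidx.append(src)
    return FrameSequence(frames=frames, frame_index=fidx, source_index=sidx,
                         fps=float(target_fps), native_fps=float(native_fps))


def _numeric_key(p: Path) -> tuple:
    m = re.findall(r"\d+", p.stem)
    return (int(m[-1]) if m else 0, p.name)


def load_frames(path: str | Path, target_fps: float,
                crop_rect: tuple[int, int, int, int] | None = None,
                native_fps: float | None = None) -> FrameSequence:
    """Read a video file or a directory of image frames and decimate.

    For a directory, frames are ordered by the trailing integer in their
    file names (zero-padded indices sort identically); ``native_fps`` must
    be supplied since image files carry no rate. For a video container the
    rate is read from metadata where possible.
    """
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise InputError(f"input path does not exist: {path}")

    if path.is_dir():
        files = sorted((p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS),
                       key=_numeric_key)
        if not files:
            raise InputError(f"no image frames found in directory {path}")
        if native_fps is None:
            raise ConfigError("native_fps is required when loading a frame directory")
        arrays = [iio.imread(f) for f in files]
    else:
        if path.suffix.lower() in _VIDEO_EXTS:
            try:
                arrays = list(iio.imiter(path))
                if native_fps is None:
                    meta = iio.immeta(path)
                    native_fps = float(meta.get("fps", 0)) or None
            except Exception as exc:  # no decoder plugin for this container
                raise InputError(
                    f"cannot decode video container {path.name}: {exc}; "
                    "extract frames to an image directory instead"
                ) from exc
            if native_fps is None:
                raise ConfigError("native fps not present in video metadata; pass native_fps")
        else:
            raise InputError(f"unsupported input file type: {path.suffix}")
    return frames_from_arrays(arrays, native_fps=native_fps, target_fps=target_fps,
                              crop_rect=crop_rect)


# ---------------------------------------------------------------------------
# annotation and summary files


def read_annotations(path: str | Path) -> AnnotationRecord:
    """Read a manual-annotation file (CSV of bite events, or JSON).

    CSV schema: columns ``event_type`` (only ``bite`` rows are consumed) and
    ``time_s``. JSON schema: ``{"subject_id", "meal_id", "bites": [t, ...],
    "chews_per_segment": [n, ...]}``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        try:
            bites = [float(t) for t in data["bites"]]
            chews = data.get("chews_per_segment")
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"malformed annotation JSON {path.name}: field {exc}") from exc
        chews = [int(c) for c in chews] if chews is not None else None
        total = int(data.get("chew_count_total", sum(chews) if chews else 0))
        return AnnotationRecord(
            bite_times=sorted(bites), chew_count_total=total,
            chew_counts_per_segment=chews,
            subject_id=str(data.get("subject_id", "")),
            meal_id=str(data.get("meal_id", "")),
        )
    df = pd.read_csv(path)
    for col in ("event_type", "time_s"):
        if col not in df.columns:
            raise ParseError(f"annotation CSV {path.name} missing column '{col}'")
    bad = set(df["event_type"]) - {"bite"}
    if bad:
        raise ParseError(f"annotation CSV {path.name}: unknown event_type values {sorted(bad)}")
    times = sorted(float(t) for t in df.loc[df["event_type"] == "bite", "time_s"])
    return AnnotationRecord(bite_times=times, chew_count_total=0)


def write_annotations(record: AnnotationRecord, path: str | Path) -> None:
    """Write an :class:`AnnotationRecord` (format chosen by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = {
            "subject_id": record.subject_id,
            "meal_id": record.meal_id,
            "bites": list(record.bite_times),
            "chew_count_total": record.chew_count_total,
        }
        if record.chew_counts_per_segment is not None:
            data["chews_per_segment"] = list(record.chew_counts_per_segment)
        path.write_text(json.dumps(data, indent=2))
    else:
        pd.DataFrame({"event_type": ["bite"] * len(record.bite_times),
                      "time_s": record.bite_times}).to_csv(path, index=False)


def write_summary(summary: dict, path: str | Path) -> None:
    """Write a meal-summary dict as versioned JSON (sorted keys, so equal
    summaries serialize byte-identically)."""
    out = dict(summary)
    out["schema_version"] = SUMMARY_SCHEMA_VERSION
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True))


def read_summary(path: str | Path) -> dict:
    with open(path) as fh:
        data = json.load(fh)
    if data.get("schema_version") != SUMMARY_SCHEMA_VERSION:
        raise ParseError(f"unsupported summary schema_version {data.get('schema_version')!r}")
    return data
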