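"""Face-ROI detection contract, confidence gating and crop extraction.

The pipeline consumes *any* single-face detector through a minimal contract:
a callable over one frame returning ``(BoundingBox, confidence)`` or ``None``.
Frames whose detection confidence falls below the gate (0.8 by default) are
dropped from the retained stream; downstream series carry a ``gap_flag`` so
the chew counter can avoid differencing across missing frames.

A synthetic oracle detector — ground-truth boxes perturbed by uniform jitter,
with seeded confidence dropouts — stands in for a trained network so the full
pipeline is exercisable without model weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .frames_io import FrameSequence, InputError, resize, to_grayscale

__all__ = [
    "BoundingBox",
    "Detection",
    "FaceCropSeries",
    "Detector",
    "detect_faces",
    "extract_crops",
    "synthetic_oracle_detector",
]

logger = logging.getLogger(__name__)

#: minimum detector confidence for a frame to be retained
DEFAULT_MIN_CONFIDENCE = 0.8
#: default face-crop shape, (rows, cols) — taller than wide for a profile face
DEFAULT_CROP_SHAPE = (150, 120)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box: ``x``/``y`` top-left corner (col/row), half-open extent."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise InputError(f"box must have positive extent, got w={self.w}, h={self.h}")

    @property
    def area(self) -> float:
        return self.w * self.h

    def clipped(self, height: int, width: int) -> "BoundingBox":
        """Clip to a frame of the given shape (may shrink, never empties to
        zero: a fully out-of-frame box raises)."""
        x0, y0 = max(self.x, 0.0), max(self.y, 0.0)
        x1, y1 = min(self.x + self.w, width), min(self.y + self.h, height)
        if x1 <= x0 or y1 <= y0:
            raise InputError("box lies entirely outside the frame")
        return BoundingBox(x0, y0, x1 - x0, y1 - y0)


@dataclass(frozen=True)
class Detection:
    box: BoundingBox
    confidence: float
    frame_index: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise InputError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass
class FaceCropSeries:
    """Fixed-shape grayscale face crops for the retained frames.

    ``gap_flag[i]`` is True when crops ``i`` and ``i+1`` are not adjacent in
    the retained-frame stream (a detection dropout sits between them); flow
    values straddling such a pair are marked invalid.
    """

    crops: list[np.ndarray]
    frame_index: list[int]
    gap_flag: list[bool] = field(default_factory=list)
    fps: float = 6.0

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.frame_index, self.frame_index[1:])):
            raise InputError("frame_index must be strictly increasing")
        shapes = {c.shape for c in self.crops}
        if len(shapes) > 1:
            raise InputError("all crops must share one shape")
        if not self.gap_flag:
            self.gap_flag = [b - a > 1 for a, b in zip(self.frame_index, self.frame_index[1:])]

    def __len__(self) -> int:
        return len(self.crops)


#: Detector contract: frame -> (box, confidence) or None. Adapters around real
#: models return at most one candidate; if several, keep the most confident.
Detector = Callable[[np.ndarray], Optional[tuple[BoundingBox, float]]]


def detect_faces(frames: FrameSequence, detector: Detector,
                 min_confidence: float = DEFAULT_MIN_CONFIDENCE) -> list[Detection]:
    """Run the detector over every frame and keep confident detections.

    Frames where the detector returns nothing, raises, or reports confidence
    below ``min_confidence`` are simply absent from the output; one bad frame
    never aborts the pipeline.
    """
    out: list[Detection] = []
    for i, frame in zip(frames.frame_index, frames.frames):
        try:
            result = detector(frame)
        except Exception:
            logger.exception("detector failed on frame %d; treating as no detection", i)
            continue
        if result is None:
            continue
        box, conf = result
        if conf >= min_confidence:
            out.append(Detection(box=box, confidence=conf, frame_index=i))
    return out


def extract_crops(frames: FrameSequence, detections: Sequence[Detection],
                  out_shape: tuple[int, int] = DEFAULT_CROP_SHAPE) -> FaceCropSeries:
    """Cut each detected box out of its frame, grayscale it and resize.

    Boxes that spill slightly outside the frame (detector jitter) are clipped
    with a warning rather than rejected, preserving time-series continuity.
    """
    rows, cols = out_shape
    by_index = {i: f for i, f in zip(frames.frame_index, frames.frames)}
    crops, fidx = [], []
    for det in detections:
        frame = by_index[det.frame_index]
        h, w = frame.shape[:2]
        box = det.box
        if box.x < 0 or box.y < 0 or box.x + box.w > w or box.y + box.h > h:
            logger.warning("clipping out-of-frame box on frame %d", det.frame_index)
            box = box.clipped(h, w)
        y0, y1 = int(round(box.y)), int(round(box.y + box.h))
        x0, x1 = int(round(box.x)), int(round(box.x + box.w))
        y1, x1 = max(y1, y0 + 1), max(x1, x0 + 1)
        patch = frame[y0:y1, x0:x1]
        if patch.ndim == 3:
            patch = to_grayscale(patch)
        crops.append(resize(patch, rows, cols))
        fidx.append(det.frame_index)
    return FaceCropSeries(crops=crops, frame_index=fidx, fps=frames.fps)


def synthetic_oracle_detector(true_boxes: dict[int, BoundingBox] | Sequence[BoundingBox],
                              jitter_px: float = 0.0, dropout_p: float = 0.0,
                              seed: int = 0) -> Detector:
    """A detector built from ground truth, for pipeline tests.

    Each call returns the true box with every edge independently perturbed by
    U[-jitter_px, +jitter_px]; confidence is 1 with probability 1-dropout_p,
    otherwise U[0, 0.8) (i.e. below the default gate). Deterministic given the
    seed *and* the call order: the returned callable keeps its own generator
    and a frame counter, so running it over a sequence twice from two separate
    instances reproduces identical output.
    """
    rng = np.random.default_rng(seed)
    counter = {"i": 0}

    def _lookup(i: int) -> BoundingBox | None:
        if isinstance(true_boxes, dict):
            return true_boxes.get(i)
        return true_boxes[i] if i < len(true_boxes) else None

    def detector(frame: np.ndarray) -> Optional[tuple[BoundingBox, float]]:
        i = counter["i"]
        counter["i"] += 1
        box = _lookup(i)
        # draw in a fixed order so dropouts and jitter are reproducible
        conf = 1.0 if rng.random() >= dropout_p else rng.uniform(0.0, 0.8)
        jit = rng.uniform(-jitter_px, jitter_px, size=4) if jitter_px > 0 else np.zeros(4)
        if box is None:
            return None
        x0, y0 = box.x + jit[0], box.y + jit[1]
        x1, y1 = box.x + box.w + jit[2], box.y + box.h + jit[3]
        if x1 <= x0 or y1 <= y0:  # degenerate after jitter; fall back to truth
            x0, y0, x1, y1 = box.x, box.y, box.x + box.w, box.y + box.h
        return BoundingBox(x0, y0, x1 - x0, y1 - y0), conf

    return detector
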