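"""Bite counting from per-frame bite probabilities.

A frame-level classifier labels each retained face crop as 'bite' (food,
hand, utensil or container at the mouth) or 'non-bite'. Isolated
misclassifications are suppressed by a centered moving average with a span of
10 frames; the smoothed trace is binarized at 0.5 and each maximal run of
ones becomes one bite event. A lone flipped label therefore contributes at
most 1/span = 0.1 to the smoothed trace and can never cross the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .frames_io import ConfigError, InputError

__all__ = [
    "BiteProbSeries",
    "BiteEvents",
    "moving_average",
    "binarize",
    "extract_bite_events",
    "count_bites",
    "synthetic_oracle_classifier",
]

DEFAULT_SMOOTHING_SPAN = 10
DEFAULT_BITE_THRESHOLD = 0.5


@dataclass
class BiteProbSeries:
    """Per-retained-frame probability (or 0/1 label) of 'bite'."""

    p: np.ndarray
    frame_index: list[int]
    fps: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if len(self.p) != len(self.frame_index):
            raise InputError("p and frame_index must align")
        if self.p.size and (self.p.min() < 0 or self.p.max() > 1):
            raise InputError("bite probabilities must lie in [0, 1]")
        if any(b <= a for a, b in zip(self.frame_index, self.frame_index[1:])):
            raise InputError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.p)


@dataclass
class BiteEvents:
    """Disjoint, sorted half-open bite intervals in retained-frame positions."""

    events: list[tuple[int, int]]

    def __post_init__(self) -> None:
        for (s0, e0), (s1, e1) in zip(self.events, self.events[1:]):
            if s1 < e0:
                raise InputError("bite events must be disjoint and sorted")
        if any(e <= s for s, e in self.events):
            raise InputError("bite events must be non-empty half-open intervals")

    @property
    def count(self) -> int:
        return len(self.events)


def moving_average(p: np.ndarray, span: int = DEFAULT_SMOOTHING_SPAN) -> np.ndarray:
    """Centered moving mean with window ``span``; the window is clipped at the
    series ends and the mean taken over the available samples.

    For even spans the window covers ``(span-1)//2`` samples to the left and
    ``span//2`` to the right of each index. Output length equals input length
    and values stay within the input range.
    """
    if span < 1:
        raise ConfigError(f"smoothing span must be >= 1, got {span}")
    p = np.asarray(p, dtype=np.float64)
    n = len(p)
    if n == 0 or span == 1:
        return p.copy()
    left, right = (span - 1) // 2, span // 2
    csum = np.concatenate([[0.0], np.cumsum(p)])
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi + 1 - lo)


def binarize(values: np.ndarray, threshold: float = DEFAULT_BITE_THRESHOLD) -> np.ndarray:
    """Threshold a smoothed trace; a value exactly at threshold counts as bite."""
    if not 0.0 < threshold < 1.0:
        raise ConfigError(f"threshold must lie in (0, 1), got {threshold}")
    return (np.asarray(values) >= threshold).astype(np.int8)


def extract_bite_events(binary: np.ndarray, min_event_frames: int = 1) -> BiteEvents:
    """Each maximal run of ones is one bite event; runs shorter than
    ``min_event_frames`` (default 1, i.e. filter off) are discarded."""
    b = np.asarray(binary).astype(bool)
    padded = np.concatenate([[False], b, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    events = [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_event_frames]
    return BiteEvents(events=events)


def count_bites(probs: BiteProbSeries, span: int = DEFAULT_SMOOTHING_SPAN,
                threshold: float = DEFAULT_BITE_THRESHOLD,
                min_event_frames: int = 1) -> BiteEvents:
    """Smooth, binarize and extract bite events in one call.

    Event positions are in *series position* space (0..len(probs)), matching
    the positions of the flow series computed from the same retained frames.
    """
    smoothed = moving_average(probs.p, span)
    return extract_bite_events(binarize(smoothed, threshold), min_event_frames)


def synthetic_oracle_classifier(true_labels: Sequence[int], label_flip_p: float = 0.0,
                                seed: int = 0) -> Callable[[np.ndarray, int], float]:
    """A stand-in frame classifier built from ground-truth labels.

    Returns a callable ``(crop, position) -> p`` that emits the true 0/1 label
    of the frame at stream position ``position``, flipped with probability
    ``label_flip_p``. Deterministic given the seed: flips are pre-drawn for
    the whole label vector.
    """
    labels = np.asarray(true_labels, dtype=np.int8)
    rng = np.random.default_rng(seed)
    flips = rng.random(len(labels)) < label_flip_p

    def classifier(crop: np.ndarray, position: int) -> float:
        lab = int(labels[position])
        return float(1 - lab if flips[position] else lab)

    return classifier
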