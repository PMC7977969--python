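"""Chew counting from the rotational optical-flow signal.

Chews are counted between bites: each inter-bite span of the 1-D rotational
signal is a candidate chewing segment (capped at 52 s — the longest chewing
sequence observed in the study data this pipeline targets). Segments whose
short-time energy falls below a meal-adaptive dynamic threshold are treated
as rest, talking or drinking and contribute no chews; in the active segments
each sufficiently prominent local maximum of the signal is one mastication
cycle.

The peak rule: a sample is a peak when it is the highest point around which
the signal drops by at least ``drop_threshold`` on both sides — i.e. a local
maximum whose topographic prominence reaches the threshold. By default the
threshold is expressed in units of the meal's robust signal amplitude (the
median over segments of half the 5th-95th percentile range) so the same
default works across renderers and cameras; raw-unit mode is available via
``normalize_amplitude``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import peak_prominences

from .bite_counting import BiteEvents
from .frames_io import ConfigError, InputError
from .optical_flow import FlowSeries

__all__ = [
    "PeakConfig",
    "ChewConfig",
    "ChewSegment",
    "MealSummary",
    "short_time_energy",
    "dynamic_threshold",
    "segment_between_bites",
    "count_peaks",
    "count_chews",
]

logger = logging.getLogger(__name__)

DEFAULT_MAX_SEGMENT_SECONDS = 52.0
DEFAULT_ENERGY_WINDOW_FRAMES = 6  # 1 s at 6 fps
DEFAULT_BETA = 0.5
DEFAULT_DROP_THRESHOLD = 0.5


@dataclass(frozen=True)
class PeakConfig:
    """Peak rule parameters: required drop on both sides, and a minimum
    spacing between counted peaks (1 = no spacing constraint)."""

    drop_threshold: float = DEFAULT_DROP_THRESHOLD
    min_separation_frames: int = 1

    def __post_init__(self) -> None:
        if self.drop_threshold <= 0:
            raise ConfigError("drop_threshold must be positive")
        if self.min_separation_frames < 1:
            raise ConfigError("min_separation_frames must be >= 1")


@dataclass(frozen=True)
class ChewConfig:
    """All chew-counting knobs, echoed into every summary."""

    max_segment_seconds: float = DEFAULT_MAX_SEGMENT_SECONDS
    energy_window_frames: int = DEFAULT_ENERGY_WINDOW_FRAMES
    beta: float = DEFAULT_BETA
    drop_threshold: float = DEFAULT_DROP_THRESHOLD
    min_separation_frames: int = 1
    normalize_amplitude: bool = True
    bridge_max_seconds: float = 1.0


@dataclass
class ChewSegment:
    """One candidate chewing segment with its energy gate decision."""

    start_frame: int
    end_frame: int
    energy: float
    active: bool
    peaks: list[int]
    chew_count: int

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise InputError("segment must be a non-empty half-open interval")
        if self.chew_count != len(self.peaks):
            raise InputError("chew_count must equal the number of peaks")
        if not self.active and self.chew_count != 0:
            raise InputError("inactive segments carry no chews")


@dataclass
class MealSummary:
    """Counted bites and chews for one meal, with per-segment detail."""

    n_bites: int
    n_chews: int
    segments: list[ChewSegment]
    config_echo: dict

    def __post_init__(self) -> None:
        if self.n_chews != sum(s.chew_count for s in self.segments):
            raise InputError("n_chews must equal the sum of segment chew counts")

    def segments_frame(self, fps: float):
        import pandas as pd
        return pd.DataFrame([
            {"start_s": s.start_frame / fps, "end_s": s.end_frame / fps,
             "mean_energy": s.energy, "active": s.active, "chew_count": s.chew_count}
            for s in self.segments
        ])


def short_time_energy(r_signal: np.ndarray, window_frames: int = DEFAULT_ENERGY_WINDOW_FRAMES,
                      hop: int = 1) -> np.ndarray:
    """Windowed sum of squared mean-removed signal values.

    ``E[k] = sum over window k of (r - mean(r_signal))**2`` with windows
    anchored every ``hop`` samples; the final window may be partial. The mean
    is the segment mean of the whole input, so a constant signal has zero
    energy everywhere.
    """
    if window_frames < 1:
        raise ConfigError("window_frames must be >= 1")
    if hop < 1:
        raise ConfigError("hop must be >= 1")
    r = np.asarray(r_signal, dtype=np.float64)
    if r.size == 0:
        return np.zeros(0)
    sq = (r - r.mean()) ** 2
    starts = np.arange(0, len(sq), hop)
    return np.array([sq[s:s + window_frames].sum() for s in starts])


def dynamic_threshold(all_segment_energies, beta: float = DEFAULT_BETA) -> float:
    """Meal-adaptive energy cutoff: ``beta`` times the median of the
    per-segment mean energies over the whole meal."""
    e = np.asarray(all_segment_energies, dtype=np.float64)
    if e.size == 0:
        raise ConfigError("dynamic_threshold needs at least one segment energy")
    return float(beta * np.median(e))


def segment_between_bites(flow: FlowSeries, bites: BiteEvents,
                          max_seconds: float = DEFAULT_MAX_SEGMENT_SECONDS
                          ) -> list[tuple[int, int]]:
    """Candidate chewing segments between consecutive bite events.

    One segment per consecutive bite pair, ``[end of bite k, start of bite
    k+1)``, plus the span after the final bite; each is truncated to the
    first ``max_seconds * fps`` samples. The span before the first bite is
    discarded (a chewing sequence follows a bite), as are segments containing
    only invalid flow samples.
    """
    n = len(flow)
    if bites.count == 0:
        logger.warning("no bite events; no chewing segments to score")
        return []
    cap = int(round(max_seconds * flow.fps))
    bounds = [(bites.events[k][1], bites.events[k + 1][0]) for k in range(bites.count - 1)]
    bounds.append((bites.events[-1][1], n))
    out = []
    for start, end in bounds:
        start, end = max(start, 0), min(end, n)
        if end <= start:
            continue
        end = min(end, start + cap)
        if not flow.valid[start:end].any():
            continue
        out.append((start, end))
    return out


def _local_maxima(s: np.ndarray) -> np.ndarray:
    """Indices i with s[i] > s[i-1] and s[i] >= s[i+1]; a plateau therefore
    contributes exactly its first index."""
    if len(s) < 3:
        return np.zeros(0, dtype=int)
    interior = np.arange(1, len(s) - 1)
    mask = (s[interior] > s[interior - 1]) & (s[interior] >= s[interior + 1])
    return interior[mask]


def count_peaks(segment_signal, cfg: PeakConfig = PeakConfig()) -> list[int]:
    """Peaks of a (median-centered) segment signal under the prominence rule.

    A local maximum counts when the signal falls by at least
    ``cfg.drop_threshold`` relative to it on both sides before reaching a
    higher sample (topographic prominence). When two counted peaks are closer
    than ``min_separation_frames``, the lower one is dropped.
    """
    s = np.asarray(segment_signal, dtype=np.float64)
    if len(s) < 3:
        return []
    cand = _local_maxima(s)
    if cand.size == 0:
        return []
    with warnings.catch_warnings():
        # flat shoulders legitimately carry zero prominence; they are filtered
        warnings.simplefilter("ignore")
        prom = peak_prominences(s, cand)[0]
    peaks = cand[prom >= cfg.drop_threshold]
    if cfg.min_separation_frames > 1 and len(peaks) > 1:
        kept: list[int] = []
        order = np.argsort(s[peaks])[::-1]  # highest first
        for i in order:
            if all(abs(int(peaks[i]) - k) >= cfg.min_separation_frames for k in kept):
                kept.append(int(peaks[i]))
        peaks = np.sort(kept)
    return [int(p) for p in peaks]


def _prepare_segments(flow: FlowSeries, segments: list[tuple[int, int]],
                      bridge_max: int) -> list[tuple[int, int, np.ndarray]]:
    """Interpolate short invalid runs inside each segment (<= bridge_max
    samples), split at longer ones, and return (start, end, signal) parts."""
    out = []
    for start, end in segments:
        r = flow.r_values[start:end]
        v = flow.valid[start:end]
        n = len(v)
        # invalid runs longer than bridge_max break the segment apart
        breaker = np.zeros(n, dtype=bool)
        i = 0
        while i < n:
            if v[i]:
                i += 1
                continue
            j = i
            while j < n and not v[j]:
                j += 1
            if j - i > bridge_max:
                breaker[i:j] = True
            i = j
        i = 0
        while i < n:
            if breaker[i]:
                i += 1
                continue
            j = i
            while j < n and not breaker[j]:
                j += 1
            vv = v[i:j]
            if vv.any():
                a = i + int(np.argmax(vv))          # first valid sample
                b = j - int(np.argmax(vv[::-1]))    # one past last valid sample
                sig = r[a:b].astype(np.float64).copy()
                m = v[a:b]
                if not m.all():  # bridge remaining short interior gaps
                    idx = np.arange(b - a)
                    sig = np.interp(idx, idx[m], sig[m])
                out.append((start + a, start + b, sig))
            i = j
    return out


def count_chews(flow: FlowSeries, bites: BiteEvents,
                cfg: ChewConfig = ChewConfig()) -> MealSummary:
    """Full chew count for one meal: segment, gate by energy, count peaks.

    Per-segment mean short-time energies feed the dynamic threshold ``T``;
    a segment is active iff its mean energy is at or above ``T``. Peaks are
    counted only in active segments, on the median-centered (and, by default,
    amplitude-normalized) signal.
    """
    raw_segments = segment_between_bites(flow, bites, cfg.max_segment_seconds)
    bridge_max = int(round(cfg.bridge_max_seconds * flow.fps))
    parts = _prepare_segments(flow, raw_segments, bridge_max)
    config_echo = asdict(cfg)
    if not parts:
        return MealSummary(n_bites=bites.count, n_chews=0, segments=[],
                           config_echo=config_echo)

    # meal-level robust amplitude: median over segments of the half 5th-95th
    # percentile range. (The interquartile range is too aggressive here: a
    # segment that is mostly rest has an IQR of ~0 even when it contains a
    # strong chewing burst, which would collapse the normalization.)
    drop = cfg.drop_threshold
    signals = [sig for _, _, sig in parts]
    if cfg.normalize_amplitude:
        spans = [0.5 * np.subtract(*np.percentile(sig, [95, 5])) for sig in signals]
        amp = float(np.median(spans))
        if amp > 0:
            signals = [sig / amp for sig in signals]

    energies = [float(np.mean(short_time_energy(sig, cfg.energy_window_frames)))
                for sig in signals]
    T = dynamic_threshold(energies, cfg.beta)

    segs: list[ChewSegment] = []
    pk_cfg = PeakConfig(drop_threshold=drop,
                        min_separation_frames=cfg.min_separation_frames)
    for (start, end, _), sig, e in zip(parts, signals, energies):
        active = e >= T
        peaks = [start + p for p in count_peaks(sig - np.median(sig), pk_cfg)] if active else []
        segs.append(ChewSegment(start_frame=start, end_frame=end, energy=e,
                                active=active, peaks=peaks, chew_count=len(peaks)))
    return MealSummary(n_bites=bites.count, n_chews=sum(s.chew_count for s in segs),
                       segments=segs, config_echo=config_echo)
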