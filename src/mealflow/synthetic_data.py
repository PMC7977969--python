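"""Synthetic meal fixtures with known ground truth.

Two levels of fidelity:

* :func:`signal_fixture` emits the 1-D signals the counting stages consume —
  a rotational-flow trace with a known number of sinusoidal chew cycles per
  segment, and per-frame bite labels optionally flipped with a given
  probability — bypassing rendering for fast tests of the counting logic.

* :func:`render_meal` renders an image sequence: a fixed random face texture
  whose lower half (the jaw, carrying a bright blob for localisation checks)
  rotates about a lateral hinge at the chewing frequency, with an occluder
  patch over the lower face during bite intervals and optional pixel noise.
  Rigid rotation is the simplest motion with a known analytic curl (2 * omega),
  matching the premise that jaw grinding is primarily rotational.

All randomness flows from the script's single seed through named generators;
the same script renders bit-identically every time.

What the generator does *not* emulate: talking, head translation, multiple
people in frame, photometric drift — the confounds a real meal video adds on
top of the modelled jaw kinematics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .bite_counting import BiteProbSeries
from .frames_io import ConfigError, FrameSequence
from .optical_flow import FlowSeries
from .roi_detection import BoundingBox

__all__ = [
    "MealScript",
    "GroundTruth",
    "default_script",
    "signal_fixture",
    "render_meal",
    "write_fixture",
    "read_fixture_ground_truth",
]

DEFAULT_FPS = 6.0


@dataclass
class MealScript:
    """Scripted study conditions for one synthetic meal.

    ``chews_per_segment`` has one entry per bite (each bite is followed by its
    chewing sequence, including the final bite). ``jaw_amplitude`` is the peak
    angular velocity of the jaw in radians per frame; the rotational-flow
    trace it induces has amplitude ``2 * jaw_amplitude``. ``noise_sigma`` is
    the additive Gaussian sigma on the signal trace (signal fixtures) or on
    pixel intensities in [0, 1] (rendered fixtures).
    """

    n_bites: int = 20
    bite_times_s: list[float] = field(default_factory=list)
    bite_duration_s: float = 2.0
    chews_per_segment: list[int] = field(default_factory=list)
    chew_freq_hz: float = 1.5          # well under the ~2 Hz chewing ceiling
    jaw_amplitude: float = 0.01
    noise_sigma: float = 0.0
    label_flip_p: float = 0.0
    detector_jitter_px: float = 0.0
    detector_dropout_p: float = 0.0
    seed: int = 42
    chew_onset_delay_s: float = 1.0    # food transport before mastication starts
    rest_s: float = 5.0                # idle tail after each chewing sequence
    lead_in_s: float = 3.0

    def __post_init__(self) -> None:
        for p in (self.label_flip_p, self.detector_dropout_p):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        if self.bite_times_s and any(b < a for a, b in
                                     zip(self.bite_times_s, self.bite_times_s[1:])):
            raise ConfigError("bite_times_s must be sorted ascending")
        if self.chews_per_segment and self.n_bites and \
                len(self.chews_per_segment) != self.n_bites:
            raise ConfigError("chews_per_segment needs one entry per bite")


@dataclass
class GroundTruth:
    """Everything the generator knows about the meal it emitted."""

    true_bite_events: list[tuple[int, int]]
    true_chew_count_total: int
    true_per_segment_counts: list[int]
    true_frame_labels: np.ndarray
    n_frames: int
    fps: float
    true_face_box: BoundingBox | None = None
    jaw_centroid: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if sum(self.true_per_segment_counts) != self.true_chew_count_total:
            raise ConfigError("per-segment counts must sum to the total")


def default_script(seed: int = 42, n_bites: int = 20,
                   chew_lo: int = 10, chew_hi: int = 25, **overrides) -> MealScript:
    """The standard study-conditions script: ``n_bites`` bites, each followed
    by a chewing sequence of 10-25 cycles at 1.5 Hz, with a 5-s rest tail."""
    rng = np.random.default_rng(seed)
    script = MealScript(n_bites=n_bites, seed=seed, **overrides)
    if not script.chews_per_segment:
        script.chews_per_segment = [int(c) for c in
                                    rng.integers(chew_lo, chew_hi + 1, size=n_bites)]
    if not script.bite_times_s:
        t = script.lead_in_s
        times = []
        for c in script.chews_per_segment:
            times.append(t)
            t += (script.bite_duration_s + script.chew_onset_delay_s
                  + c / script.chew_freq_hz + script.rest_s)
        script.bite_times_s = times
    return script


def _completed_script(script: MealScript) -> MealScript:
    if not script.bite_times_s or not script.chews_per_segment:
        return default_script(seed=script.seed, n_bites=script.n_bites,
                              **{k: getattr(script, k) for k in
                                 ("bite_duration_s", "chew_freq_hz", "jaw_amplitude",
                                  "noise_sigma", "label_flip_p", "detector_jitter_px",
                                  "detector_dropout_p", "chew_onset_delay_s",
                                  "rest_s", "lead_in_s")})
    return script


def _timeline(script: MealScript, fps: float):
    """Frame-level layout: labels, bite events, per-segment chew sinusoid."""
    last_end = (script.bite_times_s[-1] + script.bite_duration_s
                + script.chew_onset_delay_s
                + script.chews_per_segment[-1] / script.chew_freq_hz + script.rest_s)
    n = int(np.ceil(last_end * fps))
    labels = np.zeros(n, dtype=np.int8)
    events = []
    omega = np.zeros(n)  # jaw angular velocity per frame
    for t0, c in zip(script.bite_times_s, script.chews_per_segment):
        s = int(round(t0 * fps))
        e = int(round((t0 + script.bite_duration_s) * fps))
        e = min(max(e, s + 1), n)
        labels[s:e] = 1
        events.append((s, e))
        chew_start = int(round((t0 + script.bite_duration_s
                                + script.chew_onset_delay_s) * fps))
        n_chew = int(round(c * fps / script.chew_freq_hz))
        idx = np.arange(n_chew)
        stop = min(chew_start + n_chew, n)
        phase = 2 * np.pi * script.chew_freq_hz * idx / fps
        omega[chew_start:stop] = (script.jaw_amplitude * np.sin(phase))[:stop - chew_start]
    return n, labels, events, omega


def signal_fixture(script: MealScript, fps: float = DEFAULT_FPS
                   ) -> tuple[FlowSeries, BiteProbSeries, GroundTruth]:
    """Signal-level fixture: rotational trace + bite labels + ground truth.

    The rotational trace during chewing is ``2 * jaw_amplitude *
    sin(2 pi f t)`` — the curl a rigid jaw rotation of that angular velocity
    would induce — with one exact cycle per scripted chew when ``fps`` is an
    integer multiple of the chewing frequency. Bites add a large-amplitude
    transient spike; Gaussian noise of sigma ``noise_sigma`` rides on top.
    """
    script = _completed_script(script)
    rng = np.random.default_rng(np.random.SeedSequence([script.seed, 101]))
    n, labels, events, omega = _timeline(script, fps)

    r = 2.0 * omega
    for s, e in events:  # bite transient: one big swing of the flow value
        tt = np.arange(e - s)
        r[s:e] += 10.0 * script.jaw_amplitude * np.sin(2 * np.pi * tt / max(e - s, 1))
    if script.noise_sigma > 0:
        r = r + rng.normal(0.0, script.noise_sigma, size=n)

    flip = rng.random(n) < script.label_flip_p
    p = np.where(flip, 1 - labels, labels).astype(np.float64)

    flow = FlowSeries(r_values=r, frame_index=list(range(n)),
                      valid=np.ones(n, dtype=bool), fps=fps)
    probs = BiteProbSeries(p=p, frame_index=list(range(n)), fps=fps)
    gt = GroundTruth(true_bite_events=events,
                     true_chew_count_total=sum(script.chews_per_segment),
                     true_per_segment_counts=list(script.chews_per_segment),
                     true_frame_labels=labels, n_frames=n, fps=fps)
    return flow, probs, gt


# ---------------------------------------------------------------------------
# image-level rendering


def _face_texture(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    tex = gaussian_filter(rng.random((h, w)), sigma=2.0)
    lo, hi = tex.min(), tex.max()
    return 0.2 + 0.5 * (tex - lo) / (hi - lo)


def render_meal(script: MealScript, image_size: tuple[int, int] = (160, 130),
                fps: float = DEFAULT_FPS) -> tuple[FrameSequence, GroundTruth]:
    """Render the scripted meal as grayscale frames in [0, 1].

    The face occupies a fixed box; its lower half rotates rigidly about a
    lateral hinge by the cumulative scripted jaw angle, resampled bilinearly
    from the base texture each frame (no compounding of interpolation error).
    During bite intervals a bright occluder (the hand/utensil) covers part of
    the lower face. Deterministic given the script seed.
    """
    script = _completed_script(script)
    H, W = image_size
    fh, fw = int(H * 0.75), int(W * 0.62)
    fy, fx = (H - fh) // 2, (W - fw) // 2
    face_box = BoundingBox(x=fx, y=fy, w=fw, h=fh)

    rng = np.random.default_rng(np.random.SeedSequence([script.seed, 202]))
    n, labels, events, omega = _timeline(script, fps)
    theta = np.concatenate([[0.0], np.cumsum(omega)])[:n]
    if np.max(np.abs(theta)) > 0.5:
        raise ConfigError("cumulative jaw angle too large for the face geometry")

    base = np.full((H, W), 0.1)
    base[fy:fy + fh, fx:fx + fw] = _face_texture(rng, fh, fw)
    # bright jaw blob in the lower face half, for localisation checks
    jaw_cy, jaw_cx = fy + int(fh * 0.75), fx + int(fw * 0.5)
    yy, xx = np.mgrid[0:H, 0:W]
    blob = np.exp(-(((yy - jaw_cy) / 6.0) ** 2 + ((xx - jaw_cx) / 6.0) ** 2))
    base = np.clip(base + 0.25 * blob, 0.0, 1.0)

    # lower-half region rotates about a hinge at the rear of the jaw line
    jaw_top = fy + fh // 2
    hinge = (float(jaw_top), float(fx + 0.1 * fw))
    jy, jx = np.mgrid[jaw_top:fy + fh, fx:fx + fw]

    frames = []
    noise = (rng.normal(0.0, script.noise_sigma, size=(n, H, W))
             if script.noise_sigma > 0 else None)
    for i in range(n):
        frame = base.copy()
        th = theta[i]
        if th != 0.0:
            c, s = np.cos(th), np.sin(th)
            dy, dx = jy - hinge[0], jx - hinge[1]
            # content rotated by +th  =>  sample base at the -th rotation
            src_y = hinge[0] + c * dy + s * dx
            src_x = hinge[1] - s * dy + c * dx
            frame[jaw_top:fy + fh, fx:fx + fw] = map_coordinates(
                base, [src_y, src_x], order=1, mode="nearest")
        if labels[i]:
            oy, ox = fy + int(fh * 0.7), fx + int(fw * 0.55)
            frame[oy:min(oy + 18, H), ox:min(ox + 22, W)] = 0.95
        if noise is not None:
            frame = np.clip(frame + noise[i], 0.0, 1.0)
        frames.append(frame)

    seq = FrameSequence(frames=frames, frame_index=list(range(n)),
                        source_index=list(range(n)), fps=fps, native_fps=fps)
    gt = GroundTruth(true_bite_events=events,
                     true_chew_count_total=sum(script.chews_per_segment),
                     true_per_segment_counts=list(script.chews_per_segment),
                     true_frame_labels=labels, n_frames=n, fps=fps,
                     true_face_box=face_box,
                     jaw_centroid=[(float(jaw_cy), float(jaw_cx))] * n)
    return seq, gt


def write_fixture(frames: FrameSequence, gt: GroundTruth, out_dir: str | Path) -> None:
    """Write frames as zero-padded PNGs plus a ground_truth.json sidecar."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, f in zip(frames.frame_index, frames.frames):
        img = np.clip(np.asarray(f, dtype=np.float64), 0.0, 1.0)
        iio.imwrite(out / f"frame_{i:06d}.png", (img * 255).round().astype(np.uint8))
    data = {
        "fps": gt.fps,
        "n_frames": gt.n_frames,
        "true_bite_events": [list(e) for e in gt.true_bite_events],
        "true_chew_count_total": gt.true_chew_count_total,
        "true_per_segment_counts": list(gt.true_per_segment_counts),
        "true_frame_labels": [int(v) for v in gt.true_frame_labels],
        "true_face_box": (None if gt.true_face_box is None else
                          [gt.true_face_box.x, gt.true_face_box.y,
                           gt.true_face_box.w, gt.true_face_box.h]),
    }
    (out / "ground_truth.json").write_text(json.dumps(data, indent=2, sort_keys=True))


def read_fixture_ground_truth(fixture_dir: str | Path) -> GroundTruth:
    with open(Path(fixture_dir) / "ground_truth.json") as fh:
        data = json.load(fh)
    box = data.get("true_face_box")
    return GroundTruth(
        true_bite_events=[tuple(e) for e in data["true_bite_events"]],
        true_chew_count_total=data["true_chew_count_total"],
        true_per_segment_counts=data["true_per_segment_counts"],
        true_frame_labels=np.asarray(data["true_frame_labels"], dtype=np.int8),
        n_frames=data["n_frames"], fps=data["fps"],
        true_face_box=None if box is None else BoundingBox(*box),
    )
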