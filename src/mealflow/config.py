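"""Pipeline configuration: every threshold in one validated, echoable place."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from .frames_io import ConfigError

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline thresholds with their study defaults.

    The config is echoed verbatim into every summary so a run can be
    reproduced from its own output.
    """

    target_fps: float = 6.0
    min_confidence: float = 0.8
    crop_rows: int = 150
    crop_cols: int = 120
    smoothing_span: int = 10
    bite_threshold: float = 0.5
    min_event_frames: int = 1
    max_segment_seconds: float = 52.0
    energy_window_frames: int = 6
    beta: float = 0.5
    drop_threshold: float = 0.5
    normalize_amplitude: bool = True
    lk_window: int = 5
    normalize_intensity: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_fps <= 0:
            raise ConfigError("target_fps must be positive")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ConfigError("min_confidence must lie in [0, 1]")
        if self.crop_rows <= 0 or self.crop_cols <= 0:
            raise ConfigError("crop shape must be positive")
        if self.smoothing_span < 1:
            raise ConfigError("smoothing_span must be >= 1")
        if not 0.0 < self.bite_threshold < 1.0:
            raise ConfigError("bite_threshold must lie in (0, 1)")
        if self.max_segment_seconds <= 0:
            raise ConfigError("max_segment_seconds must be positive")
        if self.energy_window_frames < 1:
            raise ConfigError("energy_window_frames must be >= 1")
        if self.beta <= 0:
            raise ConfigError("beta must be positive")
        if self.drop_threshold <= 0:
            raise ConfigError("drop_threshold must be positive")
        if self.lk_window < 1 or self.lk_window % 2 == 0:
            raise ConfigError("lk_window must be odd and positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)
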