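"""Run configuration: every stage parameter in one serializable record."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """All pipeline stage parameters with their defaults.

    Units: lengths mm, times hours, angles radians, REGR h^-1.
    """

    schema_version: int = SCHEMA_VERSION
    # geometry / kinematics
    s_step: float = 0.1                # kymograph arc-length grid, mm
    dic_window: float = 2.0            # DIC correlation window, mm
    dic_search: float = 1.0            # DIC displacement search bound, mm
    dic_overlap: float = 0.75          # fractional window overlap
    dic_baseline: int = 2              # frame separation of correlated pairs
    smooth_window_mm: float = 1.5      # local-quadratic smoothing in s, mm
    regr_smooth_mm: float = 4.0        # velocity-derivative window for REGR, mm
    smooth_frames: int = 3             # temporal smoothing of curvature, frames
    rate_smooth_mm: float = 3.0        # curvature smoothing for DC/Dt path, mm
    rate_smooth_frames: int = 9        # temporal smoothing for DC/Dt path, frames
    # oscillations
    peak_quantile: float = 0.7
    link_max_gap: float = 0.75         # h
    link_max_jump: float = 8.0         # mm
    min_track_points: int = 5
    # morphometrics
    b_threshold: float = 2.8
    overshoot_delta: float = 0.02      # rad
    final_window_h: float = 2.0
    # summaries
    t_split: float = 12.0              # h
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def as_dict(self) -> dict:
        return asdict(self)
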