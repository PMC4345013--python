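"""Run configuration: every analysis threshold in one flat, checkable place.

Configs load from TOML (``key = value``, optionally grouped in sections —
section names are ignored and keys flattened).  Unknown keys are rejected so
typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass

from .errors import ConfigurationError
from .recognize import CalibrationInfo, RecognizerConfig
from .strides import StrideConfig
from .track import ArenaGeometry


@dataclass
class RunConfig:
    # calibration / acquisition
    mm_per_pixel: float = 0.045
    axis_orientation: int = 0
    frame_rate: float = 7.5
    # arena geometry (mm)
    plate_center_x: float = 0.0
    plate_center_y: float = 0.0
    plate_radius: float = 50.0
    ring_width: float = 15.0
    inside_margin_mm: float | None = None  # None -> half mean body length
    # recognizer
    threshold: float | None = None
    min_area_mm2: float = 0.8
    max_area_mm2: float = 10.0
    prune_fraction: float = 0.15
    max_stage_gap: int = 2
    invalid_warn_fraction: float = 0.2
    # kinematics
    speed_window_s: float = 0.5
    bend_threshold_deg: float = 45.0
    # strides
    smooth_window_s: float = 0.4
    min_prominence_mm: float | None = None  # None -> 3% of mean body length
    period_min_s: float = 0.4
    period_max_s: float = 5.0
    min_stride_displacement_mm: float = 0.1
    max_gap_s: float = 0.5
    # track
    path_smooth_s: float = 0.5
    sample_interval_s: float = 1.0
    turn_threshold_deg: float = 60.0
    # summary
    speed_mode: str = "per_frame"  # or "total_displacement"
    rng_seed: int = 0

    def __post_init__(self):
        if self.speed_mode not in ("per_frame", "total_displacement"):
            raise ConfigurationError(
                "speed_mode must be 'per_frame' or 'total_displacement'"
            )
        if not self.mm_per_pixel > 0:
            raise ConfigurationError("mm_per_pixel must be > 0")
        if not self.frame_rate > 0:
            raise ConfigurationError("frame_rate must be > 0")
        if not 0 < self.ring_width < self.plate_radius:
            raise ConfigurationError("need 0 < ring_width < plate_radius")
        if not self.period_min_s < self.period_max_s:
            raise ConfigurationError("need period_min_s < period_max_s")

    # ---- views onto the per-stage configs ---------------------------------
    @property
    def calibration(self) -> CalibrationInfo:
        return CalibrationInfo(self.mm_per_pixel, self.axis_orientation)

    @property
    def recognizer(self) -> RecognizerConfig:
        return RecognizerConfig(
            threshold=self.threshold,
            min_area_mm2=self.min_area_mm2,
            max_area_mm2=self.max_area_mm2,
            prune_fraction=self.prune_fraction,
            max_stage_gap=self.max_stage_gap,
            invalid_warn_fraction=self.invalid_warn_fraction,
        )

    @property
    def strides(self) -> StrideConfig:
        return StrideConfig(
            smooth_window_s=self.smooth_window_s,
            min_prominence_mm=self.min_prominence_mm,
            period_min_s=self.period_min_s,
            period_max_s=self.period_max_s,
            min_displacement_mm=self.min_stride_displacement_mm,
            max_gap_s=self.max_gap_s,
        )

    def arena(self, mean_body_length: float | None = None) -> ArenaGeometry:
        margin = self.inside_margin_mm
        if margin is None:
            margin = 0.5 * mean_body_length if mean_body_length else 2.0
        return ArenaGeometry(
            plate_center=(self.plate_center_x, self.plate_center_y),
            plate_radius=self.plate_radius,
            ring_width=self.ring_width,
            inside_margin=margin,
        )

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat: dict = {}
        for key, value in raw.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(flat) - known)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**flat)
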