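"""Midline pose containers and the tabular interchange formats.

Conventions used throughout the package:

* Image origin is the top-left pixel, pixel centers at integer coordinates,
  pixel y pointing down.
* The plate frame is in millimetres with x to the right, y up and the origin
  at the plate centre.
* Times are seconds from the first frame; frames are sampled at a fixed rate.

A pose is 13 ordered points along the animal's midline, head first: point 1
is the head tip, point 7 the body centre and point 13 the tail tip (0-based
indices 0, 6 and 12 in code).  Invalid frames carry NaN coordinates and a
``valid`` flag of False; downstream statistics skip them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PointsFileError

N_POINTS = 13
HEAD = 0
CENTER = 6
TAIL = 12

#: columns of the points interchange table, in order
POINTS_COLUMNS = ["frame_index", "time_s", "valid"] + [
    f"{axis}{k}" for k in range(1, N_POINTS + 1) for axis in ("x", "y")
]

STAGE_COLUMNS = ["frame_index", "time_s", "stage_x_mm", "stage_y_mm"]


@dataclass
class MidlinePose:
    """A single frame's midline in plate coordinates (mm)."""

    frame_index: int
    time: float
    points: np.ndarray | None  # (13, 2) mm, head first; None when invalid
    valid: bool = True
    reason: str | None = None  # why the frame is invalid, if it is

    def __post_init__(self):
        if self.valid and (self.points is None or np.shape(self.points) != (N_POINTS, 2)):
            raise ValueError("a valid pose requires 13 (x, y) points")
        if not self.valid:
            self.points = None


@dataclass
class PoseSeries:
    """Time-ordered midline poses at a fixed frame rate.

    ``points`` is an (n, 13, 2) array in mm with NaN rows where ``valid`` is
    False.  ``reasons`` maps frame index -> failure reason for invalid frames.
    """

    times: np.ndarray
    points: np.ndarray
    valid: np.ndarray
    frame_rate: float
    orientation_confidence: float = 1.0
    reasons: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.times)
        if self.points.shape != (n, N_POINTS, 2):
            raise ValueError(f"points must have shape ({n}, {N_POINTS}, 2)")
        if self.valid.shape != (n,):
            raise ValueError("valid must be one flag per frame")
        self.points = self.points.copy()
        self.points[~self.valid] = np.nan

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def center(self) -> np.ndarray:
        """(n, 2) trajectory of the body centre (point 7)."""
        return self.points[:, CENTER, :]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def __len__(self) -> int:
        return self.n_frames


def write_points_tsv(series: PoseSeries, path) -> None:
    """Write the points table: one row per frame, 13 (x, y) pairs in mm."""
    n = series.n_frames
    data = {
        "frame_index": np.arange(n, dtype=int),
        "time_s": series.times,
        "valid": series.valid.astype(int),
    }
    flat = series.points.reshape(n, -1)
    for j, name in enumerate(POINTS_COLUMNS[3:]):
        data[name] = flat[:, j]
    pd.DataFrame(data, columns=POINTS_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_points_tsv(path, frame_rate: float | None = None) -> PoseSeries:
    """Read a points table back into a :class:`PoseSeries`.

    The frame rate is inferred from the time column unless given explicitly.
    Malformed tables raise :class:`PointsFileError` naming the first bad line.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise PointsFileError(f"cannot parse points file {path}: {exc}") from exc
    missing = [c for c in POINTS_COLUMNS if c not in df.columns]
    if missing:
        raise PointsFileError(
            f"points file {path} lacks columns {missing}", line=1
        )
    bad = df["frame_index"].isna() | df["time_s"].isna() | df["valid"].isna()
    if bad.any():
        # +2: 1-based line numbers and a header row
        raise PointsFileError(
            f"points file {path} has malformed rows", line=int(bad.idxmax()) + 2
        )
    n = len(df)
    if n == 0:
        raise PointsFileError(f"points file {path} is empty")
    times = df["time_s"].to_numpy(float)
    valid = df["valid"].to_numpy(int).astype(bool)
    pts = df[POINTS_COLUMNS[3:]].to_numpy(float).reshape(n, N_POINTS, 2)
    incomplete = np.isnan(pts).any(axis=(1, 2))
    valid = valid & ~incomplete
    if frame_rate is None:
        if n < 2:
            raise PointsFileError(
                f"points file {path} has one frame; pass frame_rate explicitly"
            )
        dt = np.median(np.diff(times))
        if not dt > 0:
            raise PointsFileError(f"points file {path} has a non-increasing time axis")
        frame_rate = 1.0 / dt
    return PoseSeries(times=times, points=pts, valid=valid, frame_rate=float(frame_rate))


def write_stage_log(df: pd.DataFrame, path) -> None:
    df[STAGE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_stage_log(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise PointsFileError(f"cannot parse stage log {path}: {exc}") from exc
    missing = [c for c in STAGE_COLUMNS if c not in df.columns]
    if missing:
        raise PointsFileError(f"stage log {path} lacks columns {missing}", line=1)
    return df[STAGE_COLUMNS].astype(float)
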