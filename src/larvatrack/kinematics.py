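"""Per-frame shape and motion measures.

Body length is the chordal length of the 13-point midline.  Speeds are
central differences of point positions over a short window.  The head angle
is the bend of the head chord (point 3 -> point 1) against the anterior body
chord (point 7 -> point 3); the body angle is the deviation from straight of
the two body halves seen from the centre point (180 deg minus the interior
angle at point 7).  Both are unsigned magnitudes in [0, 180] degrees; the
animal is "bending" when either exceeds the 45-degree threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pose import HEAD, CENTER, TAIL, N_POINTS, PoseSeries

__all__ = [
    "body_length",
    "point_speeds",
    "head_body_angles",
    "bending_flags",
    "frame_metrics",
]

BEND_THRESHOLD_DEG = 45.0


def body_length(points: np.ndarray) -> np.ndarray:
    """Sum of the 12 inter-point distances; works on (..., 13, 2) arrays."""
    seg = np.linalg.norm(np.diff(points, axis=-2), axis=-1)
    return seg.sum(axis=-1)


def point_speeds(series: PoseSeries, window_s: float = 0.5) -> np.ndarray:
    """(n, 13) instantaneous speeds in mm/s by centered differencing.

    The displacement of each point over the window is divided by the elapsed
    time; frames whose window touches an invalid frame (or the series edge)
    are NaN.  ``window_s`` must span at least two frames.
    """
    h = int(round(window_s * series.frame_rate / 2))
    if h < 1:
        raise ValueError("speed window must span at least 2 frames")
    n = series.n_frames
    out = np.full((n, N_POINTS), np.nan)
    if n <= 2 * h:
        return out
    disp = series.points[2 * h:] - series.points[:-2 * h]
    dt = series.times[2 * h:] - series.times[:-2 * h]
    out[h:n - h] = np.linalg.norm(disp, axis=-1) / dt[:, None]
    return out


def _vec_angle_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    dot = (u * v).sum(axis=-1)
    cross = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    return np.degrees(np.abs(np.arctan2(cross, dot)))


def head_body_angles(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(head_angle, body_angle) in degrees for (..., 13, 2) poses.

    Zero-length chords (degenerate poses) give NaN.
    """
    p = np.asarray(points, dtype=float)
    head_chord = p[..., 0, :] - p[..., 2, :]       # point 3 -> point 1
    ant_chord = p[..., 2, :] - p[..., CENTER, :]   # point 7 -> point 3
    head = _vec_angle_deg(head_chord, ant_chord)
    a = p[..., HEAD, :] - p[..., CENTER, :]
    b = p[..., TAIL, :] - p[..., CENTER, :]
    body = 180.0 - _vec_angle_deg(a, b)
    for ang, chords in ((head, (head_chord, ant_chord)), (body, (a, b))):
        degenerate = np.zeros(np.shape(ang), dtype=bool)
        for c in chords:
            degenerate |= np.linalg.norm(c, axis=-1) < 1e-12
        if np.any(degenerate):
            ang[degenerate] = np.nan
    return head, body


def bending_flags(
    head_angle: np.ndarray,
    body_angle: np.ndarray,
    threshold: float = BEND_THRESHOLD_DEG,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Strictly-over-threshold head/body bending flags and their OR."""
    head_bending = np.asarray(head_angle) > threshold
    body_bending = np.asarray(body_angle) > threshold
    return head_bending, body_bending, head_bending | body_bending


def frame_metrics(
    series: PoseSeries,
    speed_window_s: float = 0.5,
    bend_threshold: float = BEND_THRESHOLD_DEG,
) -> pd.DataFrame:
    """Per-frame metrics table; invalid frames carry NaN rows.

    Columns: time_s, length_mm, speed_p1..speed_p13 (mm/s), head_angle_deg,
    body_angle_deg, head_bending, body_bending, bending.  The ``striding``
    and ``inside`` columns are added later by the stride and track stages.
    """
    lengths = body_length(series.points)
    speeds = point_speeds(series, speed_window_s)
    head, body = head_body_angles(series.points)
    hb, bb, bend = bending_flags(head, body, bend_threshold)
    data = {"time_s": series.times, "valid": series.valid, "length_mm": lengths}
    for k in range(N_POINTS):
        data[f"speed_p{k + 1}"] = speeds[:, k]
    data["head_angle_deg"] = head
    data["body_angle_deg"] = body
    # flags on invalid frames are meaningless; store as float NaN-able columns
    data["head_bending"] = np.where(np.isnan(head), np.nan, hb.astype(float))
    data["body_bending"] = np.where(np.isnan(body), np.nan, bb.astype(float))
    data["bending"] = np.where(np.isnan(head) | np.isnan(body), np.nan, bend.astype(float))
    return pd.DataFrame(data)
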