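"""Track-level measures: path distance, direction changes, inside/outside.

The track is the trajectory of the body centre (point 7) in plate
coordinates.  Total distance is the summed step length of the lightly
smoothed track; direction changes are sampled at a fixed interval and
counted where the turning angle between incoming and outgoing displacement
exceeds a threshold; the inside/outside partition separates time away from
versus close to or on the ring that lines the plate rim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ArenaGeometry",
    "TrackSummary",
    "path_distance",
    "direction_changes",
    "inside_mask",
    "plot_track",
]


@dataclass
class ArenaGeometry:
    """Circular plate with a ring on the outer rim (all mm)."""

    plate_center: tuple[float, float] = (0.0, 0.0)
    plate_radius: float = 50.0
    ring_width: float = 15.0
    inside_margin: float = 2.0  # typically half a body length

    def __post_init__(self):
        if not 0 < self.ring_width < self.plate_radius:
            raise ValueError("need 0 < ring_width < plate_radius")

    @property
    def inner_radius(self) -> float:
        """Radius of the ring's inner edge."""
        return self.plate_radius - self.ring_width

    @property
    def inside_radius(self) -> float:
        """Animals closer to the centre than this count as 'inside'."""
        return self.inner_radius - self.inside_margin


@dataclass
class TrackSummary:
    distance_mm: float
    distance_mm_per_min: float
    direction_change_fraction: float
    time_inside_fraction: float
    inside: np.ndarray           # per-frame flags (NaN-invalid frames False)
    change_points: pd.DataFrame  # subsampled track with turn angles and flags


def _smooth_track(center: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return center
    if window % 2 == 0:
        window += 1
    out = center.copy()
    valid = ~np.isnan(center[:, 0])
    idx = np.nonzero(valid)[0]
    if len(idx) == 0:
        return out
    splits = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[splits + 1]])
    ends = np.concatenate([idx[splits] + 1, [idx[-1] + 1]])
    for i0, i1 in zip(starts, ends):
        block = center[i0:i1]
        w = min(window, len(block) if len(block) % 2 == 1 else len(block) - 1)
        if w <= 1:
            continue
        pad = w // 2
        for ax in range(2):
            x = block[:, ax]
            padded = np.concatenate([x[pad:0:-1], x, x[-2:-2 - pad:-1]])
            out[i0:i1, ax] = np.convolve(padded, np.ones(w) / w, mode="valid")
    return out


def path_distance(
    center: np.ndarray,
    times: np.ndarray,
    frame_rate: float,
    smooth_window_s: float = 0.5,
) -> tuple[float, float]:
    """Total centre-point path length in mm and its per-minute rate.

    Steps across invalid-frame gaps are not counted; the rate divides by the
    valid observation time.  Needs at least 2 valid frames.
    """
    valid = ~np.isnan(np.asarray(center)[:, 0])
    if valid.sum() < 2:
        raise ValueError("path_distance needs at least 2 valid frames")
    window = int(round(smooth_window_s * frame_rate))
    sm = _smooth_track(np.asarray(center, dtype=float), window)
    consecutive = valid[:-1] & valid[1:]
    steps = np.linalg.norm(np.diff(sm, axis=0), axis=-1)
    total = float(steps[consecutive].sum())
    minutes = valid.sum() / frame_rate / 60.0
    return total, total / minutes


def direction_changes(
    center: np.ndarray,
    times: np.ndarray,
    sample_interval_s: float = 1.0,
    turn_threshold_deg: float = 60.0,
) -> tuple[float, pd.DataFrame]:
    """Fraction of subsampled track points where the animal turns sharply.

    The track is subsampled at ``sample_interval_s``; at each interior
    sample the turning angle between the incoming and outgoing displacement
    vectors is compared with the threshold.  Degenerate zero-displacement
    segments are skipped.  Requires at least 3 samples.
    """
    center = np.asarray(center, dtype=float)
    times = np.asarray(times, dtype=float)
    valid = ~np.isnan(center[:, 0])
    targets = np.arange(times[0], times[-1] + 1e-9, sample_interval_s)
    samples = []
    for tt in targets:
        cand = np.nonzero(valid)[0]
        if len(cand) == 0:
            break
        j = cand[np.argmin(np.abs(times[cand] - tt))]
        if not samples or j != samples[-1]:
            samples.append(int(j))
    if len(samples) < 3:
        raise ValueError("direction_changes needs a track spanning >= 3 samples")
    pts = center[samples]
    rows = []
    turns = 0
    interior = 0
    for i in range(1, len(samples) - 1):
        u = pts[i] - pts[i - 1]
        v = pts[i + 1] - pts[i]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-9 or nv < 1e-9:
            continue
        cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
        ang = float(np.degrees(np.arccos(cosang)))
        is_turn = ang > turn_threshold_deg
        interior += 1
        turns += is_turn
        rows.append((times[samples[i]], pts[i, 0], pts[i, 1], ang, is_turn))
    frame = pd.DataFrame(rows, columns=["time_s", "x_mm", "y_mm", "turn_deg", "is_change"])
    fraction = turns / interior if interior else float("nan")
    return fraction, frame


def inside_mask(center: np.ndarray, arena: ArenaGeometry) -> tuple[np.ndarray, float]:
    """Per-frame 'away from the ring' flags and the time-inside fraction.

    A frame is inside iff the centre point lies closer to the plate centre
    than ``inner_radius - inside_margin``.  Points beyond the plate radius
    are physically suspect and counted as outside.  The fraction is over
    valid frames only.
    """
    center = np.asarray(center, dtype=float)
    r = np.linalg.norm(center - np.asarray(arena.plate_center), axis=-1)
    valid = ~np.isnan(r)
    inside = np.zeros(len(center), dtype=bool)
    inside[valid] = r[valid] < arena.inside_radius
    fraction = float(inside[valid].mean()) if valid.any() else float("nan")
    return inside, fraction


def summarize_track(
    center: np.ndarray,
    times: np.ndarray,
    frame_rate: float,
    arena: ArenaGeometry,
    smooth_window_s: float = 0.5,
    sample_interval_s: float = 1.0,
    turn_threshold_deg: float = 60.0,
) -> TrackSummary:
    total, per_min = path_distance(center, times, frame_rate, smooth_window_s)
    frac, changes = direction_changes(center, times, sample_interval_s, turn_threshold_deg)
    inside, t_inside = inside_mask(center, arena)
    return TrackSummary(
        distance_mm=total,
        distance_mm_per_min=per_min,
        direction_change_fraction=frac,
        time_inside_fraction=t_inside,
        inside=inside,
        change_points=changes,
    )


def plot_track(summary: TrackSummary, center: np.ndarray, arena: ArenaGeometry, path) -> None:
    """Write a track image: the path, the ring and red direction changes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    theta = np.linspace(0, 2 * np.pi, 256)
    cx, cy = arena.plate_center
    for radius, color in ((arena.plate_radius, "0.4"), (arena.inner_radius, "0.7")):
        ax.plot(cx + radius * np.cos(theta), cy + radius * np.sin(theta), color=color, lw=1)
    ax.plot(center[:, 0], center[:, 1], "-", color="tab:blue", lw=0.8)
    ch = summary.change_points
    marked = ch[ch["is_change"]]
    ax.plot(marked["x_mm"], marked["y_mm"], "o", color="red", ms=3)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
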