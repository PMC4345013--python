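"""Frame-to-midline recognition: binarize, skeletonize, resample, map to plate.

Each grayscale frame is thresholded (the animal is dark on a light
background), reduced to its largest connected component, skeletonized, and
pruned to a single endpoint-to-endpoint path.  The path is extended to the
body tips (discrete skeletons stop roughly half a body-width short of each
end), resampled to 13 points at equal arc-length fractions, disambiguated
head-from-tail over time, and mapped into plate coordinates with the stage
log and the mm/pixel calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .errors import EmptySeriesError, TopologyError
from .pose import N_POINTS, PoseSeries

log = logging.getLogger(__name__)

__all__ = [
    "CalibrationInfo",
    "RecognizerConfig",
    "binarize_frame",
    "extract_skeleton",
    "resample_midline",
    "orient_head_tail",
    "to_plate_coords",
    "recognize_video",
]

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

#: image-axis -> plate-axis mappings (the four axis-aligned choices), as
#: (x_mm, y_mm) = M @ (dx_px, dy_px) * mm_per_pixel with dx, dy measured from
#: the image centre (pixel y down).  Orientation 0 is the default: image x
#: right = plate x right, image y down = plate y down... negated to y-up.
_AXIS_MAPS = {
    0: np.array([[1.0, 0.0], [0.0, -1.0]]),
    1: np.array([[0.0, 1.0], [1.0, 0.0]]),
    2: np.array([[-1.0, 0.0], [0.0, 1.0]]),
    3: np.array([[0.0, -1.0], [-1.0, 0.0]]),
}


@dataclass
class CalibrationInfo:
    """Pixel-to-plate mapping: scale plus one of 4 axis-aligned orientations."""

    mm_per_pixel: float
    axis_orientation: int = 0

    def __post_init__(self):
        if not self.mm_per_pixel > 0:
            raise ValueError("mm_per_pixel must be > 0")
        if self.axis_orientation not in _AXIS_MAPS:
            raise ValueError("axis_orientation must be one of 0, 1, 2, 3")

    @property
    def matrix(self) -> np.ndarray:
        return _AXIS_MAPS[self.axis_orientation] * self.mm_per_pixel


@dataclass
class RecognizerConfig:
    threshold: float | None = None      # fixed gray threshold; None = Otsu per frame
    min_area_mm2: float = 0.8           # plausible worm area bounds
    max_area_mm2: float = 10.0
    prune_fraction: float = 0.15        # branches shorter than this fraction of
                                        # the skeleton are spurious
    max_stage_gap: int = 2              # frames of missing stage data to interpolate
    invalid_warn_fraction: float = 0.2  # flag the video above this invalid rate


def binarize_frame(
    gray: np.ndarray, mm_per_pixel: float, config: RecognizerConfig | None = None
) -> tuple[np.ndarray | None, str | None]:
    """Threshold one frame and keep the single worm-sized dark component.

    Returns ``(mask, None)`` on success or ``(None, reason)`` when no
    component of plausible area exists (the frame is then carried as a gap).
    """
    cfg = config or RecognizerConfig()
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("binarize_frame expects a single-channel image")
    if gray.max() == gray.min():
        return None, "empty"
    thr = cfg.threshold if cfg.threshold is not None else threshold_otsu(gray)
    # dark animal on light background: foreground is the low side (inclusive,
    # so a pure black-on-white frame thresholds at 0 and keeps the animal)
    fg = gray <= thr
    if not fg.any():
        return None, "empty"
    labels, n_labels = ndi.label(fg)
    if n_labels == 0:
        return None, "empty"
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_labels + 1))
    biggest = int(np.argmax(sizes)) + 1
    mask = ndi.binary_fill_holes(labels == biggest)
    area_mm2 = mask.sum() * mm_per_pixel**2
    if not cfg.min_area_mm2 <= area_mm2 <= cfg.max_area_mm2:
        return None, "area"
    return mask, None


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    kernel = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
    return ndi.convolve(skel.astype(np.uint8), kernel, mode="constant")


def _walk_branch(pixels: set, start, counts_at) -> list:
    """Walk from an endpoint until a junction (or the far end); return pixels."""
    branch = [start]
    prev = None
    cur = start
    while True:
        nxt = [
            (cur[0] + dr, cur[1] + dc)
            for dr, dc in _NEIGHBORS
            if (cur[0] + dr, cur[1] + dc) in pixels and (cur[0] + dr, cur[1] + dc) != prev
        ]
        nxt = [p for p in nxt if p not in branch]
        if len(nxt) != 1 or counts_at(cur) >= 3:
            return branch
        prev, cur = cur, nxt[0]
        if counts_at(cur) >= 3:
            return branch
        branch.append(cur)


def _order_path(pixels: set, start) -> list:
    path = [start]
    seen = {start}
    cur = start
    while True:
        cands = [
            (cur[0] + dr, cur[1] + dc)
            for dr, dc in _NEIGHBORS
            if (cur[0] + dr, cur[1] + dc) in pixels and (cur[0] + dr, cur[1] + dc) not in seen
        ]
        if not cands:
            return path
        if len(cands) > 1:
            # prefer 4-connected continuation, then the straightest one
            cands.sort(key=lambda p: abs(p[0] - cur[0]) + abs(p[1] - cur[1]))
        cur = cands[0]
        path.append(cur)
        seen.add(cur)


def extract_skeleton(
    mask: np.ndarray, prune_fraction: float = 0.15
) -> np.ndarray:
    """Skeletonize a worm mask into an ordered (n, 2) path of (x, y) pixels.

    Spurious side branches shorter than ``prune_fraction`` of the skeleton
    are removed until exactly two endpoints remain; the path is then ordered
    endpoint-to-endpoint and each end is extended along its tangent to the
    body tip (stopping one local medial radius short of the mask boundary).
    Raises :class:`TopologyError` when no endpoint-to-endpoint path exists
    (loops, blobs, self-touching bodies).
    """
    skel = skeletonize(mask)
    pixels = {tuple(p) for p in np.argwhere(skel)}
    if len(pixels) < 3:
        raise TopologyError("skeleton too small to carry a midline")

    def counts_at(p):
        return sum((p[0] + dr, p[1] + dc) in pixels for dr, dc in _NEIGHBORS)

    while True:
        endpoints = [p for p in pixels if counts_at(p) == 1]
        if len(endpoints) == 2:
            break
        if len(endpoints) < 2:
            raise TopologyError("skeleton has no open ends (loop or blob)")
        branches = [_walk_branch(pixels, ep, counts_at) for ep in endpoints]
        branches.sort(key=len)
        shortest = branches[0]
        if len(shortest) > prune_fraction * len(pixels):
            raise TopologyError("cannot prune skeleton to two endpoints")
        pixels -= set(shortest)
        if len(pixels) < 3:
            raise TopologyError("skeleton vanished during pruning")

    path = _order_path(pixels, endpoints[0])
    if path[-1] != endpoints[1] or len(path) < 0.9 * len(pixels):
        raise TopologyError("skeleton path does not span endpoint to endpoint")

    rc = np.asarray(path, dtype=float)           # (n, 2) as (row, col)
    xy = _smooth_path(rc[:, ::-1].copy())        # (x=col, y=row)
    edt = ndi.distance_transform_edt(mask)
    head_ext = _extend_end(xy, mask, edt, front=True)
    tail_ext = _extend_end(xy, mask, edt, front=False)
    return np.vstack([head_ext[::-1], xy, tail_ext])


def _smooth_path(xy: np.ndarray, half_window: int = 4) -> np.ndarray:
    """Moving-average the ordered pixel path to suppress staircase jitter.

    Raw 8-connected paths overestimate arc length anisotropically (axis steps
    count 1, diagonal steps sqrt(2)), which would make equal-arc resampling
    locally uneven.  The window shrinks toward the ends so the endpoints are
    preserved exactly.
    """
    n = len(xy)
    if n < 3:
        return xy
    out = np.empty_like(xy)
    for i in range(n):
        w = min(half_window, i, n - 1 - i)
        out[i] = xy[i - w:i + w + 1].mean(axis=0)
    return out


def _extend_end(xy: np.ndarray, mask: np.ndarray, edt: np.ndarray, front: bool) -> np.ndarray:
    """Extend one end of the path toward the body tip along the local tangent.

    The discrete skeleton of a rounded body ends about one half-width short
    of the tip; walking to the mask boundary would overshoot by the cap
    radius, so the extension stops one medial radius (EDT at the endpoint)
    short of the boundary.
    """
    if front:
        end = xy[0]
        ref = xy[min(5, len(xy) - 1)]
    else:
        end = xy[-1]
        ref = xy[max(0, len(xy) - 1 - 5)]
    tangent = end - ref
    norm = np.linalg.norm(tangent)
    if norm < 1e-9:
        return np.empty((0, 2))
    tangent /= norm
    r_end = edt[int(round(end[1])), int(round(end[0]))]
    h, w = mask.shape
    step = 0.5
    pts = []
    dist = 0.0
    while True:
        dist += step
        p = end + dist * tangent
        col, row = int(round(p[0])), int(round(p[1]))
        if not (0 <= row < h and 0 <= col < w) or not mask[row, col]:
            break
        pts.append(p)
        if dist > 4 * r_end + 4:
            break
    # Rounded tip vs square-cut end: near a rounded apex the body narrows to
    # a point, while a square end (e.g. a rectangular bar) keeps its full
    # width right up to the wall.  Probe the lateral half-width just before
    # the exit: wide means square (extend to the boundary), narrow means a
    # cap (the true tip sits one medial radius short of the boundary).
    if pts:
        perp = np.array([-tangent[1], tangent[0]])
        probe = end + max(dist - 1.0, 0.0) * tangent
        half_w = 0.0
        for sgn in (1.0, -1.0):
            d = 0.0
            while d < 4 * r_end + 4:
                d += step
                q = probe + sgn * d * perp
                col, row = int(round(q[0])), int(round(q[1]))
                if not (0 <= row < h and 0 <= col < w) or not mask[row, col]:
                    break
            half_w += (d - step) / 2.0
        if half_w >= 0.7 * r_end:
            keep = dist
        else:
            keep = max(0.0, dist - r_end)
    else:
        keep = 0.0
    return np.array([p for j, p in enumerate(pts) if (j + 1) * step <= keep]).reshape(-1, 2)


def resample_midline(path: np.ndarray, n: int = N_POINTS) -> np.ndarray:
    """Resample an ordered path to ``n`` points at equal arc-length fractions.

    The curve is divided into ``n - 1`` segments of equal length; the points
    are the segment ends, with the curve endpoints preserved.
    """
    if n < 2:
        raise ValueError("resample_midline needs n >= 2")
    path = np.asarray(path, dtype=float)
    if len(path) < 2:
        raise ValueError("path must contain at least 2 points")
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] <= 0:
        raise ValueError("path has zero arc length")
    targets = np.linspace(0.0, arc[-1], n)
    return np.stack(
        [np.interp(targets, arc, path[:, 0]), np.interp(targets, arc, path[:, 1])],
        axis=1,
    )


def orient_head_tail(series: PoseSeries, speed_window_s: float = 0.5) -> PoseSeries:
    """Make endpoint labels temporally continuous and put the head first.

    Frame-to-frame, the point order (forward or reversed) that minimizes the
    summed displacement against the previous valid pose is kept.  Globally,
    the end with the larger mean instantaneous speed is called the head —
    during peristalsis head and tail speeds alternate symmetrically, but
    pause-time head sweeps make the head end strictly faster on average.
    ``orientation_confidence`` is the relative speed margin (0 when the
    choice was arbitrary, e.g. a single frame).
    """
    if series.n_valid == 0:
        raise EmptySeriesError("orient_head_tail needs at least one valid pose")
    pts = series.points.copy()
    vidx = np.nonzero(series.valid)[0]
    for a, b in zip(vidx[:-1], vidx[1:]):
        fwd = np.linalg.norm(pts[b] - pts[a], axis=1).sum()
        rev = np.linalg.norm(pts[b][::-1] - pts[a], axis=1).sum()
        if rev < fwd:
            pts[b] = pts[b][::-1]
    conf = 0.0
    if len(vidx) >= 3:
        h = max(1, int(round(speed_window_s * series.frame_rate / 2)))
        dt = 2 * h / series.frame_rate
        sp = []
        for end in (0, N_POINTS - 1):
            track = pts[:, end, :]
            disp = np.linalg.norm(track[2 * h:] - track[:-2 * h], axis=1) / dt
            sp.append(np.nanmean(disp))
        v_first, v_last = sp
        if np.isfinite(v_first) and np.isfinite(v_last) and v_first + v_last > 0:
            conf = abs(v_first - v_last) / (v_first + v_last)
            if v_last > v_first:
                pts = pts[:, ::-1, :]
    return PoseSeries(
        times=series.times,
        points=pts,
        valid=series.valid,
        frame_rate=series.frame_rate,
        orientation_confidence=float(conf),
        reasons=dict(series.reasons),
    )


def to_plate_coords(
    points_px: np.ndarray,
    stage_mm: np.ndarray,
    calibration: CalibrationInfo,
    image_shape: tuple[int, int],
) -> np.ndarray:
    """Map pixel points of one frame to plate mm: stage + oriented offset."""
    h, w = image_shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    offsets = (np.asarray(points_px, dtype=float) - center) @ calibration.matrix.T
    return np.asarray(stage_mm, dtype=float) + offsets


def _stage_for_frames(stage_log: pd.DataFrame, n_frames: int, max_gap: int):
    """Per-frame stage positions; short gaps interpolated, long gaps -> None."""
    idx = stage_log["frame_index"].to_numpy(int)
    sx = stage_log["stage_x_mm"].to_numpy(float)
    sy = stage_log["stage_y_mm"].to_numpy(float)
    order = np.argsort(idx)
    idx, sx, sy = idx[order], sx[order], sy[order]
    out = [None] * n_frames
    have = set(idx.tolist())
    for i in range(n_frames):
        if i in have:
            j = int(np.searchsorted(idx, i))
            out[i] = np.array([sx[j], sy[j]])
            continue
        lo = idx[idx < i]
        hi = idx[idx > i]
        if len(lo) == 0 or len(hi) == 0:
            continue
        gap = hi.min() - lo.max() - 1
        if gap <= max_gap:
            x = np.interp(i, idx, sx)
            y = np.interp(i, idx, sy)
            out[i] = np.array([x, y])
    return out


def recognize_video(
    frames,
    stage_log: pd.DataFrame,
    calibration: CalibrationInfo,
    config: RecognizerConfig | None = None,
    frame_rate: float = 7.5,
) -> PoseSeries:
    """Run the full per-frame pipeline over a sequence of grayscale frames.

    Frames that fail any stage are carried as gaps with a reason code
    (``empty``, ``area``, ``topology``, ``stage_gap``, ``spacing``); a video
    with more than ``invalid_warn_fraction`` invalid frames is logged as
    suspect.  Returns an oriented :class:`PoseSeries` in plate coordinates.
    """
    cfg = config or RecognizerConfig()
    n = len(frames)
    stage = _stage_for_frames(stage_log, n, cfg.max_stage_gap)
    points = np.full((n, N_POINTS, 2), np.nan)
    valid = np.zeros(n, dtype=bool)
    reasons: dict[int, str] = {}
    for i, frame in enumerate(frames):
        if stage[i] is None:
            reasons[i] = "stage_gap"
            continue
        mask, why = binarize_frame(frame, calibration.mm_per_pixel, cfg)
        if mask is None:
            reasons[i] = why
            continue
        try:
            path = extract_skeleton(mask, cfg.prune_fraction)
        except TopologyError as exc:
            reasons[i] = exc.reason
            continue
        pts_px = resample_midline(path, N_POINTS)
        seg = np.linalg.norm(np.diff(pts_px, axis=0), axis=1)
        if seg.min() <= 0 or seg.max() / seg.min() > 1.35:
            reasons[i] = "spacing"
            continue
        points[i] = to_plate_coords(pts_px, stage[i], calibration, frame.shape)
        valid[i] = True
    if not valid.any():
        raise EmptySeriesError("no frame could be recognized")
    times = np.arange(n) / frame_rate
    series = PoseSeries(
        times=times, points=points, valid=valid, frame_rate=frame_rate, reasons=reasons
    )
    invalid_rate = 1.0 - valid.mean()
    if invalid_rate > cfg.invalid_warn_fraction:
        log.warning("%.0f%% of frames invalid; recognition is suspect", 100 * invalid_rate)
    return orient_head_tail(series)
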