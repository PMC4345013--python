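"""Synthetic peristaltic-crawler simulator with ground truth.

The simulator produces the three inputs a real tracking session yields —
grayscale frames, a motorized-stage log and (directly) the 13-point midline
series — together with the true kinematic quantities, so every downstream
stage can be tested against known truth.

The model: a larva crawls on a 10 cm plate bounded by a 1.5-cm ring.  Time is
split into *runs* (continuous striding) and *pauses*.  During a run the body
length oscillates between ``mean_length - length_amplitude`` and
``mean_length + length_amplitude`` once per ``stride_period``; the tail is
planted while the body extends (the head advances) and advances while the
body contracts, so the body centre gains ``stride_distance`` per cycle.  The
body lies along the path traced by the head, which wanders gently and
reflects off the ring.  During a pause the animal stays put and sweeps its
head sideways, which is what real larvae do when reorienting.

Defaults are anchored to wild-type (Canton-S) third-instar values: body
length 4.34 mm, stride period 1.61 s, stride distance 0.89 mm, striding 76%
of the time, at 7.5 frames/s for 4 minutes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import CalibrationError, ConfigurationError
from .pose import CENTER, N_POINTS, PoseSeries

__all__ = ["SimConfig", "GroundTruth", "simulate_crawl", "render_frames"]


@dataclass
class SimConfig:
    """Parameters of one simulated tracking session (mm, s, degrees)."""

    mean_length: float = 4.34          # time-mean body length during striding
    length_amplitude: float = 0.255    # half the peak-to-peak length oscillation
    stride_period: float = 1.61        # duration of one peristalsis cycle
    stride_distance: float = 0.89      # centre-point advance per cycle
    time_striding_target: float = 0.76  # fraction of the video spent striding
    n_runs_target: int = 9             # number of striding bouts to schedule
    head_sweep_amplitude: float = 60.0  # peak head-angle during pauses, degrees
    arena_radius: float = 50.0         # plate radius (10 cm dish)
    ring_width: float = 15.0           # ring on the outer rim blocking the edge
    frame_rate: float = 7.5
    duration: float = 240.0
    noise_sd_position: float = 0.0     # per-point Gaussian jitter, mm
    rng_seed: int = 0
    # secondary shape/behaviour knobs
    extension_fraction: float = 0.5    # fraction of the cycle spent extending
    head_sweep_period: float = 4.0     # s per full sideways sweep oscillation
    path_curvature_sd: float = 0.04    # rad/mm, sets how much the path wanders
    min_pause: float = 1.5             # s, shortest pause between runs

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the violated invariant."""
        checks = [
            (self.length_amplitude > 0, "length_amplitude must be > 0"),
            (
                self.mean_length > 2 * self.length_amplitude,
                "mean_length must exceed 2*length_amplitude",
            ),
            (self.frame_rate > 0, "frame_rate must be > 0"),
            (
                self.stride_period > 2 / self.frame_rate,
                "stride_period must exceed two frame intervals (2/frame_rate)",
            ),
            (
                0.0 <= self.time_striding_target <= 1.0,
                "time_striding_target must lie in [0, 1]",
            ),
            (self.ring_width < self.arena_radius, "ring_width must be < arena_radius"),
            (self.duration > 0, "duration must be > 0"),
            (self.stride_distance > 0, "stride_distance must be > 0"),
            (self.n_runs_target >= 1, "n_runs_target must be >= 1"),
            (0 < self.extension_fraction < 1, "extension_fraction must lie in (0, 1)"),
            (
                0 <= self.head_sweep_amplitude <= 90,
                "head_sweep_amplitude must lie in [0, 90] degrees",
            ),
            (self.noise_sd_position >= 0, "noise_sd_position must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigurationError(msg)


@dataclass
class GroundTruth:
    """Everything the simulator knows that an analyst must recover."""

    striding: np.ndarray               # (n,) per-frame bool label
    midlines: np.ndarray               # (n, 13, 2) noiseless true midlines, mm
    stride_bounds: np.ndarray          # (n_strides, 2) start/end times, s
    run_bounds: np.ndarray             # (n_runs, 2) start/end times, s
    run_stride_counts: np.ndarray      # (n_runs,) strides per run
    params: dict = field(default_factory=dict)  # true VideoSummary-style vector
    config: SimConfig | None = None

    @property
    def n_strides(self) -> int:
        return len(self.stride_bounds)

    @property
    def n_runs(self) -> int:
        return len(self.run_bounds)

    def labels_frame(self) -> pd.DataFrame:
        n = len(self.striding)
        return pd.DataFrame(
            {
                "frame_index": np.arange(n),
                "time_s": np.arange(n) / self.config.frame_rate,
                "striding": self.striding.astype(int),
            }
        )

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config) if self.config else None,
            "params": {k: (None if v is None or (isinstance(v, float) and math.isnan(v)) else v)
                       for k, v in self.params.items()},
            "stride_bounds": self.stride_bounds.tolist(),
            "run_bounds": self.run_bounds.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ----------------------------------------------------------------- schedule

def _build_schedule(cfg: SimConfig, rng: np.random.Generator):
    """Lay out alternating pauses and runs.

    Returns (segments, total_strides) where each segment is
    ``("pause", t0, t1)`` or ``("run", t0, t1, n_strides)``.  Runs contain a
    whole number of strides so they begin and end at length minima.
    """
    D, T, f, n = cfg.duration, cfg.stride_period, cfg.time_striding_target, cfg.n_runs_target
    if f >= 1.0:
        k = int(math.floor(D / T))
        return [("run", 0.0, D, k)], k
    total = int(round(f * D / T))
    if total <= 0:
        return [("pause", 0.0, D)], 0
    n = min(n, total)
    # cap striding time at 90% of the video so pauses can separate the runs
    max_total = int(0.9 * D / T)
    total = min(total, max(n, max_total))
    base, rem = divmod(total, n)
    counts = np.array([base + 1] * rem + [base] * (n - rem))
    rng.shuffle(counts)
    pause_total = D - total * T
    n_pauses = n + 1
    floor_p = min(cfg.min_pause, 0.5 * pause_total / n_pauses)
    extra = rng.exponential(size=n_pauses)
    extra *= (pause_total - floor_p * n_pauses) / extra.sum()
    pauses = floor_p + extra
    segments = []
    t = 0.0
    for i in range(n):
        segments.append(("pause", t, t + pauses[i]))
        t += pauses[i]
        dur = counts[i] * T
        segments.append(("run", t, t + dur, int(counts[i])))
        t += dur
    segments.append(("pause", t, D))
    return segments, int(total)


# ----------------------------------------------------------------- path

class _WanderingPath:
    """Arc-length-parameterized path with gentle heading wander.

    The path reflects specularly off the circle of radius ``bound`` so the
    animal never reaches the ring.  Built incrementally in ``step`` (mm)
    increments; queried by linear interpolation in arc length.
    """

    STEP = 0.1

    def __init__(self, start, heading, bound, curvature_sd, rng):
        self.bound = bound
        self.curv_sd = curvature_sd
        self.rng = rng
        self.heading = float(heading)
        self.curv = 0.0
        self.xs = [float(start[0])]
        self.ys = [float(start[1])]
        self.ss = [0.0]

    def extend_to(self, s_target: float) -> None:
        ds = self.STEP
        while self.ss[-1] < s_target:
            # Ornstein-Uhlenbeck curvature: smooth, bounded wandering
            self.curv = 0.97 * self.curv + self.curv_sd * math.sqrt(ds) * self.rng.normal()
            self.curv = float(np.clip(self.curv, -0.25, 0.25))
            self.heading += self.curv * ds
            # smooth boundary avoidance: steer away from the ring with a
            # strength that grows near it, so the body never folds sharply
            px, py = self.xs[-1], self.ys[-1]
            r = math.hypot(px, py)
            if r > 0.65 * self.bound:
                nx, ny = px / r, py / r
                ux, uy = math.cos(self.heading), math.sin(self.heading)
                outward = ux * nx + uy * ny
                if outward > -0.1:
                    sense = 1.0 if (nx * uy - ny * ux) >= 0 else -1.0
                    frac = (r - 0.65 * self.bound) / (0.35 * self.bound)
                    # keeps body curvature gentle: a stride's chord stays
                    # within ~1% of its arc even while wall-following
                    steer = 0.35 * min(frac, 1.1) ** 2 * max(outward, 0.2)
                    self.heading += sense * steer * ds
            x = px + ds * math.cos(self.heading)
            y = py + ds * math.sin(self.heading)
            r_new = math.hypot(x, y)
            if r_new >= self.bound:
                # slide along the wall: rotate the heading toward the local
                # tangent at a bounded rate (so the body stays a gentle C,
                # never a hairpin) and clamp the radius just inside the ring
                nx, ny = x / r_new, y / r_new
                ux, uy = math.cos(self.heading), math.sin(self.heading)
                sense = 1.0 if (nx * uy - ny * ux) >= 0 else -1.0
                target = math.atan2(sense * nx, -sense * ny)  # tangent direction
                delta = (target - self.heading + math.pi) % (2 * math.pi) - math.pi
                self.heading += math.copysign(min(0.04, abs(delta)), delta)
                x = px + ds * math.cos(self.heading)
                y = py + ds * math.sin(self.heading)
                r_new = math.hypot(x, y)
                if r_new >= self.bound:
                    scale = (self.bound - 1e-3) / r_new
                    x *= scale
                    y *= scale
            self.xs.append(x)
            self.ys.append(y)
            step = math.hypot(x - px, y - py)
            self.ss.append(self.ss[-1] + max(step, 1e-6))

    def sample(self, s: np.ndarray) -> np.ndarray:
        ss = np.asarray(self.ss)
        return np.stack(
            [np.interp(s, ss, np.asarray(self.xs)), np.interp(s, ss, np.asarray(self.ys))],
            axis=-1,
        )


# ----------------------------------------------------------------- waveforms

def _length_wave(phi: np.ndarray, f_e: float) -> np.ndarray:
    """Normalized length cycle: -1 at phase 0 and 1, +1 at phase ``f_e``."""
    phi = np.asarray(phi, dtype=float)
    up = -np.cos(np.pi * np.minimum(phi, f_e) / f_e)
    down = np.cos(np.pi * (phi - f_e) / (1.0 - f_e))
    return np.where(phi < f_e, up, down)


def _tail_advance(phi: np.ndarray, f_e: float) -> np.ndarray:
    """Fraction of the per-cycle tail advance completed at phase ``phi``.

    The tail is planted during extension and advances linearly during
    contraction.
    """
    phi = np.asarray(phi, dtype=float)
    return np.clip((phi - f_e) / (1.0 - f_e), 0.0, 1.0)


def _rotate_about(points: np.ndarray, idx, pivot_idx: int, angle: float) -> None:
    """Rotate ``points[idx]`` about ``points[pivot_idx]`` by ``angle`` (rad)."""
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    pivot = points[pivot_idx]
    points[idx] = (points[idx] - pivot) @ rot.T + pivot


# ----------------------------------------------------------------- simulate

def simulate_crawl(config: SimConfig) -> tuple[PoseSeries, GroundTruth]:
    """Simulate one session; return the (noisy) pose series and the truth.

    Identical configs (including ``rng_seed``) give bit-identical output.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    n = int(round(cfg.duration * cfg.frame_rate))
    times = np.arange(n) / cfg.frame_rate
    T, A, L0, d = cfg.stride_period, cfg.length_amplitude, cfg.mean_length, cfg.stride_distance
    f_e = cfg.extension_fraction

    segments, total_strides = _build_schedule(cfg, rng)

    striding = np.zeros(n, dtype=bool)
    lengths = np.full(n, L0 - A)
    s_tail = np.zeros(n)
    sweep = np.zeros(n)  # head sweep angle per frame, radians

    stride_bounds = []
    run_bounds = []
    run_stride_counts = []
    base = 0.0  # tail arc position accumulated over completed runs
    amp = math.radians(cfg.head_sweep_amplitude)
    for seg in segments:
        kind, t0, t1 = seg[0], seg[1], seg[2]
        sel = (times >= t0) & (times < t1)
        if kind == "run":
            k_total = seg[3]
            tau = times[sel] - t0
            k = np.floor(tau / T)
            phi = tau / T - k
            striding[sel] = True
            lengths[sel] = L0 + A * _length_wave(phi, f_e)
            s_tail[sel] = base + (k + _tail_advance(phi, f_e)) * d
            for j in range(k_total):
                stride_bounds.append((t0 + j * T, t0 + (j + 1) * T))
            if k_total > 0:
                run_bounds.append((t0, min(t0 + k_total * T, t1)))
                run_stride_counts.append(k_total)
            base += k_total * d
            # a trailing partial cycle (time_striding_target = 1) continues the
            # waveform but contributes no stride boundary
        else:
            s_tail[sel] = base
            if cfg.head_sweep_amplitude > 0 and t1 - t0 > 0.2:
                u = times[sel] - t0
                env = np.minimum(1.0, np.minimum(u, (t1 - t0) - u) / 0.7)
                env = np.clip(env, 0.0, 1.0)
                sweep[sel] = amp * env * np.sin(2 * np.pi * u / cfg.head_sweep_period)

    # body center starts away from the ring so short sessions stay inside
    bound = cfg.arena_radius - cfg.ring_width
    r0 = rng.uniform(0.0, 0.5 * bound)
    ang0 = rng.uniform(0.0, 2 * np.pi)
    heading0 = rng.uniform(0.0, 2 * np.pi)
    start = np.array([r0 * math.cos(ang0), r0 * math.sin(ang0)])

    # the path starts one body length behind the initial tail position
    pad = L0 + 2 * A + 1.0
    path = _WanderingPath(
        start - pad * np.array([math.cos(heading0), math.sin(heading0)]),
        heading0,
        bound,
        cfg.path_curvature_sd,
        rng,
    )
    s_tail = s_tail + pad
    s_head = s_tail + lengths
    path.extend_to(float(s_head.max()) + 0.5)

    fractions = np.arange(N_POINTS) / (N_POINTS - 1)  # 0 = head ... 1 = tail
    s_points = s_head[:, None] - lengths[:, None] * fractions[None, :]
    midlines = path.sample(s_points)  # (n, 13, 2)

    # head sweeps: two equal kinks at points 3 and 2 so the head-chord angle
    # (p3->p1 vs p7->p3) equals the sweep angle exactly on a straight body
    for i in np.nonzero(sweep != 0.0)[0]:
        beta = sweep[i] / 1.5
        _rotate_about(midlines[i], [0, 1], 2, beta)
        _rotate_about(midlines[i], [0], 1, beta)

    noisy = midlines.copy()
    if cfg.noise_sd_position > 0:
        noisy = noisy + rng.normal(0.0, cfg.noise_sd_position, size=noisy.shape)

    series = PoseSeries(
        times=times,
        points=noisy,
        valid=np.ones(n, dtype=bool),
        frame_rate=cfg.frame_rate,
    )
    truth = GroundTruth(
        striding=striding,
        midlines=midlines,
        stride_bounds=np.array(stride_bounds).reshape(-1, 2),
        run_bounds=np.array(run_bounds).reshape(-1, 2),
        run_stride_counts=np.array(run_stride_counts, dtype=int),
        config=cfg,
    )
    truth.params = _true_params(cfg, truth, times)
    return series, truth


# ------------------------------------------------------- true parameters

def _seg_lengths(midlines: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.diff(midlines, axis=-2), axis=-1)


def _angles_deg(midlines: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Head and body angle (deviation from straight) per frame, degrees."""

    def ang(u, v):
        dot = (u * v).sum(-1)
        cross = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
        return np.degrees(np.abs(np.arctan2(cross, dot)))

    p = midlines
    head = ang(p[:, 0] - p[:, 2], p[:, 2] - p[:, 6])
    body = 180.0 - ang(p[:, 0] - p[:, 6], p[:, 12] - p[:, 6])
    return head, body


def _true_params(cfg: SimConfig, truth: GroundTruth, times: np.ndarray) -> dict:
    """True parameter vector, computed directly from the generated kinematics."""
    mid = truth.midlines
    n = len(times)
    dt = 1.0 / cfg.frame_rate
    lengths = _seg_lengths(mid).sum(-1)
    center = mid[:, CENTER, :]
    vel = np.full(n, np.nan)
    vel[1:-1] = np.linalg.norm(center[2:] - center[:-2], axis=-1) / (2 * dt)

    sb = truth.stride_bounds
    params: dict = {}
    params["body_length"] = float(lengths.mean())
    if len(sb):
        lo, hi, dist, dur = [], [], [], []
        cx = np.interp(sb, times, center[:, 0])
        cy = np.interp(sb, times, center[:, 1])
        for (t0, t1), x01, y01 in zip(sb, cx, cy):
            w = (times >= t0) & (times <= t1)
            lo.append(lengths[w].min())
            hi.append(lengths[w].max())
            dur.append(t1 - t0)
            dist.append(math.hypot(x01[1] - x01[0], y01[1] - y01[0]))
        params["body_length_contracted"] = float(np.mean(lo))
        params["body_length_extended"] = float(np.mean(hi))
        params["stride_duration"] = float(np.mean(dur))
        params["stride_distance"] = float(np.mean(dist))
    else:
        params["body_length_contracted"] = math.nan
        params["body_length_extended"] = math.nan
        params["stride_duration"] = math.nan
        params["stride_distance"] = math.nan

    head, body = _angles_deg(mid)
    params["time_head_bending"] = float((head > 45.0).mean())
    params["time_body_bending"] = float((body > 45.0).mean())
    params["time_bending"] = float(((head > 45.0) | (body > 45.0)).mean())

    st = truth.striding
    params["speed"] = float(np.nanmean(vel))
    params["time_striding"] = float(st.mean())
    params["speed_striding"] = float(np.nanmean(vel[st])) if st.any() else math.nan
    two_a = 2 * cfg.length_amplitude
    params["contraction_rate"] = two_a / ((1 - cfg.extension_fraction) * cfg.stride_period)
    params["extension_rate"] = two_a / (cfg.extension_fraction * cfg.stride_period)

    minutes = cfg.duration / 60.0
    params["stride_count_per_min"] = len(sb) / minutes
    rb, rc = truth.run_bounds, truth.run_stride_counts
    if len(rb):
        rdist = []
        step = np.linalg.norm(np.diff(center, axis=0), axis=-1)
        for t0, t1 in rb:
            w = (times[:-1] >= t0) & (times[1:] <= t1)
            rdist.append(step[w].sum())
        params["run_distance"] = float(np.mean(rdist))
        params["run_duration"] = float(np.mean(rb[:, 1] - rb[:, 0]))
        params["run_stride_count"] = float(np.mean(rc))
    else:
        params["run_distance"] = math.nan
        params["run_duration"] = math.nan
        params["run_stride_count"] = math.nan
    params["run_count_per_min"] = len(rb) / minutes

    params["distance_per_min"] = float(
        np.linalg.norm(np.diff(center, axis=0), axis=-1).sum() / minutes
    )
    # direction changes: 1 s subsampling, 60 degree turn threshold
    idx = np.arange(0, n, max(1, int(round(cfg.frame_rate))))
    pts = center[idx]
    turns = 0
    interior = 0
    for i in range(1, len(pts) - 1):
        u, v = pts[i] - pts[i - 1], pts[i + 1] - pts[i]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-9 or nv < 1e-9:
            continue
        interior += 1
        cosang = np.clip(u @ v / (nu * nv), -1, 1)
        if math.degrees(math.acos(cosang)) > 60.0:
            turns += 1
    params["direction_change"] = turns / interior if interior else math.nan
    inner = cfg.arena_radius - cfg.ring_width - 0.5 * params["body_length"]
    params["time_inside"] = float((np.linalg.norm(center, axis=-1) < inner).mean())
    return params


# ----------------------------------------------------------------- renderer

def render_frames(
    series: PoseSeries,
    mm_per_pixel: float = 0.045,
    frame_size: tuple[int, int] = (240, 240),
    worm_width_mm: float = 0.7,
    recenter_fraction: float = 1.0 / 3.0,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Render a pose series to dark-worm-on-white frames plus a stage log.

    The emulated stage jumps to re-center the animal whenever its centroid
    leaves the central ``recenter_fraction`` of the frame, and the per-frame
    stage position (mm) is logged — the inverse of the mapping the recognizer
    applies.  Returns ``(frames, stage_log)`` with 8-bit grayscale frames.
    """
    from skimage.draw import disk

    if worm_width_mm / mm_per_pixel <= 2.0:
        raise CalibrationError(
            f"worm width {worm_width_mm} mm is <= 2 px at {mm_per_pixel} mm/px"
        )
    h, w = frame_size
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    radius_px = 0.5 * worm_width_mm / mm_per_pixel
    half_x = 0.5 * w * mm_per_pixel * recenter_fraction
    half_y = 0.5 * h * mm_per_pixel * recenter_fraction

    first_valid = np.nonzero(series.valid)[0]
    if len(first_valid) == 0:
        raise CalibrationError("cannot render a series with no valid pose")
    stage = series.points[first_valid[0]].mean(axis=0).copy()

    frames: list[np.ndarray] = []
    rows = []
    for i in range(series.n_frames):
        canvas = np.full((h, w), 255, dtype=np.uint8)
        if series.valid[i]:
            pts = series.points[i]
            centroid = pts.mean(axis=0)
            if abs(centroid[0] - stage[0]) > half_x or abs(centroid[1] - stage[1]) > half_y:
                stage = centroid.copy()
            px = cx + (pts[:, 0] - stage[0]) / mm_per_pixel
            py = cy - (pts[:, 1] - stage[1]) / mm_per_pixel
            margin = radius_px + 1
            if (
                px.min() < margin
                or py.min() < margin
                or px.max() > w - 1 - margin
                or py.max() > h - 1 - margin
            ):
                raise CalibrationError(
                    "worm does not fit the frame; enlarge frame_size or coarsen "
                    "mm_per_pixel"
                )
            # densify the midline so stamped disks form a continuous tube
            seg = np.hypot(np.diff(px), np.diff(py))
            arc = np.concatenate([[0.0], np.cumsum(seg)])
            s = np.arange(0.0, arc[-1] + 0.4, 0.4)
            xs = np.interp(s, arc, px)
            ys = np.interp(s, arc, py)
            for x, y in zip(xs, ys):
                rr, cc = disk((y, x), radius_px, shape=(h, w))
                canvas[rr, cc] = 0
        frames.append(canvas)
        rows.append((i, series.times[i], stage[0], stage[1]))
    log = pd.DataFrame(rows, columns=["frame_index", "time_s", "stage_x_mm", "stage_y_mm"])
    return frames, log
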