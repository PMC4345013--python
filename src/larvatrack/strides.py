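"""Peristalsis detection: length extrema, striding classification, strides, runs.

A stride is one peristalsis cycle, delimited by consecutive local minima of
the body-length signal with a maximum in between.  A min-to-min interval is
accepted as a stride when its duration is physiological, its length
excursion is large enough, and the body centre actually advances — which is
what distinguishes striding from head sweeps and pauses.  Runs are maximal
groups of contiguous strides and carry the stamina statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from scipy.signal import find_peaks

from .pose import PoseSeries

__all__ = [
    "StrideConfig",
    "StrideEvent",
    "RunEvent",
    "prominent_extrema",
    "length_extrema",
    "classify_striding",
    "segment_strides",
    "detect_runs",
    "analyze_strides",
]


@dataclass
class StrideConfig:
    smooth_window_s: float = 0.4        # moving average on the length signal
    min_prominence_mm: float | None = None  # None -> 3% of mean body length
    period_min_s: float = 0.4           # plausible stride duration bounds
    period_max_s: float = 5.0
    min_displacement_mm: float = 0.1    # centre advance required per stride
    max_gap_s: float = 0.5              # pause tolerated inside one run
    stall_speed_mm_s: float | None = 0.15  # below this the animal is pausing
    stall_window_s: float = 0.5         # window for the stall speed proxy

    def prominence(self, lengths: np.ndarray) -> float:
        if self.min_prominence_mm is not None:
            return self.min_prominence_mm
        finite = np.asarray(lengths)[np.isfinite(lengths)]
        if len(finite) == 0:
            return float("inf")  # no data -> no extrema
        return 0.03 * float(finite.mean())


@dataclass
class StrideEvent:
    """One peristalsis cycle between consecutive length minima."""

    i_start: int
    i_end: int
    t_start: float
    t_end: float
    distance: float       # centre-point displacement over the cycle, mm
    length_min: float
    length_max: float
    contraction_rate: float  # mm/s, max -> closing min
    extension_rate: float    # mm/s, opening min -> max

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class RunEvent:
    """A maximal period of continuous striding."""

    t_start: float
    t_end: float
    distance: float       # centre-point path length over the run, mm
    stride_count: int
    i_start: int
    i_end: int

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(x) < 2:
        return x.astype(float)
    window = min(window, len(x))
    if window % 2 == 0:
        window += 1
    if window > len(x):
        window = len(x) if len(x) % 2 == 1 else len(x) - 1
    pad = window // 2
    padded = np.concatenate([x[pad:0:-1], x, x[-2:-2 - pad:-1]])
    return np.convolve(padded, np.ones(window) / window, mode="valid")


def _valid_blocks(valid: np.ndarray):
    """Contiguous index ranges [i0, i1) of valid frames."""
    idx = np.nonzero(valid)[0]
    if len(idx) == 0:
        return []
    splits = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[splits + 1]])
    ends = np.concatenate([idx[splits] + 1, [idx[-1] + 1]])
    return list(zip(starts, ends))


def quiescent_mask(series: PoseSeries, config: "StrideConfig") -> np.ndarray:
    """Frames where the body centre is not travelling (pausing/head-sweeping).

    The displacement of the smoothed centre over a short sliding window,
    expressed as a speed, falls well below any striding pace during pauses
    even when head sweeps jiggle the recognized midline.  Quiescent stretches
    are excised before stride extrema are detected so that no candidate
    stride can absorb pause time.
    """
    if config.stall_speed_mm_s is None:
        return np.zeros(series.n_frames, dtype=bool)
    from .track import _smooth_track

    c = _smooth_track(series.center.copy(), 4)
    w = max(1, int(round(config.stall_window_s * series.frame_rate / 2)))
    n = series.n_frames
    speed = np.full(n, np.nan)
    if n > 2 * w:
        dt = 2 * w / series.frame_rate
        speed[w:-w] = np.linalg.norm(c[2 * w:] - c[:-2 * w], axis=1) / dt
    return speed < config.stall_speed_mm_s  # NaN compares False: not quiescent


def prominent_extrema(x: np.ndarray, min_prominence: float):
    """Indices of minima and maxima with topographic prominence >= threshold."""
    x = np.asarray(x, dtype=float)
    maxima, _ = find_peaks(x, prominence=min_prominence)
    minima, _ = find_peaks(-x, prominence=min_prominence)
    return minima, maxima


def _valley_edges(x: np.ndarray, i: int, tol: float) -> tuple[int, int]:
    """Extent of the near-flat valley around minimum ``i`` (within ``tol``)."""
    lo = i
    while lo - 1 >= 0 and x[lo - 1] <= x[i] + tol:
        lo -= 1
    hi = i
    while hi + 1 < len(x) and x[hi + 1] <= x[i] + tol:
        hi += 1
    return lo, hi


def _alternate(x: np.ndarray, minima: np.ndarray, maxima: np.ndarray, flat_tol: float = 0.0):
    """Merge extrema into an alternating (index, kind) sequence.

    Consecutive same-type extrema are resolved by keeping the more extreme —
    except that a wide flat valley (a pause in the length signal) contributes
    *both* of its edges as minima, so that no min-to-min candidate stride can
    span the pause.  Sharp minima behave as single events.
    """
    events = []
    for i in minima:
        i = int(i)
        if flat_tol > 0:
            lo, hi = _valley_edges(x, i, flat_tol)
            if hi - lo >= 3:
                events.append((lo, "min", True))
                events.append((hi, "min", True))
                continue
        events.append((i, "min", False))
    events.extend((int(i), "max", False) for i in maxima)
    events.sort()
    out = []
    for i, kind, edge in events:
        if out and out[-1][1] == kind:
            j, _, prev_edge = out[-1]
            if kind == "min" and (edge or prev_edge):
                out.append((i, kind, edge))  # plateau edges stay paired
                continue
            better = x[i] < x[j] if kind == "min" else x[i] > x[j]
            if better:
                out[-1] = (i, kind, edge)
        else:
            out.append((i, kind, edge))
    return [(i, kind) for i, kind, _ in out]


def length_extrema(
    lengths: np.ndarray,
    frame_rate: float,
    min_prominence: float,
    smooth_window_s: float = 0.4,
):
    """Alternating minima/maxima of the lightly smoothed length signal.

    Returns a list of ``(frame_index, "min"|"max")`` tuples.  NaN gaps split
    the signal; blocks shorter than 2 s carry no extrema.  The smoothed
    signal locates the extrema; callers read values off the raw signal.
    """
    lengths = np.asarray(lengths, dtype=float)
    window = int(round(smooth_window_s * frame_rate))
    out = []
    for i0, i1 in _valid_blocks(~np.isnan(lengths)):
        if (i1 - i0) / frame_rate < 2.0:
            continue
        block = _smooth(lengths[i0:i1], window)
        minima, maxima = prominent_extrema(block, min_prominence)
        # a quarter of the prominence still sits well below a stride's length
        # excursion but above recognition jitter, so pauses read as wide
        # valleys while true cycle minima stay narrow
        merged = _alternate(block, minima, maxima, flat_tol=0.25 * min_prominence)
        # a block that starts or ends with a maximum (motion onset, or a flat
        # stretch touching the block edge, which peak finding cannot call a
        # minimum) contributes a boundary minimum: the near-side edge of the
        # deepest valley between the block edge and that maximum
        if merged:
            tol = 0.25 * min_prominence
            i_first, k_first = merged[0]
            if k_first == "max" and i_first > 0:
                j = int(np.argmin(block[:i_first]))
                if block[j] <= block[i_first] - min_prominence:
                    _, hi = _valley_edges(block[:i_first], j, tol)
                    merged.insert(0, (hi, "min"))
            i_last, k_last = merged[-1]
            if k_last == "max" and i_last < len(block) - 1:
                j = i_last + 1 + int(np.argmin(block[i_last + 1:]))
                if block[j] <= block[i_last] - min_prominence:
                    lo, _ = _valley_edges(block, j, tol)
                    merged.append((max(lo, i_last + 1), "min"))
        out.extend([(i + i0, kind) for i, kind in merged])
    return out


def classify_striding(
    series: PoseSeries,
    extrema,
    config: StrideConfig | None = None,
    lengths: np.ndarray | None = None,
    usable: np.ndarray | None = None,
):
    """Accept min-to-min intervals as strides; flag their frames as striding.

    Returns ``(striding, intervals)``: a per-frame boolean array and the
    accepted ``(i_min_start, i_max, i_min_end)`` index triples.
    """
    cfg = config or StrideConfig()
    if lengths is None:
        from .kinematics import body_length

        lengths = body_length(series.points)
    prom = cfg.prominence(lengths)
    center = series.center
    striding = np.zeros(series.n_frames, dtype=bool)
    intervals = []
    for k in range(len(extrema) - 2):
        (i0, k0), (im, km), (i1, k1) = extrema[k], extrema[k + 1], extrema[k + 2]
        if (k0, km, k1) != ("min", "max", "min"):
            continue
        duration = series.times[i1] - series.times[i0]
        if not cfg.period_min_s <= duration <= cfg.period_max_s:
            continue
        if not series.valid[i0:i1 + 1].all():
            continue  # a stride straddling a gap is dropped, not interpolated
        if usable is not None and np.isnan(usable[i0 + 1:i1]).any():
            continue  # the interval would span a quiescent stretch
        excursion = lengths[im] - max(lengths[i0], lengths[i1])
        if not excursion >= prom:
            continue
        disp = float(np.linalg.norm(center[i1] - center[i0]))
        if disp < cfg.min_displacement_mm:
            continue
        intervals.append((i0, im, i1))
        striding[i0:i1 + 1] = True
    return striding, intervals


def segment_strides(
    series: PoseSeries,
    intervals,
    lengths: np.ndarray | None = None,
) -> list[StrideEvent]:
    """Build one :class:`StrideEvent` per accepted interval.

    Length extrema and phase rates are read off the raw (unsmoothed) length
    signal at the located extremum frames, so noiseless piecewise-linear
    signals give exact rates.  Intervals with non-positive phase rates are
    rejected (degenerate timing).
    """
    if lengths is None:
        from .kinematics import body_length

        lengths = body_length(series.points)
    t = series.times
    center = series.center
    events = []
    for i0, im, i1 in intervals:
        win = lengths[i0:i1 + 1]
        l_max = float(lengths[im])
        t_ext = t[im] - t[i0]
        t_con = t[i1] - t[im]
        if t_ext <= 0 or t_con <= 0:
            continue
        ext_rate = (l_max - float(lengths[i0])) / t_ext
        con_rate = (l_max - float(lengths[i1])) / t_con
        if ext_rate <= 0 or con_rate <= 0:
            continue
        events.append(
            StrideEvent(
                i_start=int(i0),
                i_end=int(i1),
                t_start=float(t[i0]),
                t_end=float(t[i1]),
                distance=float(np.linalg.norm(center[i1] - center[i0])),
                length_min=float(np.nanmin(win)),
                length_max=float(np.nanmax(win)),
                contraction_rate=con_rate,
                extension_rate=ext_rate,
            )
        )
    return events


def detect_runs(
    series: PoseSeries,
    strides: list[StrideEvent],
    max_gap_s: float = 0.5,
) -> list[RunEvent]:
    """Merge consecutive strides separated by <= ``max_gap_s`` into runs."""
    if not strides:
        return []
    center = series.center
    groups = [[strides[0]]]
    for ev in strides[1:]:
        if ev.t_start - groups[-1][-1].t_end <= max_gap_s:
            groups[-1].append(ev)
        else:
            groups.append([ev])
    runs = []
    for grp in groups:
        i0, i1 = grp[0].i_start, grp[-1].i_end
        steps = np.linalg.norm(np.diff(center[i0:i1 + 1], axis=0), axis=-1)
        runs.append(
            RunEvent(
                t_start=grp[0].t_start,
                t_end=grp[-1].t_end,
                distance=float(np.nansum(steps)),
                stride_count=len(grp),
                i_start=int(i0),
                i_end=int(i1),
            )
        )
    return runs


def analyze_strides(series: PoseSeries, config: StrideConfig | None = None):
    """Full stride stage: returns (striding flags, strides, runs)."""
    from .kinematics import body_length

    cfg = config or StrideConfig()
    lengths = body_length(series.points)
    quiet = quiescent_mask(series, cfg)
    masked = lengths.copy()
    masked[quiet] = np.nan
    extrema = length_extrema(
        masked, series.frame_rate, cfg.prominence(lengths), cfg.smooth_window_s
    )
    striding, intervals = classify_striding(series, extrema, cfg, lengths, masked)
    strides = segment_strides(series, intervals, lengths)
    runs = detect_runs(series, strides, cfg.max_gap_s)
    return striding, strides, runs
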