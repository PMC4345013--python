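"""Per-video summaries, batch processing, CV, and control normalization.

Each video reduces to one parameter vector: shape (body length, bending
times), peristalsis (speed, striding fraction, per-stride statistics),
stamina (run statistics) and track measures.  Per-frame parameters are
averaged over valid frames (striding-only subsets where that applies);
per-video parameters are computed once.  Missing quantities (e.g. stride
duration in a video with no strides) stay missing — never zero.

Batch mode processes a folder of points tables into one summary table, and
genetic comparisons divide each animal's values by the mean of control
animals tracked the same day, which cancels day effects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .kinematics import frame_metrics
from .pose import PoseSeries, read_points_tsv
from .strides import RunEvent, StrideEvent, analyze_strides
from .track import ArenaGeometry, TrackSummary, summarize_track

log = logging.getLogger(__name__)

__all__ = [
    "PARAMETERS",
    "FOOTNOTE2_PARAMETERS",
    "VideoSummary",
    "summarize_video",
    "analyze_series",
    "batch_process",
    "coefficient_of_variation",
    "normalize_by_control",
    "profile_matrix",
    "profile_correlation",
]

#: the per-video parameter vector, in report order
PARAMETERS = [
    "body_length",
    "body_length_contracted",
    "body_length_extended",
    "time_head_bending",
    "time_body_bending",
    "time_bending",
    "speed",
    "time_striding",
    "speed_striding",
    "stride_duration",
    "stride_distance",
    "contraction_rate",
    "extension_rate",
    "stride_count_per_min",
    "run_distance",
    "run_duration",
    "run_stride_count",
    "run_count_per_min",
    "distance_per_min",
    "direction_change",
    "time_inside",
]

#: parameters that also get inside/outside variants
FOOTNOTE2_PARAMETERS = [
    "time_head_bending",
    "time_body_bending",
    "time_bending",
    "speed",
    "time_striding",
    "speed_striding",
    "stride_duration",
    "stride_distance",
    "contraction_rate",
    "extension_rate",
]

METADATA_COLUMNS = ["video_id", "date", "genotype", "sex", "stage"]


@dataclass
class VideoSummary:
    values: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    n_frames: int = 0
    n_valid_frames: int = 0
    error: bool = False
    high_invalid: bool = False

    def to_row(self) -> dict:
        row = dict(self.metadata)
        row.update(
            n_frames=self.n_frames,
            n_valid_frames=self.n_valid_frames,
            error=int(self.error),
            high_invalid=int(self.high_invalid),
        )
        row.update(self.values)
        return row


def _nanmean(x) -> float:
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    return float(x.mean()) if len(x) else math.nan


def _stride_stats(strides: list[StrideEvent]) -> dict:
    if not strides:
        return {
            "body_length_contracted": math.nan,
            "body_length_extended": math.nan,
            "stride_duration": math.nan,
            "stride_distance": math.nan,
            "contraction_rate": math.nan,
            "extension_rate": math.nan,
        }
    return {
        "body_length_contracted": _nanmean([s.length_min for s in strides]),
        "body_length_extended": _nanmean([s.length_max for s in strides]),
        "stride_duration": _nanmean([s.duration for s in strides]),
        "stride_distance": _nanmean([s.distance for s in strides]),
        "contraction_rate": _nanmean([s.contraction_rate for s in strides]),
        "extension_rate": _nanmean([s.extension_rate for s in strides]),
    }


def _masked_block(
    metrics: pd.DataFrame,
    striding: np.ndarray,
    strides: list[StrideEvent],
    mask: np.ndarray,
    speed_mode: str,
    center: np.ndarray,
    frame_rate: float,
) -> dict:
    """The footnote-2 parameter block restricted to ``mask`` frames."""
    m = mask & metrics["valid"].to_numpy(bool)
    out: dict = {}
    speeds = metrics["speed_p7"].to_numpy(float)
    if speed_mode == "total_displacement":
        idx = np.nonzero(m)[0]
        if len(idx) >= 2:
            steps = np.linalg.norm(np.diff(center[idx], axis=0), axis=-1)
            out["speed"] = float(steps.sum() / ((len(idx) - 1) / frame_rate))
        else:
            out["speed"] = math.nan
    else:
        out["speed"] = _nanmean(speeds[m])
    out["time_head_bending"] = _nanmean(metrics["head_bending"].to_numpy(float)[m])
    out["time_body_bending"] = _nanmean(metrics["body_bending"].to_numpy(float)[m])
    out["time_bending"] = _nanmean(metrics["bending"].to_numpy(float)[m])
    out["time_striding"] = float(striding[m].mean()) if m.any() else math.nan
    st_mask = m & striding
    out["speed_striding"] = _nanmean(speeds[st_mask]) if st_mask.any() else math.nan
    # a stride belongs to the masked subset when its midpoint frame does
    sel = [s for s in strides if m[(s.i_start + s.i_end) // 2]]
    stats = _stride_stats(sel)
    for key in ("stride_duration", "stride_distance", "contraction_rate", "extension_rate"):
        out[key] = stats[key]
    return out, sel


def analyze_series(
    series: PoseSeries,
    config: RunConfig | None = None,
    arena: ArenaGeometry | None = None,
    metadata: dict | None = None,
):
    """Run kinematics, strides and track on a pose series.

    Returns ``(summary, metrics, strides, runs, track_summary)``; the
    metrics table carries the filled ``striding`` and ``inside`` columns.
    """
    cfg = config or RunConfig()
    metrics = frame_metrics(series, cfg.speed_window_s, cfg.bend_threshold_deg)
    striding, strides, runs = analyze_strides(series, cfg.strides)
    metrics["striding"] = striding.astype(int)

    mean_len = _nanmean(metrics["length_mm"])
    if arena is None:
        arena = cfg.arena(mean_len if np.isfinite(mean_len) else None)
    try:
        track = summarize_track(
            series.center,
            series.times,
            series.frame_rate,
            arena,
            cfg.path_smooth_s,
            cfg.sample_interval_s,
            cfg.turn_threshold_deg,
        )
    except ValueError:
        # too few valid frames for a track; every track quantity is missing
        track = TrackSummary(
            distance_mm=math.nan,
            distance_mm_per_min=math.nan,
            direction_change_fraction=math.nan,
            time_inside_fraction=math.nan,
            inside=np.zeros(series.n_frames, dtype=bool),
            change_points=pd.DataFrame(
                columns=["time_s", "x_mm", "y_mm", "turn_deg", "is_change"]
            ),
        )
    metrics["inside"] = track.inside.astype(int)

    summary = summarize_video(series, metrics, striding, strides, runs, track, cfg, metadata)
    return summary, metrics, strides, runs, track


def summarize_video(
    series: PoseSeries,
    metrics: pd.DataFrame,
    striding: np.ndarray,
    strides: list[StrideEvent],
    runs: list[RunEvent],
    track: TrackSummary,
    config: RunConfig | None = None,
    metadata: dict | None = None,
) -> VideoSummary:
    """Collapse one video's engines into the per-video parameter vector."""
    cfg = config or RunConfig()
    meta = {k: (metadata or {}).get(k) for k in METADATA_COLUMNS}
    n_valid = series.n_valid
    summary = VideoSummary(
        metadata=meta,
        n_frames=series.n_frames,
        n_valid_frames=n_valid,
        high_invalid=(1 - n_valid / max(series.n_frames, 1)) > cfg.invalid_warn_fraction,
    )
    if n_valid == 0:
        summary.error = True
        summary.values = {p: math.nan for p in PARAMETERS}
        return summary

    values: dict = {}
    values["body_length"] = _nanmean(metrics["length_mm"])
    all_mask = np.ones(series.n_frames, dtype=bool)
    overall, _ = _masked_block(
        metrics, striding, strides, all_mask, cfg.speed_mode, series.center, series.frame_rate
    )
    values.update(overall)
    values.update(
        {
            k: _stride_stats(strides)[k]
            for k in ("body_length_contracted", "body_length_extended")
        }
    )

    minutes = series.duration / 60.0
    values["stride_count_per_min"] = len(strides) / minutes
    values["stride_count_total"] = len(strides)
    if runs:
        values["run_distance"] = _nanmean([r.distance for r in runs])
        values["run_duration"] = _nanmean([r.duration for r in runs])
        values["run_stride_count"] = _nanmean([r.stride_count for r in runs])
    else:
        values["run_distance"] = math.nan
        values["run_duration"] = math.nan
        values["run_stride_count"] = math.nan
    values["run_count_per_min"] = len(runs) / minutes
    values["run_count_total"] = len(runs)

    values["distance_per_min"] = track.distance_mm_per_min
    values["direction_change"] = track.direction_change_fraction
    values["time_inside"] = track.time_inside_fraction

    for variant, mask in (("inside", track.inside), ("outside", ~track.inside)):
        block, _ = _masked_block(
            metrics, striding, strides, mask, cfg.speed_mode, series.center, series.frame_rate
        )
        values.update({f"{k}_{variant}": v for k, v in block.items()})

    summary.values = values
    return summary


def batch_process(
    folder,
    metadata: pd.DataFrame | None = None,
    config: RunConfig | None = None,
    pattern: str = "*.tsv",
) -> pd.DataFrame:
    """Summarize every points table in ``folder`` into one row each.

    Unparseable files are logged and skipped, not fatal.  Rows are ordered
    by filename so re-runs are byte-identical.  ``metadata`` (columns
    video_id, date, genotype, sex, stage) is joined on the file stem.
    """
    cfg = config or RunConfig()
    folder = Path(folder)
    files = sorted(p for p in folder.glob(pattern) if p.is_file())
    meta_by_id = {}
    if metadata is not None:
        for _, row in metadata.iterrows():
            meta_by_id[str(row["video_id"])] = row.to_dict()
    rows = []
    for path in files:
        vid = path.stem
        try:
            series = read_points_tsv(path, frame_rate=cfg.frame_rate)
            summary, *_ = analyze_series(
                series, cfg, metadata=meta_by_id.get(vid, {"video_id": vid})
            )
        except Exception as exc:  # noqa: BLE001 - a bad file must not kill the batch
            log.warning("skipping %s: %s", path.name, exc)
            continue
        row = summary.to_row()
        row["video_id"] = vid
        rows.append(row)
    if not rows:
        log.warning("no parseable points file in %s", folder)
        return pd.DataFrame(columns=METADATA_COLUMNS + PARAMETERS)
    return pd.DataFrame(rows)


def coefficient_of_variation(values) -> float:
    """Sample-SD / mean as a percent; NaN when undefined (n < 2 or mean 0)."""
    x = np.asarray(list(values), dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        return math.nan
    mean = x.mean()
    if mean == 0:
        return math.nan
    return float(100.0 * x.std(ddof=1) / mean)


def normalize_by_control(
    table: pd.DataFrame,
    control_genotype: str,
    parameters: list[str] | None = None,
    date_col: str = "date",
    genotype_col: str = "genotype",
) -> pd.DataFrame:
    """Divide each animal's values by the same-date control mean.

    Animals on dates without controls get missing normalized values (logged);
    parameters whose control mean is zero are skipped with a warning.
    """
    params = parameters or [p for p in PARAMETERS if p in table.columns]
    controls = table[table[genotype_col] == control_genotype]
    if controls.empty:
        raise ValueError(f"no rows with control genotype {control_genotype!r}")
    control_means = controls.groupby(date_col)[params].mean()
    out = table.copy()
    for date, group in table.groupby(date_col):
        if date not in control_means.index:
            log.warning("no same-date control for date %s; values left missing", date)
            out.loc[group.index, params] = np.nan
            continue
        means = control_means.loc[date]
        for p in params:
            denom = means[p]
            if not np.isfinite(denom) or denom == 0:
                log.warning("control mean for %s on %s is zero/undefined; skipped", p, date)
                out.loc[group.index, p] = np.nan
            else:
                out.loc[group.index, p] = group[p] / denom
    return out


def profile_matrix(
    table: pd.DataFrame,
    control_genotype: str,
    parameters: list[str] | None = None,
    stat: str = "mean",
    date_col: str = "date",
    genotype_col: str = "genotype",
) -> pd.DataFrame:
    """Genotype x parameter phenotypic profile on control-normalized values.

    ``stat="mean"``: mean normalized value per genotype (control row == 1 by
    construction).  ``stat="sd"``: each genotype's SD of normalized values
    divided by the control's SD.
    """
    if stat not in ("mean", "sd"):
        raise ValueError("stat must be 'mean' or 'sd'")
    params = parameters or [p for p in PARAMETERS if p in table.columns]
    norm = normalize_by_control(table, control_genotype, params, date_col, genotype_col)
    grouped = norm.groupby(genotype_col)[params]
    if stat == "mean":
        return grouped.mean()
    sds = grouped.std(ddof=1)
    return sds / sds.loc[control_genotype]


def profile_correlation(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between genotype profile rows.

    A profile correlated with itself is 1 by definition, including the
    control's constant all-ones row (where Pearson is otherwise degenerate).
    """
    corr = profiles.T.corr(method="pearson")
    for g in profiles.index:
        if np.isfinite(profiles.loc[g]).any():
            corr.loc[g, g] = 1.0
    return corr
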