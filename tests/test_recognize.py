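"""Recognizer: binarization, skeleton, resampling, orientation, plate mapping."""

import numpy as np
import pandas as pd
import pytest

import larvatrack as lt
from larvatrack.errors import EmptySeriesError, TopologyError
from larvatrack.kinematics import body_length
from larvatrack.pose import N_POINTS, PoseSeries
from larvatrack.recognize import (
    CalibrationInfo,
    RecognizerConfig,
    binarize_frame,
    extract_skeleton,
    orient_head_tail,
    resample_midline,
    to_plate_coords,
)

MM_PER_PX = 0.045


def _arc_length(path):
    return float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())


# ----------------------------------------------------------------- binarize

def test_uniform_white_frame_is_invalid():
    mask, why = binarize_frame(np.full((50, 50), 255, np.uint8), MM_PER_PX)
    assert mask is None and why == "empty"


def test_specks_below_min_area_are_discarded():
    frame = np.full((120, 120), 255, np.uint8)
    frame[40:52, 20:100] = 0          # worm-like bar, 960 px ~ 1.9 mm^2
    for r, c in [(5, 5), (100, 10), (10, 110)]:
        frame[r:r + 3, c:c + 3] = 0   # specks
    mask, why = binarize_frame(frame, MM_PER_PX)
    assert why is None
    assert mask.sum() == 12 * 80      # exactly the bar survives


def test_binarized_area_matches_rendered_mask(rendered_session):
    _, _, frames, _, _ = rendered_session
    for frame in frames[::25]:
        true_area = (frame < 128).sum()
        mask, why = binarize_frame(frame, MM_PER_PX)
        assert why is None
        assert mask.sum() == pytest.approx(true_area, rel=0.02)


# ----------------------------------------------------------------- skeleton

def test_bar_skeleton_spans_the_bar():
    mask = np.zeros((21, 120), dtype=bool)
    mask[8:13, 10:110] = True          # 100 x 5 bar
    path = extract_skeleton(mask)
    assert _arc_length(path) == pytest.approx(99.0, abs=2.0)
    ys = path[:, 1]
    assert np.allclose(ys, 10.0, atol=1.5)  # centerline of rows 8..12


def test_disk_mask_has_no_midline():
    yy, xx = np.mgrid[0:60, 0:60]
    mask = (yy - 30) ** 2 + (xx - 30) ** 2 < 20 ** 2
    with pytest.raises(TopologyError):
        extract_skeleton(mask)


def test_c_shaped_worm_length_recovered():
    # half-annulus of radius 30 px, width 10 px: midline arc = pi * 30
    yy, xx = np.mgrid[0:90, 0:90]
    r = np.hypot(yy - 45, xx - 45)
    mask = (r > 25) & (r < 35) & (yy <= 45)
    path = extract_skeleton(mask)
    assert _arc_length(path) == pytest.approx(np.pi * 30, rel=0.05)


# ----------------------------------------------------------------- resample

def test_resample_gives_13_points_12_segments():
    t = np.linspace(0, 1, 400)
    path = np.stack([100 * t, 20 * np.sin(3 * t)], axis=1)
    pts = resample_midline(path)
    assert pts.shape == (N_POINTS, 2)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    assert len(seg) == 12


def test_resample_straight_path_unit_spacing():
    path = np.stack([np.linspace(0, 12, 241), np.zeros(241)], axis=1)
    pts = resample_midline(path)
    np.testing.assert_allclose(pts[:, 0], np.arange(13.0), atol=1e-9)


def test_resample_semicircle_equal_arcs():
    r = 40.0
    theta = np.linspace(0, np.pi, 4000)
    path = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    pts = resample_midline(path)
    # neighbouring points subtend arc pi*r/12: chord = 2 r sin(pi/24)
    chords = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    np.testing.assert_allclose(chords, 2 * r * np.sin(np.pi / 24), rtol=1e-4)


def test_resample_rejects_degenerate_n():
    with pytest.raises(ValueError):
        resample_midline(np.zeros((10, 2)), n=1)


# ----------------------------------------------------------------- orientation

def test_orientation_fixes_random_flips(sim_session):
    cfg, series, truth = sim_session
    rng = np.random.default_rng(0)
    flipped = truth.midlines.copy()
    flips = rng.random(len(flipped)) < 0.5
    flipped[flips] = flipped[flips, ::-1, :]
    scrambled = PoseSeries(
        times=series.times,
        points=flipped,
        valid=np.ones(len(flipped), bool),
        frame_rate=cfg.frame_rate,
    )
    oriented = orient_head_tail(scrambled)
    # temporal continuity: endpoint tracks never jump by a body segment
    seg = cfg.mean_length / 12
    for end in (0, N_POINTS - 1):
        jumps = np.linalg.norm(np.diff(oriented.points[:, end, :], axis=0), axis=1)
        assert jumps.mean() < seg
    # the true head is identified in nearly all frames
    err = np.linalg.norm(oriented.points[:, 0] - truth.midlines[:, 0], axis=1)
    assert (err < seg / 2).mean() >= 0.95
    assert oriented.orientation_confidence > 0


def test_single_frame_orientation_is_arbitrary_with_zero_confidence():
    series = PoseSeries(
        times=np.array([0.0]),
        points=np.linspace(0, 1, 26).reshape(1, 13, 2),
        valid=np.array([True]),
        frame_rate=7.5,
    )
    oriented = orient_head_tail(series)
    assert oriented.orientation_confidence == 0.0


def test_orientation_requires_a_valid_pose():
    series = PoseSeries(
        times=np.array([0.0, 0.1]),
        points=np.full((2, 13, 2), np.nan),
        valid=np.array([False, False]),
        frame_rate=7.5,
    )
    with pytest.raises(EmptySeriesError):
        orient_head_tail(series)


# ----------------------------------------------------------------- plate mapping

def test_image_center_maps_to_stage_position():
    calib = CalibrationInfo(MM_PER_PX)
    pts = np.array([[(240 - 1) / 2, (240 - 1) / 2]])
    out = to_plate_coords(pts, np.array([3.0, -2.0]), calib, (240, 240))
    np.testing.assert_allclose(out, [[3.0, -2.0]], atol=1e-12)


def test_stage_shift_translates_plate_coords():
    calib = CalibrationInfo(MM_PER_PX)
    pts = np.array([[100.0, 80.0]])
    a = to_plate_coords(pts, np.array([0.0, 0.0]), calib, (240, 240))
    b = to_plate_coords(pts, np.array([2.0, 0.0]), calib, (240, 240))
    np.testing.assert_allclose(b - a, [[2.0, 0.0]], atol=1e-12)


def test_stage_gaps_interpolate_up_to_two_frames(rendered_session):
    cfg, truth, frames, stage, _ = rendered_session
    n = 60
    sub = stage.iloc[:n]
    # drop frames 10-11 (gap of 2: interpolated) and 30-33 (gap of 4: invalid)
    keep = ~sub["frame_index"].isin([10, 11, 30, 31, 32, 33])
    rec = lt.recognize_video(
        frames[:n], sub[keep], CalibrationInfo(MM_PER_PX), frame_rate=cfg.frame_rate
    )
    assert rec.valid[10] and rec.valid[11]
    assert not rec.valid[31] and rec.reasons[31] == "stage_gap"


# ----------------------------------------------------------------- round trip

def test_round_trip_midline_rmse_below_0p1_mm(rendered_session):
    cfg, truth, frames, stage, rec = rendered_session
    ok = rec.valid
    err = rec.points[ok] - truth.midlines[ok]
    rmse = np.sqrt(np.nanmean(np.sum(err**2, axis=-1)))
    assert rmse < 0.1


def test_round_trip_body_length_within_5_percent(rendered_session):
    cfg, truth, frames, stage, rec = rendered_session
    rec_len = np.nanmean(body_length(rec.points))
    assert rec_len == pytest.approx(truth.params["body_length"], rel=0.05)


def test_round_trip_center_track_rmse(rendered_session):
    cfg, truth, frames, stage, rec = rendered_session
    err = np.linalg.norm(rec.points[:, 6] - truth.midlines[:, 6], axis=-1)
    # straight-bodied (striding) frames: stage mapping accurate to < 0.05 mm;
    # head-sweeping pause frames add midline bias but stay within 0.1 mm
    straight = rec.valid & truth.striding
    assert np.sqrt(np.mean(err[straight] ** 2)) < 0.05
    assert np.sqrt(np.mean(err[rec.valid] ** 2)) < 0.1


def test_half_rate_recognition_matches_full_rate(rendered_session):
    cfg, truth, frames, stage, rec = rendered_session
    half = lt.recognize_video(
        frames[:80:2],
        stage.iloc[:80:2].assign(frame_index=np.arange(40)),
        CalibrationInfo(MM_PER_PX),
        frame_rate=cfg.frame_rate / 2,
    )
    full_even = rec.points[:80:2]
    ok = half.valid & rec.valid[:80:2]
    # geometry is per-frame: identical poses up to head/tail orientation
    fwd = np.nanmax(np.abs(half.points[ok] - full_even[ok]))
    rev = np.nanmax(np.abs(half.points[ok][:, ::-1, :] - full_even[ok]))
    assert min(fwd, rev) < 1e-9
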