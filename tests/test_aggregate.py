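"""Per-video summaries, batch tables, CV, and control normalization."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import larvatrack as lt
from larvatrack.aggregate import (
    PARAMETERS,
    batch_process,
    coefficient_of_variation,
    normalize_by_control,
    profile_correlation,
    profile_matrix,
)
from larvatrack.pose import PoseSeries, write_points_tsv


@pytest.fixture(scope="module")
def summarized(sim_session):
    cfg, series, truth = sim_session
    summary, metrics, strides, runs, track = lt.analyze_series(series)
    return cfg, truth, summary


def test_summary_recovers_ground_truth_vector(summarized):
    cfg, truth, summary = summarized
    for key, true_val in truth.params.items():
        if key not in summary.values or not np.isfinite(true_val):
            continue
        got = summary.values[key]
        if abs(true_val) < 0.25:
            assert got == pytest.approx(true_val, abs=0.05), key
        else:
            assert got == pytest.approx(true_val, rel=0.10), key


def test_all_pause_video_reports_missing_stride_values():
    cfg = lt.SimConfig(duration=60.0, time_striding_target=0.0, rng_seed=0)
    series, _ = lt.simulate_crawl(cfg)
    summary, *_ = lt.analyze_series(series)
    assert summary.values["time_striding"] == 0.0
    assert math.isnan(summary.values["stride_duration"])
    assert math.isnan(summary.values["run_duration"])
    assert summary.values["distance_per_min"] < 1.0


def test_zero_valid_frames_marks_summary_error():
    n = 20
    series = PoseSeries(
        times=np.arange(n) / 7.5,
        points=np.full((n, 13, 2), np.nan),
        valid=np.zeros(n, dtype=bool),
        frame_rate=7.5,
    )
    summary, *_ = lt.analyze_series(series)
    assert summary.error
    assert all(math.isnan(v) for v in summary.values.values())


def test_stride_count_identity_on_synthetic_summaries():
    for seed in range(3):
        cfg = lt.SimConfig(duration=240.0, rng_seed=seed)
        series, _ = lt.simulate_crawl(cfg)
        summary, *_ = lt.analyze_series(series)
        v = summary.values
        identity = 60.0 * v["time_striding"] / v["stride_duration"]
        assert v["stride_count_per_min"] == pytest.approx(identity, rel=0.15)


def test_summary_orders_length_variants(summarized):
    _, _, summary = summarized
    v = summary.values
    assert v["body_length_contracted"] <= v["body_length"] <= v["body_length_extended"]


# ----------------------------------------------------------------- CV

@pytest.mark.parametrize(
    "values, expected",
    [
        ([1, 1, 1], 0.0),
        ([2, 4], 100 * math.sqrt(2) / 3),  # 47.14%
        ([-2, -2], 0.0),
    ],
)
def test_cv_known_values(values, expected):
    assert coefficient_of_variation(values) == pytest.approx(expected, abs=0.01)


def test_cv_undefined_cases():
    assert math.isnan(coefficient_of_variation([3.0]))
    assert math.isnan(coefficient_of_variation([-1.0, 1.0]))


@given(c=st.floats(0.01, 100.0))
def test_cv_scale_invariant(c):
    vals = np.array([1.2, 3.4, 2.2, 5.1])
    assert coefficient_of_variation(c * vals) == pytest.approx(
        coefficient_of_variation(vals), rel=1e-9
    )


# ----------------------------------------------------------------- batch

def _write_video(tmp_path, name, seed, duration=40.0):
    cfg = lt.SimConfig(duration=duration, rng_seed=seed)
    series, _ = lt.simulate_crawl(cfg)
    write_points_tsv(series, tmp_path / f"{name}.tsv")


def test_batch_processes_folder_and_skips_corrupt_file(tmp_path):
    for i in range(2):
        _write_video(tmp_path, f"vid{i}", seed=i)
    (tmp_path / "broken.tsv").write_text("frame_index\tnot_a_points_file\n1\tx\n")
    table = batch_process(tmp_path)
    assert len(table) == 2
    assert list(table["video_id"]) == ["vid0", "vid1"]  # sorted by filename


def test_batch_is_deterministic(tmp_path):
    for i in range(2):
        _write_video(tmp_path, f"vid{i}", seed=i)
    a = batch_process(tmp_path)
    b = batch_process(tmp_path)
    pd.testing.assert_frame_equal(a, b)


def test_batch_empty_folder_returns_empty_table(tmp_path):
    table = batch_process(tmp_path)
    assert table.empty


# ----------------------------------------------------------------- normalization

def _toy_table():
    rng = np.random.default_rng(3)
    rows = []
    for date in ("2024-01-01", "2024-01-02"):
        day_effect = {"2024-01-01": 1.0, "2024-01-02": 1.3}[date]
        for genotype, shift in (("ctrl", 1.0), ("mutA", 0.8)):
            for i in range(4):
                rows.append(
                    {
                        "video_id": f"{date}-{genotype}-{i}",
                        "date": date,
                        "genotype": genotype,
                        "speed": day_effect * shift * (0.6 + 0.02 * rng.normal()),
                        "stride_distance": day_effect * shift * (0.9 + 0.02 * rng.normal()),
                    }
                )
    return pd.DataFrame(rows)


def test_day_effects_cancel_under_control_normalization():
    table = _toy_table()
    params = ["speed", "stride_distance"]
    norm = normalize_by_control(table, "ctrl", params)
    scaled = table.copy()
    c = 7.3
    day = scaled["date"] == "2024-01-02"
    scaled.loc[day, params] = scaled.loc[day, params] * c
    norm_scaled = normalize_by_control(scaled, "ctrl", params)
    pd.testing.assert_frame_equal(norm[params], norm_scaled[params])


def test_self_normalized_profile_is_unity_with_correlation_one():
    table = _toy_table()
    params = ["speed", "stride_distance"]
    prof = profile_matrix(table, "ctrl", params)
    np.testing.assert_allclose(prof.loc["ctrl"], 1.0, atol=1e-12)
    corr = profile_correlation(prof)
    assert corr.loc["ctrl", "ctrl"] == pytest.approx(1.0)


def test_missing_same_date_control_leaves_values_missing():
    table = _toy_table()
    extra = pd.DataFrame(
        [{"video_id": "x", "date": "2024-02-09", "genotype": "mutA",
          "speed": 0.5, "stride_distance": 0.8}]
    )
    table = pd.concat([table, extra], ignore_index=True)
    norm = normalize_by_control(table, "ctrl", ["speed", "stride_distance"])
    orphan = norm[norm["date"] == "2024-02-09"]
    assert orphan[["speed", "stride_distance"]].isna().all().all()


def test_perturbed_genotype_deviates_per_configured_truth_ratio():
    """Two synthetic 'genotypes' differing only in stride distance: the
    normalized profile deviates from 1 exactly where the configured truths
    differ, by their ratio."""
    rows = []
    truths = {}
    for genotype, d in (("ctrl", 0.89), ("slowstep", 0.62)):
        truth_params = []
        for i in range(3):
            cfg = lt.SimConfig(duration=120.0, stride_distance=d, rng_seed=20 + i)
            series, truth = lt.simulate_crawl(cfg)
            summary, *_ = lt.analyze_series(series)
            row = {"video_id": f"{genotype}{i}", "date": "d0", "genotype": genotype}
            row.update({k: summary.values[k] for k in ("stride_distance", "stride_duration", "body_length")})
            rows.append(row)
            truth_params.append(truth.params)
        truths[genotype] = pd.DataFrame(truth_params).mean()
    table = pd.DataFrame(rows)
    params = ["stride_distance", "stride_duration", "body_length"]
    prof = profile_matrix(table, "ctrl", params)
    expected = truths["slowstep"] / truths["ctrl"]
    for p in params:
        assert prof.loc["slowstep", p] == pytest.approx(expected[p], rel=0.05), p
    # only the perturbed parameter moved away from unity
    assert prof.loc["slowstep", "stride_distance"] < 0.8
    assert prof.loc["slowstep", "stride_duration"] == pytest.approx(1.0, abs=0.05)
    assert prof.loc["slowstep", "body_length"] == pytest.approx(1.0, abs=0.05)
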