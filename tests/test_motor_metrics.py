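"""The 62-metric vector: inventory contract, closed-form fixtures,
missingness accounting, and determinism."""

import copy
import math

import numpy as np
import pytest

from pdmotion.motor_metrics import (
    METRIC_INVENTORY,
    METRIC_NAMES,
    balance_metrics,
    complex_task_metric,
    extract_all,
    gait_metrics,
    open_close_metrics,
    reach_metrics,
    tremor_metrics,
)
from pdmotion.session_io import (
    JOINTS,
    CameraTrack,
    ForcePlateTrack,
    ImuTrack,
    MarkerChannel,
    TaskRecording,
)
from pdmotion.simulator import SeverityProfile, SimConfig, simulate_subject


def test_inventory_has_exactly_62_uniquely_named_metrics():
    assert len(METRIC_INVENTORY) == 62
    assert len(set(METRIC_NAMES)) == 62
    per_task = {}
    for name, info in METRIC_INVENTORY.items():
        per_task.setdefault(info["task"], []).append(name)
    assert {t: len(v) for t, v in per_task.items()} == {
        "T1A": 10, "T1B": 10, "T4": 10, "T2A": 3, "T2B": 3, "T3": 1,
        "T5A": 2, "T5B": 2, "T6_EO": 8, "T6_EC": 8, "T7": 5,
    }


# ---------------------------------------------------------------------------
# Constructed fixtures
# ---------------------------------------------------------------------------

FS_CAM = 30.0
FS_IMU = 64.0


def _min_jerk_reach_recording(n_reps=10, d=0.3, T=0.5, pause=1.0, pad=1.0):
    """Ideal noiseless reaching task: n identical minimum-jerk strokes."""
    dur = pad + n_reps * T + (n_reps - 1) * pause + pad
    n = int(round(dur * FS_CAM)) + 1
    t = np.arange(n) / FS_CAM
    x = np.zeros(n)
    level = 0.0
    for k in range(n_reps):
        start = pad + k * (T + pause)
        tau = np.clip((t - start) / T, 0, 1)
        direction = 1.0 if k % 2 == 0 else -1.0
        x += direction * d * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    pos = np.zeros((n, len(JOINTS), 3))
    pos[:, JOINTS.index("wrist_r"), 0] = x
    cam = CameraTrack(t, pos)
    n_imu = int(round(dur * FS_IMU)) + 1
    imu = ImuTrack(
        "index_finger",
        np.arange(n_imu) / FS_IMU,
        np.zeros((n_imu, 3)),
        np.zeros((n_imu, 3)),
    )
    marker = MarkerChannel(np.array([pad - 0.5, dur - pad + 0.5]))
    return TaskRecording(task="T1A", marker=marker, camera=cam, imus=[imu])


class TestReachMetrics:
    def test_ten_identical_minimum_jerk_reaches(self):
        out = reach_metrics(_min_jerk_reach_recording())
        assert out["n_movements"] == 10
        assert out["duration_mean"] == pytest.approx(0.5, abs=0.07)
        assert out["duration_sd"] == pytest.approx(0.0, abs=0.05)
        assert out["smoothness_mean"] == pytest.approx(1 / 1.875, abs=0.04)
        assert out["path_length"] == pytest.approx(10 * 0.3, rel=0.03)
        assert out["mean_speed_mean"] == pytest.approx(0.3 / 0.5, rel=0.1)
        assert out["max_speed_mean"] == pytest.approx(1.875 * 0.3 / 0.5, rel=0.05)

    def test_stationary_wrist_yields_missing_stats(self):
        rec = _min_jerk_reach_recording(d=0.0)
        out = reach_metrics(rec)
        assert all(math.isnan(out[k]) for k in out)

    def test_smoothness_invariant_to_position_rescaling(self):
        rec1 = _min_jerk_reach_recording()
        rec2 = copy.deepcopy(rec1)
        rec2.camera.positions *= 1000.0  # meters -> millimeters
        s1 = reach_metrics(rec1)["smoothness_mean"]
        s2 = reach_metrics(rec2)["smoothness_mean"]
        assert s1 == pytest.approx(s2, rel=1e-6)


def _open_close_recording(period=1.0, n_events=10, pad=1.0):
    dur = pad + n_events * period + pad
    n = int(round(dur * FS_IMU)) + 1
    t = np.arange(n) / FS_IMU
    gyro = np.zeros((n, 3))
    inside = (t >= pad) & (t <= pad + n_events * period)
    gyro[inside, 0] = 3.0 * np.sin(2 * np.pi * (t[inside] - pad - period / 2) / period)
    imu = ImuTrack("index_finger", t, gyro, np.zeros((n, 3)))
    marker = MarkerChannel(np.array([pad, pad + n_events * period]))
    return TaskRecording(task="T2A", marker=marker, imus=[imu])


class TestOpenCloseMetrics:
    def test_ten_events_over_ten_seconds(self):
        out = open_close_metrics(_open_close_recording())
        assert out["movement_time"] == pytest.approx(1.0, abs=0.02)
        assert out["ipi_mean"] == pytest.approx(1.0, abs=0.02)
        assert out["ipi_sd"] == pytest.approx(0.0, abs=0.02)

    def test_too_few_events_flagged_missing(self):
        out = open_close_metrics(_open_close_recording(n_events=1))
        assert all(math.isnan(v) for v in out.values())


class TestComplexTask:
    @pytest.mark.parametrize("events,expected", [((0.0, 20.06), 20.06), ((1.0, 2.0), 1.0)])
    def test_total_time_is_marker_window(self, events, expected):
        rec = TaskRecording(task="T3", marker=MarkerChannel(np.array(events)))
        assert complex_task_metric(rec)["total_time"] == pytest.approx(expected)


def _tremor_recording(freq, amp=0.5, dur=15.0, pad=0.5, noise=0.0, seed=0):
    total = dur + 2 * pad
    n = int(round(total * FS_IMU)) + 1
    t = np.arange(n) / FS_IMU
    rng = np.random.default_rng(seed)
    accel = rng.normal(0.0, noise, (n, 3))
    accel[:, 2] += 9.81 + amp * np.sin(2 * np.pi * freq * t)
    imu = ImuTrack("index_finger", t, np.zeros((n, 3)), accel)
    marker = MarkerChannel(np.array([pad, pad + dur]))
    return TaskRecording(task="T5A", marker=marker, imus=[imu])


class TestTremorMetrics:
    def test_in_band_tremor_dominates(self):
        out = tremor_metrics(_tremor_recording(5.0), (3, 6))
        assert out["power_ratio_multitaper"] > 0.9
        assert out["power_ratio_fft"] > 0.9

    def test_out_of_band_tremor_is_small(self):
        out = tremor_metrics(_tremor_recording(10.0), (3, 6))
        assert out["power_ratio_multitaper"] < 0.05
        assert out["power_ratio_fft"] < 0.05

    def test_methods_agree_on_white_noise(self):
        diffs = []
        for seed in range(20):
            out = tremor_metrics(
                _tremor_recording(5.0, amp=0.0, noise=0.3, seed=seed), (3, 6)
            )
            diffs.append(out["power_ratio_multitaper"] - out["power_ratio_fft"])
        assert np.max(np.abs(diffs)) < 0.05


def _balance_recording(cop_ml, cop_ap, fs=98.0, with_imu=True):
    n = len(cop_ml)
    t = np.arange(n) / fs
    plate = ForcePlateTrack(t, np.asarray(cop_ml, float), np.asarray(cop_ap, float))
    imus = []
    if with_imu:
        n_imu = int(round(t[-1] * FS_IMU)) + 1
        imus = [
            ImuTrack(
                "l5",
                np.arange(n_imu) / FS_IMU,
                np.zeros((n_imu, 3)),
                np.tile([0.0, 0.0, 9.81], (n_imu, 1)),
            )
        ]
    marker = MarkerChannel(np.array([0.0, t[-1]]))
    return TaskRecording(task="T6_EO", marker=marker, plate=plate, imus=imus)


class TestBalanceMetrics:
    def test_square_path_length_is_exact(self):
        # 10 cm x 10 cm square traced once: perimeter 40 cm
        side = np.linspace(0, 10, 368)
        ml = np.concatenate([side, np.full(368, 10.0), side[::-1], np.zeros(368)])
        ap = np.concatenate([np.zeros(368), side, np.full(368, 10.0), side[::-1]])
        out = balance_metrics(_balance_recording(ml, ap))
        assert out["cop_path_length"] == pytest.approx(40.0, rel=1e-9)

    def test_isotropic_gaussian_ellipse_area_matches_chi2(self):
        # 95% covariance ellipse of N(0, I): area = pi * 5.991 * sigma^2
        areas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cop = rng.normal(0.0, 1.0, (1470, 2))
            out = balance_metrics(_balance_recording(cop[:, 0], cop[:, 1]))
            areas.append(out["ellipse_area"])
        assert np.mean(areas) == pytest.approx(np.pi * 5.991, rel=0.15)

    def test_zero_trunk_acceleration_gives_zero_jerk(self):
        cop = np.zeros((1470, 2))
        out = balance_metrics(_balance_recording(cop[:, 0], cop[:, 1]))
        assert out["jerk_mean"] == pytest.approx(0.0, abs=1e-9)


def _walk_recording(task, walk_time=7.28, stride_period=1.04, pad=0.5):
    total = walk_time + 2 * pad
    n = int(round(total * FS_IMU)) + 1
    t = np.arange(n) / FS_IMU
    z = np.zeros(n)
    k = 0
    while True:
        c = pad + stride_period / 2 + k * stride_period
        if c > pad + walk_time - stride_period / 4:
            break
        z += 4.0 * np.exp(-0.5 * ((t - c) / 0.08) ** 2)
        k += 1
    gyro = np.zeros((n, 3))
    gyro[:, 2] = z
    imus = [
        ImuTrack("l5", t, np.zeros((n, 3)), np.tile([0.0, 0.0, 9.81], (n, 1))),
        ImuTrack("ankle_right", t, gyro, np.zeros((n, 3))),
    ]
    marker = MarkerChannel(np.array([pad, pad + walk_time]))
    return TaskRecording(task=task, marker=marker, imus=imus)


class TestGaitMetrics:
    def test_stride_timing_recovered(self):
        recs = {t: _walk_recording(t) for t in ("T7_W1", "T7_W2", "T7_W3", "T7_W4")}
        out = gait_metrics(recs)
        assert out["gait_stride_duration_mean" .removeprefix("gait_")] == pytest.approx(
            1.04, abs=0.02
        )
        assert out["total_walk_time"] == pytest.approx(7.28, abs=0.01)
        assert out["stride_count"] == 7  # floor((7.28 - 0.26) / 1.04) bursts fit

    def test_constant_velocity_walk_has_near_zero_normalized_jerk(self):
        recs = {t: _walk_recording(t) for t in ("T7_W1", "T7_W2")}
        out = gait_metrics(recs)
        assert out["normalized_jerk"] == pytest.approx(0.0, abs=1e-9)

    def test_missing_walks_flag_metrics(self):
        out = gait_metrics({})
        assert all(math.isnan(v) for v in out.values())


# ---------------------------------------------------------------------------
# Whole-session extraction
# ---------------------------------------------------------------------------


class TestExtractAll:
    def test_complete_session_has_62_values_none_missing(self, moderate_session):
        vec = extract_all(moderate_session)
        assert set(vec.values) == set(METRIC_NAMES)
        assert vec.n_missing == 0

    def test_session_without_force_plate_flags_12_metrics(self, moderate_session):
        session = copy.deepcopy(moderate_session)
        for task in ("T6_EO", "T6_EC"):
            session.recordings[task].plate = None
        vec = extract_all(session)
        assert len(vec.values) == 62
        assert vec.n_missing == 12  # 6 CoP metrics per balance condition
        assert not vec.missing["t6_eo_jerk_mean"]  # trunk IMU still present

    def test_extraction_is_deterministic(self, moderate_session):
        v1 = extract_all(moderate_session)
        v2 = extract_all(moderate_session)
        assert v1.values == v2.values
        assert v1.missing == v2.missing

    def test_severity_monotonicity_over_bradykinesia_sweep(self):
        from scipy.stats import spearmanr

        sev = np.linspace(0.0, 1.0, 20)
        speeds, durations = [], []
        for i, s in enumerate(sev):
            session = simulate_subject(
                SeverityProfile(s_brady=float(s)), SimConfig(), seed=500 + i
            )
            vec = extract_all(session)
            speeds.append(vec.values["t1a_mean_speed_mean"])
            durations.append(vec.values["t1a_duration_mean"])
        assert spearmanr(sev, speeds).statistic < -0.9
        assert spearmanr(sev, durations).statistic > 0.9
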