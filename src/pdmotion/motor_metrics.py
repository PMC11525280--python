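"""The canonical 62-metric motor feature vector.

One subject-visit yields exactly 62 named metrics, grouped by task:

* reaching tasks (continuous / discrete elbow flexion-extension, hand-to-
  nose): per-movement mean speed, max speed, duration, smoothness (each as
  mean and SD over movements), movement count, and wrist path length —
  10 metrics x 3 tasks;
* hand opening-closing (shoulder / waist level): movement time (task time
  over number of openings) and inter-peak-interval mean and SD — 3 x 2;
* complex multi-joint sequence: total completion time — 1;
* rest / postural tremor: fraction of accelerometer-amplitude power in the
  3-6 Hz (rest) or 5-8 Hz (postural) band, estimated by multitaper and by
  Hann-periodogram FFT — 2 x 2;
* balance eyes-open / eyes-closed: CoP path length, per-component CoP SD,
  95% covariance-ellipse axes and area, and trunk jerk mean and peak —
  8 x 2;
* gait: mean walk time, normalized jerk (walks 1-2), stride-duration mean
  and SD and stride count (walks 3-4) — 5.

Metrics that cannot be computed (missing stream, zero movements) are
flagged missing, never dropped: the vector always has 62 entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pdmotion.errors import PdMotionError
from pdmotion.segmentation import detect_hand_open_events, detect_strides, segment_movements
from pdmotion.session_io import Session, TaskRecording, task_window, crop_streams
from pdmotion.signal_prep import (
    accel_amplitude,
    band_power_ratio,
    interpolate_missing,
    jerk,
    lowpass_butter,
    lowpass_fir,
    speed_profile,
    spectrum,
)

#: 95% coverage quantile of a chi-square with 2 degrees of freedom, used
#: for the CoP confidence ellipse.
CHI2_95_2DF = 5.991464547107979

#: Repetition count prescribed by the exam protocol for repeated tasks.
PROTOCOL_REPS = 10

#: Tremor frequency bands (Hz): rest and postural.
REST_BAND = (3.0, 6.0)
POSTURAL_BAND = (5.0, 8.0)

REACH_TASKS = ("T1A", "T1B", "T4")
OPEN_CLOSE_TASKS = ("T2A", "T2B")
TREMOR_TASKS = {"T5A": REST_BAND, "T5B": POSTURAL_BAND}
BALANCE_TASKS = ("T6_EO", "T6_EC")
WALK_TASKS = ("T7_W1", "T7_W2", "T7_W3", "T7_W4")

_REACH_NAMES = (
    ("mean_speed_mean", "m/s"),
    ("mean_speed_sd", "m/s"),
    ("max_speed_mean", "m/s"),
    ("max_speed_sd", "m/s"),
    ("duration_mean", "s"),
    ("duration_sd", "s"),
    ("smoothness_mean", "-"),
    ("smoothness_sd", "-"),
    ("n_movements", "count"),
    ("path_length", "m"),
)
_OPEN_CLOSE_NAMES = (("movement_time", "s"), ("ipi_mean", "s"), ("ipi_sd", "s"))
_TREMOR_NAMES = (("power_ratio_multitaper", "-"), ("power_ratio_fft", "-"))
_BALANCE_NAMES = (
    ("cop_path_length", "cm"),
    ("cop_sd_ap", "cm"),
    ("cop_sd_ml", "cm"),
    ("ellipse_major", "cm"),
    ("ellipse_minor", "cm"),
    ("ellipse_area", "cm^2"),
    ("jerk_mean", "m/s^3"),
    ("jerk_peak", "m/s^3"),
)
_GAIT_NAMES = (
    ("total_walk_time", "s"),
    ("normalized_jerk", "1/s^2"),
    ("stride_duration_mean", "s"),
    ("stride_duration_sd", "s"),
    ("stride_count", "count"),
)


def _build_inventory() -> dict[str, dict[str, str]]:
    inv: dict[str, dict[str, str]] = {}
    for task in REACH_TASKS:
        for name, units in _REACH_NAMES:
            inv[f"{task.lower()}_{name}"] = {
                "task": task, "stream": "camera", "computation": "reach_metrics",
                "units": units,
            }
    for task in OPEN_CLOSE_TASKS:
        for name, units in _OPEN_CLOSE_NAMES:
            inv[f"{task.lower()}_{name}"] = {
                "task": task, "stream": "imu_index_finger",
                "computation": "open_close_metrics", "units": units,
            }
    inv["t3_total_time"] = {
        "task": "T3", "stream": "marker", "computation": "complex_task_metric",
        "units": "s",
    }
    for task in TREMOR_TASKS:
        for name, units in _TREMOR_NAMES:
            inv[f"{task.lower()}_{name}"] = {
                "task": task, "stream": "imu_index_finger",
                "computation": "tremor_metrics", "units": units,
            }
    for task in BALANCE_TASKS:
        for name, units in _BALANCE_NAMES:
            stream = "imu_l5" if name.startswith("jerk") else "plate"
            inv[f"{task.lower()}_{name}"] = {
                "task": task, "stream": stream, "computation": "balance_metrics",
                "units": units,
            }
    for name, units in _GAIT_NAMES:
        stream = "imu_l5" if name in ("total_walk_time", "normalized_jerk") else "imu_ankle"
        inv[f"gait_{name}"] = {
            "task": "T7", "stream": stream, "computation": "gait_metrics",
            "units": units,
        }
    assert len(inv) == 62
    return inv


#: Canonical inventory: metric name -> task, stream, computation, units.
METRIC_INVENTORY: dict[str, dict[str, str]] = _build_inventory()
METRIC_NAMES: tuple[str, ...] = tuple(METRIC_INVENTORY)


@dataclass
class MetricVector:
    """The named 62-element motor feature vector for one subject-visit."""

    subject_id: str
    visit_day: int
    values: dict[str, float] = field(default_factory=dict)
    missing: dict[str, bool] = field(default_factory=dict)
    #: Auxiliary (non-inventory) quantities, e.g. alternate tremor power
    #: computations and per-task times.
    aux: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in METRIC_NAMES:
            self.values.setdefault(name, math.nan)
            self.missing.setdefault(name, True)

    def set(self, name: str, value: float) -> None:
        if name not in METRIC_INVENTORY:
            raise KeyError(f"{name!r} is not in the 62-metric inventory")
        if value is None or not math.isfinite(value):
            self.values[name] = math.nan
            self.missing[name] = True
        else:
            self.values[name] = float(value)
            self.missing[name] = False

    @property
    def n_missing(self) -> int:
        return sum(self.missing.values())

    def to_series(self) -> pd.Series:
        return pd.Series(
            {name: self.values[name] for name in METRIC_NAMES}, name=self.subject_id
        )


def metrics_table(vectors: list[MetricVector]) -> pd.DataFrame:
    """Cohort table: one row per subject-visit, 62 metric columns plus a
    missing-flag column per metric."""
    rows = []
    for vec in vectors:
        row: dict = {"subject_id": vec.subject_id, "visit_day": vec.visit_day}
        row.update({name: vec.values[name] for name in METRIC_NAMES})
        row.update({f"{name}__missing": vec.missing[name] for name in METRIC_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


def data_dictionary() -> pd.DataFrame:
    """Generated data dictionary for the metric inventory."""
    return pd.DataFrame(
        [{"metric": name, **info} for name, info in METRIC_INVENTORY.items()]
    )


# ---------------------------------------------------------------------------
# Per-task computations
# ---------------------------------------------------------------------------


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def _wrist_joint(rec: TaskRecording) -> str:
    return "wrist_r" if rec.side == "right" else "wrist_l"


def reach_metrics(rec: TaskRecording, expected_n: int = PROTOCOL_REPS) -> dict[str, float]:
    """Per-movement statistics and wrist path length for a reaching task."""
    t0, t1 = task_window(rec)
    rec = crop_streams(rec, (t0, t1))
    out: dict[str, float] = {name: math.nan for name, _ in _REACH_NAMES}
    if rec.camera is None:
        return out
    cam = interpolate_missing(rec.camera)
    profile = speed_profile(cam, _wrist_joint(rec))
    segments = segment_movements(
        profile, gyro=rec.imu("index_finger"), expected_n=expected_n
    )
    # drop movements overlapping un-interpolated camera gaps
    if cam.missing.any():
        gaps = cam.timestamps[cam.missing]
        segments = [
            s for s in segments
            if not np.any((gaps >= s.t_start) & (gaps <= s.t_end))
        ]
    pos = lowpass_fir(cam.joint(_wrist_joint(rec)).T, cam.fs, 10.0)
    out["path_length"] = float(np.sum(np.linalg.norm(np.diff(pos, axis=1), axis=0)))
    out["n_movements"] = float(len(segments))
    if not segments:
        return {name: math.nan for name, _ in _REACH_NAMES}
    for key, vals in (
        ("mean_speed", [s.mean_speed for s in segments]),
        ("max_speed", [s.max_speed for s in segments]),
        ("duration", [s.duration for s in segments]),
        ("smoothness", [s.smoothness for s in segments]),
    ):
        arr = np.asarray(vals)
        out[f"{key}_mean"] = float(arr.mean())
        out[f"{key}_sd"] = _sd(arr)
    return out


def open_close_metrics(rec: TaskRecording) -> dict[str, float]:
    """Movement time and inter-peak intervals for hand opening-closing."""
    t0, t1 = task_window(rec)
    rec = crop_streams(rec, (t0, t1))
    out = {name: math.nan for name, _ in _OPEN_CLOSE_NAMES}
    imu = rec.imu("index_finger")
    if imu is None:
        return out
    events = detect_hand_open_events(imu)
    if events.times.size < 2:
        return out
    out["movement_time"] = (t1 - t0) / events.times.size
    ipi = events.intervals
    out["ipi_mean"] = float(ipi.mean())
    out["ipi_sd"] = _sd(ipi)
    return out


def complex_task_metric(rec: TaskRecording) -> dict[str, float]:
    """Total time to complete the complex multi-joint sequence."""
    t0, t1 = task_window(rec)
    return {"total_time": t1 - t0}


def tremor_metrics(rec: TaskRecording, band: tuple[float, float]) -> dict[str, float]:
    """Band-power ratios of the finger accelerometer amplitude."""
    t0, t1 = task_window(rec)
    rec = crop_streams(rec, (t0, t1))
    out = {name: math.nan for name, _ in _TREMOR_NAMES}
    imu = rec.imu("index_finger")
    if imu is None or imu.timestamps.size < 4 * imu.fs:
        return out
    amp = accel_amplitude(imu)
    out["power_ratio_multitaper"] = band_power_ratio(amp, imu.fs, band, "multitaper")
    out["power_ratio_fft"] = band_power_ratio(amp, imu.fs, band, "fft")
    return out


def tremor_aux_metrics(rec: TaskRecording, band: tuple[float, float]) -> dict[str, float]:
    """Alternate tremor computations (not in the canonical inventory):
    mean in-band power and mean total power, multitaper and FFT."""
    t0, t1 = task_window(rec)
    rec = crop_streams(rec, (t0, t1))
    imu = rec.imu("index_finger")
    out: dict[str, float] = {}
    if imu is None or imu.timestamps.size < 4 * imu.fs:
        return out
    amp = accel_amplitude(imu)
    for method in ("multitaper", "fft"):
        spec = spectrum(amp, imu.fs, method=method)
        in_band = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
        out[f"mean_band_power_{method}"] = float(spec.power[in_band].mean())
        out[f"mean_total_power_{method}"] = float(spec.power.mean())
    return out


def _cop_ellipse(cop: np.ndarray) -> tuple[float, float, float]:
    """95% covariance-ellipse axis lengths and area of a 2D CoP cloud.

    Axis length is the full axis, 2*sqrt(chi2_95 * eigenvalue); area is
    pi * chi2_95 * sqrt(det(cov)).
    """
    cov = np.cov(cop, rowvar=False)
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    major = 2.0 * math.sqrt(CHI2_95_2DF * eigvals[0])
    minor = 2.0 * math.sqrt(CHI2_95_2DF * eigvals[1])
    area = math.pi * CHI2_95_2DF * math.sqrt(eigvals[0] * eigvals[1])
    return major, minor, area


def balance_metrics(rec: TaskRecording) -> dict[str, float]:
    """CoP posturography plus trunk jerk for one balance condition.

    L5 accelerometer convention: accel_x antero-posterior, accel_y
    medio-lateral, accel_z vertical (gravity-aligned).
    """
    t0, t1 = task_window(rec)
    rec = crop_streams(rec, (t0, t1))
    out = {name: math.nan for name, _ in _BALANCE_NAMES}
    if rec.plate is not None:
        cop = np.column_stack([rec.plate.cop_ml, rec.plate.cop_ap])
        out["cop_path_length"] = float(
            np.sum(np.linalg.norm(np.diff(cop, axis=0), axis=1))
        )
        out["cop_sd_ap"] = _sd(rec.plate.cop_ap)
        out["cop_sd_ml"] = _sd(rec.plate.cop_ml)
        out["ellipse_major"], out["ellipse_minor"], out["ellipse_area"] = _cop_ellipse(cop)
    imu = rec.imu("l5")
    if imu is not None and imu.timestamps.size > 30:
        ap_ml = lowpass_butter(imu.accel[:, :2].T, imu.fs, cutoff=5.0).T
        _, out["jerk_mean"], out["jerk_peak"] = jerk(ap_ml, imu.fs)
    return out


def gait_metrics(recs: dict[str, TaskRecording]) -> dict[str, float]:
    """Gait metrics pooled over the four 10 m walks.

    Walks 1-2 contribute normalized jerk (mean trunk jerk amplitude over
    mean walking speed, speed = 10 m / walk time); walks 3-4 contribute
    stride timing from the most-affected-side ankle gyroscope. Walk time
    is averaged over all available walks.
    """
    out = {name: math.nan for name, _ in _GAIT_NAMES}
    times = []
    for task in WALK_TASKS:
        if task in recs:
            t0, t1 = task_window(recs[task])
            times.append(t1 - t0)
    if times:
        out["total_walk_time"] = float(np.mean(times))

    norm_jerks = []
    for task in ("T7_W1", "T7_W2"):
        rec = recs.get(task)
        if rec is None:
            continue
        t0, t1 = task_window(rec)
        rec_c = crop_streams(rec, (t0, t1))
        imu = rec_c.imu("l5")
        if imu is None or imu.timestamps.size < 100:
            continue
        ap_ml = lowpass_butter(imu.accel[:, :2].T, imu.fs, cutoff=5.0).T
        amp, mean_jerk, _ = jerk(ap_ml, imu.fs)
        speed = 10.0 / (t1 - t0)
        norm_jerks.append(mean_jerk / speed)
    if norm_jerks:
        out["normalized_jerk"] = float(np.mean(norm_jerks))

    dur_means, dur_sds, counts = [], [], []
    for task in ("T7_W3", "T7_W4"):
        rec = recs.get(task)
        if rec is None:
            continue
        t0, t1 = task_window(rec)
        rec_c = crop_streams(rec, (t0, t1))
        ankle = rec_c.imu("ankle_right" if rec.side == "right" else "ankle_left")
        if ankle is None:
            ankle = rec_c.imu("ankle_left") or rec_c.imu("ankle_right")
        if ankle is None or ankle.timestamps.size < 100:
            continue
        _, durations, count = detect_strides(ankle)
        if count >= 2:
            dur_means.append(durations.mean())
            dur_sds.append(_sd(durations))
            counts.append(count)
    if counts:
        out["stride_duration_mean"] = float(np.mean(dur_means))
        out["stride_duration_sd"] = float(np.mean(dur_sds))
        out["stride_count"] = float(math.floor(np.mean(counts) + 0.5))
    return out


def extract_all(session: Session) -> MetricVector:
    """Compute the full 62-metric vector for one session.

    Missingness (absent streams, zero detected movements, too-short
    signals) is recorded in the missing mask; the vector always carries
    exactly 62 named entries.
    """
    vec = MetricVector(session.subject_id, session.visit_day)

    def _apply(task: str, values: dict[str, float], prefix: str) -> None:
        for name, value in values.items():
            vec.set(f"{prefix}_{name}", value)

    for task in REACH_TASKS:
        if task in session.recordings:
            try:
                _apply(task, reach_metrics(session.recordings[task]), task.lower())
            except PdMotionError:
                pass
    for task in OPEN_CLOSE_TASKS:
        if task in session.recordings:
            try:
                _apply(task, open_close_metrics(session.recordings[task]), task.lower())
            except PdMotionError:
                pass
    if "T3" in session.recordings:
        try:
            _apply("T3", complex_task_metric(session.recordings["T3"]), "t3")
        except PdMotionError:
            pass
    for task, band in TREMOR_TASKS.items():
        if task in session.recordings:
            rec = session.recordings[task]
            try:
                _apply(task, tremor_metrics(rec, band), task.lower())
                for key, val in tremor_aux_metrics(rec, band).items():
                    vec.aux[f"{task.lower()}_{key}"] = val
            except PdMotionError:
                pass
    for task in BALANCE_TASKS:
        if task in session.recordings:
            try:
                _apply(task, balance_metrics(session.recordings[task]), task.lower())
            except PdMotionError:
                pass
    walks = {t: session.recordings[t] for t in WALK_TASKS if t in session.recordings}
    if walks:
        try:
            _apply("T7", gait_metrics(walks), "gait")
        except PdMotionError:
            pass

    # per-task times kept as auxiliary context
    for task, rec in session.recordings.items():
        try:
            t0, t1 = task_window(rec)
            vec.aux[f"{task.lower()}_task_time"] = t1 - t0
        except PdMotionError:
            pass
    return vec
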