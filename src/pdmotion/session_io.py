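"""On-disk session format and in-memory data model for multimodal recordings.

A *session* is one subject-visit: a set of task recordings, each combining
some of a camera skeleton stream (20 joints x 3D position, nominally 30 Hz),
one or more inertial measurement units (3-axis gyroscope in rad/s plus
3-axis accelerometer in m/s^2, nominally 64 Hz), a force-plate
center-of-pressure stream (2D, in cm, nominally 98 Hz), and a marker channel
whose first and last events bound the task.

On disk a session is a directory with a ``manifest.json`` and one UTF-8 CSV
per stream, all timestamped on a single session clock (synchronization is
assumed done upstream by the acquisition software).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from pdmotion.errors import FormatError, SegmentationError, ValidationError

# The 20-joint skeleton produced by the camera system.
JOINTS: tuple[str, ...] = (
    "hip_center",
    "spine",
    "shoulder_center",
    "head",
    "shoulder_l",
    "shoulder_r",
    "elbow_l",
    "elbow_r",
    "wrist_l",
    "wrist_r",
    "hand_l",
    "hand_r",
    "hip_l",
    "hip_r",
    "knee_l",
    "knee_r",
    "ankle_l",
    "ankle_r",
    "foot_l",
    "foot_r",
)

IMU_PLACEMENTS: tuple[str, ...] = ("index_finger", "l5", "ankle_right", "ankle_left")

# Motor-task registry. The exam comprises 7 tasks, several with variants,
# giving 14 recordings per session:
#   T1A/T1B continuous/discrete elbow flexion-extension; T2A/T2B hand
#   opening-closing at shoulder/waist level; T3 complex multi-joint sequence;
#   T4 hand-to-nose; T5A/T5B rest/postural hand tremor; T6 balance (eyes
#   open/closed); T7 four 10 m walks.
TASKS: tuple[str, ...] = (
    "T1A",
    "T1B",
    "T2A",
    "T2B",
    "T3",
    "T4",
    "T5A",
    "T5B",
    "T6_EO",
    "T6_EC",
    "T7_W1",
    "T7_W2",
    "T7_W3",
    "T7_W4",
)

UPPER_LIMB_TASKS = ("T1A", "T1B", "T2A", "T2B", "T3", "T4", "T5A", "T5B")
BALANCE_TASKS = ("T6_EO", "T6_EC")
WALK_TASKS = ("T7_W1", "T7_W2", "T7_W3", "T7_W4")

#: Required streams per task: (camera, imu placements, force plate).
REQUIRED_STREAMS: dict[str, tuple[bool, tuple[str, ...], bool]] = {
    **{t: (True, ("index_finger",), False) for t in UPPER_LIMB_TASKS},
    **{t: (False, ("l5",), True) for t in BALANCE_TASKS},
    **{t: (False, ("l5", "ankle"), False) for t in WALK_TASKS},
}

NOMINAL_RATES = {"camera": 30.0, "imu": 64.0, "plate": 98.0}

#: UPDRS-III motor-exam item identifiers (each scored 0-4).
UPDRS_ITEMS: tuple[str, ...] = tuple(f"Q{i}" for i in range(18, 32))


def _check_monotone(t: np.ndarray, stream: str) -> None:
    if t.size == 0:
        raise ValidationError(f"{stream}: empty timestamp vector")
    if not np.all(np.isfinite(t)):
        raise ValidationError(f"{stream}: non-finite timestamps")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        bad = int(np.argmax(np.diff(t) <= 0))
        raise ValidationError(
            f"{stream}: timestamps not strictly increasing at index {bad}"
        )


def _check_finite(a: np.ndarray, stream: str) -> None:
    if not np.all(np.isfinite(a)):
        bad = int(np.argwhere(~np.isfinite(a).reshape(a.shape[0], -1).all(axis=1))[0])
        raise ValidationError(f"{stream}: non-finite value at row {bad}")


@dataclass
class CameraTrack:
    """Skeleton stream: per-frame 3D positions of the 20 joints, in meters.

    Camera frame convention: x lateral (+right), y vertical (+up),
    z depth (+away from camera). ``positions`` has shape
    (n_frames, 20, 3), joint order per :data:`JOINTS`. Missing frames are
    flagged in ``missing`` (per-frame boolean).
    """

    timestamps: np.ndarray
    positions: np.ndarray
    missing: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(self.timestamps.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)

    def validate(self, name: str = "camera") -> None:
        _check_monotone(self.timestamps, name)
        if self.positions.shape != (self.timestamps.size, len(JOINTS), 3):
            raise ValidationError(
                f"{name}: positions shape {self.positions.shape} does not match "
                f"({self.timestamps.size}, {len(JOINTS)}, 3) — every frame needs "
                f"all {len(JOINTS)} joints"
            )
        if not np.all(np.isfinite(self.positions[~self.missing])):
            raise ValidationError(f"{name}: non-finite position in non-missing frame")
        if self.timestamps.size > 1:
            rate = 1.0 / np.median(np.diff(self.timestamps))
            if not (0.9 * NOMINAL_RATES["camera"] <= rate <= 1.1 * NOMINAL_RATES["camera"]):
                raise ValidationError(
                    f"{name}: median rate {rate:.1f} Hz outside 30 Hz +/- 10%"
                )

    def joint(self, name: str) -> np.ndarray:
        """(n_frames, 3) trajectory of one joint."""
        if name not in JOINTS:
            raise ValidationError(f"unknown joint {name!r}")
        return self.positions[:, JOINTS.index(name), :]

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.timestamps)))


@dataclass
class ImuTrack:
    """Inertial stream: 3-axis gyroscope (rad/s) and accelerometer (m/s^2).

    ``placement`` is one of :data:`IMU_PLACEMENTS`. Gyro axes are named
    x_rot/y_rot/z_rot; by convention x_rot is the flexion-extension axis of
    the instrumented segment (hand-open peaks for finger placement) and
    z_rot is the sagittal-plane rotation axis at the ankle (stride peaks).
    """

    placement: str
    timestamps: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)

    def validate(self, name: Optional[str] = None) -> None:
        name = name or f"imu_{self.placement}"
        if self.placement not in IMU_PLACEMENTS:
            raise ValidationError(f"{name}: unknown placement {self.placement!r}")
        _check_monotone(self.timestamps, name)
        n = self.timestamps.size
        if self.gyro.shape != (n, 3) or self.accel.shape != (n, 3):
            raise ValidationError(f"{name}: gyro/accel shapes must be ({n}, 3)")
        _check_finite(self.gyro, name)
        _check_finite(self.accel, name)

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.timestamps)))


@dataclass
class ForcePlateTrack:
    """Force-plate center-of-pressure stream, medio-lateral and
    antero-posterior components in centimeters."""

    timestamps: np.ndarray
    cop_ml: np.ndarray
    cop_ap: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.cop_ml = np.asarray(self.cop_ml, dtype=float)
        self.cop_ap = np.asarray(self.cop_ap, dtype=float)

    def validate(self, name: str = "plate") -> None:
        _check_monotone(self.timestamps, name)
        n = self.timestamps.size
        if self.cop_ml.shape != (n,) or self.cop_ap.shape != (n,):
            raise ValidationError(f"{name}: CoP components must have length {n}")
        for comp, arr in (("cop_ml", self.cop_ml), ("cop_ap", self.cop_ap)):
            bad = np.flatnonzero(~np.isfinite(arr))
            if bad.size:
                raise ValidationError(
                    f"{name}.{comp}: non-finite value at row {int(bad[0])}"
                )

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.timestamps)))


@dataclass
class MarkerChannel:
    """Event-marker channel set by the experimenter's remote controller."""

    event_times: np.ndarray
    labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if self.labels is None:
            self.labels = ["" for _ in range(self.event_times.size)]

    def validate(self, name: str = "marker") -> None:
        if self.event_times.size and not np.all(np.diff(self.event_times) >= 0):
            raise ValidationError(f"{name}: event times not sorted")
        if len(self.labels) != self.event_times.size:
            raise ValidationError(f"{name}: labels length mismatch")


@dataclass
class TaskRecording:
    """All synchronized streams for one motor task of one session."""

    task: str
    marker: MarkerChannel
    camera: Optional[CameraTrack] = None
    imus: list[ImuTrack] = field(default_factory=list)
    plate: Optional[ForcePlateTrack] = None
    side: str = "right"

    def imu(self, placement: str) -> Optional[ImuTrack]:
        for imu in self.imus:
            if imu.placement == placement:
                return imu
        return None

    def validate(self) -> None:
        if self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}")
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be left/right, got {self.side!r}")
        self.marker.validate(f"{self.task}/marker")
        if self.camera is not None:
            self.camera.validate(f"{self.task}/camera")
        for imu in self.imus:
            imu.validate(f"{self.task}/imu_{imu.placement}")
        if self.plate is not None:
            self.plate.validate(f"{self.task}/plate")

        need_cam, need_imus, need_plate = REQUIRED_STREAMS[self.task]
        if need_cam and self.camera is None:
            raise ValidationError(f"{self.task}: camera stream required")
        if need_plate and self.plate is None:
            raise ValidationError(f"{self.task}: force-plate stream required")
        placements = {imu.placement for imu in self.imus}
        for req in need_imus:
            if req == "ankle":
                if not placements & {"ankle_left", "ankle_right"}:
                    raise ValidationError(f"{self.task}: ankle IMU required")
            elif req not in placements:
                raise ValidationError(f"{self.task}: {req} IMU required")


@dataclass
class UPDRSExam:
    """UPDRS-III motor exam: item scores Q18-Q31 (each 0-4) and their sum."""

    items: dict[str, int]
    total: Optional[int] = None

    def __post_init__(self) -> None:
        if self.total is None:
            self.total = int(sum(self.items.values()))

    def validate(self) -> None:
        for key, score in self.items.items():
            if score not in (0, 1, 2, 3, 4):
                raise ValidationError(f"UPDRS {key}: score {score} outside 0..4")
        if self.total != sum(self.items.values()):
            raise ValidationError(
                f"UPDRS total {self.total} != sum of items {sum(self.items.values())}"
            )


@dataclass
class Session:
    """One subject-visit: task recordings plus the optional clinical exam."""

    subject_id: str
    visit_day: int
    recordings: dict[str, TaskRecording]
    updrs: Optional[UPDRSExam] = None
    side: str = "right"

    def validate(self) -> None:
        if not self.subject_id:
            raise ValidationError("subject_id must be nonempty")
        if self.visit_day not in (1, 2):
            raise ValidationError(f"visit_day must be 1 or 2, got {self.visit_day}")
        for task, rec in self.recordings.items():
            if task != rec.task:
                raise ValidationError(f"recording key {task} != rec.task {rec.task}")
            rec.validate()
        if self.updrs is not None:
            self.updrs.validate()


# ---------------------------------------------------------------------------
# Task windowing and cropping
# ---------------------------------------------------------------------------


def task_window(rec: TaskRecording) -> tuple[float, float]:
    """Task bounds: first and last marker event times.

    The experimenter marks at least the beginning and the end of each task;
    intermediate events are allowed and ignored. Total task time is
    ``t_end - t_start``.
    """
    t = rec.marker.event_times
    if t.size < 2:
        raise SegmentationError(
            f"{rec.task}: need >= 2 marker events to bound the task, got {t.size}"
        )
    t_start, t_end = float(t[0]), float(t[-1])
    if t_end <= t_start:
        raise SegmentationError(f"{rec.task}: degenerate task window")
    return t_start, t_end


def _crop_indices(t: np.ndarray, lo: float, hi: float, tol: float) -> np.ndarray:
    return np.flatnonzero((t >= lo - tol) & (t <= hi + tol))


def crop_streams(rec: TaskRecording, window: tuple[float, float]) -> TaskRecording:
    """Restrict every stream to the window, preserving the session clock.

    A skew tolerance of one nominal sample period is accepted at the
    boundaries (streams are synchronized upstream, not resampled here).
    """
    lo, hi = window
    out = TaskRecording(
        task=rec.task,
        marker=MarkerChannel(rec.marker.event_times.copy(), list(rec.marker.labels)),
        side=rec.side,
    )
    if rec.camera is not None:
        tol = 1.0 / NOMINAL_RATES["camera"]
        idx = _crop_indices(rec.camera.timestamps, lo, hi, tol)
        if idx.size == 0:
            raise ValidationError(f"{rec.task}/camera: crop window empty")
        out.camera = CameraTrack(
            rec.camera.timestamps[idx],
            rec.camera.positions[idx],
            rec.camera.missing[idx],
        )
    for imu in rec.imus:
        tol = 1.0 / NOMINAL_RATES["imu"]
        idx = _crop_indices(imu.timestamps, lo, hi, tol)
        if idx.size == 0:
            raise ValidationError(f"{rec.task}/imu_{imu.placement}: crop window empty")
        out.imus.append(
            ImuTrack(imu.placement, imu.timestamps[idx], imu.gyro[idx], imu.accel[idx])
        )
    if rec.plate is not None:
        tol = 1.0 / NOMINAL_RATES["plate"]
        idx = _crop_indices(rec.plate.timestamps, lo, hi, tol)
        if idx.size == 0:
            raise ValidationError(f"{rec.task}/plate: crop window empty")
        out.plate = ForcePlateTrack(
            rec.plate.timestamps[idx], rec.plate.cop_ml[idx], rec.plate.cop_ap[idx]
        )
    return out


# ---------------------------------------------------------------------------
# Disk format
# ---------------------------------------------------------------------------


def _camera_frame(track: CameraTrack) -> pd.DataFrame:
    cols = {"time_s": track.timestamps}
    for j, joint in enumerate(JOINTS):
        for k, ax in enumerate("xyz"):
            cols[f"{joint}_{ax}"] = track.positions[:, j, k]
    cols["missing"] = track.missing.astype(int)
    return pd.DataFrame(cols)


def _camera_from_frame(df: pd.DataFrame, name: str) -> CameraTrack:
    try:
        t = df["time_s"].to_numpy(float)
        pos = np.stack(
            [
                np.stack([df[f"{joint}_{ax}"].to_numpy(float) for ax in "xyz"], axis=1)
                for joint in JOINTS
            ],
            axis=1,
        )
    except KeyError as exc:
        raise FormatError(f"{name}: missing column {exc}") from exc
    missing = (
        df["missing"].to_numpy(bool) if "missing" in df.columns else None
    )
    return CameraTrack(t, pos, missing)


def _imu_frame(imu: ImuTrack) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": imu.timestamps,
            "gyro_x": imu.gyro[:, 0],
            "gyro_y": imu.gyro[:, 1],
            "gyro_z": imu.gyro[:, 2],
            "accel_x": imu.accel[:, 0],
            "accel_y": imu.accel[:, 1],
            "accel_z": imu.accel[:, 2],
        }
    )


def _imu_from_frame(df: pd.DataFrame, placement: str, name: str) -> ImuTrack:
    try:
        t = df["time_s"].to_numpy(float)
        gyro = df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(float)
        accel = df[["accel_x", "accel_y", "accel_z"]].to_numpy(float)
    except KeyError as exc:
        raise FormatError(f"{name}: missing column {exc}") from exc
    return ImuTrack(placement, t, gyro, accel)


def write_session(session: Session, path: str | Path) -> None:
    """Write a session directory: manifest.json plus one CSV per stream."""
    session.validate()
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "subject_id": session.subject_id,
        "visit_day": session.visit_day,
        "side": session.side,
        "tasks": sorted(session.recordings, key=TASKS.index),
        "streams": {},
        "rates_hz": NOMINAL_RATES,
    }
    for task in manifest["tasks"]:
        rec = session.recordings[task]
        tdir = root / task
        tdir.mkdir(exist_ok=True)
        entry: dict = {"imu": []}
        pd.DataFrame(
            {"time_s": rec.marker.event_times, "label": rec.marker.labels}
        ).to_csv(tdir / "marker.csv", index=False)
        entry["marker"] = f"{task}/marker.csv"
        if rec.camera is not None:
            _camera_frame(rec.camera).to_csv(tdir / "camera.csv", index=False)
            entry["camera"] = f"{task}/camera.csv"
        for imu in rec.imus:
            fname = f"imu_{imu.placement}.csv"
            _imu_frame(imu).to_csv(tdir / fname, index=False)
            entry["imu"].append(f"{task}/{fname}")
        if rec.plate is not None:
            pd.DataFrame(
                {
                    "time_s": rec.plate.timestamps,
                    "cop_ml_cm": rec.plate.cop_ml,
                    "cop_ap_cm": rec.plate.cop_ap,
                }
            ).to_csv(tdir / "plate.csv", index=False)
            entry["plate"] = f"{task}/plate.csv"
        manifest["streams"][task] = entry
    if session.updrs is not None:
        manifest["updrs"] = {"items": session.updrs.items, "total": session.updrs.total}
    with open(root / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)


def _read_csv(root: Path, rel: str) -> pd.DataFrame:
    fpath = root / rel
    if not fpath.exists():
        raise FormatError(f"manifest references absent file {rel}")
    return pd.read_csv(fpath)


def read_session(path: str | Path) -> Session:
    """Read and validate a session directory written by :func:`write_session`."""
    root = Path(path)
    mpath = root / "manifest.json"
    if not mpath.exists():
        raise FormatError(f"no manifest.json in {root}")
    with open(mpath, encoding="utf-8") as fh:
        manifest = json.load(fh)
    for key in ("subject_id", "visit_day", "side", "tasks", "streams"):
        if key not in manifest:
            raise FormatError(f"manifest missing key {key!r}")

    recordings: dict[str, TaskRecording] = {}
    for task in manifest["tasks"]:
        entry = manifest["streams"].get(task)
        if entry is None:
            raise FormatError(f"manifest lists task {task} without a streams entry")
        mdf = _read_csv(root, entry["marker"])
        marker = MarkerChannel(
            mdf["time_s"].to_numpy(float),
            [("" if pd.isna(x) else str(x)) for x in mdf.get("label", [])],
        )
        rec = TaskRecording(task=task, marker=marker, side=manifest["side"])
        if "camera" in entry:
            rec.camera = _camera_from_frame(
                _read_csv(root, entry["camera"]), f"{task}/camera"
            )
        for rel in entry.get("imu", []):
            placement = Path(rel).stem.removeprefix("imu_")
            rec.imus.append(
                _imu_from_frame(_read_csv(root, rel), placement, f"{task}/{rel}")
            )
        if "plate" in entry:
            pdf = _read_csv(root, entry["plate"])
            try:
                rec.plate = ForcePlateTrack(
                    pdf["time_s"].to_numpy(float),
                    pdf["cop_ml_cm"].to_numpy(float),
                    pdf["cop_ap_cm"].to_numpy(float),
                )
            except KeyError as exc:
                raise FormatError(f"{task}/plate: missing column {exc}") from exc
        recordings[task] = rec

    updrs = None
    if "updrs" in manifest:
        updrs = UPDRSExam(
            {k: int(v) for k, v in manifest["updrs"]["items"].items()},
            int(manifest["updrs"]["total"]),
        )
    session = Session(
        subject_id=str(manifest["subject_id"]),
        visit_day=int(manifest["visit_day"]),
        recordings=recordings,
        updrs=updrs,
        side=str(manifest["side"]),
    )
    session.validate()
    return session


def read_updrs_table(path: str | Path) -> pd.DataFrame:
    """Read a cohort UPDRS table (subject_id, visit_day, Q18..Q31, total)."""
    df = pd.read_csv(path)
    needed = {"subject_id", "visit_day", "total", *UPDRS_ITEMS}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"UPDRS table missing columns {sorted(missing)}")
    return df


def write_updrs_table(exams: list[tuple[str, int, UPDRSExam]], path: str | Path) -> None:
    rows = []
    for subject_id, visit_day, exam in exams:
        row = {"subject_id": subject_id, "visit_day": visit_day}
        row.update(exam.items)
        row["total"] = exam.total
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
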