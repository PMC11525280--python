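"""Synthetic multimodal sessions with controllable symptom severities.

No public recordings of this motor exam exist, so the package ships a
generator that emulates the full 7-task protocol: minimum-jerk reaching
slowed by bradykinesia, hand opening-closing bursts, 3-6 Hz rest and
5-8 Hz postural tremor on the finger accelerometer, center-of-pressure
sway as a mean-reverting random walk whose diffusion grows with postural
instability, and walks with stride-locked ankle-gyroscope bursts. A linked
UPDRS-III exam is produced from the same latent severities through a fixed
item-weight matrix plus ordinal rater noise, so parameter-recovery
experiments (metric-severity correlations, score prediction, phenotype
clustering) have a known ground truth.

Severities live in [0, 1] per symptom domain. All generator constants are
fields of :class:`SimConfig`; a single seed fixes every random draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from pdmotion.session_io import (
    JOINTS,
    CameraTrack,
    ForcePlateTrack,
    ImuTrack,
    MarkerChannel,
    Session,
    TaskRecording,
    UPDRSExam,
)

GRAVITY = 9.81

#: UPDRS item weights over the severity domains
#: (brady, trem_rest, trem_post, postural, gait); rows sum to 1 so an
#: all-ones profile saturates every item at 4.
UPDRS_WEIGHTS: dict[str, tuple[float, float, float, float, float]] = {
    "Q18": (0.2, 0.2, 0.2, 0.2, 0.2),   # speech
    "Q19": (0.2, 0.2, 0.2, 0.2, 0.2),   # facial expression
    "Q20": (0.0, 1.0, 0.0, 0.0, 0.0),   # rest tremor
    "Q21": (0.0, 0.0, 1.0, 0.0, 0.0),   # action/postural tremor
    "Q22": (0.5, 0.125, 0.125, 0.125, 0.125),  # rigidity (mixed)
    "Q23": (1.0, 0.0, 0.0, 0.0, 0.0),   # finger taps
    "Q24": (1.0, 0.0, 0.0, 0.0, 0.0),   # hand movements
    "Q25": (1.0, 0.0, 0.0, 0.0, 0.0),   # pronation-supination
    "Q26": (1.0, 0.0, 0.0, 0.0, 0.0),   # leg agility
    "Q27": (0.0, 0.0, 0.0, 0.5, 0.5),   # arising from chair
    "Q28": (0.0, 0.0, 0.0, 1.0, 0.0),   # posture
    "Q29": (0.0, 0.0, 0.0, 0.0, 1.0),   # gait
    "Q30": (0.0, 0.0, 0.0, 1.0, 0.0),   # postural stability
    "Q31": (1.0, 0.0, 0.0, 0.0, 0.0),   # body bradykinesia
}


@dataclass
class SeverityProfile:
    """Latent symptom severities in [0, 1] per domain."""

    s_brady: float = 0.0
    s_trem_rest: float = 0.0
    s_trem_post: float = 0.0
    s_postural: float = 0.0
    s_gait: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.s_brady, self.s_trem_rest, self.s_trem_post, self.s_postural, self.s_gait]
        )

    def clipped(self) -> "SeverityProfile":
        a = np.clip(self.as_array(), 0.0, 1.0)
        return SeverityProfile(*a.tolist())


@dataclass
class SimConfig:
    """Generator configuration; defaults encode the exam protocol
    (10 repetitions, 15 s balance holds, four 10 m walks) and sensor-noise
    levels consistent with consumer-grade hardware."""

    n_subjects: int = 50
    seed: int = 0
    # cohort severity model
    severity_alpha: float = 2.0
    severity_beta: float = 2.0
    domain_noise_sd: float = 0.15
    # planted-phenotype mode (0 disables)
    planted_k: int = 0
    planted_separation: float = 0.6
    planted_base: float = 0.15
    planted_base_sd: float = 0.08
    # UPDRS generation
    rater_noise_sd: float = 0.3
    # day-2 replicate
    day2: bool = False
    day2_drift_sd: float = 0.05
    # protocol
    reps: int = 10
    rest_duration_s: float = 30.0
    postural_duration_s: float = 15.0
    balance_duration_s: float = 15.0
    walk_distance_m: float = 10.0
    n_walks: int = 4
    # sampling rates (Hz)
    fs_camera: float = 30.0
    fs_imu: float = 64.0
    fs_plate: float = 98.0
    # reaching
    reach_amplitude_m: float = 0.45
    reach_duration_base_s: float = 0.4
    reach_duration_slope: float = 1.5
    # hand opening-closing
    open_close_period_base_s: float = 0.5
    open_close_period_slope: float = 1.5
    # complex sequence
    complex_time_base_s: float = 20.0
    complex_time_slope: float = 1.15
    # tremor
    tremor_accel_base: float = 0.02
    tremor_accel_gain: float = 0.25
    # balance
    cop_diffusion_base: float = 0.1
    cop_diffusion_slope: float = 4.0
    cop_eyes_closed_factor: float = 1.5
    cop_mean_reversion: float = 0.3
    sway_accel_base: float = 0.02
    sway_accel_slope: float = 4.0
    # gait
    walk_speed_base: float = 1.4
    walk_speed_slope: float = 0.5
    stride_period_base_s: float = 1.0
    stride_period_slope: float = 0.4
    gait_accel_base: float = 0.6
    gait_accel_slope: float = 1.0
    # sensor noise
    cam_noise_sd_m: float = 0.0015
    gyro_noise_sd: float = 0.05
    accel_noise_sd: float = 0.05
    cop_noise_sd_cm: float = 0.01
    pink_noise_sd: float = 0.03
    pad_s: float = 0.6

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Low-level signal builders
# ---------------------------------------------------------------------------


def _pink_noise(n: int, rng: np.random.Generator, sd: float) -> np.ndarray:
    """Approximate 1/f noise via spectral shaping."""
    if n < 4 or sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]
    spec /= np.sqrt(freqs)
    out = np.fft.irfft(spec, n)
    return sd * out / out.std()


def _min_jerk_pos(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk unit displacement profile on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


_BASE_SKELETON = {
    "hip_center": (0.0, 0.9, 2.5),
    "spine": (0.0, 1.1, 2.5),
    "shoulder_center": (0.0, 1.35, 2.5),
    "head": (0.0, 1.55, 2.5),
    "shoulder_l": (-0.2, 1.35, 2.5),
    "shoulder_r": (0.2, 1.35, 2.5),
    "elbow_l": (-0.25, 1.1, 2.45),
    "elbow_r": (0.25, 1.1, 2.45),
    "wrist_l": (-0.3, 0.9, 2.4),
    "wrist_r": (0.3, 0.9, 2.4),
    "hand_l": (-0.32, 0.85, 2.38),
    "hand_r": (0.32, 0.85, 2.38),
    "hip_l": (-0.12, 0.9, 2.5),
    "hip_r": (0.12, 0.9, 2.5),
    "knee_l": (-0.13, 0.5, 2.5),
    "knee_r": (0.13, 0.5, 2.5),
    "ankle_l": (-0.13, 0.1, 2.5),
    "ankle_r": (0.13, 0.1, 2.5),
    "foot_l": (-0.13, 0.05, 2.4),
    "foot_r": (0.13, 0.05, 2.4),
}


def _camera(
    duration: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    wrist: Optional[tuple[str, np.ndarray]] = None,
) -> CameraTrack:
    """Static skeleton plus sensor noise; optionally one joint follows the
    supplied displacement trajectory (n, 3)."""
    n = int(round(duration * cfg.fs_camera)) + 1
    t = np.arange(n) / cfg.fs_camera
    pos = np.empty((n, len(JOINTS), 3))
    for j, joint in enumerate(JOINTS):
        pos[:, j, :] = _BASE_SKELETON[joint]
    if wrist is not None:
        joint, traj = wrist
        pos[:, JOINTS.index(joint), :] += traj[:n]
    pos += rng.normal(0.0, cfg.cam_noise_sd_m, pos.shape)
    return CameraTrack(t, pos)


def _imu(
    placement: str,
    duration: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    gyro: Optional[np.ndarray] = None,
    accel: Optional[np.ndarray] = None,
) -> ImuTrack:
    """IMU stream = supplied clean components + gravity on the third accel
    axis + white and 1/f sensor noise."""
    n = int(round(duration * cfg.fs_imu)) + 1
    t = np.arange(n) / cfg.fs_imu
    g = np.zeros((n, 3)) if gyro is None else gyro[:n].copy()
    a = np.zeros((n, 3)) if accel is None else accel[:n].copy()
    a[:, 2] += GRAVITY
    g += rng.normal(0.0, cfg.gyro_noise_sd, g.shape)
    a += rng.normal(0.0, cfg.accel_noise_sd, a.shape)
    for k in range(3):
        a[:, k] += _pink_noise(n, rng, cfg.pink_noise_sd)
    return ImuTrack(placement, t, g, a)


def _marker(duration: float, pad: float) -> MarkerChannel:
    return MarkerChannel(np.array([pad, pad + duration]), ["start", "end"])


def _reach_trajectory(
    n_reps: int, amp: float, T: float, pause: float, pad: float, fs: float
) -> tuple[np.ndarray, float]:
    """Alternating up/down minimum-jerk reaches along the vertical axis.

    Returns (displacement (n, 3), active duration)."""
    duration = n_reps * T + (n_reps - 1) * pause
    n = int(round((duration + 2 * pad) * fs)) + 1
    t = np.arange(n) / fs
    y = np.zeros(n)
    level = 0.0
    for k in range(n_reps):
        start = pad + k * (T + pause)
        tau = (t - start) / T
        direction = 1.0 if k % 2 == 0 else -1.0
        y += direction * amp * _min_jerk_pos(tau)
        level += direction * amp
    traj = np.zeros((n, 3))
    traj[:, 1] = y
    traj[:, 2] = 0.05 * np.sin(np.pi * y / max(amp, 1e-9))  # slight arc in depth
    return traj, duration


# ---------------------------------------------------------------------------
# Task generators
# ---------------------------------------------------------------------------


def _reach_task(
    task: str,
    profile: SeverityProfile,
    cfg: SimConfig,
    rng: np.random.Generator,
    side: str,
) -> TaskRecording:
    T = cfg.reach_duration_base_s * (1 + cfg.reach_duration_slope * profile.s_brady)
    if task == "T4":
        T *= 1.4  # hand-to-nose at natural (slower) pace
    pause = {"T1A": 0.15, "T1B": 2.0, "T4": 0.4}[task]
    wrist = "wrist_r" if side == "right" else "wrist_l"
    traj, active = _reach_trajectory(
        cfg.reps, cfg.reach_amplitude_m, T, pause, cfg.pad_s, cfg.fs_camera
    )
    total = active + 2 * cfg.pad_s
    cam = _camera(total, cfg, rng, wrist=(wrist, traj))

    # finger gyro mirrors elbow angular velocity (movement half-cycles)
    n_imu = int(round(total * cfg.fs_imu)) + 1
    t_imu = np.arange(n_imu) / cfg.fs_imu
    gyro = np.zeros((n_imu, 3))
    for k in range(cfg.reps):
        start = cfg.pad_s + k * (T + pause)
        tau = (t_imu - start) / T
        inside = (tau >= 0) & (tau <= 1)
        direction = 1.0 if k % 2 == 0 else -1.0
        gyro[inside, 0] += direction * 3.5 * np.sin(np.pi * tau[inside]) ** 2
    imu = _imu("index_finger", total, cfg, rng, gyro=gyro)
    return TaskRecording(
        task=task, marker=_marker(active, cfg.pad_s), camera=cam, imus=[imu], side=side
    )


def _open_close_task(
    task: str, profile: SeverityProfile, cfg: SimConfig, rng: np.random.Generator, side: str
) -> TaskRecording:
    period = cfg.open_close_period_base_s * (
        1 + cfg.open_close_period_slope * profile.s_brady
    )
    active = cfg.reps * period
    total = active + 2 * cfg.pad_s
    n = int(round(total * cfg.fs_imu)) + 1
    t = np.arange(n) / cfg.fs_imu
    gyro = np.zeros((n, 3))
    inside = (t >= cfg.pad_s) & (t <= cfg.pad_s + active)
    # hand-open peaks once per period (positive x_rot lobes)
    phase = 2 * np.pi * (t - cfg.pad_s - period / 2.0) / period
    gyro[inside, 0] = 3.0 * np.sin(phase[inside])
    imu = _imu("index_finger", total, cfg, rng, gyro=gyro)
    cam = _camera(total, cfg, rng)
    return TaskRecording(
        task=task, marker=_marker(active, cfg.pad_s), camera=cam, imus=[imu], side=side
    )


def _complex_task(
    profile: SeverityProfile, cfg: SimConfig, rng: np.random.Generator, side: str
) -> TaskRecording:
    active = cfg.complex_time_base_s * (1 + cfg.complex_time_slope * profile.s_brady)
    total = active + 2 * cfg.pad_s
    n = int(round(total * cfg.fs_imu)) + 1
    t = np.arange(n) / cfg.fs_imu
    gyro = np.zeros((n, 3))
    gyro[:, 0] = 2.0 * np.sin(2 * np.pi * 0.8 * t)
    imu = _imu("index_finger", total, cfg, rng, gyro=gyro)
    wrist = "wrist_r" if side == "right" else "wrist_l"
    traj = np.zeros((n, 3))
    cam_n = int(round(total * cfg.fs_camera)) + 1
    t_cam = np.arange(cam_n) / cfg.fs_camera
    traj = np.zeros((cam_n, 3))
    traj[:, 1] = 0.2 * np.sin(2 * np.pi * 0.8 * t_cam)
    cam = _camera(total, cfg, rng, wrist=(wrist, traj))
    return TaskRecording(
        task="T3", marker=_marker(active, cfg.pad_s), camera=cam, imus=[imu], side=side
    )


def _tremor_task(
    task: str, profile: SeverityProfile, cfg: SimConfig, rng: np.random.Generator, side: str
) -> TaskRecording:
    if task == "T5A":
        duration = cfg.rest_duration_s
        sev = profile.s_trem_rest
        freq = rng.uniform(3.5, 5.5)
    else:
        duration = cfg.postural_duration_s
        sev = profile.s_trem_post
        freq = rng.uniform(5.5, 7.5)
    total = duration + 2 * cfg.pad_s
    n = int(round(total * cfg.fs_imu)) + 1
    t = np.arange(n) / cfg.fs_imu
    amp = cfg.tremor_accel_base + cfg.tremor_accel_gain * sev
    phase = rng.uniform(0, 2 * np.pi)
    accel = np.zeros((n, 3))
    # tremor mostly along the gravity axis so the demeaned amplitude keeps it
    accel[:, 2] = amp * np.sin(2 * np.pi * freq * t + phase)
    accel[:, 0] = 0.3 * amp * np.sin(2 * np.pi * freq * t + phase + 0.7)
    gyro = np.zeros((n, 3))
    gyro[:, 0] = 0.2 * amp * np.sin(2 * np.pi * freq * t + phase)
    imu = _imu("index_finger", total, cfg, rng, gyro=gyro, accel=accel)
    cam = _camera(total, cfg, rng)
    return TaskRecording(
        task=task, marker=_marker(duration, cfg.pad_s), camera=cam, imus=[imu], side=side
    )


def _balance_task(
    task: str, profile: SeverityProfile, cfg: SimConfig, rng: np.random.Generator, side: str
) -> TaskRecording:
    duration = cfg.balance_duration_s
    total = duration + 2 * cfg.pad_s
    n = int(round(total * cfg.fs_plate)) + 1
    dt = 1.0 / cfg.fs_plate
    sigma = cfg.cop_diffusion_base * (1 + cfg.cop_diffusion_slope * profile.s_postural)
    if task == "T6_EC":
        sigma *= cfg.cop_eyes_closed_factor
    cop = np.zeros((n, 2))
    steps = rng.normal(0.0, sigma * np.sqrt(dt), (n - 1, 2))
    for i in range(1, n):
        cop[i] = cop[i - 1] * (1 - cfg.cop_mean_reversion * dt) + steps[i - 1]
    cop += rng.normal(0.0, cfg.cop_noise_sd_cm, cop.shape)
    t = np.arange(n) * dt
    plate = ForcePlateTrack(t, cop[:, 0], cop[:, 1])

    # trunk sway acceleration: smooth coloured noise scaled by severity
    n_imu = int(round(total * cfg.fs_imu)) + 1
    a_sd = cfg.sway_accel_base * (1 + cfg.sway_accel_slope * profile.s_postural)
    from pdmotion.signal_prep import lowpass_butter

    accel = np.zeros((n_imu, 3))
    for k in range(2):
        accel[:, k] = lowpass_butter(
            rng.normal(0.0, a_sd * 4.0, n_imu), cfg.fs_imu, cutoff=2.0, order=2
        )
    imu = _imu("l5", total, cfg, rng, accel=accel)
    return TaskRecording(
        task=task, marker=_marker(duration, cfg.pad_s), plate=plate, imus=[imu], side=side
    )


def _walk_task(
    task: str, profile: SeverityProfile, cfg: SimConfig, rng: np.random.Generator, side: str
) -> TaskRecording:
    speed = cfg.walk_speed_base * (1 - cfg.walk_speed_slope * profile.s_gait)
    walk_time = cfg.walk_distance_m / speed
    period = cfg.stride_period_base_s * (1 + cfg.stride_period_slope * profile.s_gait)
    total = walk_time + 2 * cfg.pad_s
    n = int(round(total * cfg.fs_imu)) + 1
    t = np.arange(n) / cfg.fs_imu

    def ankle(placement: str, phase_shift: float) -> ImuTrack:
        z = np.zeros(n)
        k = 0
        while True:
            center = cfg.pad_s + period / 2.0 + phase_shift + k * period
            if center > cfg.pad_s + walk_time - period / 4.0:
                break
            z += 4.0 * np.exp(-0.5 * ((t - center) / 0.08) ** 2)
            k += 1
        gyro = np.zeros((n, 3))
        gyro[:, 2] = z
        return _imu(placement, total, cfg, rng, gyro=gyro)

    step_freq = 2.0 / period
    a_amp = cfg.gait_accel_base * (1 + cfg.gait_accel_slope * profile.s_gait)
    accel = np.zeros((n, 3))
    inside = (t >= cfg.pad_s) & (t <= cfg.pad_s + walk_time)
    accel[inside, 0] = a_amp * np.sin(2 * np.pi * step_freq * t[inside])
    accel[inside, 1] = 0.6 * a_amp * np.sin(np.pi * step_freq * t[inside] + 0.4)
    l5 = _imu("l5", total, cfg, rng, accel=accel)
    imus = [l5, ankle("ankle_right", 0.0), ankle("ankle_left", period / 2.0)]
    return TaskRecording(
        task=task, marker=_marker(walk_time, cfg.pad_s), imus=imus, side=side
    )


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def simulate_subject(
    profile: SeverityProfile,
    config: Optional[SimConfig] = None,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "S000",
    visit_day: int = 1,
    side: str = "right",
) -> Session:
    """Generate one complete 14-task session for the given severities."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    profile = profile.clipped()
    recs: dict[str, TaskRecording] = {}
    for task in ("T1A", "T1B", "T4"):
        recs[task] = _reach_task(task, profile, cfg, rng, side)
    for task in ("T2A", "T2B"):
        recs[task] = _open_close_task(task, profile, cfg, rng, side)
    recs["T3"] = _complex_task(profile, cfg, rng, side)
    for task in ("T5A", "T5B"):
        recs[task] = _tremor_task(task, profile, cfg, rng, side)
    for task in ("T6_EO", "T6_EC"):
        recs[task] = _balance_task(task, profile, cfg, rng, side)
    for task in ("T7_W1", "T7_W2", "T7_W3", "T7_W4"):
        recs[task] = _walk_task(task, profile, cfg, rng, side)
    session = Session(
        subject_id=subject_id, visit_day=visit_day, recordings=recs, side=side
    )
    session.validate()
    return session


def simulate_updrs(
    profile: SeverityProfile,
    rater_noise_sd: float = 0.3,
    seed: int | np.random.SeedSequence = 0,
) -> UPDRSExam:
    """Ordinal UPDRS-III exam linked to the severity profile.

    Item score = clip(round(4 * w_item . s + eps), 0, 4) with
    eps ~ N(0, rater_noise_sd) emulating rater variability.
    """
    rng = np.random.default_rng(seed)
    s = profile.clipped().as_array()
    items = {}
    for item, w in UPDRS_WEIGHTS.items():
        raw = 4.0 * float(np.dot(w, s)) + rng.normal(0.0, rater_noise_sd)
        items[item] = int(np.clip(round(raw), 0, 4))
    return UPDRSExam(items)


def _draw_profiles(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[SeverityProfile], list[str]]:
    profiles, labels = [], []
    if cfg.planted_k > 0:
        archetypes = ["tremor", "bradykinesia", "instability", "gait"][: cfg.planted_k]
        for i in range(cfg.n_subjects):
            arch = archetypes[i % len(archetypes)]
            base = np.clip(
                cfg.planted_base + rng.normal(0.0, cfg.planted_base_sd, 5), 0.0, 1.0
            )
            s = SeverityProfile(*base.tolist())
            if arch == "tremor":
                s.s_trem_rest += cfg.planted_separation
                s.s_trem_post += cfg.planted_separation
            elif arch == "bradykinesia":
                s.s_brady += cfg.planted_separation
            elif arch == "instability":
                s.s_postural += cfg.planted_separation
            else:
                s.s_gait += cfg.planted_separation
            profiles.append(s.clipped())
            labels.append(arch)
    else:
        for _ in range(cfg.n_subjects):
            g = rng.beta(cfg.severity_alpha, cfg.severity_beta)
            s = np.clip(g + rng.normal(0.0, cfg.domain_noise_sd, 5), 0.0, 1.0)
            profiles.append(SeverityProfile(*s.tolist()))
            labels.append("")
    return profiles, labels


@dataclass
class CohortResult:
    """Simulated cohort: observed data plus the generating ground truth."""

    sessions: list[Session]
    updrs: pd.DataFrame
    truth: pd.DataFrame
    day2_sessions: list[Session] = field(default_factory=list)
    day2_updrs: Optional[pd.DataFrame] = None


def simulate_cohort(config: Optional[SimConfig] = None) -> CohortResult:
    """Generate a cohort of sessions with linked UPDRS exams.

    Severities come from a latent global-severity model (g ~ Beta(a, b),
    domain severity = clip(g + noise)) or, in planted-phenotype mode, from
    k archetype groups separated by ``planted_separation`` in their
    signature domains. The truth table records severities and labels for
    parameter-recovery experiments. With ``day2=True`` each subject gets a
    replicate visit with small severity drift.
    """
    cfg = config or SimConfig()
    root = np.random.SeedSequence(cfg.seed)
    ss_draw, ss_subj, ss_updrs, ss_day2 = root.spawn(4)
    rng = np.random.default_rng(ss_draw)
    profiles, labels = _draw_profiles(cfg, rng)

    subj_seeds = ss_subj.spawn(cfg.n_subjects)
    updrs_seeds = ss_updrs.spawn(cfg.n_subjects)
    sessions, updrs_rows, truth_rows = [], [], []
    for i, profile in enumerate(profiles):
        sid = f"S{i:03d}"
        session = simulate_subject(
            profile, cfg, seed=subj_seeds[i], subject_id=sid, visit_day=1
        )
        exam = simulate_updrs(profile, cfg.rater_noise_sd, seed=updrs_seeds[i])
        session.updrs = exam
        sessions.append(session)
        updrs_rows.append(
            {"subject_id": sid, "visit_day": 1, **exam.items, "total": exam.total}
        )
        truth_rows.append(
            {
                "subject_id": sid,
                "phenotype": labels[i],
                "s_brady": profile.s_brady,
                "s_trem_rest": profile.s_trem_rest,
                "s_trem_post": profile.s_trem_post,
                "s_postural": profile.s_postural,
                "s_gait": profile.s_gait,
            }
        )

    day2_sessions: list[Session] = []
    day2_rows = []
    if cfg.day2:
        d2_seeds = ss_day2.spawn(2 * cfg.n_subjects + 1)
        drift_rng = np.random.default_rng(d2_seeds[-1])
        for i, profile in enumerate(profiles):
            drifted = SeverityProfile(
                *(profile.as_array() + drift_rng.normal(0.0, cfg.day2_drift_sd, 5))
            ).clipped()
            sid = f"S{i:03d}"
            session = simulate_subject(
                drifted, cfg, seed=d2_seeds[2 * i], subject_id=sid, visit_day=2
            )
            exam = simulate_updrs(drifted, cfg.rater_noise_sd, seed=d2_seeds[2 * i + 1])
            session.updrs = exam
            day2_sessions.append(session)
            day2_rows.append(
                {"subject_id": sid, "visit_day": 2, **exam.items, "total": exam.total}
            )

    return CohortResult(
        sessions=sessions,
        updrs=pd.DataFrame(updrs_rows),
        truth=pd.DataFrame(truth_rows),
        day2_sessions=day2_sessions,
        day2_updrs=pd.DataFrame(day2_rows) if day2_rows else None,
    )
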