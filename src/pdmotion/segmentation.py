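"""Segmentation of task recordings into elementary movements and events.

Reaching-type tasks are segmented on the wrist speed profile: contiguous
regions of activity are located, extended outward to the enclosing speed
minima, and split at interior minima that dip below a fraction ``theta`` of
the neighbouring peaks. When the speed profile is too degraded to show the
expected repetitions (severely bradykinetic movement), boundaries are
refined from zero crossings of the finger gyroscope's flexion-extension
component. Discrete events — hand-fully-open peaks and strides — are
detected as gyroscope peaks with prominence/height and refractory criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from pdmotion.session_io import ImuTrack
from pdmotion.signal_prep import SpeedProfile, lowpass_butter

#: Fraction of the neighbouring segment peaks a speed minimum must dip
#: below to count as a movement boundary.
SEGMENT_THETA = 0.2
#: Minimum spacing between reach boundaries / hand-open events (s).
SEGMENT_REFRACTORY_S = 0.25
#: Fraction of the global peak speed below which samples count as rest.
ACTIVITY_FRAC = 0.1
#: Fraction of the local peak speed below which boundary extension stops
#: (keeps zero-phase filter tails out of the movement).
EDGE_FLOOR_FRAC = 0.002
#: Stride peaks: height threshold is mean + K * SD of the gyro signal.
STRIDE_HEIGHT_K_SD = 1.0
#: Minimum spacing between stride peaks (s).
STRIDE_REFRACTORY_S = 0.5
#: Absolute stride-peak floor (rad/s): rejects sensor noise when no real
#: gait rotation is present.
STRIDE_MIN_HEIGHT = 0.5
#: Hand-open peaks keep prominence >= this fraction of the median
#: positive-peak prominence.
HANDOPEN_PROMINENCE_FRAC = 0.5


@dataclass
class MovementSegment:
    """One elementary movement with its per-movement kinematics."""

    t_start: float
    t_end: float
    mean_speed: float
    max_speed: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def smoothness(self) -> float:
        """Ratio of mean to max speed; 1 only for constant-speed movement."""
        return self.mean_speed / self.max_speed


@dataclass
class EventSeries:
    """Sorted discrete event times of one kind (hand_open or stride)."""

    times: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.times)


def _active_regions(active: np.ndarray, gap: int) -> list[tuple[int, int]]:
    """Contiguous True runs, merging runs separated by fewer than ``gap``."""
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > gap)
    starts = np.concatenate([[idx[0]], idx[splits + 1]])
    ends = np.concatenate([idx[splits], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def _extend_to_minima(v: np.ndarray, i0: int, i1: int, floor: float) -> tuple[int, int]:
    # strictly decreasing walk from the activity threshold to the movement
    # edge; flat plateaus (rest) and the noise/filter-tail floor stop it
    while i0 > 0 and floor <= v[i0 - 1] < v[i0]:
        i0 -= 1
    while i1 < v.size - 1 and floor <= v[i1 + 1] < v[i1]:
        i1 += 1
    return i0, i1


def _split_at_minima(v: np.ndarray, i0: int, i1: int, dist: int, theta: float) -> list[int]:
    """Boundaries (absolute indices incl. i0/i1) splitting [i0, i1] at
    interior minima deep enough relative to the flanking peaks."""
    seg = v[i0 : i1 + 1]
    minima, _ = sps.find_peaks(-seg, distance=dist)
    bounds = [0, *minima.tolist(), seg.size - 1]
    # iteratively drop the shallowest violating boundary (merge intervals)
    while len(bounds) > 2:
        peaks = [seg[bounds[k] : bounds[k + 1] + 1].max() for k in range(len(bounds) - 1)]
        ratios = [
            seg[bounds[k]] / max(min(peaks[k - 1], peaks[k]), 1e-300)
            for k in range(1, len(bounds) - 1)
        ]
        worst = int(np.argmax(ratios))
        if ratios[worst] < theta:
            break
        del bounds[worst + 1]
    return [i0 + b for b in bounds]


def segment_movements(
    profile: SpeedProfile,
    gyro: Optional[ImuTrack] = None,
    expected_n: Optional[int] = None,
    theta: float = SEGMENT_THETA,
    refractory_s: float = SEGMENT_REFRACTORY_S,
    activity_frac: float = ACTIVITY_FRAC,
) -> list[MovementSegment]:
    """Split a speed profile into elementary movements.

    If fewer than ``expected_n`` segments are found and a finger gyroscope
    is available, boundaries are refined from zero crossings of its
    flexion-extension component (each movement is a half-cycle of x_rot).
    Returns an empty list (not an error) when no movement is present.
    """
    v = np.asarray(profile.v, dtype=float)
    t = profile.timestamps
    fs = profile.fs
    vmax = float(v.max(initial=0.0))
    if vmax <= 1e-9:
        return []
    dist = max(1, int(round(refractory_s * fs)))

    segments: list[MovementSegment] = []
    for r0, r1 in _active_regions(v > activity_frac * vmax, dist):
        floor = EDGE_FLOOR_FRAC * float(v[r0 : r1 + 1].max())
        i0, i1 = _extend_to_minima(v, r0, r1, floor)
        bounds = _split_at_minima(v, i0, i1, dist, theta)
        for k in range(len(bounds) - 1):
            a, b = bounds[k], bounds[k + 1]
            seg_v = v[a : b + 1]
            if seg_v.max() <= activity_frac * vmax or b - a < 2:
                continue
            segments.append(
                MovementSegment(
                    t_start=float(t[a]),
                    t_end=float(t[b]),
                    mean_speed=float(seg_v.mean()),
                    max_speed=float(seg_v.max()),
                )
            )

    if (
        expected_n is not None
        and len(segments) < expected_n
        and gyro is not None
        and gyro.timestamps.size > 40
    ):
        refined = _segments_from_gyro(profile, gyro, refractory_s, activity_frac)
        if len(refined) > len(segments):
            segments = refined
    return segments


def _segments_from_gyro(
    profile: SpeedProfile,
    gyro: ImuTrack,
    refractory_s: float,
    activity_frac: float,
) -> list[MovementSegment]:
    """Boundary refinement from gyro zero crossings (severely degraded
    speed profiles): each half-cycle of the filtered x_rot component is one
    flexion or extension movement."""
    x = lowpass_butter(gyro.gyro[:, 0], gyro.fs, cutoff=5.0)
    sign = np.sign(x)
    sign[sign == 0] = 1
    crossings = np.flatnonzero(np.diff(sign) != 0)
    if crossings.size < 2:
        return []
    times = gyro.timestamps[crossings]
    keep = [0]
    for i in range(1, times.size):
        if times[i] - times[keep[-1]] >= refractory_s:
            keep.append(i)
    times = times[keep]

    v, t = profile.v, profile.timestamps
    vmax = v.max()
    segments: list[MovementSegment] = []
    for a_t, b_t in zip(times[:-1], times[1:]):
        mask = (t >= a_t) & (t <= b_t)
        if mask.sum() < 3:
            continue
        seg_v = v[mask]
        if seg_v.max() <= activity_frac * vmax:
            continue
        segments.append(
            MovementSegment(
                t_start=float(a_t),
                t_end=float(b_t),
                mean_speed=float(seg_v.mean()),
                max_speed=float(seg_v.max()),
            )
        )
    return segments


def detect_hand_open_events(
    imu: ImuTrack,
    refractory_s: float = SEGMENT_REFRACTORY_S,
    prominence_frac: float = HANDOPEN_PROMINENCE_FRAC,
) -> EventSeries:
    """Hand-fully-open events: positive peaks of the gyroscope's
    flexion-extension component (x_rot), lowpass filtered at 5 Hz.

    Peaks must be positive, spaced at least ``refractory_s`` apart, and
    have prominence at least ``prominence_frac`` times the median
    prominence of all positive peaks (rejects ripple between openings).
    """
    fs = imu.fs
    x = lowpass_butter(imu.gyro[:, 0], fs, cutoff=5.0)
    dist = max(1, int(round(refractory_s * fs)))
    peaks, props = sps.find_peaks(x, distance=dist, prominence=0.0)
    peaks = peaks[x[peaks] > 0]
    if peaks.size == 0:
        return EventSeries(np.empty(0), "hand_open")
    # pad with the global minimum so edge peaks get their full prominence
    xp = np.concatenate([[x.min()], x, [x.min()]])
    prom = sps.peak_prominences(xp, peaks + 1)[0]
    med = np.median(prom)
    keep = prom >= prominence_frac * med
    return EventSeries(imu.timestamps[peaks[keep]], "hand_open")


def detect_strides(
    imu: ImuTrack,
    height_k_sd: float = STRIDE_HEIGHT_K_SD,
    refractory_s: float = STRIDE_REFRACTORY_S,
    min_height: float = STRIDE_MIN_HEIGHT,
) -> tuple[EventSeries, np.ndarray, int]:
    """Stride events from an ankle gyroscope.

    Peaks of the sagittal-plane component (z_rot, where gait rotation is
    most evident), lowpass filtered at 5 Hz, with height at least
    mean + ``height_k_sd`` * SD of the filtered signal and spacing at least
    ``refractory_s``; an absolute floor ``min_height`` rejects noise-only
    recordings. Returns (events, stride durations, stride count).
    """
    fs = imu.fs
    z = lowpass_butter(imu.gyro[:, 2], fs, cutoff=5.0)
    height = max(z.mean() + height_k_sd * z.std(), min_height)
    dist = max(1, int(round(refractory_s * fs)))
    peaks, _ = sps.find_peaks(z, height=height, distance=dist)
    times = imu.timestamps[peaks]
    events = EventSeries(times, "stride")
    return events, np.diff(times), int(times.size)
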