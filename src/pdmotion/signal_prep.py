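"""Filtering, differentiation, and spectral primitives for metric extraction.

All filters are applied forward-backward (zero phase) so that segmentation
boundaries and peak times carry no filter delay. Spectral power is estimated
with DPSS multitapers (NW=4, 7 tapers) on demeaned amplitude signals; total
power is integrated from 0.5 Hz to Nyquist to exclude DC / gravity leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from pdmotion.errors import ValidationError
from pdmotion.session_io import CameraTrack, ImuTrack

#: Default FIR length (taps) for the 10 Hz position lowpass.
FIR_TAPS = 31
#: Multitaper time-bandwidth product and taper count.
SPECTRUM_NW = 4.0
SPECTRUM_K = 7
#: Lower integration bound for "total power" (Hz); excludes DC leakage.
SPECTRUM_F_MIN = 0.5
#: Edge margin (s) excluded from peak statistics of filtered-then-
#: differentiated signals, to suppress zero-phase filter transients.
EDGE_MARGIN_S = 0.25


@dataclass
class SpeedProfile:
    """Speed magnitude of a joint trajectory (m/s) on its own time base."""

    timestamps: np.ndarray
    v: np.ndarray

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.timestamps)))


@dataclass
class Spectrum:
    """One-sided power spectral density estimate."""

    freqs: np.ndarray
    power: np.ndarray
    method: str


def lowpass_fir(x: np.ndarray, fs: float, cutoff: float, taps: int = FIR_TAPS) -> np.ndarray:
    """Zero-phase Hamming-window FIR lowpass.

    Applied forward-backward with ``filtfilt``, so the effective magnitude
    response is the squared design response and phase is identically zero.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 2 * cutoff:
        raise ValidationError(f"fs={fs} must exceed twice the cutoff {cutoff}")
    if x.shape[-1] <= 3 * taps:
        raise ValidationError(
            f"signal length {x.shape[-1]} too short for a {taps}-tap zero-phase filter"
        )
    b = sps.firwin(taps, cutoff, fs=fs, window="hamming")
    return sps.filtfilt(b, [1.0], x, axis=-1)


def lowpass_butter(
    x: np.ndarray, fs: float, cutoff: float = 5.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth lowpass (designed order ``order``, applied
    forward-backward so the magnitude response is squared)."""
    x = np.asarray(x, dtype=float)
    if fs <= 2 * cutoff:
        raise ValidationError(f"fs={fs} must exceed twice the cutoff {cutoff}")
    sos = sps.butter(order, cutoff, fs=fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if x.shape[-1] <= padlen:
        raise ValidationError(f"signal length {x.shape[-1]} too short to filter")
    return sps.sosfiltfilt(sos, x, axis=-1)


def derivative(x: np.ndarray, fs: float) -> np.ndarray:
    """First time-derivative: central differences interior, one-sided ends."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise ValidationError("derivative needs at least 3 samples")
    return np.gradient(x, 1.0 / fs, axis=-1)


def speed_profile(track: CameraTrack, joint: str, cutoff: float = 10.0) -> SpeedProfile:
    """Speed profile of one joint: 10 Hz FIR-filtered positions,
    differentiated, Euclidean norm of the three velocity components."""
    pos = track.joint(joint)  # (n, 3)
    fs = track.fs
    if pos.shape[0] < fs:
        raise ValidationError(f"need >= 1 s of camera data for joint {joint}")
    filt = lowpass_fir(pos.T, fs, cutoff)  # (3, n)
    vel = derivative(filt, fs)
    v = np.linalg.norm(vel, axis=0)
    return SpeedProfile(track.timestamps.copy(), v)


def interpolate_missing(track: CameraTrack, max_gap: int = 3) -> CameraTrack:
    """Linearly interpolate missing camera frames with gaps <= ``max_gap``.

    Longer gaps stay flagged; downstream per-movement statistics drop
    segments overlapping them.
    """
    missing = track.missing.copy()
    pos = track.positions.copy()
    if not missing.any():
        return track
    idx = np.flatnonzero(missing)
    good = np.flatnonzero(~missing)
    if good.size < 2:
        return track
    # group consecutive missing indices
    groups = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for grp in groups:
        if grp.size > max_gap or grp[0] == 0 or grp[-1] == missing.size - 1:
            continue
        lo, hi = grp[0] - 1, grp[-1] + 1
        w = (track.timestamps[grp] - track.timestamps[lo]) / (
            track.timestamps[hi] - track.timestamps[lo]
        )
        pos[grp] = pos[lo] + w[:, None, None] * (pos[hi] - pos[lo])
        missing[grp] = False
    return CameraTrack(track.timestamps.copy(), pos, missing)


def accel_amplitude(imu: ImuTrack) -> np.ndarray:
    """Mean-removed Euclidean norm of the 3 accelerometer components.

    Demeaning removes the quasi-static gravity contribution so band-power
    ratios reflect oscillatory (tremor) content only.
    """
    amp = np.linalg.norm(imu.accel, axis=1)
    return amp - amp.mean()


def spectrum(x: np.ndarray, fs: float, method: str = "multitaper") -> Spectrum:
    """One-sided PSD of a demeaned signal.

    ``multitaper`` averages periodograms over 7 DPSS tapers (NW=4);
    ``fft`` is a single Hann-taper periodogram.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    if method == "multitaper":
        tapers = sps.windows.dpss(n, SPECTRUM_NW, Kmax=SPECTRUM_K)
        psd = np.zeros(n // 2 + 1)
        freqs = np.fft.rfftfreq(n, 1.0 / fs)
        for taper in tapers:
            spec = np.fft.rfft(x * taper)
            psd += (np.abs(spec) ** 2) / fs
        psd /= SPECTRUM_K
        # one-sided correction (all bins except DC and Nyquist-if-even)
        psd[1:] *= 2.0
        if n % 2 == 0:
            psd[-1] /= 2.0
        return Spectrum(freqs, psd, "multitaper")
    if method == "fft":
        freqs, psd = sps.periodogram(x, fs=fs, window="hann", detrend="constant")
        return Spectrum(freqs, psd, "fft")
    raise ValidationError(f"unknown spectral method {method!r}")


def band_power_ratio(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float],
    method: str = "multitaper",
    f_min: float = SPECTRUM_F_MIN,
) -> float:
    """Fraction of spectral power inside ``band`` relative to total power
    (integrated from ``f_min`` to Nyquist)."""
    x = np.asarray(x, dtype=float)
    lo, hi = band
    nyq = fs / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValidationError(f"band {band} outside (0, {nyq}) Hz")
    if x.size < 4 * fs:
        raise ValidationError(
            f"band_power_ratio needs >= 4 s of signal, got {x.size / fs:.2f} s"
        )
    spec = spectrum(x, fs, method=method)

    def _integrate(flo: float, fhi: float) -> float:
        mask = (spec.freqs >= flo) & (spec.freqs <= fhi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(spec.power[mask], spec.freqs[mask]))

    total = _integrate(f_min, nyq)
    if total <= 0:
        return 0.0
    return min(_integrate(lo, hi) / total, 1.0)


def jerk(accel_2d: np.ndarray, fs: float) -> tuple[np.ndarray, float, float]:
    """Jerk amplitude from two horizontal acceleration components.

    ``accel_2d`` has shape (n, 2): antero-posterior and medio-lateral
    acceleration (already lowpass filtered). Returns the jerk-amplitude
    signal (norm of the per-direction derivatives) plus its mean and peak,
    with one :data:`EDGE_MARGIN_S` margin excluded at each end of the peak
    statistic to suppress differentiation edge transients.
    """
    accel_2d = np.asarray(accel_2d, dtype=float)
    if accel_2d.ndim != 2 or accel_2d.shape[1] != 2:
        raise ValidationError("jerk expects an (n, 2) AP/ML acceleration array")
    if accel_2d.shape[0] < 3:
        raise ValidationError("jerk needs at least 3 samples")
    j = derivative(accel_2d.T, fs)  # (2, n)
    amp = np.linalg.norm(j, axis=0)
    margin = int(round(EDGE_MARGIN_S * fs))
    core = amp[margin : amp.size - margin] if amp.size > 2 * margin else amp
    return amp, float(core.mean()), float(core.max())


def edge_mask(n: int, fs: float, margin_s: float = EDGE_MARGIN_S) -> np.ndarray:
    """Boolean mask that is False within ``margin_s`` of either end."""
    m = int(round(margin_s * fs))
    mask = np.ones(n, dtype=bool)
    if 2 * m < n:
        mask[:m] = False
        mask[n - m :] = False
    return mask
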