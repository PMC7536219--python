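"""Observables: RR tachogram, LF/HF spectral powers, and the total percent
of phase synchronization (S index).

The S index quantifies intermittent locking between the ~0.1 Hz components
of heart rate and arterial pressure (in experiments: photoplethysmogram).
Both signals are band-passed (0.05-0.15 Hz), instantaneous phases are taken
from the analytic signal, and horizontal plateaus of the unwrapped phase
difference are detected with a sliding-window linear fit; S is the plateau
time as a percent of the accounted record duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal

__all__ = [
    "BeatSeries", "UniformSeries", "SpectralIndexes", "SyncResult",
    "rr_to_uniform", "spectral_indexes", "rr_spectral_indexes",
    "bandpass_phase", "detect_plateaus", "s_index", "resample_uniform",
]

LF_BAND = (0.04, 0.15)     # Hz
HF_BAND = (0.15, 0.40)     # Hz
SYNC_BAND = (0.05, 0.15)   # Hz, band of the S-index pipeline
FS_RESAMPLE = 4.0          # Hz, tachogram resampling rate


@dataclass(frozen=True)
class BeatSeries:
    """Beat times with RR intervals and optional per-beat pressures."""

    times: np.ndarray            # s, strictly increasing
    rr: np.ndarray               # s, > 0
    sap: np.ndarray | None = None
    dap: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        rr = np.asarray(self.rr, dtype=float)
        if t.ndim != 1 or t.shape != rr.shape:
            raise ValueError("times and rr must be equal-length 1-d arrays")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(rr <= 0):
            raise ValueError("RR intervals must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "rr", rr)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class UniformSeries:
    """Uniformly sampled signal with its time base."""

    t: np.ndarray
    x: np.ndarray
    fs: float

    @property
    def duration(self) -> float:
        return (len(self.x) - 1) / self.fs


@dataclass(frozen=True)
class SpectralIndexes:
    """LF and HF band powers of an RR tachogram, in ms^2."""

    lf: float
    hf: float
    settings: dict = field(repr=False, default_factory=dict)
    freqs: np.ndarray | None = field(repr=False, default=None)
    psd: np.ndarray | None = field(repr=False, default=None)


@dataclass(frozen=True)
class SyncResult:
    """Phase-difference plateaus and the S index."""

    s: float                               # percent of accounted duration
    plateaus: list[tuple[float, float]]    # (start s, end s), disjoint
    phase_diff: np.ndarray = field(repr=False, default=None)
    fs: float = FS_RESAMPLE
    settings: dict = field(repr=False, default_factory=dict)


def rr_to_uniform(series: BeatSeries, fs_resample: float = FS_RESAMPLE
                  ) -> UniformSeries:
    """Interpolate the beat-wise RR sequence onto a uniform grid.

    Cubic-spline interpolation of RR(t) at the beat times, evaluated at
    ``fs_resample``; the grid starts at the first beat and ends at the last.
    """
    if len(series) < 3:
        raise ValueError("at least 3 beats are required for resampling")
    if fs_resample <= 0:
        raise ValueError("fs_resample must be positive")
    t0, t1 = series.times[0], series.times[-1]
    n = int(np.floor((t1 - t0) * fs_resample)) + 1
    t = t0 + np.arange(n) / fs_resample
    spl = interpolate.CubicSpline(series.times, series.rr)
    return UniformSeries(t=t, x=spl(t), fs=float(fs_resample))


def resample_uniform(t: np.ndarray, x: np.ndarray, fs: float = FS_RESAMPLE,
                     lowpass_hz: float | None = 1.0) -> UniformSeries:
    """Resample an arbitrary (t, x) signal onto a uniform grid, used to bring
    stored pressure trajectories to the analysis rate.

    Pulsatile signals carry cardiac harmonics far above the analysis
    Nyquist; when the source grid is uniform and ``lowpass_hz`` is set, a
    zero-phase Butterworth low-pass is applied before decimation so those
    harmonics do not alias into the 0.04-0.4 Hz analysis bands.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time base must be strictly increasing")
    dts = np.diff(t)
    uniform_src = dts.size > 0 and np.allclose(dts, dts[0], rtol=1e-6)
    if lowpass_hz is not None and uniform_src:
        fs_src = 1.0 / dts[0]
        if fs_src > 2.5 * lowpass_hz:
            sos = signal.butter(6, lowpass_hz, btype="low", fs=fs_src,
                                output="sos")
            x = signal.sosfiltfilt(sos, x)
    n = int(np.floor((t[-1] - t[0]) * fs)) + 1
    tg = t[0] + np.arange(n) / fs
    return UniformSeries(t=tg, x=np.interp(tg, t, x), fs=float(fs))


MIN_SPECTRAL_RECORD_S = 300.0


def spectral_indexes(x: np.ndarray, fs: float,
                     lf_band: tuple[float, float] = LF_BAND,
                     hf_band: tuple[float, float] = HF_BAND,
                     window_s: float = 100.0) -> SpectralIndexes:
    """Band powers of a uniformly sampled tachogram via Welch's averaged
    modified periodogram (Hann window, 50% overlap, per-segment mean
    removal).

    ``x`` is interpreted in ms, so the returned powers are in ms^2.  The
    record must be at least ``MIN_SPECTRAL_RECORD_S`` seconds long to
    resolve the lower LF edge.
    """
    x = np.asarray(x, dtype=float)
    duration = (len(x) - 1) / fs
    if duration < MIN_SPECTRAL_RECORD_S:
        raise ValueError(
            f"record of {duration:.0f} s is too short for spectral indexes; "
            f"minimum is {MIN_SPECTRAL_RECORD_S:.0f} s")
    nperseg = min(int(round(window_s * fs)), len(x))
    f, psd = signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                          noverlap=nperseg // 2, detrend="constant")
    df = f[1] - f[0]
    lf = float(np.sum(psd[(f >= lf_band[0]) & (f < lf_band[1])]) * df)
    hf = float(np.sum(psd[(f >= hf_band[0]) & (f < hf_band[1])]) * df)
    return SpectralIndexes(lf=lf, hf=hf,
                           settings={"fs": fs, "window_s": window_s,
                                     "lf_band": lf_band, "hf_band": hf_band,
                                     "estimator": "welch/hann/50%"},
                           freqs=f, psd=psd)


def rr_spectral_indexes(series: BeatSeries,
                        fs_resample: float = FS_RESAMPLE) -> SpectralIndexes:
    """LF/HF powers of a beat series: resample the RR tachogram (seconds),
    convert to ms, and apply :func:`spectral_indexes`."""
    u = rr_to_uniform(series, fs_resample)
    return spectral_indexes(u.x * 1000.0, u.fs)


def bandpass_phase(x: np.ndarray, fs: float,
                   band: tuple[float, float] = SYNC_BAND,
                   order: int = 2) -> np.ndarray:
    """Unwrapped instantaneous phase of the band-passed signal.

    Zero-phase Butterworth band-pass (forward-backward), then the analytic
    signal's phase.  For a pure in-band tone the phase slope equals 2*pi*f.
    """
    x = np.asarray(x, dtype=float)
    if not np.any(x != 0):
        raise ValueError("cannot extract a phase from an all-zero signal")
    min_len = 10.0 / band[1]   # ten periods of the band's upper edge
    if (len(x) - 1) / fs < max(min_len, 10.0 / ((band[0] + band[1]) / 2 * 1.0)):
        raise ValueError("record too short for phase extraction in this band")
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    xf = signal.sosfiltfilt(sos, x - np.mean(x))
    return np.unwrap(np.angle(signal.hilbert(xf)))


def detect_plateaus(dphi: np.ndarray, fs: float, window_s: float = 13.0,
                    slope_threshold: float = 0.01,
                    min_duration_s: float = 13.0,
                    edge_exclude_s: float = 0.0
                    ) -> list[tuple[float, float]]:
    """Horizontal sections of an unwrapped phase-difference series.

    A sliding centered window of ``window_s`` seconds is linearly fitted at
    every sample; a sample is a plateau candidate when the local |slope| is
    below ``slope_threshold`` (rad/s).  Runs of candidates shorter than
    ``min_duration_s`` are discarded; ``edge_exclude_s`` masks both record
    ends (filter transients).  Returns disjoint (start, end) times in
    seconds relative to the start of ``dphi``.
    """
    dphi = np.asarray(dphi, dtype=float)
    n = len(dphi)
    w = int(round(window_s * fs))
    if w < 3:
        raise ValueError("window too short for a slope fit")
    if w > n:
        raise ValueError("fit window longer than the record")
    # slope of the LS line over a centered window, via ramp convolution
    k = np.arange(w) - (w - 1) / 2.0
    denom = np.sum(k * k) / fs            # converts per-sample to per-second
    slope = np.convolve(dphi, k[::-1], mode="valid") / denom   # len n-w+1
    hw = (w - 1) / 2.0
    candidate = np.zeros(n, dtype=bool)
    candidate[int(np.ceil(hw)): int(np.ceil(hw)) + len(slope)] = \
        np.abs(slope) < slope_threshold
    margin = max(edge_exclude_s, hw / fs)
    lo = int(np.ceil(margin * fs))
    candidate[:lo] = False
    if lo > 0:
        candidate[-lo:] = False

    plateaus: list[tuple[float, float]] = []
    in_run = False
    start = 0
    for i in range(n + 1):
        on = i < n and candidate[i]
        if on and not in_run:
            in_run, start = True, i
        elif not on and in_run:
            in_run = False
            if (i - start) / fs >= min_duration_s:
                plateaus.append((start / fs, (i - 1) / fs))
    return plateaus


def s_index(rr_signal: UniformSeries, pressure_signal: UniformSeries,
            band: tuple[float, float] = SYNC_BAND,
            window_s: float = 13.0, slope_threshold: float = 0.01,
            min_duration_s: float = 13.0) -> SyncResult:
    """Total percent of phase synchronization between RR and pressure.

    Both inputs must share the sampling rate and be time-aligned to within
    1 s; they are cropped to the common length.  The filter edge transients
    (two band-center periods at each end) are excluded from the accounting,
    and S is the plateau time divided by the accounted duration, in percent.
    """
    if rr_signal.fs != pressure_signal.fs:
        raise ValueError("signals must share the sampling rate")
    fs = rr_signal.fs
    if abs(rr_signal.duration - pressure_signal.duration) > 1.0:
        raise ValueError(
            f"signal durations differ by more than 1 s "
            f"({rr_signal.duration:.1f} vs {pressure_signal.duration:.1f})")
    n = min(len(rr_signal.x), len(pressure_signal.x))
    ph_rr = bandpass_phase(rr_signal.x[:n], fs, band)
    ph_bp = bandpass_phase(pressure_signal.x[:n], fs, band)
    dphi = ph_rr - ph_bp
    f_center = 0.5 * (band[0] + band[1])
    edge = 2.0 / f_center
    plateaus = detect_plateaus(dphi, fs, window_s=window_s,
                               slope_threshold=slope_threshold,
                               min_duration_s=min_duration_s,
                               edge_exclude_s=edge)
    duration = (n - 1) / fs
    hw = (int(round(window_s * fs)) - 1) / 2.0 / fs
    usable = duration - 2.0 * max(edge, hw)
    total = sum(b - a for a, b in plateaus)
    s = 100.0 * total / usable if usable > 0 else 0.0
    s = min(100.0, max(0.0, s))
    return SyncResult(s=s, plateaus=plateaus, phase_diff=dphi, fs=fs,
                      settings={"band": band, "window_s": window_s,
                                "slope_threshold": slope_threshold,
                                "min_duration_s": min_duration_s,
                                "edge_exclude_s": edge})
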