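"""Analysis-stack oracles: tachogram resampling, band powers, phase
extraction, plateau detection, S index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tiltsim.indices import (BeatSeries, UniformSeries, bandpass_phase,
                             detect_plateaus, rr_to_uniform, s_index,
                             spectral_indexes, resample_uniform)


def _beats_from_rr(rr_of_t, t_end=700.0, rr0=0.85):
    """Integrate beat times whose instantaneous RR follows rr_of_t."""
    times = [0.0]
    while times[-1] < t_end:
        times.append(times[-1] + rr_of_t(times[-1]))
    t = np.array(times)
    return BeatSeries(times=t[1:], rr=np.diff(t))


# --- rr_to_uniform ---------------------------------------------------------

def test_constant_rr_resamples_to_constant():
    series = _beats_from_rr(lambda t: 0.8, t_end=100.0)
    u = rr_to_uniform(series)
    np.testing.assert_allclose(u.x, 0.8, rtol=1e-9)


def test_sinusoidal_tachogram_is_recovered():
    a, b, f = 0.85, 0.05, 0.1
    series = _beats_from_rr(lambda t: a + b * np.sin(2 * np.pi * f * t))
    u = rr_to_uniform(series)
    # mean preserved to < 0.1 %
    assert abs(np.mean(u.x) - a) / a < 1e-3
    # recovered oscillation amplitude within 5 %
    core = u.x[(u.t > 50) & (u.t < 650)]
    amp = 0.5 * (np.max(core) - np.min(core))
    assert abs(amp - b) / b < 0.05


def test_resampling_uniform_series_is_idempotent():
    fs = 4.0
    t = np.arange(0, 200, 1 / fs)
    x = 0.8 + 0.01 * np.sin(2 * np.pi * 0.1 * t)
    series = BeatSeries(times=t, rr=x)
    u1 = rr_to_uniform(series, fs)
    series2 = BeatSeries(times=u1.t, rr=u1.x)
    u2 = rr_to_uniform(series2, fs)
    np.testing.assert_allclose(u1.x, u2.x, rtol=1e-10)


def test_beat_series_validation():
    with pytest.raises(ValueError):
        BeatSeries(times=np.array([0.0, 1.0, 0.5]),
                   rr=np.array([1.0, 1.0, 1.0]))
    with pytest.raises(ValueError):
        BeatSeries(times=np.array([0.0, 1.0]), rr=np.array([1.0, -1.0]))
    with pytest.raises(ValueError):
        rr_to_uniform(BeatSeries(times=np.array([0.0, 1.0]),
                                 rr=np.array([1.0, 1.0])))


# --- spectral indexes ------------------------------------------------------

@pytest.mark.parametrize("freq,band", [(0.10, "lf"), (0.25, "hf")])
def test_pure_tone_lands_entirely_in_its_band(freq, band):
    fs, dur, amp = 4.0, 600.0, 30.0
    t = np.arange(0, dur, 1 / fs)
    x = 850.0 + amp * np.sin(2 * np.pi * freq * t)
    spec = spectral_indexes(x, fs)
    inside = spec.lf if band == "lf" else spec.hf
    outside = spec.hf if band == "lf" else spec.lf
    assert inside == pytest.approx(amp ** 2 / 2.0, rel=0.05)
    assert outside < 0.02 * inside


def test_band_powers_invariant_to_additive_constant():
    fs = 4.0
    t = np.arange(0, 600, 1 / fs)
    x = 20.0 * np.sin(2 * np.pi * 0.1 * t)
    a = spectral_indexes(x, fs)
    b = spectral_indexes(x + 5000.0, fs)
    assert b.lf == pytest.approx(a.lf, rel=1e-6)
    assert b.hf == pytest.approx(a.hf, rel=1e-6)


def test_parseval_total_power_matches_variance():
    rng = np.random.default_rng(0)
    fs = 4.0
    x = rng.normal(size=int(4096 * fs))
    spec = spectral_indexes(x, fs)
    df = spec.freqs[1] - spec.freqs[0]
    total = np.sum(spec.psd) * df
    assert abs(total / np.var(x) - 1.0) < 0.02


def test_white_tachogram_splits_by_band_width():
    rng = np.random.default_rng(1)
    fs = 4.0
    x = 30.0 * rng.normal(size=int(4096 * fs))
    spec = spectral_indexes(x, fs)
    assert spec.lf + spec.hf < np.var(x)
    ratio = spec.lf / spec.hf
    assert ratio == pytest.approx(0.11 / 0.25, rel=0.15)


def test_short_record_rejected_with_minimum_in_message():
    with pytest.raises(ValueError, match="300"):
        spectral_indexes(np.zeros(100), 4.0)


# --- phase extraction ------------------------------------------------------

def test_tone_phase_slope_equals_angular_frequency():
    fs = 4.0
    t = np.arange(0, 600, 1 / fs)
    ph = bandpass_phase(np.sin(2 * np.pi * 0.1 * t), fs)
    core = slice(int(50 * fs), int(550 * fs))
    slope = np.polyfit(t[core], ph[core], 1)[0]
    assert slope == pytest.approx(2 * np.pi * 0.1, rel=0.01)


def test_sign_flip_shifts_phase_by_pi():
    fs = 4.0
    t = np.arange(0, 600, 1 / fs)
    x = np.sin(2 * np.pi * 0.1 * t)
    d = bandpass_phase(x, fs) - bandpass_phase(-x, fs)
    core = d[int(50 * fs):int(550 * fs)]
    assert np.allclose(np.abs(np.cos(core)), np.abs(np.cos(np.pi)), atol=0.05)


def test_chirp_yields_monotone_instantaneous_frequency():
    fs = 4.0
    t = np.arange(0, 800, 1 / fs)
    from scipy.signal import chirp
    x = chirp(t, f0=0.06, f1=0.14, t1=t[-1], method="linear")
    ph = bandpass_phase(x, fs)
    inst_f = np.gradient(ph, 1 / fs) / (2 * np.pi)
    # smooth over 30 s and check the trend inside the record
    kernel = np.ones(int(30 * fs)) / int(30 * fs)
    sm = np.convolve(inst_f, kernel, mode="valid")
    core = sm[int(60 * fs):-int(60 * fs)]
    assert np.all(np.diff(core[::int(30 * fs)]) > 0)


def test_zero_signal_has_no_phase():
    with pytest.raises(ValueError):
        bandpass_phase(np.zeros(4000), 4.0)


# --- plateau detection -----------------------------------------------------

def test_constant_difference_is_one_full_plateau():
    fs = 4.0
    d = np.full(int(600 * fs), 2.0)
    plats = detect_plateaus(d, fs)
    assert len(plats) == 1
    a, b = plats[0]
    assert b - a > 0.9 * 600


def test_fast_ramp_has_no_plateaus():
    fs = 4.0
    t = np.arange(0, 600, 1 / fs)
    assert detect_plateaus(0.2 * t, fs) == []


def test_piecewise_flat_then_ramp_gives_half_plateau():
    fs, dur = 4.0, 600.0
    t = np.arange(0, dur, 1 / fs)
    d = np.where(t < dur / 2, 0.0, 0.3 * (t - dur / 2))
    plats = detect_plateaus(d, fs, window_s=13.0)
    frac = sum(b - a for a, b in plats) / dur
    assert frac == pytest.approx(0.5, abs=13.0 / dur)


def test_tightening_slope_threshold_never_extends_plateaus():
    rng = np.random.default_rng(3)
    fs = 4.0
    d = np.cumsum(rng.normal(scale=0.01, size=int(900 * fs))) / fs
    totals = []
    for thr in (0.05, 0.02, 0.01, 0.005, 0.002):
        plats = detect_plateaus(d, fs, slope_threshold=thr)
        totals.append(sum(b - a for a, b in plats))
    assert np.all(np.diff(totals) <= 1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), scale=st.floats(0.001, 0.2))
def test_plateaus_are_disjoint_ordered_and_inside_record(seed, scale):
    rng = np.random.default_rng(seed)
    fs = 4.0
    d = np.cumsum(rng.normal(scale=scale, size=int(400 * fs))) / fs
    plats = detect_plateaus(d, fs)
    prev_end = -np.inf
    for a, b in plats:
        assert 0.0 <= a < b <= 400.0
        assert a > prev_end
        prev_end = b


def test_window_longer_than_record_rejected():
    with pytest.raises(ValueError):
        detect_plateaus(np.zeros(40), 4.0, window_s=100.0)


# --- S index ---------------------------------------------------------------

def _tone_pair(f1, f2, dur=600.0, fs=4.0, noise=0.02, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(0, dur, 1 / fs)
    x = np.sin(2 * np.pi * f1 * t) + noise * rng.normal(size=len(t))
    y = np.sin(2 * np.pi * f2 * t + 0.5) + noise * rng.normal(size=len(t))
    return (UniformSeries(t, x, fs), UniformSeries(t, y, fs))


def test_identical_tones_are_fully_synchronized():
    u, v = _tone_pair(0.1, 0.1)
    assert s_index(u, v).s > 99.0


def test_s_invariant_to_rescaling_either_signal():
    u, v = _tone_pair(0.1, 0.1, noise=0.05)
    base = s_index(u, v).s
    assert s_index(UniformSeries(u.t, 37.0 * u.x, u.fs), v).s == base
    assert s_index(u, UniformSeries(v.t, 0.001 * v.x, v.fs)).s == base


def test_s_bounded_and_plateaus_disjoint():
    u, v = _tone_pair(0.1, 0.11, noise=0.3, seed=5)
    res = s_index(u, v)
    assert 0.0 <= res.s <= 100.0
    prev = -1.0
    for a, b in res.plateaus:
        assert a > prev and b > a
        prev = b


def test_duration_mismatch_rejected():
    u, _ = _tone_pair(0.1, 0.1, dur=600.0)
    _, v = _tone_pair(0.1, 0.1, dur=500.0)
    with pytest.raises(ValueError, match="durations"):
        s_index(u, v)
    with pytest.raises(ValueError, match="sampling"):
        s_index(u, UniformSeries(u.t[::2], u.x[::2], 2.0))


def test_pressure_resampler_removes_cardiac_harmonics():
    # a pulsatile signal sampled at 50 Hz: after resampling to 4 Hz, the
    # 0.04-0.4 Hz region must not inherit aliased pulse harmonics
    fs_src = 50.0
    t = np.arange(0, 600, 1 / fs_src)
    pulse = np.abs(np.sin(np.pi * 1.21 * t)) ** 3       # sharp 1.21 Hz pulses
    u = resample_uniform(t, pulse, 4.0)
    from scipy.signal import welch
    f, psd = welch(u.x - u.x.mean(), fs=4.0, nperseg=1024)
    band = (f >= 0.04) & (f <= 0.4)
    assert np.sum(psd[band]) * (f[1] - f[0]) < 1e-6 * np.var(pulse)
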