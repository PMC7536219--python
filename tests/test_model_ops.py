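"""Unit tests of the elementary model operations (closed forms, sign
conventions, saturations)."""

import math

import numpy as np
import pytest

from tiltsim import model
from tiltsim.respiration import RespirationProcess, respiration_signal


# --- baroreceptors ---------------------------------------------------------

def test_baroreceptor_vanishes_at_set_point(defaults):
    p = defaults.replace(k_bd_u=0.0)
    assert model.baroreceptor_activity(defaults.p0_u, 0.0, "upper", p) == 0.0


def test_baroreceptor_linear_form(defaults):
    # k_p*(p-p0) + k_d*dpdt with k_p=0.02, k_d=0.00125, p-p0=50, dpdt=800
    p = defaults.replace(k_bp_u=0.02, k_bd_u=0.00125, p0_u=50.0)
    a = model.baroreceptor_activity(100.0, 800.0, "upper", p)
    assert a == pytest.approx(0.02 * 50 + 0.00125 * 800)  # = 2.0


def test_baroreceptor_clips_negative_drive(defaults):
    a = model.baroreceptor_activity(1.0, -5000.0, "lower", defaults)
    assert a == 0.0


def test_baroreceptor_rejects_bad_inputs(defaults):
    with pytest.raises(ValueError):
        model.baroreceptor_activity(float("nan"), 0.0, "upper", defaults)
    with pytest.raises(ValueError):
        model.baroreceptor_activity(-10.0, 0.0, "upper", defaults)
    with pytest.raises(ValueError):
        model.baroreceptor_activity(100.0, 0.0, "elbow", defaults)


# --- hydrostatic term ------------------------------------------------------

def test_hydrostatic_zero_supine_and_full_at_test_angle(defaults):
    assert model.hydrostatic_pressure(0.0, defaults) == 0.0
    assert model.hydrostatic_pressure(
        defaults.alpha_test, defaults, site="lower") == pytest.approx(
            defaults.p_hst_lower)
    assert model.hydrostatic_pressure(
        defaults.alpha_test, defaults, site="upper") == pytest.approx(
            -defaults.p_hst_upper)


def test_hydrostatic_monotone_in_sin_alpha(defaults):
    angles = np.linspace(0.0, 90.0, 10)
    vals = [model.hydrostatic_pressure(a, defaults) for a in angles]
    assert np.all(np.diff(vals) > 0)


@pytest.mark.parametrize("alpha", [-1.0, 95.0])
def test_hydrostatic_rejects_out_of_range_angle(defaults, alpha):
    with pytest.raises(ValueError):
        model.hydrostatic_pressure(alpha, defaults)


# --- parasympathetic branch ------------------------------------------------

def test_vagal_activity_increases_with_baroreceptor_drive(defaults):
    # Table-1 sign convention: baroreceptors excite the vagal branch, so
    # zero drive is the *minimum* and doubling drive never decreases v_p.
    lo = model.parasympathetic_activity(0.0, 0.0, 0.0, defaults)
    mid = model.parasympathetic_activity(3.0, 3.0, 0.0, defaults)
    hi = model.parasympathetic_activity(6.0, 6.0, 0.0, defaults)
    assert lo == 0.0
    assert lo <= mid <= hi


def test_vagal_activity_is_nonnegative_and_validates(defaults):
    assert model.parasympathetic_activity(1.0, 0.0, -50.0, defaults) == 0.0
    with pytest.raises(ValueError):
        model.parasympathetic_activity(-1.0, 0.0, 0.0, defaults)


# --- noradrenaline kinetics ------------------------------------------------

def test_noradrenaline_free_decay_closed_form(defaults):
    c, dt = 1.7, 1e-4
    tau = defaults.tau_cc
    t_end = 3.0
    for _ in range(int(t_end / dt)):
        c += dt * model.noradrenaline_rate(c, 0.0, defaults, "heart")
    assert c == pytest.approx(1.7 * math.exp(-t_end / tau), rel=1e-3)


@pytest.mark.parametrize("compartment", ["heart", "vessel"])
def test_noradrenaline_fixed_point_equals_gain_tau_activity(defaults,
                                                            compartment):
    v_bar = 2.5
    tau = defaults.tau_cc if compartment == "heart" else defaults.tau_cv
    k = defaults.k_cc if compartment == "heart" else defaults.k_cv
    c, dt = 0.0, 1e-3
    for _ in range(int(80 * tau / dt)):
        c += dt * model.noradrenaline_rate(c, v_bar, defaults, compartment)
    assert abs(c - k * tau * v_bar) < 1e-8
    # and the rate vanishes exactly at the fixed point
    assert model.noradrenaline_rate(k * tau * v_bar, v_bar, defaults,
                                    compartment) == pytest.approx(0.0,
                                                                  abs=1e-14)


def test_noradrenaline_rejects_invalid(defaults):
    with pytest.raises(ValueError):
        model.noradrenaline_rate(-0.1, 1.0, defaults, "heart")
    with pytest.raises(ValueError):
        model.noradrenaline_rate(0.1, 1.0, defaults, "lung")


# --- sinus node ------------------------------------------------------------

def test_unmodulated_cycle_length_equals_intrinsic_period(defaults):
    # f_s = f_p = 1 (neutral): phase needs exactly T0 to cross 1
    dt = 1e-3
    phi, t = 0.0, 0.0
    while True:
        phi, crossing = model.sinus_node_step(phi, 1.0, 1.0, defaults, dt)
        if crossing is not None:
            t += crossing * dt
            break
        t += dt
    assert t == pytest.approx(defaults.T0, rel=1e-9)


def test_sympathetic_factor_strictly_shortens_cycle(defaults):
    rr = []
    for f_s in (1.0, 1.2, 1.5, 2.0):
        phi, t = 0.0, 0.0
        while True:
            phi, crossing = model.sinus_node_step(phi, f_s, 1.0, defaults,
                                                  1e-3)
            if crossing is not None:
                t += crossing * 1e-3
                break
            t += 1e-3
        rr.append(t)
    assert np.all(np.diff(rr) < 0)


def test_sinus_node_step_validates(defaults):
    with pytest.raises(ValueError):
        model.sinus_node_step(0.5, 1.0, 1.0, defaults, 0.0)
    with pytest.raises(ValueError):
        model.sinus_node_step(1.2, 1.0, 1.0, defaults, 0.01)


# --- heart-rate factors ----------------------------------------------------

def test_factors_at_neutral_inputs(defaults):
    f_s, f_p = model.heart_rate_factors(0.0, 0.0, defaults)
    assert f_s == 1.0 and f_p == 1.0


def test_sympathetic_factor_saturates(defaults):
    grid = np.geomspace(1e-3, 1e6, 200)
    vals = [model.heart_rate_factors(c, 0.0, defaults)[0] for c in grid]
    assert np.all(np.diff(vals) > 0)            # monotone increasing
    bound = 1.0 + defaults.k_fs * defaults.c_sat_s
    assert max(vals) < bound                    # finite supremum


def test_parasympathetic_factor_monotone_decreasing(defaults):
    grid = np.linspace(0.0, 20.0, 100)
    vals = [model.heart_rate_factors(0.0, v, defaults)[1] for v in grid]
    assert np.all(np.diff(vals) < 0)
    assert vals[-1] > 1.0 - defaults.k_fp       # bounded below


# --- contractility and systole ---------------------------------------------

def test_contractility_increasing_in_noradrenaline(defaults):
    vals = [model.contractility(0.85, c, defaults) for c in
            np.linspace(0.0, 2.0, 50)]
    assert np.all(np.diff(vals) > 0)
    assert vals[0] > 0


def test_contractility_nondecreasing_in_previous_interval(defaults):
    vals = [model.contractility(T, 0.15, defaults) for T in
            np.linspace(0.4, 1.6, 50)]
    assert np.all(np.diff(vals) >= 0)


def test_systolic_pressure_exceeds_diastolic_and_grows_with_s(defaults):
    saps = [model.systolic_update(75.0, 0.85, s, defaults)
            for s in (20.0, 40.0, 60.0)]
    assert np.all(np.diff(saps) > 0)
    assert saps[0] > 75.0


def test_systolic_upstroke_matches_hand_evaluation(defaults):
    # p(x) = DAP + s * x * e^(1-x); at DAP=75, s=40, x=0.5:
    # 75 + 40 * 0.5 * e^0.5 = 75 + 20 * 1.6487212707 = 107.974425...
    x = 0.5
    val = model.systolic_pressure(75.0, 40.0, x * defaults.tau_sys, defaults)
    assert val == pytest.approx(107.9744254140026, rel=1e-12)
    # the peak equals DAP + s (the systolic_update value)
    peak = model.systolic_pressure(75.0, 40.0, defaults.tau_sys, defaults)
    assert peak == pytest.approx(model.systolic_update(75.0, 0.85, 40.0,
                                                       defaults))


# --- windkessel and resistance ---------------------------------------------

def test_diastolic_decay_closed_form_and_scaling(defaults):
    dpdt = model.diastolic_decay(120.0, 0.8, defaults)
    assert dpdt == pytest.approx(-120.0 / (0.8 * defaults.C_wk))
    assert model.diastolic_decay(120.0, 0.4, defaults) == pytest.approx(
        2.0 * dpdt)                    # halving R doubles the decay rate
    with pytest.raises(ValueError):
        model.diastolic_decay(120.0, 0.0, defaults)
    with pytest.raises(ValueError):
        model.diastolic_decay(-5.0, 0.8, defaults)


def test_resistance_is_deterministic_positive_map(defaults):
    r1 = model.vascular_resistance(2.3, defaults)
    assert r1 == model.vascular_resistance(2.3, defaults)
    assert r1 > 0
    grid = np.linspace(0.0, 5.0, 50)
    vals = [model.vascular_resistance(c, defaults) for c in grid]
    assert np.all(np.diff(vals) > 0)
    with pytest.raises(ValueError):
        model.vascular_resistance(-1.0, defaults)


# --- respiration -----------------------------------------------------------

def test_noiseless_respiration_is_strictly_periodic():
    proc = RespirationProcess(0.25, 0.0, 100.0, seed=3)
    t = np.linspace(0.0, 50.0, 5001)
    r1 = proc.waveform(t)
    r2 = proc.waveform(t + 4.0)        # one full cycle at 0.25 Hz
    np.testing.assert_allclose(r1, r2, atol=1e-9)


def test_mean_breath_frequency_recovers_f_br():
    # ~1e4 breaths: sample mean of the per-breath frequency within MC error
    proc = RespirationProcess(0.25, 0.0016, 40000.0, seed=7)
    assert proc.n_breaths > 9000
    se = 0.04 / math.sqrt(proc.n_breaths)
    assert abs(proc.frequencies.mean() - 0.25) < 4 * se


def test_respiration_amplitude_is_constant_per_breath():
    proc = RespirationProcess(0.25, 0.0016, 2000.0, seed=5, amplitude=1.0)
    t = np.arange(0.0, 1999.0, 0.01)
    r = proc.waveform(t)
    assert np.max(np.abs(r)) <= 1.0 + 1e-12
    # every breath reaches the full amplitude
    for k in range(0, proc.n_breaths - 1, 37):
        seg = (t >= proc.onsets[k]) & (t < proc.onsets[k + 1])
        assert r[seg].max() == pytest.approx(1.0, abs=5e-3)


def test_degenerate_breath_frequencies_are_redrawn():
    proc = RespirationProcess(0.08, 0.01, 5000.0, seed=11)
    assert np.all(proc.frequencies > 0.05)


def test_respiration_signal_wrapper_and_validation():
    r = respiration_signal([0.0, 1.0, 2.0], 0.25, 0.0, 2.0, seed=0)
    assert r[0] == pytest.approx(0.0, abs=1e-12)
    assert np.max(np.abs(r)) <= 2.0
    with pytest.raises(ValueError):
        RespirationProcess(-0.1, 0.0, 10.0, seed=0)
    with pytest.raises(ValueError):
        RespirationProcess(0.25, -1.0, 10.0, seed=0)


# --- delay history ---------------------------------------------------------

def test_delay_history_contract():
    h = model.DelayHistory(span_s=2.0, dt=0.1, fill=1.0)
    assert h.lookup(1.5) == 1.0                 # constant pre-history
    for v in np.arange(21.0):
        h.push(v)
    assert h.lookup(0.0) == 20.0                # current value
    assert h.lookup(0.5) == 15.0                # exact grid point
    assert h.lookup(0.55) == pytest.approx(14.5)  # linear interpolation
    assert h.span >= 2.0
    with pytest.raises(ValueError):
        h.lookup(5.0)
    with pytest.raises(ValueError):
        h.lookup(-0.1)


def test_sympathetic_loop_rate_zero_at_fixed_point(defaults):
    # choose v at the loop's fixed point for frozen inputs -> derivative 0
    vb, r = 5.0, 0.0
    u = defaults.a_s - defaults.k_sb * vb + defaults.k_sr * r
    # solve v = G*sigma(a - k_ss*v - k_sb*vb) by bisection (the map itself
    # is unstable at the fixed point -- that instability IS the oscillator)
    lo, hi = 0.0, defaults.G_s
    for _ in range(200):
        v = 0.5 * (lo + hi)
        if defaults.G_s / (1.0 + math.exp(-(u - defaults.k_ss * v))) > v:
            lo = v
        else:
            hi = v
    rate = model.sympathetic_loop_rate(v, v, vb, r, defaults, "heart")
    assert rate == pytest.approx(0.0, abs=1e-10)
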