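"""Fixed-step integration kernel for the two-loop autonomic-control model.

The model is a hybrid delay-differential system: four ODE states (two
sympathetic loop activities, two noradrenaline concentrations) advanced with
explicit Euler steps, the sinus-node phase advanced with an interpolated
threshold crossing, and arterial pressure advanced *exactly* within each step
(analytic systolic pulse, exponential windkessel decay with the resistance
held over the step).  Delay terms are served from full-history arrays with
linear interpolation between grid points.

Everything here is plumbing; the model equations themselves are documented
in :mod:`tiltsim.model`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .params import PARAM_ORDER

# Packed-vector indices (module-level ints; the JIT treats them as constants).
_I = {name: i for i, name in enumerate(PARAM_ORDER)}
P_T0 = _I["T0"]; P_K_FS = _I["k_fs"]; P_C_SAT_S = _I["c_sat_s"]
P_K_FP = _I["k_fp"]; P_V_SAT_P = _I["v_sat_p"]
P_C_WK = _I["C_wk"]; P_TAU_SYS = _I["tau_sys"]; P_R0 = _I["R0"]
P_K_R = _I["k_R"]; P_S_MAX = _I["S_max"]; P_S0 = _I["s0"]
P_K_SC = _I["k_sc"]; P_K_ST = _I["k_sT"]
P_P0_U = _I["p0_u"]; P_K_BP_U = _I["k_bp_u"]; P_K_BD_U = _I["k_bd_u"]
P_P0_L = _I["p0_l"]; P_K_BP_L = _I["k_bp_l"]; P_K_BD_L = _I["k_bd_l"]
P_PHST_U = _I["p_hst_upper"]; P_PHST_L = _I["p_hst_lower"]
P_ALPHA_TEST = _I["alpha_test"]
P_TAU_S = _I["tau_s"]; P_THETA_S = _I["theta_s"]; P_G_S = _I["G_s"]
P_K_SS = _I["k_ss"]; P_K_SB = _I["k_sb"]; P_K_SR = _I["k_sr"]; P_A_S = _I["a_s"]
P_TAU_V = _I["tau_v"]; P_THETA_V = _I["theta_v"]; P_G_V = _I["G_v"]
P_K_VV = _I["k_vv"]; P_K_VB = _I["k_vb"]; P_K_VR = _I["k_vr"]; P_A_V = _I["a_v"]
P_TAU_CC = _I["tau_cc"]; P_K_CC = _I["k_cc"]; P_THETA_CC = _I["theta_cc"]
P_TAU_CV = _I["tau_cv"]; P_K_CV = _I["k_cv"]; P_THETA_CV = _I["theta_cv"]
P_K_PB_U = _I["k_pb_u"]; P_K_PB_L = _I["k_pb_l"]; P_K_PR = _I["k_pr"]
P_F_BR = _I["f_br"]; P_SIGMA2_XI = _I["sigma2_xi"]

# Stored-trajectory column order.
STATE_COLUMNS = ("p", "v_b", "v_b_l", "v_s", "v_s_l", "v_p",
                 "c_c", "c_v", "f_s", "f_p", "R", "s", "r", "alpha")
N_STATE_COLS = len(STATE_COLUMNS)

# Initial-state vector layout (see model.ModelState / model.initial_state).
INIT_P, INIT_PHI, INIT_VS, INIT_VSL, INIT_CC, INIT_CV, \
    INIT_TPREV, INIT_DAP, INIT_TSINCE, INIT_VBF, INIT_VBLF = range(11)
N_INIT = 11

# Status codes returned by the kernel.
STATUS_OK = 0
STATUS_NONFINITE = 1     # a state became non-finite / pressure non-positive
STATUS_BEAT_OVERFLOW = 2

DEG = math.pi / 180.0


@njit(cache=True, inline="always")
def _hist_lookup(arr, n, lag):
    """Linear interpolation of a history array at fractional lag (steps)."""
    idx = n - lag
    if idx <= 0.0:
        return arr[0]
    i0 = int(math.floor(idx))
    w = idx - i0
    if i0 >= n:
        return arr[n]
    return arr[i0] * (1.0 - w) + arr[i0 + 1] * w


@njit(cache=True)
def run_kernel(pv, dt, n_steps, stride,
               br_onsets, br_freqs,
               sched_t, sched_a,
               init):
    """Integrate the model for ``n_steps`` steps of size ``dt``.

    Returns ``(status, bad_step, out_states, n_beats, beat_t, beat_rr,
    beat_sap, beat_dap, final_state)``; trajectories are stored every
    ``stride`` steps (row 0 is t=0).
    """
    T0 = pv[P_T0]; k_fs = pv[P_K_FS]; c_sat_s = pv[P_C_SAT_S]
    k_fp = pv[P_K_FP]; v_sat_p = pv[P_V_SAT_P]
    C = pv[P_C_WK]; tau_sys = pv[P_TAU_SYS]; R0 = pv[P_R0]; k_R = pv[P_K_R]
    S_max = pv[P_S_MAX]; s0 = pv[P_S0]; k_sc = pv[P_K_SC]; k_sT = pv[P_K_ST]
    p0_u = pv[P_P0_U]; k_bp_u = pv[P_K_BP_U]; k_bd_u = pv[P_K_BD_U]
    p0_l = pv[P_P0_L]; k_bp_l = pv[P_K_BP_L]; k_bd_l = pv[P_K_BD_L]
    phst_u = pv[P_PHST_U]; phst_l = pv[P_PHST_L]
    sin_aref = math.sin(pv[P_ALPHA_TEST] * DEG)
    tau_s = pv[P_TAU_S]; G_s = pv[P_G_S]; k_ss = pv[P_K_SS]
    k_sb = pv[P_K_SB]; k_sr = pv[P_K_SR]; a_s = pv[P_A_S]
    tau_v = pv[P_TAU_V]; G_v = pv[P_G_V]; k_vv = pv[P_K_VV]
    k_vb = pv[P_K_VB]; k_vr = pv[P_K_VR]; a_v = pv[P_A_V]
    tau_cc = pv[P_TAU_CC]; k_cc = pv[P_K_CC]
    tau_cv = pv[P_TAU_CV]; k_cv = pv[P_K_CV]
    k_pb_u = pv[P_K_PB_U]; k_pb_l = pv[P_K_PB_L]; k_pr = pv[P_K_PR]

    lag_s = pv[P_THETA_S] / dt
    lag_v = pv[P_THETA_V] / dt
    lag_cc = pv[P_THETA_CC] / dt
    lag_cv = pv[P_THETA_CV] / dt

    # Full history arrays for the delayed signals.
    hv_s = np.empty(n_steps + 1)
    hv_sl = np.empty(n_steps + 1)
    hv_b = np.empty(n_steps + 1)
    hv_bl = np.empty(n_steps + 1)

    n_store = n_steps // stride + 1
    out = np.empty((n_store, N_STATE_COLS))

    max_beats = int(n_steps * dt / 0.2) + 8
    beat_t = np.empty(max_beats)
    beat_rr = np.empty(max_beats)
    beat_sap = np.empty(max_beats)
    beat_dap = np.empty(max_beats)
    n_beats = 0

    # Unpack initial state.
    p = init[INIT_P]; phi = init[INIT_PHI]
    v_s = init[INIT_VS]; v_sl = init[INIT_VSL]
    c_c = init[INIT_CC]; c_v = init[INIT_CV]
    T_prev = init[INIT_TPREV]; dap = init[INIT_DAP]
    t_beat_last = -init[INIT_TSINCE]
    vb_f = init[INIT_VBF]; vbl_f = init[INIT_VBLF]
    sig0 = s0 + k_sc * c_c + k_sT * T_prev
    s_cur = S_max * (1.0 - math.exp(-sig0 / S_max))
    if s_cur < 0.1:
        s_cur = 0.1

    kb = 0
    n_br = len(br_freqs)
    ks = 0
    n_sched = len(sched_t)
    status = STATUS_OK
    bad_step = -1

    for n in range(n_steps + 1):
        t = n * dt
        # --- respiration ---------------------------------------------------
        while kb < n_br - 1 and t >= br_onsets[kb + 1]:
            kb += 1
        r = math.sin(2.0 * math.pi * br_freqs[kb] * (t - br_onsets[kb]))
        # --- posture -------------------------------------------------------
        while ks < n_sched - 2 and t >= sched_t[ks + 1]:
            ks += 1
        if n_sched == 1 or t <= sched_t[0]:
            alpha = sched_a[0]
        elif t >= sched_t[n_sched - 1]:
            alpha = sched_a[n_sched - 1]
        else:
            w = (t - sched_t[ks]) / (sched_t[ks + 1] - sched_t[ks])
            alpha = sched_a[ks] * (1.0 - w) + sched_a[ks + 1] * w
        sa = math.sin(alpha * DEG) / sin_aref
        ph_u = phst_u * sa
        ph_l = phst_l * sa

        # --- algebraic signals --------------------------------------------
        R_cur = R0 + k_R * math.sqrt(c_v)
        x = (t - t_beat_last) / tau_sys
        if x <= 1.0:
            dpdt = (s_cur / tau_sys) * (1.0 - x) * math.exp(1.0 - x)
        else:
            dpdt = -p / (R_cur * C)
        v_b = k_bp_u * (p - ph_u - p0_u) + k_bd_u * dpdt
        if v_b < 0.0:
            v_b = 0.0
        v_bl = k_bp_l * (p + ph_l - p0_l) + k_bd_l * dpdt
        if v_bl < 0.0:
            v_bl = 0.0
        v_p = k_pb_u * v_b * (1.0 + k_pr * r) + k_pb_l * v_bl
        if v_p < 0.0:
            v_p = 0.0
        f_s = 1.0 + k_fs * c_c / (1.0 + c_c / c_sat_s)
        f_p = 1.0 - k_fp * (1.0 - math.exp(-v_p / v_sat_p))

        # central afferent integration: the control loops see the
        # baroreceptor signal smoothed over ~one cardiac cycle (T0)
        hv_s[n] = v_s
        hv_sl[n] = v_sl
        hv_b[n] = vb_f
        hv_bl[n] = vbl_f

        if n % stride == 0:
            i = n // stride
            out[i, 0] = p; out[i, 1] = v_b; out[i, 2] = v_bl
            out[i, 3] = v_s; out[i, 4] = v_sl; out[i, 5] = v_p
            out[i, 6] = c_c; out[i, 7] = c_v; out[i, 8] = f_s
            out[i, 9] = f_p; out[i, 10] = R_cur; out[i, 11] = s_cur
            out[i, 12] = r; out[i, 13] = alpha

        if n == n_steps:
            break

        # --- afferent smoothing (Euler) -----------------------------------
        vb_f = vb_f + dt * (v_b - vb_f) / T0
        vbl_f = vbl_f + dt * (v_bl - vbl_f) / T0

        # --- sympathetic loops (Euler) ------------------------------------
        u_s = (a_s - k_ss * _hist_lookup(hv_s, n, lag_s)
               - k_sb * _hist_lookup(hv_b, n, lag_s) + k_sr * r)
        v_s = v_s + dt / tau_s * (-v_s + G_s / (1.0 + math.exp(-u_s)))
        if v_s < 0.0:
            v_s = 0.0
        u_v = (a_v - k_vv * _hist_lookup(hv_sl, n, lag_v)
               - k_vb * _hist_lookup(hv_bl, n, lag_v) + k_vr * r)
        v_sl = v_sl + dt / tau_v * (-v_sl + G_v / (1.0 + math.exp(-u_v)))
        if v_sl < 0.0:
            v_sl = 0.0

        # --- noradrenaline kinetics (Euler) -------------------------------
        c_c = c_c + dt * (-c_c / tau_cc + k_cc * _hist_lookup(hv_s, n, lag_cc))
        if c_c < 0.0:
            c_c = 0.0
        c_v = c_v + dt * (-c_v / tau_cv + k_cv * _hist_lookup(hv_sl, n, lag_cv))
        if c_v < 0.0:
            c_v = 0.0

        # --- sinus node & pressure ----------------------------------------
        dphi = f_s * f_p / T0
        phi_new = phi + dt * dphi
        s_end = t_beat_last + tau_sys
        t_next = t + dt
        if phi_new >= 1.0:
            frac = (1.0 - phi) / (phi_new - phi)
            tc = t + frac * dt
            # pressure at the crossing
            if tc <= s_end:
                xs = (tc - t_beat_last) / tau_sys
                p_tc = dap + s_cur * xs * math.exp(1.0 - xs)
            elif t >= s_end:
                p_tc = p * math.exp(-(tc - t) / (R_cur * C))
            else:
                p_peak = dap + s_cur
                p_tc = p_peak * math.exp(-(tc - s_end) / (R_cur * C))
            rr = tc - t_beat_last
            dap = p_tc
            sig = s0 + k_sc * c_c + k_sT * rr
            s_cur = S_max * (1.0 - math.exp(-sig / S_max))
            if s_cur < 0.1:
                s_cur = 0.1
            if n_beats >= max_beats:
                status = STATUS_BEAT_OVERFLOW
                bad_step = n
                break
            beat_t[n_beats] = tc
            beat_rr[n_beats] = rr
            beat_sap[n_beats] = dap + s_cur
            beat_dap[n_beats] = dap
            n_beats += 1
            T_prev = rr
            t_beat_last = tc
            xs = (t_next - tc) / tau_sys
            p = dap + s_cur * xs * math.exp(1.0 - xs)
            phi = phi_new - 1.0
        else:
            if t_next <= s_end:
                xs = (t_next - t_beat_last) / tau_sys
                p = dap + s_cur * xs * math.exp(1.0 - xs)
            elif t >= s_end:
                p = p * math.exp(-dt / (R_cur * C))
            else:
                p_peak = dap + s_cur
                p = p_peak * math.exp(-(t_next - s_end) / (R_cur * C))
            phi = phi_new

        if not (p > 0.0 and math.isfinite(p) and math.isfinite(v_s)
                and math.isfinite(v_sl) and math.isfinite(c_c)
                and math.isfinite(c_v)):
            status = STATUS_NONFINITE
            bad_step = n
            break

    final_state = np.empty(N_INIT)
    final_state[INIT_P] = p
    final_state[INIT_PHI] = phi
    final_state[INIT_VS] = v_s
    final_state[INIT_VSL] = v_sl
    final_state[INIT_CC] = c_c
    final_state[INIT_CV] = c_v
    final_state[INIT_TPREV] = T_prev
    final_state[INIT_DAP] = dap
    final_state[INIT_TSINCE] = n_steps * dt - t_beat_last
    final_state[INIT_VBF] = vb_f
    final_state[INIT_VBLF] = vbl_f

    return (status, bad_step, out, n_beats,
            beat_t[:n_beats], beat_rr[:n_beats],
            beat_sap[:n_beats], beat_dap[:n_beats], final_state)
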