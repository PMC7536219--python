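"""Two-loop self-exciting model of cardiovascular autonomic control.

The model couples a sinus-node phase oscillator, a lumped arterial
windkessel, two baroreceptor sites (aortic/carotid and lower body), two
self-exciting time-delay sympathetic loops (heart rate/contractility and
peripheral vascular tone), an instantaneous parasympathetic branch, and
first-order delayed noradrenaline kinetics in heart muscle and vessel wall.
Respiration enters as a constant-amplitude stochastic waveform.  A passive
head-up tilt is represented by hydrostatic pressure offsets applied to the
baroreceptor input pressures: the lower-body site feels the added blood
column, the carotid site feels the drop, both proportional to sin(alpha)
and zero in the supine position.

Equations (parameters named as in :mod:`tiltsim.params`):

* sinus node:  dphi/dt = f_s * f_p / T0;  a beat fires when phi crosses 1.
  f_s = 1 + k_fs * c_c / (1 + c_c / c_sat_s)         (saturating, >= 1)
  f_p = 1 - k_fp * (1 - exp(-v_p / v_sat_p))         (in (1 - k_fp, 1])
* systole (duration tau_sys after a beat at time t_k):
  p(t) = DAP + s * x * exp(1 - x),  x = (t - t_k)/tau_sys,
  so the peak (SAP) equals DAP + s;  contractility
  s = S_max * (1 - exp(-(s0 + k_sc*c_c + k_sT*T_prev)/S_max)).
* diastole (windkessel runoff):  dp/dt = -p / (R * C_wk),
  R = R0 + k_R * sqrt(c_v)   (saturating uptake law).
* baroreceptors (Warner form, each site i in {upper, lower}):
  v_b^i = max(0, k_bp_i * (p_i - p0_i) + k_bd_i * dp/dt),
  p_upper = p - p_hst_upper * sin(alpha)/sin(alpha_test),
  p_lower = p + p_hst_lower * sin(alpha)/sin(alpha_test).
* sympathetic loops (self-exciting delayed feedback, sigma = logistic):
  tau dv/dt = -v + G * sigma(a - k_self * v(t-theta) - k_baro * n_b(t-theta)
                             + k_resp * r(t)),
  where n_b is the baroreceptor activity after central afferent
  integration, a first-order smoothing stage with time constant T0 (the
  loops integrate the phasic afferent volley over about one cardiac
  cycle; the vagal branch receives the raw phasic signal).
* parasympathetic branch (no acetylcholine state; respiratory gating is
  multiplicative in the baroreceptor drive, so respiratory sinus arrhythmia
  scales with vagal tone and weakens upright):
  v_p = max(0, k_pb_u * v_b * (1 + k_pr * r(t)) + k_pb_l * v_b^l).
* noradrenaline:  dc/dt = -c/tau + k * v(t - theta)  per compartment.

Integration is fixed-step (default dt = 0.01 s) with linear interpolation
both in the delay buffers and for the beat-threshold crossing; pressure is
advanced exactly within each step (analytic systole, exponential diastole).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from ._kernel import STATE_COLUMNS
from .params import ModelParameters
from .respiration import RespirationProcess

__all__ = [
    "IntegrationError", "DelayHistory", "PostureSchedule", "ModelRun",
    "baroreceptor_activity", "hydrostatic_pressure", "sympathetic_loop_rate",
    "parasympathetic_activity", "noradrenaline_rate", "heart_rate_factors",
    "sinus_node_step", "contractility", "systolic_update", "systolic_pressure",
    "diastolic_decay", "vascular_resistance", "initial_state", "integrate",
    "relax", "isolated_loop_run",
]


class IntegrationError(RuntimeError):
    """Numerical failure during integration (non-finite state)."""


def _require_finite(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")


# ---------------------------------------------------------------------------
# Elementary operations (same formulas as the JIT kernel; exposed for direct
# use and testing)
# ---------------------------------------------------------------------------

def hydrostatic_pressure(alpha_deg: float, params: ModelParameters,
                         t: float | None = None, site: str = "lower") -> float:
    """Hydrostatic pressure offset felt by a baroreceptor site at tilt angle
    ``alpha_deg``.

    Zero in the supine position; equals the site coefficient at the reference
    test angle; scales with sin(alpha) in between.  The lower-body site
    receives the offset with positive sign (added blood column), the upper
    site with negative sign (carotid column drains).
    """
    _require_finite(alpha=alpha_deg)
    if not 0.0 <= alpha_deg <= 90.0:
        raise ValueError(f"tilt angle must be in [0, 90] deg, got {alpha_deg}")
    scale = math.sin(math.radians(alpha_deg)) / math.sin(
        math.radians(params.alpha_test))
    if site == "lower":
        return params.p_hst_lower * scale
    if site == "upper":
        return -params.p_hst_upper * scale
    raise ValueError(f"unknown site {site!r}")


def baroreceptor_activity(p: float, dpdt: float, site: str,
                          params: ModelParameters,
                          p_hst: float = 0.0) -> float:
    """Warner-type baroreceptor activity: proportional + rate term, clipped
    at zero.  ``p_hst`` is the (signed) hydrostatic offset already resolved
    for the site; pass the :func:`hydrostatic_pressure` value directly.
    """
    _require_finite(p=p, dpdt=dpdt, p_hst=p_hst)
    if p <= 0:
        raise ValueError(f"pressure must be positive, got {p}")
    if site == "upper":
        a = params.k_bp_u * (p + p_hst - params.p0_u) + params.k_bd_u * dpdt
    elif site == "lower":
        a = params.k_bp_l * (p + p_hst - params.p0_l) + params.k_bd_l * dpdt
    else:
        raise ValueError(f"unknown site {site!r}")
    return max(0.0, a)


def sympathetic_loop_rate(v: float, v_delayed: float, vb_delayed: float,
                          respiration: float, params: ModelParameters,
                          loop: str) -> float:
    """Time derivative of a self-exciting sympathetic loop activity.

    Relaxation toward a saturating (logistic) function of the delayed inputs;
    delayed self-inhibition makes the isolated loop a ~0.1 Hz limit-cycle
    oscillator, the delayed baroreceptor input shifts its operating point.
    """
    _require_finite(v=v, v_delayed=v_delayed, vb_delayed=vb_delayed,
                    respiration=respiration)
    if loop == "heart":
        tau, G = params.tau_s, params.G_s
        u = (params.a_s - params.k_ss * v_delayed
             - params.k_sb * vb_delayed + params.k_sr * respiration)
    elif loop == "vessel":
        tau, G = params.tau_v, params.G_v
        u = (params.a_v - params.k_vv * v_delayed
             - params.k_vb * vb_delayed + params.k_vr * respiration)
    else:
        raise ValueError(f"unknown loop {loop!r}")
    return (-v + G / (1.0 + math.exp(-u))) / tau


def parasympathetic_activity(v_b: float, v_b_l: float, respiration: float,
                             params: ModelParameters) -> float:
    """Vagal activity: excited by baroreceptor drive, multiplicatively gated
    by respiration, clipped at zero; no separate acetylcholine state."""
    _require_finite(v_b=v_b, v_b_l=v_b_l, respiration=respiration)
    if v_b < 0 or v_b_l < 0:
        raise ValueError("baroreceptor activities must be >= 0")
    return max(0.0, params.k_pb_u * v_b * (1.0 + params.k_pr * respiration)
               + params.k_pb_l * v_b_l)


def noradrenaline_rate(c: float, delayed_activity: float,
                       params: ModelParameters, compartment: str) -> float:
    """dc/dt of noradrenaline: first-order decay plus gain times the delayed
    sympathetic activity (steady state = gain * decay time * activity)."""
    _require_finite(c=c, delayed_activity=delayed_activity)
    if c < 0:
        raise ValueError("concentration must be >= 0")
    if compartment == "heart":
        tau, k = params.tau_cc, params.k_cc
    elif compartment == "vessel":
        tau, k = params.tau_cv, params.k_cv
    else:
        raise ValueError(f"unknown compartment {compartment!r}")
    if tau <= 0:
        raise ValueError("decay time must be positive")
    return -c / tau + k * delayed_activity


def heart_rate_factors(c_c: float, v_p: float,
                       params: ModelParameters) -> tuple[float, float]:
    """(f_s, f_p): sympathetic acceleration (saturating in c_c, >= 1) and
    parasympathetic deceleration (saturating in v_p, <= 1)."""
    _require_finite(c_c=c_c, v_p=v_p)
    if c_c < 0 or v_p < 0:
        raise ValueError("c_c and v_p must be >= 0")
    f_s = 1.0 + params.k_fs * c_c / (1.0 + c_c / params.c_sat_s)
    f_p = 1.0 - params.k_fp * (1.0 - math.exp(-v_p / params.v_sat_p))
    return f_s, f_p


def sinus_node_step(phi: float, f_s: float, f_p: float,
                    params: ModelParameters, dt: float):
    """Advance the sinus-node phase by one step.

    Returns ``(phi_new, crossing)`` where ``crossing`` is the within-step
    fraction (0..1) at which phi crossed 1 (the beat time is
    ``t + crossing*dt``) or ``None`` if no beat fired; phi wraps to [0, 1).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"phase must be in [0, 1), got {phi}")
    dphi = f_s * f_p / params.T0
    phi_new = phi + dt * dphi
    if phi_new >= 1.0:
        frac = (1.0 - phi) / (phi_new - phi)
        return phi_new - 1.0, frac
    return phi_new, None


def contractility(T_prev: float, c_c: float, params: ModelParameters) -> float:
    """Heart contractility s (mmHg of pulse pressure): saturating in the
    inotropic drive s0 + k_sc*c_c + k_sT*T_prev (Starling filling term)."""
    _require_finite(T_prev=T_prev, c_c=c_c)
    if T_prev <= 0:
        raise ValueError("previous cycle length must be positive")
    if c_c < 0:
        raise ValueError("c_c must be >= 0")
    sig = params.s0 + params.k_sc * c_c + params.k_sT * T_prev
    s = params.S_max * (1.0 - math.exp(-sig / params.S_max))
    return max(s, 0.1)


def systolic_update(dap_prev: float, T_prev: float, s: float,
                    params: ModelParameters) -> float:
    """Systolic pressure of the new cycle: the peak of the systolic pulse,
    SAP = DAP_prev + s.  ``T_prev`` enters through the contractility ``s``
    (see :func:`contractility`) and is only validated here."""
    _require_finite(dap_prev=dap_prev, T_prev=T_prev, s=s)
    if dap_prev <= 0 or T_prev <= 0 or s <= 0:
        raise ValueError("dap_prev, T_prev and s must be positive")
    return dap_prev + s


def systolic_pressure(dap_prev: float, s: float, t_since_beat: float,
                      params: ModelParameters) -> float:
    """Pressure on the smoothed systolic upstroke:
    p = DAP + s * x * exp(1-x) with x = t_since_beat / tau_sys."""
    x = t_since_beat / params.tau_sys
    if not 0.0 <= x <= 1.0:
        raise ValueError("t_since_beat outside the systolic phase")
    return dap_prev + s * x * math.exp(1.0 - x)


def diastolic_decay(p: float, R: float, params: ModelParameters,
                    respiration: float = 0.0) -> float:
    """Windkessel runoff dp/dt = -p/(R*C_wk).  ``respiration`` is accepted
    for interface uniformity; arterial runoff does not couple to it in this
    parameterization (respiration acts through the control loops)."""
    _require_finite(p=p, R=R)
    if p <= 0:
        raise ValueError("pressure must be positive")
    if R <= 0:
        raise ValueError("resistance must be positive")
    return -p / (R * params.C_wk)


def vascular_resistance(c_v: float, params: ModelParameters) -> float:
    """Total peripheral resistance R = R0 + k_R * sqrt(c_v) (a.u.)."""
    _require_finite(c_v=c_v)
    if c_v < 0:
        raise ValueError("c_v must be >= 0")
    R = params.R0 + params.k_R * math.sqrt(c_v)
    if R <= 0:
        raise ValueError("parameters yield non-positive resistance")
    return R


# ---------------------------------------------------------------------------
# Delay history (reference implementation of the ring-buffer contract; the
# JIT kernel uses flat history arrays with the same interpolation rule)
# ---------------------------------------------------------------------------

class DelayHistory:
    """Ring buffer of past values of one signal, looked up by lag.

    ``lookup(0)`` returns the current (most recently pushed) value;
    ``lookup(tau)`` linearly interpolates between the recorded grid points;
    lags beyond the recorded past return the oldest value (constant
    pre-history).
    """

    def __init__(self, span_s: float, dt: float, fill: float = 0.0):
        if span_s <= 0 or dt <= 0:
            raise ValueError("span and dt must be positive")
        self.dt = float(dt)
        self.n = int(math.ceil(span_s / dt)) + 2
        self._buf = np.full(self.n, float(fill))
        self._head = 0
        self._count = 0

    @property
    def span(self) -> float:
        return (self.n - 1) * self.dt

    def push(self, value: float) -> None:
        self._head = (self._head + 1) % self.n
        self._buf[self._head] = value
        self._count = min(self._count + 1, self.n)

    def lookup(self, lag_s: float) -> float:
        if lag_s < 0:
            raise ValueError("lag must be >= 0")
        lag = lag_s / self.dt
        if lag > self.n - 1:
            raise ValueError(
                f"lag {lag_s} s exceeds history span {self.span} s")
        i0 = int(math.floor(lag))
        w = lag - i0
        a = self._buf[(self._head - i0) % self.n]
        if w == 0.0:
            return float(a)
        b = self._buf[(self._head - i0 - 1) % self.n]
        return float(a * (1.0 - w) + b * w)


# ---------------------------------------------------------------------------
# Posture schedules and runs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PostureSchedule:
    """Piecewise-linear tilt angle alpha(t) in degrees."""

    times: np.ndarray
    angles: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.angles, dtype=float)
        if t.ndim != 1 or t.shape != a.shape or t.size == 0:
            raise ValueError("times and angles must be equal-length 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("schedule times must be strictly increasing")
        if np.any((a < 0) | (a > 90)):
            raise ValueError("tilt angles must be within [0, 90] deg")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "angles", a)

    @classmethod
    def constant(cls, angle_deg: float) -> "PostureSchedule":
        return cls(np.array([0.0]), np.array([float(angle_deg)]))

    @classmethod
    def tilt(cls, t_tilt_s: float, angle_deg: float,
             transition_s: float = 10.0) -> "PostureSchedule":
        """Supine until ``t_tilt_s``, then a linear ramp to ``angle_deg``
        over ``transition_s`` seconds."""
        return cls(np.array([0.0, t_tilt_s, t_tilt_s + transition_s]),
                   np.array([0.0, 0.0, float(angle_deg)]))

    def alpha(self, t: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.times, self.angles)


_STATUS_MSG = {
    _kernel.STATUS_NONFINITE: "state became non-finite or pressure non-positive",
    _kernel.STATUS_BEAT_OVERFLOW: "beat buffer overflow (runaway heart rate)",
}


@dataclass
class ModelRun:
    """One realization: uniform-grid state trajectories plus beat events."""

    params: ModelParameters
    dt: float
    store_stride: int
    seed: int
    posture: PostureSchedule
    time: np.ndarray                       # stored grid, s
    states: pd.DataFrame                   # columns = STATE_COLUMNS
    beats: pd.DataFrame                    # beat_time_s, RR_s, SAP_mmHg, DAP_mmHg
    final_state: np.ndarray = field(repr=False, default=None)

    @property
    def duration(self) -> float:
        return float(self.time[-1])

    def state_means(self, window: tuple[float, float] | None = None) -> pd.Series:
        from .protocol import state_variable_means   # noqa: avoid cycle at import
        return state_variable_means(self, window)[0]

    def beats_in(self, window: tuple[float, float]) -> pd.DataFrame:
        t0, t1 = window
        m = (self.beats["beat_time_s"] >= t0) & (self.beats["beat_time_s"] <= t1)
        return self.beats.loc[m]

    def beat_series(self, window: tuple[float, float] | None = None):
        """BeatSeries view (indices-module input) over an optional window."""
        from .indices import BeatSeries
        b = self.beats if window is None else self.beats_in(window)
        return BeatSeries(times=b["beat_time_s"].to_numpy(),
                          rr=b["RR_s"].to_numpy(),
                          sap=b["SAP_mmHg"].to_numpy(),
                          dap=b["DAP_mmHg"].to_numpy())


def initial_state(params: ModelParameters) -> np.ndarray:
    """Generic near-operating-point initial condition (supine-like)."""
    init = np.empty(_kernel.N_INIT)
    init[_kernel.INIT_P] = 95.0
    init[_kernel.INIT_PHI] = 0.0
    init[_kernel.INIT_VS] = 2.0
    init[_kernel.INIT_VSL] = 1.9
    init[_kernel.INIT_CC] = 0.14
    init[_kernel.INIT_CV] = 2.3
    init[_kernel.INIT_TPREV] = 0.85
    init[_kernel.INIT_DAP] = 75.0
    init[_kernel.INIT_TSINCE] = 0.5
    init[_kernel.INIT_VBF] = 5.2
    init[_kernel.INIT_VBLF] = 5.2
    return init


def integrate(params: ModelParameters, duration_s: float, seed: int,
              posture: PostureSchedule | float = 0.0, dt: float = 0.01,
              store_stride: int = 4,
              init_state: np.ndarray | None = None) -> ModelRun:
    """Integrate the full model for ``duration_s`` seconds.

    Deterministic given ``(params, seed, dt)``: the only stochastic input is
    the respiration process driven by its own seeded generator.

    Parameters
    ----------
    posture : PostureSchedule or float
        Tilt-angle schedule, or a constant angle in degrees.
    store_stride : int
        Trajectories are stored every ``store_stride`` steps.
    init_state : ndarray, optional
        State vector as returned by :func:`relax` (pre-relaxed snapshot);
        defaults to a generic supine-like state.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration_s <= params.max_delay:
        raise ValueError("duration must exceed the largest loop delay")
    if isinstance(posture, (int, float)):
        posture = PostureSchedule.constant(float(posture))
    n_steps = int(round(duration_s / dt))
    resp = RespirationProcess(params.f_br, params.sigma2_xi,
                              duration_s + 2.0, seed)
    init = initial_state(params) if init_state is None \
        else np.asarray(init_state, dtype=float).copy()

    (status, bad_step, out, n_beats, beat_t, beat_rr, beat_sap, beat_dap,
     final_state) = _kernel.run_kernel(
        params.to_vector(), float(dt), n_steps, int(store_stride),
        resp.onsets, resp.frequencies,
        posture.times, posture.angles, init)

    if status != _kernel.STATUS_OK:
        bad = "state"
        if status == _kernel.STATUS_NONFINITE:
            names = ("p", "v_s", "v_s_l", "c_c", "c_v")
            vals = (final_state[_kernel.INIT_P], final_state[_kernel.INIT_VS],
                    final_state[_kernel.INIT_VSL], final_state[_kernel.INIT_CC],
                    final_state[_kernel.INIT_CV])
            for nm, v in zip(names, vals):
                if not np.isfinite(v) or (nm == "p" and v <= 0):
                    bad = nm
                    break
        raise IntegrationError(
            f"integration aborted at t={bad_step * dt:.2f} s "
            f"({_STATUS_MSG[status]}; first offending variable: {bad})")

    time = np.arange(out.shape[0]) * (dt * store_stride)
    states = pd.DataFrame(out, columns=list(STATE_COLUMNS))
    beats = pd.DataFrame({
        "beat_time_s": beat_t, "RR_s": beat_rr,
        "SAP_mmHg": beat_sap, "DAP_mmHg": beat_dap,
    })
    return ModelRun(params=params, dt=dt, store_stride=store_stride,
                    seed=seed, posture=posture, time=time, states=states,
                    beats=beats, final_state=final_state)


def relax(params: ModelParameters, duration_s: float, seed: int,
          posture: PostureSchedule | float = 0.0, dt: float = 0.01,
          init_state: np.ndarray | None = None) -> np.ndarray:
    """Run the model and return the final state vector (a pre-relaxed
    snapshot usable as ``init_state`` of a subsequent run)."""
    run = integrate(params, duration_s, seed, posture=posture, dt=dt,
                    store_stride=max(1, int(round(duration_s / dt / 100))),
                    init_state=init_state)
    return run.final_state


def isolated_loop_run(params: ModelParameters, loop: str, duration_s: float,
                      baro_input: float, dt: float = 0.01,
                      v0: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Free-run one sympathetic loop with its baroreceptor input frozen at an
    operating-point value and respiration off.

    Returns ``(t, v)``.  Used to exhibit the loop's intrinsic ~0.1 Hz limit
    cycle independently of the rest of the circulation.
    """
    if loop == "heart":
        tau, theta = params.tau_s, params.theta_s
    elif loop == "vessel":
        tau, theta = params.tau_v, params.theta_v
    else:
        raise ValueError(f"unknown loop {loop!r}")
    n = int(round(duration_s / dt))
    if theta >= duration_s:
        raise ValueError("duration must exceed the loop delay")
    lag = theta / dt
    v = np.empty(n + 1)
    v[0] = v0
    for i in range(n):
        idx = i - lag
        if idx <= 0:
            v_del = v[0]
        else:
            i0 = int(math.floor(idx))
            w = idx - i0
            v_del = v[i0] * (1.0 - w) + v[min(i0 + 1, i)] * w
        dv = sympathetic_loop_rate(v[i], v_del, baro_input, 0.0, params, loop)
        v[i + 1] = max(0.0, v[i] + dt * dv)
    return np.arange(n + 1) * dt, v
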