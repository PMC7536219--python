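"""Head-up tilt protocol on the model: equilibration, posture contrast,
transient exclusion, and paired index extraction.

Rather than simulating one long record through the tilt manoeuvre, the
paired contrast runs each realization twice from the same seed — once
supine (alpha = 0) and once upright (alpha = tilt angle) — so that posture
is the only difference within a pair (variance reduction for the paired
ensemble statistics).  Each run discards a configurable transient before
the recording window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indices import rr_spectral_indexes, rr_to_uniform, resample_uniform, s_index
from .model import ModelRun, PostureSchedule, integrate
from .params import ModelParameters

__all__ = ["TiltProtocol", "PairedRunSummary", "run_tilt_protocol",
           "state_variable_means", "run_indexes"]

#: state variables averaged for the posture contrast (per-run time means)
SUMMARY_STATE_VARS = ("R", "s", "v_b", "v_b_l", "v_s_l", "v_s", "v_p",
                      "c_c", "c_v", "f_s", "f_p", "p")
#: beat/spectral/synchronization indexes
SUMMARY_INDEX_VARS = ("HR", "SAP", "DAP", "LF", "HF", "S")


@dataclass(frozen=True)
class TiltProtocol:
    """Timing of the simulated passive head-up tilt test.

    The human protocol it mirrors: 10 min preliminary rest (no recording),
    10 min supine recording, tilt to ~80 deg, 5 min post-tilt exclusion,
    10 min upright recording.  For the model the preliminary and exclusion
    stages collapse into ``transient_s`` of discarded simulation per posture.
    """

    transient_s: float = 300.0      # discarded equilibration per run
    record_s: float = 600.0         # recording window per posture
    tilt_angle_deg: float = 80.0
    preliminary_s: float = 600.0    # human-protocol stages, kept for record
    post_tilt_exclusion_s: float = 300.0
    dt: float = 0.01
    store_stride: int = 2    # 50 Hz storage keeps aliased cardiac harmonics tiny

    def __post_init__(self):
        for name in ("transient_s", "record_s", "preliminary_s",
                     "post_tilt_exclusion_s", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.tilt_angle_deg <= 90:
            raise ValueError("tilt angle must be in (0, 90] deg")

    @property
    def window(self) -> tuple[float, float]:
        return (self.transient_s, self.transient_s + self.record_s)

    @property
    def duration(self) -> float:
        return self.transient_s + self.record_s


@dataclass(frozen=True)
class PairedRunSummary:
    """Ensemble means and SDs of indexes and state variables per posture."""

    table: pd.DataFrame          # columns: variable, posture, mean, sd
    per_run: pd.DataFrame        # one row per (realization, posture)
    n_realizations: int
    seeds: tuple[int, ...]
    protocol: TiltProtocol = field(repr=False, default=None)

    def mean(self, variable: str, posture: str) -> float:
        t = self.table
        row = t[(t["variable"] == variable) & (t["posture"] == posture)]
        if row.empty:
            raise KeyError(f"no summary entry for {variable}/{posture}")
        return float(row["mean"].iloc[0])

    def sd(self, variable: str, posture: str) -> float:
        t = self.table
        row = t[(t["variable"] == variable) & (t["posture"] == posture)]
        if row.empty:
            raise KeyError(f"no summary entry for {variable}/{posture}")
        return float(row["sd"].iloc[0])


def state_variable_means(run: ModelRun,
                         window: tuple[float, float] | None = None
                         ) -> tuple[pd.Series, pd.Series]:
    """Time means and SDs of all stored state variables over ``window``.

    The average is taken over the uniform storage grid restricted to the
    window (inclusive endpoints).
    """
    if window is None:
        window = (float(run.time[0]), float(run.time[-1]))
    t0, t1 = window
    mask = (run.time >= t0) & (run.time <= t1)
    if not np.any(mask):
        raise ValueError(f"window ({t0}, {t1}) contains no stored samples")
    sub = run.states.loc[mask]
    return sub.mean(), sub.std(ddof=0)


def run_indexes(run: ModelRun, window: tuple[float, float],
                compute_spectral: bool = True,
                compute_sync: bool = True) -> dict[str, float]:
    """HR (beats/min), SAP/DAP (mmHg), LF/HF (ms^2) and S (%) of one run
    restricted to the recording window."""
    beats = run.beats_in(window)
    if len(beats) < 3:
        raise ValueError("recording window contains fewer than 3 beats")
    rr = beats["RR_s"].to_numpy()
    out = {
        "HR": 60.0 / float(np.mean(rr)),
        "SAP": float(beats["SAP_mmHg"].mean()),
        "DAP": float(beats["DAP_mmHg"].mean()),
    }
    series = run.beat_series(window)
    if compute_spectral:
        spec = rr_spectral_indexes(series)
        out["LF"] = spec.lf
        out["HF"] = spec.hf
    if compute_sync:
        mask = (run.time >= window[0]) & (run.time <= window[1])
        rr_u = rr_to_uniform(series)
        bp_u = resample_uniform(run.time[mask],
                                run.states["p"].to_numpy()[mask])
        n = min(len(rr_u.x), len(bp_u.x))
        from .indices import UniformSeries
        out["S"] = s_index(
            UniformSeries(rr_u.t[:n], rr_u.x[:n], rr_u.fs),
            UniformSeries(bp_u.t[:n], bp_u.x[:n], bp_u.fs)).s
    return out


def _summarize(run: ModelRun, window: tuple[float, float]) -> dict[str, float]:
    means, _ = state_variable_means(run, window)
    row = {v: float(means[v]) for v in SUMMARY_STATE_VARS}
    row.update(run_indexes(run, window))
    return row


def run_tilt_protocol(params: ModelParameters, n_realizations: int,
                      seed0: int, protocol: TiltProtocol | None = None,
                      init_supine: np.ndarray | None = None,
                      init_upright: np.ndarray | None = None
                      ) -> PairedRunSummary:
    """Simulate ``n_realizations`` paired supine/upright runs and return the
    ensemble summary.

    Realization ``i`` uses seed ``seed0 + i`` for both postures, so within a
    pair the respiration noise is identical and posture is the only
    difference.  Indexes and state means are computed on the recording
    window only (after the transient discard).
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    protocol = protocol or TiltProtocol()
    seeds = tuple(seed0 + i for i in range(n_realizations))
    rows = []
    for i, seed in enumerate(seeds):
        for posture, angle, init in (
                ("supine", 0.0, init_supine),
                ("upright", protocol.tilt_angle_deg, init_upright)):
            try:
                run = integrate(params, protocol.duration, seed,
                                posture=PostureSchedule.constant(angle),
                                dt=protocol.dt,
                                store_stride=protocol.store_stride,
                                init_state=init)
            except Exception as exc:
                raise RuntimeError(
                    f"realization {i} ({posture}) failed: {exc}") from exc
            row = _summarize(run, protocol.window)
            row["realization"] = i
            row["posture"] = posture
            rows.append(row)
    per_run = pd.DataFrame(rows)
    records = []
    for v in list(SUMMARY_STATE_VARS) + list(SUMMARY_INDEX_VARS):
        for posture in ("supine", "upright"):
            vals = per_run.loc[per_run["posture"] == posture, v].to_numpy()
            records.append({"variable": v, "posture": posture,
                            "mean": float(np.mean(vals)),
                            "sd": float(np.std(vals, ddof=0))})
    table = pd.DataFrame(records)
    return PairedRunSummary(table=table, per_run=per_run,
                            n_realizations=n_realizations, seeds=seeds,
                            protocol=protocol)
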