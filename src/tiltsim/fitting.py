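"""Ensemble objective function and variable-step gradient descent over the
31 fitted coefficients.

The objective is the sum over five indexes (mean HR, SAP, DAP, LF, HF) of
the squared relative mismatch between ensemble-averaged model indexes and
their targets,

    L(p) = sum_i ((I_i^model(p) - I_i^target) / I_i^target)^2 ,

and fitting stops when L < eps (eps = 0.05, at which point every index is
within ~10% of its target).  The optimizer is a normalized-gradient descent
with a variable step: forward finite differences in box-scaled coordinates,
step halved on a failed trial and grown 1.5x on success, terminating on
step underflow.  Objective evaluations reuse a common seed list so the
finite differences are not drowned by respiration noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .model import IntegrationError, PostureSchedule, integrate
from .params import ModelParameters
from .protocol import TiltProtocol, run_indexes

__all__ = ["IndexTargets", "FitResult", "model_indexes", "objective",
           "gradient_descent", "fit", "FAILURE_PENALTY"]

INDEX_NAMES = ("HR", "SAP", "DAP", "LF", "HF")

#: objective value assigned when the integration blows up at a trial point
FAILURE_PENALTY = 1.0e3


@dataclass(frozen=True)
class IndexTargets:
    """Target mean indexes: HR in beats/min, SAP/DAP in mmHg, LF/HF in ms^2."""

    hr: float
    sap: float
    dap: float
    lf: float
    hf: float

    def __post_init__(self):
        for name in ("hr", "sap", "dap", "lf", "hf"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"target {name} must be positive, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {"HR": self.hr, "SAP": self.sap, "DAP": self.dap,
                "LF": self.lf, "HF": self.hf}


@dataclass
class FitResult:
    """Outcome of one fitting run."""

    params: ModelParameters
    final_l: float
    trajectory: list[float]
    relative_errors: dict[str, float]
    converged: bool
    n_evaluations: int
    n_realizations: int
    seeds: tuple[int, ...]
    indexes: dict[str, float] = field(default_factory=dict)


def model_indexes(params: ModelParameters, n_realizations: int, seed0: int,
                  protocol: TiltProtocol | None = None,
                  posture: str = "upright") -> dict[str, float]:
    """Ensemble means of the five indexes from (by default) upright runs.

    Realization ``i`` uses seed ``seed0 + i``; with ``sigma2_xi = 0`` the
    model is deterministic and all realizations coincide.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    protocol = protocol or TiltProtocol()
    angle = protocol.tilt_angle_deg if posture == "upright" else 0.0
    acc = {k: 0.0 for k in INDEX_NAMES}
    for i in range(n_realizations):
        run = integrate(params, protocol.duration, seed0 + i,
                        posture=PostureSchedule.constant(angle),
                        dt=protocol.dt, store_stride=protocol.store_stride)
        idx = run_indexes(run, protocol.window, compute_sync=False)
        for k in INDEX_NAMES:
            acc[k] += idx[k]
    return {k: v / n_realizations for k, v in acc.items()}


def objective(indexes: Mapping[str, float], targets: IndexTargets) -> float:
    """L = sum over the five indexes of squared relative mismatch."""
    tg = targets.as_dict()
    l = 0.0
    for k in INDEX_NAMES:
        if tg[k] == 0:
            raise ValueError(f"target {k} must be nonzero")
        l += ((indexes[k] - tg[k]) / tg[k]) ** 2
    return l


def gradient_descent(fun: Callable[[np.ndarray], float], z0: np.ndarray,
                     eps: float, *, fd_step: float = 1.0e-3,
                     step0: float = 0.05, step_underflow: float = 1.0e-8,
                     max_iterations: int = 500,
                     bounds: tuple[float, float] = (0.0, 1.0)
                     ) -> tuple[np.ndarray, list[float], bool, int]:
    """Variable-step normalized-gradient descent in box-scaled coordinates.

    Forward finite differences (``fd_step``); a trial step is accepted only
    if it decreases the objective, the step is halved on failure and grown
    1.5x on success, and the search stops when the objective drops below
    ``eps``, the step underflows below ``step_underflow * step0``, or
    ``max_iterations`` gradients have been used.  Returns
    ``(z_best, trajectory, converged, n_evaluations)``.
    """
    lo, hi = bounds
    z = np.clip(np.asarray(z0, dtype=float).copy(), lo, hi)
    n_eval = 0

    def f(zz: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        return fun(zz)

    l_cur = f(z)
    trajectory = [l_cur]
    step = step0
    converged = l_cur < eps
    it = 0
    while not converged and it < max_iterations:
        it += 1
        g = np.zeros_like(z)
        for j in range(len(z)):
            zj = z.copy()
            h = fd_step if zj[j] + fd_step <= hi else -fd_step
            zj[j] += h
            g[j] = (f(zj) - l_cur) / h
        gn = np.linalg.norm(g)
        if gn == 0:
            break
        d = -g / gn
        improved = False
        while step >= step_underflow * step0:
            z_try = np.clip(z + step * d, lo, hi)
            l_try = f(z_try)
            if l_try < l_cur:
                z, l_cur = z_try, l_try
                trajectory.append(l_cur)
                step *= 1.5
                improved = True
                break
            step *= 0.5
        if not improved:
            break            # step underflow: return best-so-far
        if l_cur < eps:
            converged = True
    return z, trajectory, converged, n_eval


def _scale(params: ModelParameters, names: Sequence[str]) -> np.ndarray:
    z = np.empty(len(names))
    for j, nm in enumerate(names):
        lo, hi = ModelParameters.bounds(nm)
        z[j] = (params[nm] - lo) / (hi - lo)
    return z


def _unscale(z: np.ndarray, base: ModelParameters,
             names: Sequence[str]) -> ModelParameters:
    updates = {}
    for j, nm in enumerate(names):
        lo, hi = ModelParameters.bounds(nm)
        updates[nm] = lo + float(np.clip(z[j], 0.0, 1.0)) * (hi - lo)
    return base.replace(**updates)


def fit(params0: ModelParameters, targets: IndexTargets, eps: float = 0.05,
        n_realizations: int = 1, seed0: int = 1,
        protocol: TiltProtocol | None = None,
        max_iterations: int = 200, step0: float = 0.02) -> FitResult:
    """Fit the 31 fitted-tagged coefficients to the index targets.

    Only fitted-tagged parameters move; every iterate respects the box
    constraints; all objective evaluations share the seed list
    ``seed0 .. seed0+n-1`` (common random numbers).  Returns the best-found
    parameters with ``converged=False`` if the step underflows or the
    iteration cap is hit before ``L < eps``.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    protocol = protocol or TiltProtocol()
    names = ModelParameters.fitted_names()
    seeds = tuple(seed0 + i for i in range(n_realizations))

    cache: dict[bytes, float] = {}

    def fun(z: np.ndarray) -> float:
        key = z.tobytes()
        if key in cache:
            return cache[key]
        p = _unscale(z, params0, names)
        try:
            idx = model_indexes(p, n_realizations, seed0, protocol)
            l = objective(idx, targets)
        except (IntegrationError, RuntimeError, ValueError):
            l = FAILURE_PENALTY
        cache[key] = l
        return l

    z0 = _scale(params0, names)
    z_best, trajectory, converged, n_eval = gradient_descent(
        fun, z0, eps, step0=step0, max_iterations=max_iterations)
    p_best = _unscale(z_best, params0, names)
    try:
        idx = model_indexes(p_best, n_realizations, seed0, protocol)
        rel = {k: (idx[k] - targets.as_dict()[k]) / targets.as_dict()[k]
               for k in INDEX_NAMES}
        final_l = objective(idx, targets)
    except (IntegrationError, RuntimeError, ValueError):
        idx, rel, final_l = {}, {}, FAILURE_PENALTY
    return FitResult(params=p_best, final_l=final_l, trajectory=trajectory,
                     relative_errors=rel, converged=converged and
                     final_l < eps, n_evaluations=n_eval,
                     n_realizations=n_realizations, seeds=seeds, indexes=idx)
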