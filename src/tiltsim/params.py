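"""Model parameters: the 47 named coefficients of the autonomic-control model.

Every coefficient carries a provenance tag:

* ``fixed`` (14) — structural constants with weak influence on the index
  fit, held at their nominal values;
* ``fitted`` (31) — coefficients adjusted by the calibration / fitting
  procedure (only these move during :func:`tiltsim.fitting.fit`);
* ``from_data`` (2) — respiration statistics (mean breath frequency and the
  variance of the per-breath frequency noise) that in an experimental
  setting are estimated directly from recorded respiration.

The shipped default values live in ``tiltsim/data/default_params.yaml``; the
equations in :mod:`tiltsim.model` never hard-code them.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "ParamDef",
    "PARAM_DEFS",
    "PARAM_ORDER",
    "ModelParameters",
    "default_parameters",
    "load_parameters",
]


@dataclass(frozen=True)
class ParamDef:
    """Static definition of one model coefficient."""

    name: str
    group: str
    tag: str          # fixed | fitted | from_data
    bounds: tuple[float, float]
    unit: str
    doc: str


# Canonical order; the integration kernel addresses the packed vector by the
# positions defined here.
PARAM_DEFS: tuple[ParamDef, ...] = (
    # --- sinus node -------------------------------------------------------
    ParamDef("T0", "sinus_node", "fixed", (0.5, 2.0), "s",
             "intrinsic sinus-node period (denervated cycle length)"),
    ParamDef("k_fs", "sinus_node", "fitted", (0.0, 20.0), "1/a.u.",
             "sympathetic chronotropic gain: slope of f_s in saturated c_c"),
    ParamDef("c_sat_s", "sinus_node", "fixed", (0.1, 50.0), "a.u.",
             "noradrenaline scale at which the chronotropic effect saturates"),
    ParamDef("k_fp", "sinus_node", "fitted", (0.0, 1.0), "-",
             "maximal parasympathetic deceleration (1 - inf f_p)"),
    ParamDef("v_sat_p", "sinus_node", "fixed", (0.1, 20.0), "a.u.",
             "parasympathetic activity scale at which f_p saturates"),
    # --- hemodynamics -----------------------------------------------------
    ParamDef("C_wk", "hemodynamics", "fixed", (0.2, 10.0), "a.u.",
             "windkessel arterial compliance (decay constant = R*C_wk)"),
    ParamDef("tau_sys", "hemodynamics", "fixed", (0.05, 0.3), "s",
             "duration of the smoothed systolic upstroke"),
    ParamDef("R0", "hemodynamics", "fitted", (0.1, 3.0), "a.u.",
             "peripheral resistance at zero vascular noradrenaline"),
    ParamDef("k_R", "hemodynamics", "fitted", (-1.0, 1.0), "a.u./a.u.",
             "sensitivity of peripheral resistance to c_v"),
    ParamDef("S_max", "hemodynamics", "fixed", (20.0, 500.0), "mmHg",
             "saturation ceiling of the contractility pulse pressure"),
    ParamDef("s0", "hemodynamics", "fitted", (-200.0, 200.0), "mmHg",
             "contractility offset"),
    ParamDef("k_sc", "hemodynamics", "fitted", (0.0, 200.0), "mmHg/a.u.",
             "inotropic gain: contractility per unit cardiac noradrenaline"),
    ParamDef("k_sT", "hemodynamics", "fitted", (0.0, 500.0), "mmHg/s",
             "Starling gain: contractility per second of previous cycle"),
    # --- baroreceptors ----------------------------------------------------
    ParamDef("p0_u", "baroreceptors", "fitted", (0.0, 120.0), "mmHg",
             "set-point pressure of the aortic/carotid (upper) site"),
    ParamDef("k_bp_u", "baroreceptors", "fitted", (0.0, 2.0), "a.u./mmHg",
             "proportional gain of the upper site"),
    ParamDef("k_bd_u", "baroreceptors", "fitted", (0.0, 0.1), "a.u.s/mmHg",
             "rate-sensitivity gain of the upper site (Warner dp/dt term)"),
    ParamDef("p0_l", "baroreceptors", "fitted", (0.0, 120.0), "mmHg",
             "set-point pressure of the lower-body site"),
    ParamDef("k_bp_l", "baroreceptors", "fitted", (0.0, 2.0), "a.u./mmHg",
             "proportional gain of the lower-body site"),
    ParamDef("k_bd_l", "baroreceptors", "fitted", (0.0, 0.1), "a.u.s/mmHg",
             "rate-sensitivity gain of the lower-body site"),
    # --- tilt -------------------------------------------------------------
    ParamDef("p_hst_upper", "tilt", "fitted", (0.0, 60.0), "mmHg",
             "upright hydrostatic pressure drop felt by the upper site"),
    ParamDef("p_hst_lower", "tilt", "fitted", (0.0, 80.0), "mmHg",
             "upright hydrostatic pressure rise felt by the lower-body site"),
    ParamDef("alpha_test", "tilt", "fixed", (10.0, 90.0), "deg",
             "reference tilt angle at which the hydrostatic coefficients apply"),
    # --- sympathetic heart-rate loop --------------------------------------
    ParamDef("tau_s", "sympathetic_heart", "fixed", (0.2, 10.0), "s",
             "relaxation time of the heart-rate sympathetic loop"),
    ParamDef("theta_s", "sympathetic_heart", "fixed", (0.5, 8.0), "s",
             "conduction delay of the heart-rate sympathetic loop"),
    ParamDef("G_s", "sympathetic_heart", "fitted", (0.5, 30.0), "a.u.",
             "saturation level of the heart-loop firing nonlinearity"),
    ParamDef("k_ss", "sympathetic_heart", "fitted", (0.0, 10.0), "1/a.u.",
             "delayed self-inhibition gain (source of the 0.1 Hz limit cycle)"),
    ParamDef("k_sb", "sympathetic_heart", "fitted", (0.0, 10.0), "1/a.u.",
             "baroreceptor inhibition gain onto the heart loop"),
    ParamDef("k_sr", "sympathetic_heart", "fitted", (0.0, 5.0), "-",
             "respiratory coupling into the heart loop"),
    ParamDef("a_s", "sympathetic_heart", "fitted", (-50.0, 80.0), "-",
             "central drive offset of the heart loop"),
    # --- sympathetic vascular-tone loop -----------------------------------
    ParamDef("tau_v", "sympathetic_vessel", "fixed", (0.2, 10.0), "s",
             "relaxation time of the vascular-tone sympathetic loop"),
    ParamDef("theta_v", "sympathetic_vessel", "fixed", (0.5, 8.0), "s",
             "conduction delay of the vascular-tone sympathetic loop"),
    ParamDef("G_v", "sympathetic_vessel", "fitted", (0.5, 30.0), "a.u.",
             "saturation level of the vessel-loop firing nonlinearity"),
    ParamDef("k_vv", "sympathetic_vessel", "fitted", (0.0, 10.0), "1/a.u.",
             "delayed self-inhibition gain of the vessel loop"),
    ParamDef("k_vb", "sympathetic_vessel", "fitted", (0.0, 10.0), "1/a.u.",
             "lower-body baroreceptor inhibition gain onto the vessel loop"),
    ParamDef("k_vr", "sympathetic_vessel", "fitted", (0.0, 5.0), "-",
             "respiratory coupling into the vessel loop"),
    ParamDef("a_v", "sympathetic_vessel", "fitted", (-50.0, 80.0), "-",
             "central drive offset of the vessel loop"),
    # --- noradrenaline kinetics -------------------------------------------
    ParamDef("tau_cc", "noradrenaline", "fitted", (0.2, 20.0), "s",
             "decay time of noradrenaline in the heart muscle"),
    ParamDef("k_cc", "noradrenaline", "fitted", (0.0, 5.0), "a.u./(a.u. s)",
             "release gain: cardiac noradrenaline per unit delayed v_s"),
    ParamDef("theta_cc", "noradrenaline", "fixed", (0.0, 5.0), "s",
             "delay from heart-loop activity to cardiac release"),
    ParamDef("tau_cv", "noradrenaline", "fitted", (0.2, 20.0), "s",
             "decay time of noradrenaline in the vessel wall"),
    ParamDef("k_cv", "noradrenaline", "fitted", (0.0, 5.0), "a.u./(a.u. s)",
             "release gain: vascular noradrenaline per unit delayed v_s^l"),
    ParamDef("theta_cv", "noradrenaline", "fixed", (0.0, 5.0), "s",
             "delay from vessel-loop activity to vascular release"),
    # --- parasympathetic branch -------------------------------------------
    ParamDef("k_pb_u", "parasympathetic", "fitted", (0.0, 5.0), "-",
             "upper-baroreceptor excitation gain of the vagal branch"),
    ParamDef("k_pb_l", "parasympathetic", "fixed", (0.0, 5.0), "-",
             "lower-baroreceptor excitation gain of the vagal branch"),
    ParamDef("k_pr", "parasympathetic", "fitted", (0.0, 5.0), "a.u.",
             "respiratory gating of the vagal branch (source of RSA)"),
    # --- respiration ------------------------------------------------------
    ParamDef("f_br", "respiration", "from_data", (0.05, 0.6), "Hz",
             "mean breathing frequency"),
    ParamDef("sigma2_xi", "respiration", "from_data", (0.0, 0.05), "Hz^2",
             "variance of the zero-mean Gaussian noise added to f_br each breath"),
)

PARAM_ORDER: tuple[str, ...] = tuple(d.name for d in PARAM_DEFS)
_DEF_BY_NAME: dict[str, ParamDef] = {d.name: d for d in PARAM_DEFS}

N_FIXED = sum(1 for d in PARAM_DEFS if d.tag == "fixed")
N_FITTED = sum(1 for d in PARAM_DEFS if d.tag == "fitted")
N_FROM_DATA = sum(1 for d in PARAM_DEFS if d.tag == "from_data")
assert (N_FIXED, N_FITTED, N_FROM_DATA) == (14, 31, 2)
assert len(PARAM_DEFS) == 47


class ModelParameters:
    """Container for one complete coefficient vector.

    Behaves like an immutable-by-convention mapping with attribute access;
    ``replace`` returns a modified copy.  Construction validates box
    constraints and the structural invariants (nonnegative delays, positive
    relaxation/decay times).
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float]):
        unknown = set(values) - set(PARAM_ORDER)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        missing = set(PARAM_ORDER) - set(values)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")
        vals = {k: float(values[k]) for k in PARAM_ORDER}
        self._validate(vals)
        object.__setattr__(self, "_values", vals)

    @staticmethod
    def _validate(vals: dict[str, float]) -> None:
        for name, v in vals.items():
            if not np.isfinite(v):
                raise ValueError(f"parameter {name} is not finite: {v}")
            lo, hi = _DEF_BY_NAME[name].bounds
            if not (lo <= v <= hi):
                raise ValueError(
                    f"parameter {name}={v} outside bounds [{lo}, {hi}]")
        for name in ("theta_s", "theta_v", "theta_cc", "theta_cv"):
            if vals[name] < 0:
                raise ValueError(f"delay {name} must be >= 0")
        for name in ("tau_s", "tau_v", "tau_cc", "tau_cv"):
            if vals[name] <= 0:
                raise ValueError(f"relaxation/decay time {name} must be > 0")

    # -- mapping interface -------------------------------------------------
    def __getattr__(self, name: str) -> float:
        try:
            return self._values[name]
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __iter__(self):
        return iter(PARAM_ORDER)

    def __len__(self) -> int:
        return len(PARAM_ORDER)

    def __eq__(self, other) -> bool:
        return isinstance(other, ModelParameters) and self._values == other._values

    def __repr__(self) -> str:
        return f"ModelParameters({self._values!r})"

    def as_dict(self) -> dict[str, float]:
        return dict(self._values)

    def replace(self, **updates: float) -> "ModelParameters":
        vals = dict(self._values)
        vals.update(updates)
        return ModelParameters(vals)

    # -- provenance helpers ------------------------------------------------
    @staticmethod
    def tags() -> dict[str, str]:
        return {d.name: d.tag for d in PARAM_DEFS}

    @staticmethod
    def fitted_names() -> tuple[str, ...]:
        return tuple(d.name for d in PARAM_DEFS if d.tag == "fitted")

    @staticmethod
    def bounds(name: str) -> tuple[float, float]:
        return _DEF_BY_NAME[name].bounds

    @property
    def max_delay(self) -> float:
        return max(self.theta_s, self.theta_v, self.theta_cc, self.theta_cv)

    # -- packing for the integration kernel --------------------------------
    def to_vector(self) -> np.ndarray:
        return np.array([self._values[k] for k in PARAM_ORDER], dtype=np.float64)

    @classmethod
    def from_vector(cls, vec: Iterable[float]) -> "ModelParameters":
        vec = np.asarray(list(vec), dtype=float)
        if vec.shape != (len(PARAM_ORDER),):
            raise ValueError(f"expected {len(PARAM_ORDER)} values")
        return cls(dict(zip(PARAM_ORDER, vec)))

    # -- file I/O ----------------------------------------------------------
    def to_yaml(self, path) -> None:
        groups: dict[str, dict] = {}
        for d in PARAM_DEFS:
            groups.setdefault(d.group, {})[d.name] = {
                "value": self._values[d.name],
                "tag": d.tag,
                "bounds": list(d.bounds),
                "unit": d.unit,
            }
        with open(path, "w") as fh:
            yaml.safe_dump(groups, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            groups = yaml.safe_load(fh)
        vals: dict[str, float] = {}
        for group, entries in groups.items():
            for name, entry in entries.items():
                d = _DEF_BY_NAME.get(name)
                if d is None:
                    raise ValueError(f"unknown parameter {name!r} in {path}")
                if d.group != group:
                    raise ValueError(
                        f"parameter {name} listed under {group!r}, "
                        f"expected {d.group!r}")
                if isinstance(entry, Mapping):
                    if "tag" in entry and entry["tag"] != d.tag:
                        raise ValueError(
                            f"parameter {name}: tag {entry['tag']!r} does not "
                            f"match registry tag {d.tag!r}")
                    vals[name] = float(entry["value"])
                else:
                    vals[name] = float(entry)
        return cls(vals)


def default_parameters() -> ModelParameters:
    """The shipped calibrated coefficient set (free-running healthy subject)."""
    ref = importlib.resources.files("tiltsim.data") / "default_params.yaml"
    with importlib.resources.as_file(ref) as path:
        return ModelParameters.from_yaml(path)


def load_parameters(path=None) -> ModelParameters:
    """Load a parameter file, falling back to the shipped defaults."""
    if path is None:
        return default_parameters()
    return ModelParameters.from_yaml(path)
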