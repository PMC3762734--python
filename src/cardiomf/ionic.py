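"""Single-cell ionic models: the human ventricular myocyte and the passive
fibroblast.

The myocyte is the TNNP-2004 epicardial cell (twelve membrane currents, ten
voltage gates, two calcium-dependent gates, four ion pools).  The fibroblast
is an RC element: C_f dV_f/dt = -G_f (V_f - E_f) + I_in, so an uncoupled
fibroblast relaxes exponentially to its resting potential E_f with time
constant C_f/G_f.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _model
from ._model import GATE_FE, GATE_RL
from .params import (
    CURRENT_NAMES, INITIAL_STATE, N_STATE, STATE_NAMES,
    FibroblastParams, MyocyteParams,
)

__all__ = [
    "MyocyteState", "CurrentBreakdown", "MyocyteParams", "FibroblastParams",
    "myocyte_currents", "fibroblast_current", "fibroblast_relaxation",
    "resting_state", "GATE_RL", "GATE_FE",
]


class NumericalError(RuntimeError):
    """Raised when a state variable leaves its valid numeric range."""


@dataclass
class MyocyteState:
    """Full state of one ventricular myocyte.

    Gates are dimensionless in [0, 1]; concentrations in mM; V_m in mV.
    """

    V_m: float = INITIAL_STATE[0]
    m: float = INITIAL_STATE[1]
    h: float = INITIAL_STATE[2]
    j: float = INITIAL_STATE[3]
    d: float = INITIAL_STATE[4]
    f: float = INITIAL_STATE[5]
    fCa: float = INITIAL_STATE[6]
    r: float = INITIAL_STATE[7]
    s: float = INITIAL_STATE[8]
    xr1: float = INITIAL_STATE[9]
    xr2: float = INITIAL_STATE[10]
    xs: float = INITIAL_STATE[11]
    g: float = INITIAL_STATE[12]
    Na_i: float = INITIAL_STATE[13]
    K_i: float = INITIAL_STATE[14]
    Ca_i: float = INITIAL_STATE[15]
    Ca_SR: float = INITIAL_STATE[16]

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=np.float64)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "MyocyteState":
        if y.shape != (N_STATE,):
            raise ValueError(f"state vector must have shape ({N_STATE},)")
        return cls(**{n: float(v) for n, v in zip(STATE_NAMES, y)})

    def validate(self) -> None:
        """Check finiteness, gate bounds and concentration positivity."""
        for name in STATE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise NumericalError(f"state variable {name!r} is non-finite: {v}")
        for gate in ("m", "h", "j", "d", "f", "r", "s", "xr1", "xr2", "xs"):
            v = getattr(self, gate)
            if not -1e-9 <= v <= 1.0 + 1e-9:
                raise ValueError(f"gate {gate!r} out of [0, 1]: {v}")
        for conc in ("Na_i", "K_i", "Ca_i", "Ca_SR"):
            if getattr(self, conc) <= 0:
                raise ValueError(f"concentration {conc!r} must be positive")


@dataclass(frozen=True)
class CurrentBreakdown:
    """The twelve membrane current densities (pA/pF) and their sum."""

    I_Na: float
    I_CaL: float
    I_to: float
    I_Ks: float
    I_Kr: float
    I_K1: float
    I_NaCa: float
    I_NaK: float
    I_pCa: float
    I_pK: float
    I_bNa: float
    I_bCa: float

    @property
    def I_ion(self) -> float:
        return sum(getattr(self, n) for n in CURRENT_NAMES)

    def as_dict(self) -> dict:
        d = {n: getattr(self, n) for n in CURRENT_NAMES}
        d["I_ion"] = self.I_ion
        return d


def myocyte_currents(state: MyocyteState,
                     params: MyocyteParams | None = None) -> CurrentBreakdown:
    """Evaluate all twelve membrane currents for a given state.

    Pure function of the state; raises :class:`NumericalError` naming the
    offending variable if the state is non-finite.
    """
    state.validate()
    pa = (params or MyocyteParams()).pack()
    vals = _model.membrane_currents(state.to_array(), pa)
    return CurrentBreakdown(*[float(v) for v in vals])


def fibroblast_current(V_f: float, params: FibroblastParams) -> float:
    """Passive fibroblast membrane current G_f (V_f - E_f), in pA."""
    if not np.isfinite(V_f):
        raise NumericalError(f"V_f is non-finite: {V_f}")
    return params.G_f * (V_f - params.E_f)


def fibroblast_relaxation(V0: float, t: np.ndarray,
                          params: FibroblastParams) -> np.ndarray:
    """Closed-form uncoupled relaxation V_f(t) = E_f + (V0 - E_f) e^{-t/tau}."""
    return params.E_f + (V0 - params.E_f) * np.exp(-params.G_f * np.asarray(t)
                                                   / params.C_f)


_RESTING_CACHE: dict = {}


def resting_state(params: MyocyteParams | None = None, settle_ms: float = 0.0,
                  dt: float = 0.02) -> MyocyteState:
    """Quiescent myocyte state.

    With settle_ms = 0 this is the published TNNP-2004 resting state, which
    is the initial condition for all stimulation protocols.  A positive
    settle_ms integrates the unstimulated cell for that long first (the model
    drifts by a fraction of a mV over seconds); results are cached.
    """
    params = params or MyocyteParams()
    key = (params, round(settle_ms, 6), dt)
    if key not in _RESTING_CACHE:
        if settle_ms <= 0:
            st = MyocyteState.from_array(INITIAL_STATE)
        else:
            pa = params.pack()
            res = _model.run_composite_kernel(
                INITIAL_STATE.copy(), 0.0, pa, dt, int(round(settle_ms / dt)),
                np.zeros((0, 3)), 1.0, 0.0, 0.0, 0.0, GATE_RL,
                max(1, int(round(settle_ms / dt))), False)
            st = MyocyteState.from_array(res[7])
        _RESTING_CACHE[key] = st
    cached = _RESTING_CACHE[key]
    return MyocyteState(**{n: getattr(cached, n) for n in STATE_NAMES})
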