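"""Myocyte-fibroblast (MF) composites: a single myocyte coupled to N_f
identical passive fibroblasts through gap junctions.

The N_f identical fibroblasts, each joined to the myocyte by a per-junction
conductance g_j, share one membrane potential and are simulated as a single
lumped fibroblast with capacitance N_f C_f, conductance N_f G_f and aggregate
coupling G_gap = N_f g_j.  This reduction is exact (the lumped ODE divides
through to the per-fibroblast one) and is what makes the composite's response
genuinely N_f-dependent at fixed g_j.

AP morphology conventions
-------------------------
* The upstroke reference time is the instant of maximal dV/dt.
* APD levels use the "zero-baseline" convention by default: the x% level is
  the fixed voltage x/100 * V_rest taken from the (control) AP, i.e.
  repolarization is measured as the fractional return from 0 mV to rest.
  This is the convention under which the composite deltas reproduce the
  reference single-cell results; the more common amplitude convention
  V_max - x% (V_max - V_rest) is available via level_mode="amplitude".
* The resting potential of a beat is its post-AP diastolic minimum (the
  pre-upstroke value is also reported).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _model
from ._model import GATE_RL
from .ionic import MyocyteState, NumericalError
from .params import CURRENT_NAMES, FibroblastParams, MyocyteParams

__all__ = [
    "CompositeConfig", "SingleCellResult", "APMorphology", "APDelta",
    "run_single_cell", "step_composite", "measure_ap_morphology",
    "delta_vs_uncoupled", "classify_regime", "TABLE_PROTOCOL",
]

#: Single-beat protocol used throughout: one -52 pA/pF, 3 ms stimulus at t=50 ms.
TABLE_PROTOCOL = ((50.0, 3.0, -52.0),)

# Activation / upstroke detection defaults (configurable per call)
ACTIVATION_THRESHOLD = -40.0  # mV
UPSTROKE_SLOPE = 5.0  # mV/ms


@dataclass(frozen=True)
class CompositeConfig:
    """One myocyte plus N_f identical passive fibroblasts.

    g_j is the per-junction gap conductance (nS); the aggregate coupling is
    G_gap = N_f * g_j.  stimulus is a tuple of (start ms, duration ms,
    amplitude pA/pF) events.
    """

    N_f: int = 1
    g_j: float = 8.0
    fib: FibroblastParams = field(default_factory=FibroblastParams)
    stimulus: tuple = TABLE_PROTOCOL
    myo: MyocyteParams = field(default_factory=MyocyteParams)

    def __post_init__(self):
        if self.N_f < 0:
            raise ValueError(f"N_f must be >= 0, got {self.N_f}")
        if self.g_j < 0:
            raise ValueError(f"g_j must be >= 0, got {self.g_j}")

    @property
    def G_gap(self) -> float:
        """Aggregate myocyte-side gap conductance N_f * g_j, nS."""
        return self.N_f * self.g_j

    def lumped_fibroblast(self) -> FibroblastParams:
        """Exact single-fibroblast equivalent of the N_f identical ones."""
        n = max(self.N_f, 1)
        return FibroblastParams(C_f=n * self.fib.C_f, G_f=n * self.fib.G_f,
                                E_f=self.fib.E_f)

    def uncoupled(self) -> "CompositeConfig":
        return replace(self, N_f=0)


@dataclass
class SingleCellResult:
    """Uniformly sampled traces from a composite run."""

    t: np.ndarray          # ms
    V_m: np.ndarray        # mV
    V_f: np.ndarray        # mV
    I_gap: np.ndarray      # pA, positive = out of the myocyte
    currents: np.ndarray | None  # (n, 12) pA/pF, CURRENT_NAMES order, or None
    config: CompositeConfig
    dt: float

    def current(self, name: str) -> np.ndarray:
        if self.currents is None:
            raise ValueError("currents were not recorded")
        return self.currents[:, CURRENT_NAMES.index(name)]

    def to_frame(self):
        import pandas as pd
        data = {"t": self.t, "V_m": self.V_m, "V_f": self.V_f,
                "I_gap": self.I_gap}
        if self.currents is not None:
            for k, n in enumerate(CURRENT_NAMES):
                data[n] = self.currents[:, k]
        return pd.DataFrame(data)


def run_single_cell(cfg: CompositeConfig, t_end: float = 1500.0,
                    dt: float = 0.02, record_every: int = 1,
                    record_currents: bool = False,
                    y0: np.ndarray | None = None,
                    V_f0: float | None = None,
                    gate_mode: int = GATE_RL) -> SingleCellResult:
    """Integrate the composite for t_end ms from the resting initial state.

    The myocyte starts from the published resting initial conditions (or y0);
    the fibroblast starts at its resting potential E_f (or V_f0).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    pa = cfg.myo.pack()
    lf = cfg.lumped_fibroblast()
    ggap = cfg.G_gap
    stim = np.array(cfg.stimulus, dtype=np.float64).reshape(-1, 3)
    y0 = INITIAL_STATE_OF(cfg.myo) if y0 is None else np.asarray(y0, float)
    vf0 = cfg.fib.E_f if V_f0 is None else float(V_f0)
    n_steps = int(round(t_end / dt))
    (status, t_fail, t, vm, vf, ig, cur, _y, _vf) = _model.run_composite_kernel(
        y0.copy(), vf0, pa, dt, n_steps, stim, lf.C_f, lf.G_f, lf.E_f,
        ggap, gate_mode, record_every, record_currents)
    if status != 0:
        raise NumericalError(
            f"unstable integration (|V_m| > 200 mV) at t = {t_fail:.2f} ms")
    return SingleCellResult(t=t, V_m=vm, V_f=vf, I_gap=ig,
                            currents=cur if record_currents else None,
                            config=cfg, dt=dt * record_every)


def step_composite(m: MyocyteState, V_f: float, cfg: CompositeConfig,
                   dt: float, i_stim: float = 0.0):
    """Advance the composite by one step; returns (state, V_f, I_gap in pA).

    The gap current I_gap = G_gap (V_m - V_f) leaves the myocyte and enters
    the lumped fibroblast with the opposite sign, conserving charge at the
    junction; the myocyte-side contribution is converted to a current density
    through the myocyte capacitance C_m.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    pa = cfg.myo.pack()
    lf = cfg.lumped_fibroblast()
    y = m.to_array()
    if not np.all(np.isfinite(y)) or not np.isfinite(V_f):
        raise NumericalError("non-finite state passed to step_composite")
    igap = cfg.G_gap * (y[0] - V_f)
    _model.step_cell(y, dt, i_stim, igap / cfg.myo.C_m, pa, GATE_RL)
    vf_new = V_f + dt * (-(lf.G_f * (V_f - lf.E_f)) + igap) / lf.C_f
    return MyocyteState.from_array(y), vf_new, igap


def INITIAL_STATE_OF(myo: MyocyteParams) -> np.ndarray:
    from .params import INITIAL_STATE
    return INITIAL_STATE.copy()


@dataclass
class APMorphology:
    """Morphological features of one action potential (nan = undefined)."""

    APD70: float
    APD80: float
    APD90: float
    V_rest: float       # post-AP diastolic minimum
    V_rest_pre: float   # value just before the upstroke
    dVdt_max: float     # mV/ms
    V_max: float        # mV
    V_notch: float      # mV
    V_plateau: float    # mV
    regime: str         # excitable | autorhythmic | oscillatory
    t_upstroke: float   # ms, time of max dV/dt (nan if no AP)
    levels: dict        # the absolute voltage level used per percentage


def _cross_down(t, v, i0, level):
    """First downward crossing time of `level` after index i0 (interpolated)."""
    seg = v[i0:]
    below = np.nonzero(seg < level)[0]
    if len(below) == 0 or below[0] == 0:
        return math.nan
    k = i0 + below[0]
    # linear interpolation between samples k-1 and k
    f = (v[k - 1] - level) / (v[k - 1] - v[k])
    return t[k - 1] + f * (t[k] - t[k - 1])


def measure_ap_morphology(t: np.ndarray, V: np.ndarray,
                          percentages=(70, 80, 90),
                          level_voltages: dict | None = None,
                          level_mode: str = "zero_baseline",
                          search_from: float = 0.0) -> APMorphology:
    """Measure AP morphology on a V_m(t) trace containing one (or no) AP.

    level_voltages, if given, fixes the absolute APD level per percentage
    (used to share the control AP's levels when measuring a coupled beat).
    search_from restricts the upstroke search to t >= search_from (to skip
    spontaneous pre-stimulus activity).
    """
    t = np.asarray(t, float)
    V = np.asarray(V, float)
    if t.shape != V.shape or t.size < 3:
        raise ValueError("t and V must be equal-length 1D arrays, n >= 3")
    dt = t[1] - t[0]
    dVdt = np.diff(V) / dt
    j0 = int(np.searchsorted(t, search_from))
    if search_from > 0:
        # pin the measurement to the stimulated upstroke: max slope within
        # 20 ms of the stimulus onset
        j1 = min(j0 + max(int(round(20.0 / dt)), 2), dVdt.size)
    else:
        j1 = dVdt.size
    iup = j0 + int(np.argmax(dVdt[j0:j1]))
    dvdt_max = float(dVdt[iup])
    nan = math.nan

    if dvdt_max < UPSTROKE_SLOPE:  # no action potential: flat (or drifting) trace
        return APMorphology(nan, nan, nan, float(V.min()), float(V[0]),
                            dvdt_max, float(V.max()), nan, nan,
                            "excitable", nan, {})

    # AP onset: walk back from the upstroke until the trace is quiet
    k = iup
    while k > j0 and dVdt[k - 1] > 1.0:
        k -= 1
    v_rest_pre = float(V[k])
    # peak: within 10 ms of the upstroke (later spontaneous APs excluded)
    ipk = min(iup + max(int(round(10.0 / dt)), 2), V.size)
    imax = iup + int(np.argmax(V[iup:ipk]))
    v_max = float(V[imax])

    if level_voltages is None:
        if level_mode == "zero_baseline":
            level_voltages = {p: p / 100.0 * v_rest_pre for p in percentages}
        elif level_mode == "amplitude":
            level_voltages = {p: v_max - p / 100.0 * (v_max - v_rest_pre)
                              for p in percentages}
        else:
            raise ValueError(f"unknown level_mode {level_mode!r}")

    apds = {}
    for p in percentages:
        tc = _cross_down(t, V, imax, level_voltages[p])
        apds[p] = tc - t[iup] if not math.isnan(tc) else nan

    # notch: first local minimum after the peak; plateau: max after the notch
    v_notch = nan
    v_plateau = nan
    seg = V[imax:]
    mins = np.nonzero((seg[1:-1] <= seg[:-2]) & (seg[1:-1] <= seg[2:]))[0]
    if len(mins) > 0:
        inotch = imax + 1 + int(mins[0])
        # only a genuine notch if it sits above the resting range
        if V[inotch] > v_rest_pre + 10.0:
            v_notch = float(V[inotch])
            v_plateau = float(V[inotch:].max())

    # diastolic minimum after the AP, bounded by the next upstroke (if any);
    # taken from late diastole so the brief post-repolarization undershoot
    # does not bias the resting value
    k = min(imax + int(round(50.0 / dt)), V.size - 1)
    nxt = np.nonzero((V[k:-1] < ACTIVATION_THRESHOLD)
                     & (V[k + 1:] >= ACTIVATION_THRESHOLD)
                     & (np.diff(V[k:]) / dt > UPSTROKE_SLOPE))[0]
    kend = k + int(nxt[0]) if len(nxt) else V.size
    k0 = imax + int(round(550.0 / dt))
    if k0 >= kend:  # short diastole: use its last quarter
        k0 = imax + 3 * (kend - imax) // 4
    v_rest = float(V[k0:kend].min()) if kend > k0 else float(V[min(kend, V.size) - 1])

    regime = classify_regime(t, V, stimulated_at=t[iup])
    apd70, apd80, apd90 = (apds.get(p, nan) for p in (70, 80, 90))
    return APMorphology(apd70, apd80, apd90, v_rest, v_rest_pre, dvdt_max,
                        v_max, v_notch, v_plateau, regime, float(t[iup]),
                        dict(level_voltages))


def classify_regime(t: np.ndarray, V: np.ndarray,
                    stimulated_at: float | None = None,
                    upstroke_count: int = 2,
                    osc_peak_to_peak: float = 2.0,
                    min_slope: float = 0.5) -> str:
    """Classify a trace as excitable, autorhythmic or oscillatory.

    autorhythmic: >= `upstroke_count` spontaneous upstrokes (crossing
    -40 mV with dV/dt > `min_slope`) outside a +-20 ms window around
    `stimulated_at`; oscillatory: sustained sub-threshold oscillations with
    peak-to-peak > `osc_peak_to_peak` mV in the last half of the trace.
    Spontaneous upstrokes of a depolarized composite are slow (calcium-
    driven, ~1 mV/ms at threshold), hence the permissive default slope.
    """
    t = np.asarray(t, float)
    V = np.asarray(V, float)
    dt = t[1] - t[0]
    dVdt = np.diff(V) / dt
    crossings = np.nonzero((V[:-1] < ACTIVATION_THRESHOLD)
                           & (V[1:] >= ACTIVATION_THRESHOLD)
                           & (dVdt > min_slope))[0]
    tc = t[crossings]
    if stimulated_at is not None:
        tc = tc[np.abs(tc - stimulated_at) > 20.0]
    if len(tc) >= upstroke_count:
        return "autorhythmic"
    half = V[V.size // 2:]
    if len(tc) == 0 and half.max() - half.min() > osc_peak_to_peak \
            and half.max() < ACTIVATION_THRESHOLD:
        return "oscillatory"
    return "excitable"


@dataclass
class APDelta:
    """Coupled-minus-uncoupled changes in AP morphology (nan = undefined)."""

    dAPD70: float
    dAPD80: float
    dAPD90: float
    dVdt_max: float
    dV_rest: float
    coupled: APMorphology
    uncoupled: APMorphology
    autorhythmic: bool  # True if the composite fires without stimulus


def delta_vs_uncoupled(cfg: CompositeConfig, t_end: float = 2000.0,
                       dt: float = 0.02) -> APDelta:
    """Paired coupled / uncoupled single-beat runs and their differences.

    Both runs use the same stimulus protocol; APD levels are the control
    (uncoupled) AP's absolute levels, shared by both traces.  A composite
    that fires spontaneously is flagged autorhythmic (its stimulated-beat
    delta is still reported when measurable, but is of limited meaning).
    """
    stim_t = cfg.stimulus[0][0] if cfg.stimulus else 0.0
    res_u = run_single_cell(cfg.uncoupled(), t_end=t_end, dt=dt)
    res_c = run_single_cell(cfg, t_end=t_end, dt=dt)
    mu = measure_ap_morphology(res_u.t, res_u.V_m, search_from=stim_t)
    mc = measure_ap_morphology(res_c.t, res_c.V_m, search_from=stim_t,
                               level_voltages=mu.levels)
    auto = classify_regime(res_c.t, res_c.V_m, stimulated_at=mc.t_upstroke) \
        == "autorhythmic"
    if auto:
        warnings.warn("composite is autorhythmic; stimulated-beat deltas "
                      "are ill-defined", stacklevel=2)
    return APDelta(
        dAPD70=mc.APD70 - mu.APD70,
        dAPD80=mc.APD80 - mu.APD80,
        dAPD90=mc.APD90 - mu.APD90,
        dVdt_max=mc.dVdt_max - mu.dVdt_max,
        dV_rest=mc.V_rest - mu.V_rest,
        coupled=mc, uncoupled=mu, autorhythmic=auto)
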