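"""2D myocyte-fibroblast bilayer tissue.

A square lattice of myocytes (monodomain, diffusion coefficient D) with a
registered fibroblast layer on top.  Couplings follow the three wiring
categories:

* ``zero_sided``  - fibroblasts attach to their local myocyte only
  (G_ff = G_mf = G_fm = 0);
* ``one_sided``   - the fibroblast layer is internally connected (G_ff > 0);
* ``two_sided``   - in addition, each myocyte exchanges current with the four
  nearest fibroblast nodes (pairwise conductance G_mf = G_fm, required equal
  so every junction current appears with opposite signs on its two ends).

Geometry: arrays are indexed [i, j] with x = j*dx, y = i*dx (mm).  Boundaries
are no-flux (mirrored ghost nodes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _model, _tissue
from .ionic import NumericalError
from .params import INITIAL_STATE, FibroblastParams, MyocyteParams

__all__ = [
    "CouplingConfig", "BilayerGrid", "StimulusEvent", "InhomogeneitySpec",
    "TissueResult", "laplacian_noflux", "run_tissue", "step_tissue",
    "set_patch", "stability_limit",
]

#: map kernel field rows to the single-cell state-vector indices
_FIELD_TO_STATE = (1, 2, 3, 4, 5, 7, 8, 9, 10, 11, 6, 12, 13, 14, 15, 16)

_MODES = ("zero_sided", "one_sided", "two_sided")


@dataclass(frozen=True)
class CouplingConfig:
    """Inter- and cross-layer conductances of the bilayer."""

    mode: str = "zero_sided"
    D: float = 0.00154        # myocyte-layer diffusion coefficient, cm^2/ms
    G_gap: float = 0.0        # on-site myocyte-fibroblast conductance, nS
    G_ff: float = 0.0         # fibroblast intra-layer conductance, nS
    G_mf: float = 0.0         # myocyte -> neighbor-fibroblast conductance, nS
    G_fm: float = 0.0         # fibroblast -> neighbor-myocyte conductance, nS
    fib: FibroblastParams = field(default_factory=FibroblastParams)

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if min(self.D, self.G_gap, self.G_ff, self.G_mf, self.G_fm) < 0:
            raise ValueError("conductances and D must be non-negative")
        if self.mode == "zero_sided" and (self.G_ff or self.G_mf or self.G_fm):
            raise ValueError("zero_sided requires G_ff = G_mf = G_fm = 0")
        if self.mode == "one_sided" and (self.G_mf or self.G_fm):
            raise ValueError("one_sided requires G_mf = G_fm = 0")
        if self.mode == "two_sided":
            if (self.G_mf > 0) != (self.G_fm > 0):
                raise ValueError("two_sided cross couplings must be both zero "
                                 "or both positive (current conservation)")
            if not math.isclose(self.G_mf, self.G_fm):
                raise ValueError(
                    "G_mf and G_fm parameterize the same physical junctions; "
                    "they must be equal for the pairwise currents to cancel")

    @property
    def mode_int(self) -> int:
        return _MODES.index(self.mode)


@dataclass
class StimulusEvent:
    """Current injection (pA/pF) on a node set during [start, start+duration)."""

    start: float
    duration: float
    amplitude: float
    support: np.ndarray  # boolean mask (ny, nx)

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        self.support = np.ascontiguousarray(self.support, dtype=np.uint8)

    @classmethod
    def rectangle(cls, shape, start, duration, amplitude,
                  rows=slice(None), cols=slice(None)) -> "StimulusEvent":
        m = np.zeros(shape, dtype=np.uint8)
        m[rows, cols] = 1
        return cls(start, duration, amplitude, m)


class BilayerGrid:
    """Paired myocyte / fibroblast fields on an (ny, nx) lattice."""

    def __init__(self, ny: int, nx: int, dx: float = 0.225,
                 myo: MyocyteParams | None = None,
                 fib: FibroblastParams | None = None,
                 fib_mask: np.ndarray | None = None,
                 G_gap: float | np.ndarray = 0.0):
        if ny < 3 or nx < 3:
            raise ValueError("grid must be at least 3x3")
        self.ny, self.nx, self.dx = ny, nx, float(dx)
        self.myo = myo or MyocyteParams()
        self.fib = fib or FibroblastParams()
        y0 = INITIAL_STATE
        self.Vm = np.full((ny, nx), y0[0])
        self.G = np.empty((16, ny, nx))
        for row, si in enumerate(_FIELD_TO_STATE):
            self.G[row] = y0[si]
        self.Vf = np.full((ny, nx), self.fib.E_f)
        if fib_mask is None:
            fib_mask = np.ones((ny, nx), dtype=np.uint8)
        self.fib_mask = np.ascontiguousarray(fib_mask, dtype=np.uint8)
        self.ggap = np.ascontiguousarray(
            np.broadcast_to(np.asarray(G_gap, float), (ny, nx)).copy())
        self.t = 0.0

    def copy(self) -> "BilayerGrid":
        g = BilayerGrid.__new__(BilayerGrid)
        g.ny, g.nx, g.dx = self.ny, self.nx, self.dx
        g.myo, g.fib = self.myo, self.fib
        g.Vm = self.Vm.copy()
        g.G = self.G.copy()
        g.Vf = self.Vf.copy()
        g.fib_mask = self.fib_mask.copy()
        g.ggap = self.ggap.copy()
        g.t = self.t
        return g

    def set_state(self, y: np.ndarray) -> None:
        """Set every myocyte node to the single-cell state vector y (17,)."""
        self.Vm[:] = y[0]
        for row, si in enumerate(_FIELD_TO_STATE):
            self.G[row] = y[si]

    def node_state(self, i: int, j: int) -> np.ndarray:
        """Full 17-component state vector of node (i, j)."""
        y = np.empty(17)
        y[0] = self.Vm[i, j]
        for row, si in enumerate(_FIELD_TO_STATE):
            y[si] = self.G[row, i, j]
        return y

    def sodium_current(self) -> np.ndarray:
        """I_Na field (pA/pF) computed from the current state."""
        from .params import P_GNA, P_NAO, P_RTONF
        pa = self.myo.pack()
        Ena = pa[P_RTONF] * np.log(pa[P_NAO] / self.G[_tissue.TG_NAI])
        return pa[P_GNA] * self.G[_tissue.TG_M] ** 3 * self.G[_tissue.TG_H] \
            * self.G[_tissue.TG_J] * (self.Vm - Ena)


@dataclass(frozen=True)
class InhomogeneitySpec:
    """Square MF-composite patch in an otherwise myocyte-only sheet.

    corner is the lower-left corner (x_mm, y_mm); nodes are assigned by
    rounding corner/dx and side/dx to the nearest integer.
    """

    corner: tuple = (56.25, 56.25)
    side: float = 33.75
    G_gap: float = 8.0
    fib: FibroblastParams = field(default_factory=FibroblastParams)

    def node_box(self, dx: float):
        j0 = int(round(self.corner[0] / dx))
        i0 = int(round(self.corner[1] / dx))
        n = int(round(self.side / dx))
        return i0, j0, n


def set_patch(grid: BilayerGrid, spec: InhomogeneitySpec) -> BilayerGrid:
    """Turn the grid into a myocyte-only sheet with one MF-composite patch."""
    i0, j0, n = spec.node_box(grid.dx)
    if n == 0:
        return grid
    if i0 < 0 or j0 < 0 or i0 + n > grid.ny or j0 + n > grid.nx:
        raise ValueError(f"patch [{i0}:{i0 + n}, {j0}:{j0 + n}] exceeds the "
                         f"{grid.ny}x{grid.nx} domain")
    grid.fib_mask[:] = 0
    grid.fib_mask[i0:i0 + n, j0:j0 + n] = 1
    grid.ggap[:] = 0.0
    grid.ggap[i0:i0 + n, j0:j0 + n] = spec.G_gap
    grid.fib = spec.fib
    grid.Vf[:] = spec.fib.E_f
    return grid


def laplacian_noflux(field: np.ndarray, dx: float) -> np.ndarray:
    """Five-point Laplacian with edge-replicated (zero-flux) ghost nodes."""
    f = np.asarray(field, float)
    if f.ndim != 2 or min(f.shape) < 3:
        raise ValueError("field must be 2D with both dimensions >= 3")
    p = np.pad(f, 1, mode="edge")
    return (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:]
            - 4.0 * f) / dx ** 2


def stability_limit(D: float, dx: float) -> float:
    """Explicit-Euler diffusion stability bound dt <= dx^2 / (4 D), ms."""
    D_mm = D * 100.0  # cm^2/ms -> mm^2/ms
    return math.inf if D_mm == 0 else dx ** 2 / (4.0 * D_mm)


@dataclass
class TissueResult:
    t_probe: np.ndarray | None
    probes: np.ndarray | None      # (n_rec, n_probe) V_m traces
    t_snap: np.ndarray
    snap_Vm: np.ndarray            # float32 (n_snap, ny, nx)
    snap_Vf: np.ndarray | None
    snap_INa: np.ndarray | None


def run_tissue(grid: BilayerGrid, coupling: CouplingConfig,
               stimuli=(), t_end: float = 100.0, dt: float = 0.02,
               probes=(), probe_every: int = 25,
               snap_every_ms: float = 0.0, snap_t0: float = 0.0,
               snap_fields=("V_m",), gate_mode: int = 0) -> TissueResult:
    """Advance the bilayer to grid.t + t_end (the grid is updated in place).

    probes: sequence of (i, j) nodes whose V_m is recorded every
    probe_every steps.  snap_every_ms > 0 stores float32 field snapshots
    (channels from snap_fields, subset of {"V_m", "V_f", "I_Na"}) starting
    at absolute time snap_t0.
    """
    lim = stability_limit(coupling.D, grid.dx)
    if dt > lim:
        raise ValueError(f"dt = {dt} ms violates the diffusion stability "
                         f"bound {lim:.4f} ms for D = {coupling.D} cm^2/ms, "
                         f"dx = {grid.dx} mm")
    pa = grid.myo.pack()
    tab = _tissue.build_tables(pa, dt)
    n_steps = int(round(t_end / dt))
    step_offset = int(round(grid.t / dt))

    stim_start = np.array([s.start for s in stimuli], float)
    stim_dur = np.array([s.duration for s in stimuli], float)
    stim_amp = np.array([s.amplitude for s in stimuli], float)
    if stimuli:
        stim_mask = np.stack([s.support for s in stimuli]).astype(np.uint8)
    else:
        stim_mask = np.zeros((0, grid.ny, grid.nx), np.uint8)

    probe_i = np.array([p[0] for p in probes], np.int64)
    probe_j = np.array([p[1] for p in probes], np.int64)
    if len(probes):
        first = (step_offset + probe_every - 1) // probe_every
        last = (step_offset + n_steps - 1) // probe_every
        n_rec_total = last + 1
        probe_buf = np.full((n_rec_total, len(probes)), np.nan)
    else:
        probe_buf = np.zeros((0, 0))
        probe_every = 0

    if snap_every_ms > 0:
        every = max(1, int(round(snap_every_ms / dt)))
        k0 = max(step_offset, int(round(snap_t0 / dt)))
        k0 = ((k0 + every - 1) // every) * every
        snap_steps = np.arange(k0, step_offset + n_steps, every, dtype=np.int64)
    else:
        snap_steps = np.zeros(0, np.int64)
    nsnap = len(snap_steps)
    shp = (grid.ny, grid.nx)
    snap_vm = np.zeros((nsnap, *shp), np.float32)
    snap_vf = np.zeros((nsnap if "V_f" in snap_fields else 0, *shp), np.float32)
    snap_ina = np.zeros((nsnap if "I_Na" in snap_fields else 0, *shp),
                        np.float32)

    Vmn = grid.Vm.copy()
    Vfn = grid.Vf.copy()
    lf = coupling.fib
    status, parity, t_fail, i_f, j_f = _tissue.step_tissue_kernel(
        grid.Vm, Vmn, grid.Vf, Vfn, grid.G, grid.fib_mask, grid.ggap, tab, pa,
        dt, n_steps, step_offset, coupling.D * 100.0 / grid.dx ** 2,
        lf.C_f, lf.G_f, lf.E_f, coupling.G_ff, coupling.G_mf,
        coupling.mode_int, gate_mode,
        stim_start, stim_dur, stim_amp, stim_mask,
        probe_i, probe_j, probe_buf, probe_every,
        snap_steps, snap_vm, snap_vf, snap_ina)
    if parity == 1:
        grid.Vm, grid.Vf = Vmn, Vfn
    if status != 0:
        raise NumericalError(
            f"unstable tissue integration at t = {t_fail:.2f} ms, "
            f"node (i={i_f}, j={j_f})")
    grid.t += n_steps * dt

    if len(probes):
        keep = ~np.isnan(probe_buf[:, 0])
        t_probe = np.nonzero(keep)[0] * probe_every * dt
        probes_out = probe_buf[keep]
    else:
        t_probe, probes_out = None, None
    return TissueResult(t_probe, probes_out, snap_steps * dt, snap_vm,
                        snap_vf if snap_vf.shape[0] else None,
                        snap_ina if snap_ina.shape[0] else None)


def step_tissue(grid: BilayerGrid, coupling: CouplingConfig, stimuli=(),
                dt: float = 0.02, n_steps: int = 1) -> BilayerGrid:
    """Advance the grid by n_steps time steps (thin wrapper of run_tissue)."""
    run_tissue(grid, coupling, stimuli, t_end=n_steps * dt, dt=dt)
    return grid
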