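"""Experiment drivers: plane-wave conduction, S1-S2 parallel-field spiral
initiation, inhomogeneity studies and low-amplitude mesh-based control.

Sign convention: stimulus amplitudes are current densities added to the
membrane balance; depolarizing pulses are negative (a -52 pA/pF, 3 ms pulse
is the single-cell standard).  Protocol constructors accept the magnitudes
quoted for the experiments (150, 450, 30 pA/pF) and apply the sign.

Scaled-down configurations: the full 600x600 (135 mm) experiments exceed a
desk budget, so the spiral and control protocols provide `scaled(n)`
variants on an n x n lattice with the diffusion coefficient reduced to a
quarter.  Halving the diffusion length halves the spiral wavelength, so the
45 mm domain holds a rotor the way the full domain holds the full-scale one,
while the depolarization front (~2 nodes) stays resolved on the unchanged
lattice.  S2 timing is set adaptively from the position of the S1 wave back
rather than by fixed coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .analysis import CVResult, measure_cv_probes, sodium_threshold, track_tip
from .composite import ACTIVATION_THRESHOLD
from .ionic import NumericalError
from .params import FibroblastParams, MyocyteParams
from .tissue import (BilayerGrid, CouplingConfig, InhomogeneitySpec,
                     StimulusEvent, run_tissue, set_patch)

__all__ = [
    "PlaneWaveResult", "run_plane_wave", "SpiralInitProtocol",
    "initiate_spiral", "ControlMesh", "ControlOutcome", "run_control",
    "mesh_mask", "CONTROL_CV",
]

#: control-case plane-wave conduction velocity magnitude, cm/s (myocytes
#: only, D = 0.00154 cm^2/ms): used for conduction-failure time budgets.
CONTROL_CV = 68.3


def two_sided_failure_coupling() -> "CouplingConfig":
    """A two-sided coupling in the conduction-failure regime.

    One- and two-sided wiring presumes fibroblast *clusters* of a size
    comparable to a myocyte, so the per-node fibroblast parameters are the
    cluster aggregates (here ~120 small fibroblasts: C_f = 756 pF,
    G_f = 240 nS) with a near-rest reversal (E_f = -80 mV, so the cluster
    loads the front without tonically depolarizing the sheet) and strong
    cross-layer conductance.  At low and intermediate on-site couplings
    (G_gap = 0.5 or 2 nS) a plane wave fails to conduct through this
    substrate.
    """
    return CouplingConfig(mode="two_sided", G_ff=20.0, G_mf=150.0,
                          G_fm=150.0,
                          fib=FibroblastParams(C_f=756.0, G_f=240.0,
                                               E_f=-80.0))


# ---------------------------------------------------------------- plane wave

@dataclass
class PlaneWaveResult:
    cv: CVResult
    failed: bool
    t_probe: np.ndarray
    probes: np.ndarray


def run_plane_wave(coupling: CouplingConfig, G_gap: float = 0.0,
                   ny: int = 7, nx: int = 600, dx: float = 0.225,
                   dt: float = 0.02, stim_amplitude: float = 150.0,
                   stim_duration: float = 3.0, stim_width: int = 3,
                   with_fibroblasts: bool = True,
                   t_budget: float | None = None) -> PlaneWaveResult:
    """Plane-wave CV on a homogeneous strip; left-boundary stimulus.

    Conduction failure is declared when the far probe (75% of the length)
    is never depolarized above the activation threshold within the time
    budget 2 L / CV_control.
    """
    mask = np.ones((ny, nx), np.uint8) if with_fibroblasts \
        else np.zeros((ny, nx), np.uint8)
    grid = BilayerGrid(ny, nx, dx=dx, fib=coupling.fib, fib_mask=mask,
                       G_gap=G_gap)
    stim = StimulusEvent.rectangle((ny, nx), 0.0, stim_duration,
                                   -abs(stim_amplitude),
                                   cols=slice(0, stim_width))
    if t_budget is None:
        t_budget = 2.0 * nx * dx / (CONTROL_CV / 100.0)
    j1, j2 = int(0.25 * nx), int(0.75 * nx)
    res = run_tissue(grid, coupling, [stim], t_end=t_budget, dt=dt,
                     probes=[(ny // 2, j1), (ny // 2, j2)], probe_every=5)
    cv = measure_cv_probes(res.t_probe, res.probes[:, 0], res.probes[:, 1],
                           (j2 - j1) * dx)
    return PlaneWaveResult(cv, cv.failed, res.t_probe, res.probes)


# ------------------------------------------------------------------- spiral

@dataclass(frozen=True)
class SpiralInitProtocol:
    """S1-S2 parallel-field spiral initiation on a myocyte-only domain.

    Full-scale defaults: 600x600 nodes, S1 150 pA/pF for 3 ms at the left
    boundary at t = 0, S2 450 pA/pF for 3 ms at t = 560 ms just behind the
    S1 refractory tail, diffusion reduced to a quarter of 0.00154 cm^2/ms
    during initiation and restored at 882 ms.  The S2 support is the lower
    half-height of the domain, extending from the left edge to `s2_margin`
    nodes behind the -40 mV wave-back isoline at S2 time.
    """

    n: int = 600
    dx: float = 0.225
    D: float = 0.00154          # cm^2/ms during the run proper
    d_init_factor: float = 0.25  # D multiplier during initiation
    restore_time: float | None = 882.0
    s1_amplitude: float = 150.0
    s1_duration: float = 3.0
    s1_width: int = 3
    s2_amplitude: float = 450.0
    s2_duration: float = 3.0
    s2_time: float = 560.0
    s2_margin: int = 2
    t_init: float = 1500.0      # protocol end; the spiral is fully developed

    @classmethod
    def scaled(cls, n: int = 200) -> "SpiralInitProtocol":
        """Desk-scale variant: n x n domain, D/4 throughout (no further
        reduction during initiation).  S2 is timed so the S1 wave back
        (which enters the domain after one APD, ~270 ms, and travels at
        ~0.34 mm/ms) sits near mid-domain: t_S2 = 270 + 0.35 n ms."""
        s2 = 270.0 + 0.35 * n
        return cls(n=n, D=0.00154 / 4.0, d_init_factor=1.0,
                   restore_time=None, s2_time=s2, t_init=s2 + 760.0)


def _waveback_column(grid: BilayerGrid, row: int,
                     threshold: float = ACTIVATION_THRESHOLD) -> int:
    """Leftmost column of the depolarized band on `row` (the wave back)."""
    above = np.nonzero(grid.Vm[row] >= threshold)[0]
    if len(above) == 0:
        return -1
    return int(above[0])


def initiate_spiral(protocol: SpiralInitProtocol,
                    myo: MyocyteParams | None = None,
                    dt: float = 0.02, verify: bool = True):
    """Run the S1-S2 protocol; returns (grid, tip_count_at_t_init).

    The grid is myocyte-only (fibroblasts are attached afterwards by the
    caller, with V_f initialized to E_f).  If the S2 lands outside the
    vulnerable window no reentry forms; with verify=True the sodium-current
    tip count at t_init is returned (0 = no spiral).
    """
    n = protocol.n
    grid = BilayerGrid(n, n, dx=protocol.dx,
                       myo=myo or MyocyteParams(),
                       fib_mask=np.zeros((n, n), np.uint8))
    d_init = protocol.D * protocol.d_init_factor
    coup_init = CouplingConfig(mode="zero_sided", D=d_init)
    s1 = StimulusEvent.rectangle((n, n), 0.0, protocol.s1_duration,
                                 -abs(protocol.s1_amplitude),
                                 cols=slice(0, protocol.s1_width))
    run_tissue(grid, coup_init, [s1], t_end=protocol.s2_time, dt=dt)

    j_back = _waveback_column(grid, row=n // 4)
    if j_back < 0:
        raise NumericalError("S1 wave not found at S2 time; no wave back to "
                             "place the S2 stimulus behind")
    j_edge = max(j_back - protocol.s2_margin, 1)
    s2 = StimulusEvent.rectangle((n, n), protocol.s2_time,
                                 protocol.s2_duration,
                                 -abs(protocol.s2_amplitude),
                                 rows=slice(0, n // 2), cols=slice(0, j_edge))
    t_restore = protocol.restore_time
    if t_restore is None or t_restore <= protocol.s2_time:
        t_restore = protocol.s2_time + protocol.s2_duration + 1.0
    run_tissue(grid, coup_init, [s2], t_end=t_restore - grid.t, dt=dt)

    coup_run = CouplingConfig(mode="zero_sided", D=protocol.D)
    run_tissue(grid, coup_run, [], t_end=protocol.t_init - grid.t, dt=dt)

    tips = -1
    if verify:
        # track over a short continuation (on a copy; the I_Na channel is
        # the peak field swept since the previous frame)
        probe = grid.copy()
        res = run_tissue(probe, coup_run, [], t_end=24.0, dt=dt,
                         snap_every_ms=8.0, snap_t0=probe.t,
                         snap_fields=("I_Na",))
        traj = track_tip(res.t_snap, res.snap_INa, grid.dx, myo=grid.myo)
        tips = int(np.median(traj.counts))
    return grid, tips


def attach_fibroblasts(grid: BilayerGrid, fib: FibroblastParams,
                       G_gap: float) -> BilayerGrid:
    """Attach a homogeneous fibroblast layer to an existing (spiral) state,
    with V_f initialized to the fibroblast resting potential."""
    grid.fib = fib
    grid.fib_mask[:] = 1
    grid.ggap[:] = G_gap
    grid.Vf[:] = fib.E_f
    return grid


# ------------------------------------------------------------------ control

@dataclass(frozen=True)
class ControlMesh:
    """Low-amplitude control pulse applied on a square mesh of grid lines."""

    blocks: int = 4             # mesh divides the domain into blocks^2 cells
    amplitude: float = 30.0     # pA/pF (applied depolarizing)
    duration: float = 400.0     # ms
    onset: float = 0.0          # ms after the start of the control run


def mesh_mask(ny: int, nx: int, blocks: int) -> np.ndarray:
    """One-node-wide grid lines dividing the domain into blocks x blocks cells."""
    if blocks < 1:
        raise ValueError("blocks must be >= 1")
    m = np.zeros((ny, nx), np.uint8)
    for k in range(blocks + 1):
        i = int(round(k * (ny - 1) / blocks))
        j = int(round(k * (nx - 1) / blocks))
        m[i, :] = 1
        m[:, j] = 1
    return m


@dataclass
class ControlOutcome:
    terminated: bool
    t_quiet: float              # ms (absolute); nan if never quiet
    max_v_final: float


def run_control(grid: BilayerGrid, mesh: ControlMesh,
                coupling: CouplingConfig, dt: float = 0.02,
                quiet_margin: float = 200.0,
                check_every: float = 20.0) -> ControlOutcome:
    """Apply the mesh pulse to a grid holding a spiral; classify the outcome.

    Termination: at some time every myocyte node is below the activation
    threshold and no re-excitation occurs for `quiet_margin` ms after the
    pulse.  The grid is advanced in place to onset + duration + quiet_margin.
    """
    t0 = grid.t
    stimuli = []
    if mesh.amplitude != 0.0:
        stimuli.append(StimulusEvent(t0 + mesh.onset, mesh.duration,
                                     -abs(mesh.amplitude),
                                     mesh_mask(grid.ny, grid.nx, mesh.blocks)))
    t_end = mesh.onset + mesh.duration + quiet_margin
    t_quiet = math.nan
    n_chunks = int(math.ceil(t_end / check_every))
    for c in range(n_chunks):
        t_run = min(check_every, t_end - c * check_every)
        if t_run <= 0:
            break
        run_tissue(grid, coupling, stimuli, t_end=t_run, dt=dt)
        vmax = float(grid.Vm.max())
        if vmax < ACTIVATION_THRESHOLD:
            if math.isnan(t_quiet):
                t_quiet = grid.t
        else:
            t_quiet = math.nan
    terminated = (not math.isnan(t_quiet))
    return ControlOutcome(terminated, t_quiet, float(grid.Vm.max()))


# ------------------------------------------------------------ inhomogeneity

def run_inhomogeneity(spiral_grid: BilayerGrid, spec: InhomogeneitySpec,
                      coupling: CouplingConfig, t_run: float,
                      dt: float = 0.02, snap_every_ms: float = 8.0,
                      probe_inside=None, probe_outside=None):
    """Spiral dynamics in a myocyte sheet with a square MF-composite patch.

    The patch is applied to the provided spiral state; V_m probes inside and
    outside the patch and I_Na snapshots (for tip tracking) are recorded.
    Returns (grid, TissueResult, probes_indices).
    """
    grid = set_patch(spiral_grid, spec)
    i0, j0, npatch = spec.node_box(grid.dx)
    if probe_inside is None:
        probe_inside = (i0 + npatch // 2, j0 + npatch // 2)
    if probe_outside is None:
        probe_outside = (max(i0 - grid.ny // 6, 2), max(j0 - grid.nx // 6, 2))
    res = run_tissue(grid, coupling, [], t_end=t_run, dt=dt,
                     probes=[probe_inside, probe_outside], probe_every=25,
                     snap_every_ms=snap_every_ms, snap_t0=grid.t,
                     snap_fields=("V_m", "I_Na"))
    return grid, res, (probe_inside, probe_outside)
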