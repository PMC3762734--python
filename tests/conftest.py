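"""Shared fixtures.

The scaled spiral (200x200, D/4) is expensive to initiate, so it is built
once per session and reused: `spiral_state` is the developed-spiral state,
and `control_spiral_run` a 900 ms zero-coupling continuation with probe
traces and V_m / I_Na snapshots that several analyses share.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardiomf.params import FibroblastParams
from cardiomf.protocols import SpiralInitProtocol, initiate_spiral
from cardiomf.tissue import BilayerGrid, CouplingConfig, run_tissue

SCALED_N = 200
SCALED_D = 0.00154 / 4.0
SPIRAL_FIB = FibroblastParams(C_f=6.3, G_f=4.0, E_f=-49.0)


def pack_state(grid: BilayerGrid) -> np.ndarray:
    return np.concatenate([grid.Vm[None], grid.G, grid.Vf[None]], axis=0)


def make_grid(state: np.ndarray, t: float, fib=SPIRAL_FIB,
              G_gap: float = 0.0) -> BilayerGrid:
    n = state.shape[1]
    g = BilayerGrid(n, state.shape[2], dx=0.225, fib=fib, G_gap=G_gap)
    g.Vm = state[0].copy()
    g.G = state[1:17].copy()
    g.Vf = state[17].copy()
    g.t = t
    return g


@pytest.fixture(scope="session")
def spiral_state():
    """Developed scaled spiral (myocyte-only fields): (state, t, protocol)."""
    proto = SpiralInitProtocol.scaled(SCALED_N)
    grid, tips = initiate_spiral(proto, verify=False)
    return pack_state(grid), grid.t, proto


@pytest.fixture(scope="session")
def control_spiral_run(spiral_state):
    """900 ms myocyte-only continuation of the spiral: probes + snapshots."""
    state, t0, proto = spiral_state
    grid = make_grid(state, t0)
    res = run_tissue(grid, CouplingConfig(mode="zero_sided", D=proto.D), [],
                     t_end=900.0, probes=[(30, 30)], probe_every=25,
                     snap_every_ms=8.0, snap_t0=t0,
                     snap_fields=("V_m", "I_Na"))
    return res, grid.dx
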