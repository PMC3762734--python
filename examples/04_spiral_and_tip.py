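"""Initiate a spiral wave and track its tip (desk-scale, ~6 min).

Runs the S1-S2 parallel-field protocol on the scaled 200x200 domain
(D = 0.00154/4 cm^2/ms), continues the developed spiral for 900 ms, and
prints the tip statistics and rotation period from two independent
estimators (probe inter-beat intervals and tip revolutions).
"""

import numpy as np

from cardiomf import CouplingConfig
from cardiomf.analysis import beat_statistics, rotation_period, track_tip
from cardiomf.protocols import SpiralInitProtocol, initiate_spiral
from cardiomf.tissue import run_tissue

proto = SpiralInitProtocol.scaled(200)
grid, tips = initiate_spiral(proto)
print(f"spiral initiated at t = {grid.t:.0f} ms; tips found: {tips}")

res = run_tissue(grid, CouplingConfig(mode="zero_sided", D=proto.D), [],
                 t_end=900.0, probes=[(30, 30)], probe_every=25,
                 snap_every_ms=8.0, snap_t0=grid.t,
                 snap_fields=("V_m", "I_Na"))

traj = track_tip(res.t_snap, res.snap_INa, grid.dx)
t, x, y = traj.valid()
print(f"tip tracked in {len(x)}/{len(traj.t)} frames; "
      f"core near ({x.mean():.1f}, {y.mean():.1f}) mm")

bs = beat_statistics(res.probes[:, 0], res.t_probe[1] - res.t_probe[0])
p_ibi, s_ibi = rotation_period(bs)
p_tip, _ = rotation_period(traj)
print(f"rotation period: {p_ibi:.1f} +- {s_ibi:.1f} ms (probe ibi), "
      f"{p_tip:.1f} ms (tip revolutions)")
print()
print("A single reentrant wave rotates in the domain; both period")
print("estimators agree to within a few ms.")
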