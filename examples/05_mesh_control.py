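"""Low-amplitude mesh-based spiral control (desk-scale, ~6 min).

Initiates the scaled spiral, attaches a zero-sided fibroblast layer
(G_gap = 8 nS), and applies a 30 pA/pF, 400 ms pulse on a 2x2 mesh of grid
lines.  The mesh lines become refractory walls that absorb the reentrant
wave; a null pulse leaves the spiral rotating.
"""

from cardiomf import CouplingConfig, FibroblastParams
from cardiomf.protocols import (ControlMesh, SpiralInitProtocol,
                                attach_fibroblasts, initiate_spiral,
                                run_control)

fib = FibroblastParams(6.3, 4.0, -49.0)
proto = SpiralInitProtocol.scaled(200)
grid, _ = initiate_spiral(proto, verify=False)
base = grid.copy()

for label, amp in (("null pulse", 0.0), ("30 pA/pF mesh pulse", 30.0)):
    g = base.copy()
    attach_fibroblasts(g, fib, G_gap=8.0)
    coup = CouplingConfig(mode="zero_sided", D=proto.D, fib=fib)
    out = run_control(g, ControlMesh(blocks=2, amplitude=amp,
                                     duration=400.0), coup)
    verdict = (f"terminated (quiet from t = {out.t_quiet:.0f} ms)"
               if out.terminated else
               f"persists (max V_m = {out.max_v_final:.0f} mV)")
    print(f"{label:>22}: spiral {verdict}")
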