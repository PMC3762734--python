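"""AP morphology versus gap-junctional coupling.

Sweeps G_gap for two fibroblast resting potentials and prints how APD90,
the maximal upstroke velocity and the resting potential of the composite
change - the two qualitative branches of fibroblast loading: depolarized
fibroblasts (E_f = -9 mV) lengthen the AP, polarized ones (E_f = -39 mV)
shorten it, while V_rest rises and (dV/dt)max falls in both cases.
"""

import warnings

from cardiomf import CompositeConfig, FibroblastParams, delta_vs_uncoupled

print(f"{'E_f (mV)':>9} {'G_gap (nS)':>11} {'dAPD90 (ms)':>12} "
      f"{'d(dV/dt)max':>12} {'dV_rest (mV)':>13}")
for ef in (-9.0, -39.0):
    for ggap in (0.0, 2.0, 4.0, 8.0):
        cfg = CompositeConfig(N_f=1, g_j=ggap,
                              fib=FibroblastParams(6.3, 4.0, ef))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = delta_vs_uncoupled(cfg)
        print(f"{ef:>9.0f} {ggap:>11.1f} {d.dAPD90:>12.2f} "
              f"{d.dVdt_max:>12.2f} {d.dV_rest:>13.2f}")
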