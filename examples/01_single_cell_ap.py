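"""One myocyte-fibroblast composite beat.

Couples a human ventricular myocyte to a passive fibroblast (C_f = 6.3 pF,
G_f = 4 nS, E_f = -9 mV) through an 8 nS gap junction, fires one beat with
the standard -52 pA/pF, 3 ms stimulus, and prints the AP morphology next to
the isolated myocyte's.
"""

from cardiomf import CompositeConfig, FibroblastParams, delta_vs_uncoupled

cfg = CompositeConfig(N_f=1, g_j=8.0,
                      fib=FibroblastParams(C_f=6.3, G_f=4.0, E_f=-9.0))
d = delta_vs_uncoupled(cfg)

print("isolated myocyte : APD90 = %.1f ms, (dV/dt)max = %.1f mV/ms, "
      "V_rest = %.1f mV" % (d.uncoupled.APD90, d.uncoupled.dVdt_max,
                            d.uncoupled.V_rest))
print("MF composite     : APD90 = %.1f ms, (dV/dt)max = %.1f mV/ms, "
      "V_rest = %.1f mV" % (d.coupled.APD90, d.coupled.dVdt_max,
                            d.coupled.V_rest))
print("coupled - isolated: dAPD90 = %+.2f ms, d(dV/dt)max = %+.2f mV/ms, "
      "dV_rest = %+.2f mV" % (d.dAPD90, d.dVdt_max, d.dV_rest))
print()
print("A depolarized fibroblast (E_f = -9 mV) elevates the myocyte's")
print("diastolic potential, blunts the upstroke (resting Na-channel")
print("inactivation) and prolongs late repolarization.")
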