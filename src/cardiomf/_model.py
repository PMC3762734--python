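"""Numba kernels: exact scalar evaluation of the ionic model and the
single-cell / myocyte-fibroblast composite integrator.

The voltage and ion concentrations are advanced with forward Euler; the ten
voltage-dependent gates use, by default, the exponential (Rush-Larsen) update
m <- m_inf + (m - m_inf) * exp(-dt/tau_m), which is the standard integrator
for this model family (the fast Na activation gate has tau well below any
practical dt near rest, so a plain forward-Euler gate update is unstable
there).  A forward-Euler gate mode is available for experimentation.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .params import (
    P_GNA, P_GCAL, P_GTO, P_GKS, P_GKR, P_GK1, P_GPCA, P_GPK, P_GBNA, P_GBCA,
    P_PNAK, P_KMK, P_KMNA, P_KNACA, P_KMNAI, P_KMCA, P_KSAT, P_ALPHA, P_GAMMA,
    P_NAO, P_KO, P_CAO, P_PKNA, P_AREL, P_BREL, P_CREL, P_VMAXUP, P_KUP,
    P_VLEAK, P_TAUG, P_TAUFCA, P_BUFC, P_KBUFC, P_BUFSR, P_KBUFSR, P_KPCA,
    P_RTONF, P_F, P_CONVCONC, P_VCOVERVSR, P_CM,
    IV, IM, IH, IJ, ID, IF, IFCA, IR, IS, IXR1, IXR2, IXS, IG,
    INAI, IKI, ICAI, ICASR,
)

GATE_RL = 0  # Rush-Larsen exponential gate update (default)
GATE_FE = 1  # forward-Euler gate update


@njit(cache=True)
def gate_rates(V):
    """Steady states and time constants of the ten voltage-dependent gates.

    Returns (inf, tau) as two length-10 arrays ordered
    (m, h, j, d, f, r, s, xr1, xr2, xs); tau in ms.
    """
    inf = np.empty(10)
    tau = np.empty(10)

    # fast Na activation m
    inf[0] = 1.0 / ((1.0 + math.exp((-56.86 - V) / 9.03)) ** 2)
    am = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + math.exp((V + 35.0) / 5.0)) \
        + 0.1 / (1.0 + math.exp((V - 50.0) / 200.0))
    tau[0] = am * bm

    # fast Na inactivation h
    inf[1] = 1.0 / ((1.0 + math.exp((V + 71.55) / 7.43)) ** 2)
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.3485 * V)
    tau[1] = 1.0 / (ah + bh)

    # slow Na inactivation j
    inf[2] = inf[1]
    if V >= -40.0:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        aj = ((-2.5428e4 * math.exp(0.2444 * V)
               - 6.948e-6 * math.exp(-0.04391 * V)) * (V + 37.78)
              / (1.0 + math.exp(0.311 * (V + 79.23))))
        bj = 0.02424 * math.exp(-0.01052 * V) \
            / (1.0 + math.exp(-0.1378 * (V + 40.14)))
    tau[2] = 1.0 / (aj + bj)

    # L-type Ca activation d
    inf[3] = 1.0 / (1.0 + math.exp((-5.0 - V) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - V) / 20.0))
    tau[3] = ad * bd + gd

    # L-type Ca voltage inactivation f
    inf[4] = 1.0 / (1.0 + math.exp((V + 20.0) / 7.0))
    tau[4] = (1125.0 * math.exp(-((V + 27.0) ** 2) / 240.0)
              + 80.0 + 165.0 / (1.0 + math.exp((25.0 - V) / 10.0)))

    # transient outward activation r (epicardial)
    inf[5] = 1.0 / (1.0 + math.exp((20.0 - V) / 6.0))
    tau[5] = 9.5 * math.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8

    # transient outward inactivation s (epicardial)
    inf[6] = 1.0 / (1.0 + math.exp((V + 20.0) / 5.0))
    tau[6] = (85.0 * math.exp(-((V + 45.0) ** 2) / 320.0)
              + 5.0 / (1.0 + math.exp((V - 20.0) / 5.0)) + 3.0)

    # rapid delayed rectifier xr1, xr2
    inf[7] = 1.0 / (1.0 + math.exp((-26.0 - V) / 7.0))
    ax1 = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
    bx1 = 6.0 / (1.0 + math.exp((V + 30.0) / 11.5))
    tau[7] = ax1 * bx1
    inf[8] = 1.0 / (1.0 + math.exp((V + 88.0) / 24.0))
    ax2 = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
    bx2 = 1.12 / (1.0 + math.exp((V - 60.0) / 20.0))
    tau[8] = ax2 * bx2

    # slow delayed rectifier xs
    inf[9] = 1.0 / (1.0 + math.exp((-5.0 - V) / 14.0))
    axs = 1100.0 / math.sqrt(1.0 + math.exp((-10.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((V - 60.0) / 20.0))
    tau[9] = axs * bxs

    return inf, tau


@njit(cache=True)
def membrane_currents(y, pa):
    """The twelve membrane current densities (pA/pF) for state vector y."""
    V = y[IV]
    rtonf = pa[P_RTONF]
    Ek = rtonf * math.log(pa[P_KO] / y[IKI])
    Ena = rtonf * math.log(pa[P_NAO] / y[INAI])
    Eks = rtonf * math.log((pa[P_KO] + pa[P_PKNA] * pa[P_NAO])
                           / (y[IKI] + pa[P_PKNA] * y[INAI]))
    Eca = 0.5 * rtonf * math.log(pa[P_CAO] / y[ICAI])

    INa = pa[P_GNA] * y[IM] ** 3 * y[IH] * y[IJ] * (V - Ena)

    # L-type Ca current (GHK-like driving term)
    x = 2.0 * V / rtonf
    if abs(x) < 1e-7:
        # V -> 0 limit of the GHK-like driving term
        drive = 2.0 * pa[P_F] * (y[ICAI] - 0.341 * pa[P_CAO])
    else:
        ex = math.exp(x)
        drive = (4.0 * V * pa[P_F] / rtonf) \
            * (y[ICAI] * ex - 0.341 * pa[P_CAO]) / (ex - 1.0)
    ICaL = pa[P_GCAL] * y[ID] * y[IF] * y[IFCA] * drive

    Ito = pa[P_GTO] * y[IR] * y[IS] * (V - Ek)
    IKs = pa[P_GKS] * y[IXS] * y[IXS] * (V - Eks)
    sqko = math.sqrt(pa[P_KO] / 5.4)
    IKr = pa[P_GKR] * sqko * y[IXR1] * y[IXR2] * (V - Ek)

    u = V - Ek
    ak1 = 0.1 / (1.0 + math.exp(0.06 * (u - 200.0)))
    bk1 = (3.0 * math.exp(0.0002 * (u + 100.0)) + math.exp(0.1 * (u - 10.0))) \
        / (1.0 + math.exp(-0.5 * u))
    IK1 = pa[P_GK1] * sqko * ak1 / (ak1 + bk1) * u

    eg = math.exp(pa[P_GAMMA] * V / rtonf)
    eg1 = math.exp((pa[P_GAMMA] - 1.0) * V / rtonf)
    INaCa = (pa[P_KNACA]
             * (eg * y[INAI] ** 3 * pa[P_CAO]
                - eg1 * pa[P_NAO] ** 3 * y[ICAI] * pa[P_ALPHA])
             / ((pa[P_KMNAI] ** 3 + pa[P_NAO] ** 3)
                * (pa[P_KMCA] + pa[P_CAO])
                * (1.0 + pa[P_KSAT] * eg1)))

    INaK = (pa[P_PNAK] * pa[P_KO] * y[INAI]
            / ((pa[P_KO] + pa[P_KMK]) * (y[INAI] + pa[P_KMNA]))
            / (1.0 + 0.1245 * math.exp(-0.1 * V / rtonf)
               + 0.0353 * math.exp(-V / rtonf)))

    IpCa = pa[P_GPCA] * y[ICAI] / (pa[P_KPCA] + y[ICAI])
    IpK = pa[P_GPK] * u / (1.0 + math.exp((25.0 - V) / 5.98))
    IbNa = pa[P_GBNA] * (V - Ena)
    IbCa = pa[P_GBCA] * (V - Eca)

    return INa, ICaL, Ito, IKs, IKr, IK1, INaCa, INaK, IpCa, IpK, IbNa, IbCa


@njit(cache=True)
def step_cell(y, dt, i_stim, i_ext, pa, gate_mode):
    """Advance one myocyte by dt (in place).

    i_stim : external stimulus current density, pA/pF (enters the K+ balance)
    i_ext  : additional membrane current density, pA/pF (e.g. gap-junctional
             load converted by C_m); does not enter the ion balances.
    Returns the total ionic current density I_ion (pA/pF).
    """
    V = y[IV]
    (INa, ICaL, Ito, IKs, IKr, IK1, INaCa, INaK, IpCa, IpK, IbNa, IbCa) = \
        membrane_currents(y, pa)
    Iion = INa + ICaL + Ito + IKs + IKr + IK1 + INaCa + INaK \
        + IpCa + IpK + IbNa + IbCa

    # calcium subsystem (uses gate values at the current step)
    cai = y[ICAI]
    casr = y[ICASR]
    Ileak = pa[P_VLEAK] * (casr - cai)
    Iup = pa[P_VMAXUP] / (1.0 + (pa[P_KUP] / cai) ** 2)
    Irel = (pa[P_AREL] * casr * casr / (pa[P_BREL] ** 2 + casr * casr)
            + pa[P_CREL]) * y[ID] * y[IG]

    bufc = 1.0 / (1.0 + pa[P_BUFC] * pa[P_KBUFC] / ((cai + pa[P_KBUFC]) ** 2))
    bufsr = 1.0 / (1.0 + pa[P_BUFSR] * pa[P_KBUFSR]
                   / ((casr + pa[P_KBUFSR]) ** 2))
    dcai = bufc * (Ileak - Iup + Irel
                   - (ICaL + IbCa + IpCa - 2.0 * INaCa) * pa[P_CONVCONC] / 2.0)
    dcasr = bufsr * pa[P_VCOVERVSR] * (Iup - Irel - Ileak)

    dnai = -(INa + IbNa + 3.0 * INaK + 3.0 * INaCa) * pa[P_CONVCONC]
    dki = -(i_stim + IK1 + Ito + IKr + IKs - 2.0 * INaK + IpK) * pa[P_CONVCONC]

    # calcium-dependent gates (forward Euler, tau >> dt)
    c8 = (cai / 0.000325) ** 8
    afca = 1.0 / (1.0 + c8)
    bfca = 0.1 / (1.0 + math.exp((cai - 0.0005) / 0.0001))
    gfca = 0.2 / (1.0 + math.exp((cai - 0.00075) / 0.0008))
    fcainf = (afca + bfca + gfca + 0.23) / 1.46
    if not (fcainf > y[IFCA] and V > -60.0):
        y[IFCA] += dt * (fcainf - y[IFCA]) / pa[P_TAUFCA]

    if cai < 0.00035:
        ginf = 1.0 / (1.0 + (cai / 0.00035) ** 6)
    else:
        ginf = 1.0 / (1.0 + (cai / 0.00035) ** 16)
    if not (ginf > y[IG] and V > -60.0):
        y[IG] += dt * (ginf - y[IG]) / pa[P_TAUG]

    # voltage-dependent gates
    inf, tau = gate_rates(V)
    if gate_mode == GATE_RL:
        y[IM] = inf[0] + (y[IM] - inf[0]) * math.exp(-dt / tau[0])
        y[IH] = inf[1] + (y[IH] - inf[1]) * math.exp(-dt / tau[1])
        y[IJ] = inf[2] + (y[IJ] - inf[2]) * math.exp(-dt / tau[2])
        y[ID] = inf[3] + (y[ID] - inf[3]) * math.exp(-dt / tau[3])
        y[IF] = inf[4] + (y[IF] - inf[4]) * math.exp(-dt / tau[4])
        y[IR] = inf[5] + (y[IR] - inf[5]) * math.exp(-dt / tau[5])
        y[IS] = inf[6] + (y[IS] - inf[6]) * math.exp(-dt / tau[6])
        y[IXR1] = inf[7] + (y[IXR1] - inf[7]) * math.exp(-dt / tau[7])
        y[IXR2] = inf[8] + (y[IXR2] - inf[8]) * math.exp(-dt / tau[8])
        y[IXS] = inf[9] + (y[IXS] - inf[9]) * math.exp(-dt / tau[9])
    else:
        y[IM] += dt * (inf[0] - y[IM]) / tau[0]
        y[IH] += dt * (inf[1] - y[IH]) / tau[1]
        y[IJ] += dt * (inf[2] - y[IJ]) / tau[2]
        y[ID] += dt * (inf[3] - y[ID]) / tau[3]
        y[IF] += dt * (inf[4] - y[IF]) / tau[4]
        y[IR] += dt * (inf[5] - y[IR]) / tau[5]
        y[IS] += dt * (inf[6] - y[IS]) / tau[6]
        y[IXR1] += dt * (inf[7] - y[IXR1]) / tau[7]
        y[IXR2] += dt * (inf[8] - y[IXR2]) / tau[8]
        y[IXS] += dt * (inf[9] - y[IXS]) / tau[9]

    y[INAI] += dt * dnai
    y[IKI] += dt * dki
    y[ICAI] += dt * dcai
    y[ICASR] += dt * dcasr
    y[IV] = V - dt * (Iion + i_stim + i_ext)
    return Iion


@njit(cache=True)
def run_composite_kernel(y0, vf0, pa, dt, n_steps, stim, Cf, Gf, Ef, Ggap,
                         gate_mode, rec_every, record_currents):
    """Integrate a myocyte coupled to one (equivalent) passive fibroblast.

    stim : (n_events, 3) array of (start ms, duration ms, amplitude pA/pF).
    Ggap : aggregate gap-junctional conductance N_f * g_j, nS.
    Returns (status, t_fail, t_rec, Vm_rec, Vf_rec, Igap_rec, cur_rec, y, vf);
    status 0 = ok, 1 = instability (|V_m| > 200 mV) at t_fail.
    """
    y = y0.copy()
    vf = vf0
    Cm = pa[P_CM]
    n_rec = n_steps // rec_every + 1
    t_rec = np.empty(n_rec)
    vm_rec = np.empty(n_rec)
    vf_rec = np.empty(n_rec)
    ig_rec = np.empty(n_rec)
    ncur = 12 if record_currents else 1
    cur_rec = np.zeros((n_rec, ncur))
    idx = 0
    t_rec[0] = 0.0
    vm_rec[0] = y[IV]
    vf_rec[0] = vf
    ig_rec[0] = Ggap * (y[IV] - vf)
    if record_currents:
        cc = membrane_currents(y, pa)
        for q in range(12):
            cur_rec[0, q] = cc[q]

    for k in range(n_steps):
        t = k * dt
        i_stim = 0.0
        for e in range(stim.shape[0]):
            if stim[e, 0] <= t < stim[e, 0] + stim[e, 1]:
                i_stim += stim[e, 2]
        igap = Ggap * (y[IV] - vf)  # pA, positive = out of the myocyte
        step_cell(y, dt, i_stim, igap / Cm, pa, gate_mode)
        vf += dt * (-(Gf * (vf - Ef)) + igap) / Cf
        if abs(y[IV]) > 200.0 or y[IV] != y[IV]:
            return 1, (k + 1) * dt, t_rec[:idx + 1], vm_rec[:idx + 1], \
                vf_rec[:idx + 1], ig_rec[:idx + 1], cur_rec[:idx + 1], y, vf
        if (k + 1) % rec_every == 0:
            idx += 1
            t_rec[idx] = (k + 1) * dt
            vm_rec[idx] = y[IV]
            vf_rec[idx] = vf
            ig_rec[idx] = Ggap * (y[IV] - vf)
            if record_currents:
                cc = membrane_currents(y, pa)
                for q in range(12):
                    cur_rec[idx, q] = cc[q]
    return 0, -1.0, t_rec[:idx + 1], vm_rec[:idx + 1], vf_rec[:idx + 1], \
        ig_rec[:idx + 1], cur_rec[:idx + 1], y, vf
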