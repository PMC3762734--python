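"""Numba kernel for the 2D myocyte-fibroblast bilayer.

Forward-Euler monodomain stepping of the myocyte sheet (diffusive
intra-layer coupling D * lap(V_m)) with an optional fibroblast layer on top:
on-site gap-junctional exchange G_gap (V_m - V_f), fibroblast-fibroblast
intra-layer conductances G_ff (one-/two-sided) and myocyte-fibroblast
cross-layer neighbor conductances (two-sided).  No-flux boundaries via
edge-replicated ghost nodes (which also keep every pairwise conductance
term exactly charge-conserving at the border).

For speed, all purely voltage-dependent factors of the ionic model (gate
steady states and exponential update factors, the L-type Ca and exchanger /
pump prefactors, the inward-rectifier factor on V - E_K) are tabulated on a
0.05 mV grid and linearly interpolated; concentration-dependent parts are
evaluated exactly.  Tables are generated from the same scalar rate/current
functions used by the single-cell path.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from . import _model
from .params import (
    P_GNA, P_GCAL, P_GTO, P_GKS, P_GKR, P_GK1, P_GPCA, P_GPK, P_GBNA, P_GBCA,
    P_PNAK, P_KMK, P_KMNA, P_KNACA, P_KMNAI, P_KMCA, P_KSAT, P_ALPHA, P_GAMMA,
    P_NAO, P_KO, P_CAO, P_PKNA, P_AREL, P_BREL, P_CREL, P_VMAXUP, P_KUP,
    P_VLEAK, P_TAUG, P_TAUFCA, P_BUFC, P_KBUFC, P_BUFSR, P_KBUFSR, P_KPCA,
    P_RTONF, P_F, P_CONVCONC, P_VCOVERVSR, P_CM,
)

# field-array layout (16, ny, nx): gates then pools
(TG_M, TG_H, TG_J, TG_D, TG_F, TG_R, TG_S, TG_XR1, TG_XR2, TG_XS,
 TG_FCA, TG_G, TG_NAI, TG_KI, TG_CAI, TG_CASR) = range(16)

VT_MIN = -120.0
VT_MAX = 80.0
VT_DV = 0.05

_TABLE_CACHE: dict = {}


def build_tables(pa: np.ndarray, dt: float) -> np.ndarray:
    """Voltage lookup tables (37 rows) for the tissue kernel."""
    key = (pa.tobytes(), dt)
    if key in _TABLE_CACHE:
        return _TABLE_CACHE[key]
    n = int(round((VT_MAX - VT_MIN) / VT_DV)) + 1
    V = VT_MIN + VT_DV * np.arange(n)
    tab = np.empty((37, n))
    for i in range(n):
        inf, tau = _model.gate_rates(V[i])
        tab[0:10, i] = inf
        tab[10:20, i] = np.exp(-dt / tau)
        tab[20:30, i] = dt / tau

    rtonf = pa[P_RTONF]
    F = pa[P_F]
    x = 2.0 * V / rtonf
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        ex = np.exp(x)
        pref = pa[P_GCAL] * 4.0 * V * F / rtonf
        A = pref * ex / (ex - 1.0)
        B = pref * 0.341 * pa[P_CAO] / (ex - 1.0)
    near0 = np.abs(V) < 1e-9
    A[near0] = pa[P_GCAL] * 2.0 * F
    B[near0] = pa[P_GCAL] * 2.0 * F * 0.341 * pa[P_CAO]
    tab[30] = A
    tab[31] = B

    eg = np.exp(pa[P_GAMMA] * V / rtonf)
    eg1 = np.exp((pa[P_GAMMA] - 1.0) * V / rtonf)
    denom = ((pa[P_KMNAI] ** 3 + pa[P_NAO] ** 3) * (pa[P_KMCA] + pa[P_CAO])
             * (1.0 + pa[P_KSAT] * eg1))
    tab[32] = pa[P_KNACA] * eg * pa[P_CAO] / denom
    tab[33] = pa[P_KNACA] * eg1 * pa[P_NAO] ** 3 * pa[P_ALPHA] / denom
    tab[34] = (pa[P_PNAK] * pa[P_KO] / (pa[P_KO] + pa[P_KMK])
               / (1.0 + 0.1245 * np.exp(-0.1 * V / rtonf)
                  + 0.0353 * np.exp(-V / rtonf)))
    tab[35] = pa[P_GPK] / (1.0 + np.exp((25.0 - V) / 5.98))

    u = V  # row 36 is indexed by u = V - E_K
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (u - 200.0)))
    bk1 = ((3.0 * np.exp(0.0002 * (u + 100.0)) + np.exp(0.1 * (u - 10.0)))
           / (1.0 + np.exp(-0.5 * u)))
    tab[36] = pa[P_GK1] * math.sqrt(pa[P_KO] / 5.4) * ak1 / (ak1 + bk1)

    tab = np.ascontiguousarray(tab)
    _TABLE_CACHE[key] = tab
    return tab


@njit(cache=True, fastmath=True)
def _interp(tab, row, pos, i0, w):
    return tab[row, i0] * (1.0 - w) + tab[row, i0 + 1] * w


@njit(cache=True, fastmath=True)
def step_tissue_kernel(Vm, Vmn, Vf, Vfn, G, fib, ggap, tab, pa, dt, n_steps,
                       step_offset, Ddt, Cf, Gf, Ef, Gff, Gx, mode, gate_mode,
                       stim_start, stim_dur, stim_amp, stim_mask,
                       probe_i, probe_j, probe_buf, probe_every,
                       snap_steps, snap_vm, snap_vf, snap_ina):
    """Advance the bilayer n_steps; returns (status, parity, fail_t, fail_i, fail_j).

    parity: 0 if the final V lives in Vm/Vf, 1 if in Vmn/Vfn.
    Ddt = D / dx^2 in 1/ms.  probe_buf shape (n_probe_rec, nprobe); snap_*
    are float32 buffers of shape (n_snap, ny, nx) (size-0 first axis
    disables a channel).

    The Nernst potentials are refreshed from the ion pools every
    E_REFRESH steps (0.16 ms at dt = 0.02): the pools drift on second
    timescales, so the interim error is well below the table-interpolation
    error, and it removes four log evaluations per node-step.
    """
    ny, nx = Vm.shape
    nev = stim_start.shape[0]
    invdv = 1.0 / VT_DV
    rtonf = pa[P_RTONF]
    nt = tab.shape[1]
    snap_ptr = 0
    gna = pa[P_GNA]
    sqko = math.sqrt(pa[P_KO] / 5.4)
    do_vf_snap = snap_vf.shape[0] > 0
    do_ina_snap = snap_ina.shape[0] > 0

    E_REFRESH = 8
    EK = np.empty((ny, nx))
    ENA = np.empty((ny, nx))
    EKS = np.empty((ny, nx))
    ECA = np.empty((ny, nx))

    for k in range(n_steps):
        if k % E_REFRESH == 0:
            for i in range(ny):
                for j in range(nx):
                    EK[i, j] = rtonf * math.log(pa[P_KO] / G[TG_KI, i, j])
                    ENA[i, j] = rtonf * math.log(pa[P_NAO] / G[TG_NAI, i, j])
                    EKS[i, j] = rtonf * math.log(
                        (pa[P_KO] + pa[P_PKNA] * pa[P_NAO])
                        / (G[TG_KI, i, j] + pa[P_PKNA] * G[TG_NAI, i, j]))
                    ECA[i, j] = 0.5 * rtonf * math.log(pa[P_CAO]
                                                       / G[TG_CAI, i, j])
        if k % 2 == 0:
            Va = Vm; Vb = Vmn; Fa = Vf; Fb = Vfn
        else:
            Va = Vmn; Vb = Vm; Fa = Vfn; Fb = Vf
        tglob = (step_offset + k) * dt
        take_snap = snap_ptr < snap_steps.shape[0] \
            and snap_steps[snap_ptr] == step_offset + k

        for i in range(ny):
            # edge-replicated ghosts: zero boundary flux AND exact pairwise
            # cancellation of every conductance term at the border
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < ny - 1 else ny - 1
            for j in range(nx):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < nx - 1 else nx - 1
                V = Va[i, j]
                # abort only on true numerical blow-up; strong boundary
                # stimuli push V transiently past physiological bounds
                if V != V or abs(V) > 1.0e4:
                    return 1, k % 2, tglob, i, j
                lap = Va[im, j] + Va[ip, j] + Va[i, jm] + Va[i, jp] - 4.0 * V

                istim = 0.0
                for e in range(nev):
                    if stim_start[e] <= tglob < stim_start[e] + stim_dur[e] \
                            and stim_mask[e, i, j] != 0:
                        istim += stim_amp[e]

                # table position
                pos = (V - VT_MIN) * invdv
                if pos < 0.0:
                    pos = 0.0
                elif pos > nt - 2.0:
                    pos = nt - 2.0
                i0 = int(pos)
                w = pos - i0

                nai = G[TG_NAI, i, j]
                ki = G[TG_KI, i, j]
                cai = G[TG_CAI, i, j]
                casr = G[TG_CASR, i, j]
                Ek = EK[i, j]
                Ena = ENA[i, j]
                Eks = EKS[i, j]
                Eca = ECA[i, j]

                INa = gna * G[TG_M, i, j] ** 3 * G[TG_H, i, j] \
                    * G[TG_J, i, j] * (V - Ena)
                ICaL = G[TG_D, i, j] * G[TG_F, i, j] * G[TG_FCA, i, j] \
                    * (_interp(tab, 30, pos, i0, w) * cai
                       - _interp(tab, 31, pos, i0, w))
                Ito = pa[P_GTO] * G[TG_R, i, j] * G[TG_S, i, j] * (V - Ek)
                IKs = pa[P_GKS] * G[TG_XS, i, j] ** 2 * (V - Eks)
                IKr = pa[P_GKR] * sqko * G[TG_XR1, i, j] * G[TG_XR2, i, j] \
                    * (V - Ek)
                u = V - Ek
                posu = (u - VT_MIN) * invdv
                if posu < 0.0:
                    posu = 0.0
                elif posu > nt - 2.0:
                    posu = nt - 2.0
                iu = int(posu)
                wu = posu - iu
                IK1 = _interp(tab, 36, posu, iu, wu) * u
                INaCa = _interp(tab, 32, pos, i0, w) * nai ** 3 \
                    - _interp(tab, 33, pos, i0, w) * cai
                INaK = _interp(tab, 34, pos, i0, w) * nai / (nai + pa[P_KMNA])
                IpCa = pa[P_GPCA] * cai / (pa[P_KPCA] + cai)
                IpK = _interp(tab, 35, pos, i0, w) * u
                IbNa = pa[P_GBNA] * (V - Ena)
                IbCa = pa[P_GBCA] * (V - Eca)
                Iion = INa + ICaL + Ito + IKs + IKr + IK1 + INaCa + INaK \
                    + IpCa + IpK + IbNa + IbCa

                if do_ina_snap and snap_ptr < snap_ina.shape[0]:
                    # I_Na channel: peak |I_Na| since the previous frame
                    # (the instantaneous sub-ms surge would be aliased by
                    # any practical frame cadence)
                    a = -INa if INa < 0.0 else INa
                    if a > snap_ina[snap_ptr, i, j]:
                        snap_ina[snap_ptr, i, j] = a

                # gap / cross-layer load, pA
                iext = 0.0
                has_fib = fib[i, j] != 0
                if has_fib:
                    iext += ggap[i, j] * (V - Fa[i, j])
                if mode == 2:
                    if fib[im, j] != 0:
                        iext += Gx * (V - Fa[im, j])
                    if fib[ip, j] != 0:
                        iext += Gx * (V - Fa[ip, j])
                    if fib[i, jm] != 0:
                        iext += Gx * (V - Fa[i, jm])
                    if fib[i, jp] != 0:
                        iext += Gx * (V - Fa[i, jp])

                Vb[i, j] = V + dt * (Ddt * lap - (Iion + istim)
                                     - iext / pa[P_CM])

                # calcium subsystem
                Ileak = pa[P_VLEAK] * (casr - cai)
                Iup = pa[P_VMAXUP] / (1.0 + (pa[P_KUP] / cai) ** 2)
                Irel = (pa[P_AREL] * casr * casr
                        / (pa[P_BREL] ** 2 + casr * casr)
                        + pa[P_CREL]) * G[TG_D, i, j] * G[TG_G, i, j]
                bufc = 1.0 / (1.0 + pa[P_BUFC] * pa[P_KBUFC]
                              / ((cai + pa[P_KBUFC]) ** 2))
                bufsr = 1.0 / (1.0 + pa[P_BUFSR] * pa[P_KBUFSR]
                               / ((casr + pa[P_KBUFSR]) ** 2))
                dcai = bufc * (Ileak - Iup + Irel
                               - (ICaL + IbCa + IpCa - 2.0 * INaCa)
                               * pa[P_CONVCONC] / 2.0)
                dcasr = bufsr * pa[P_VCOVERVSR] * (Iup - Irel - Ileak)
                dnai = -(INa + IbNa + 3.0 * INaK + 3.0 * INaCa) * pa[P_CONVCONC]
                dki = -(istim + IK1 + Ito + IKr + IKs - 2.0 * INaK + IpK) \
                    * pa[P_CONVCONC]

                c8 = (cai / 0.000325) ** 8
                afca = 1.0 / (1.0 + c8)
                bfca = 0.1 / (1.0 + math.exp((cai - 0.0005) / 0.0001))
                gfca = 0.2 / (1.0 + math.exp((cai - 0.00075) / 0.0008))
                fcainf = (afca + bfca + gfca + 0.23) / 1.46
                if not (fcainf > G[TG_FCA, i, j] and V > -60.0):
                    G[TG_FCA, i, j] += dt * (fcainf - G[TG_FCA, i, j]) \
                        / pa[P_TAUFCA]
                if cai < 0.00035:
                    ginf = 1.0 / (1.0 + (cai / 0.00035) ** 6)
                else:
                    ginf = 1.0 / (1.0 + (cai / 0.00035) ** 16)
                if not (ginf > G[TG_G, i, j] and V > -60.0):
                    G[TG_G, i, j] += dt * (ginf - G[TG_G, i, j]) / pa[P_TAUG]

                if gate_mode == 0:  # Rush-Larsen
                    for q in range(10):
                        inf = _interp(tab, q, pos, i0, w)
                        rl = _interp(tab, 10 + q, pos, i0, w)
                        G[q, i, j] = inf + (G[q, i, j] - inf) * rl
                else:  # forward Euler
                    for q in range(10):
                        inf = _interp(tab, q, pos, i0, w)
                        dtt = _interp(tab, 20 + q, pos, i0, w)
                        G[q, i, j] += dtt * (inf - G[q, i, j])

                G[TG_NAI, i, j] = nai + dt * dnai
                G[TG_KI, i, j] = ki + dt * dki
                G[TG_CAI, i, j] = cai + dt * dcai
                G[TG_CASR, i, j] = casr + dt * dcasr

                # fibroblast layer
                if has_fib:
                    vfc = Fa[i, j]
                    rhs = -(Gf * (vfc - Ef)) + ggap[i, j] * (V - vfc)
                    if mode >= 1:
                        if fib[im, j] != 0:
                            rhs += Gff * (Fa[im, j] - vfc)
                        if fib[ip, j] != 0:
                            rhs += Gff * (Fa[ip, j] - vfc)
                        if fib[i, jm] != 0:
                            rhs += Gff * (Fa[i, jm] - vfc)
                        if fib[i, jp] != 0:
                            rhs += Gff * (Fa[i, jp] - vfc)
                    if mode == 2:
                        rhs += Gx * (Va[im, j] + Va[ip, j] + Va[i, jm]
                                     + Va[i, jp] - 4.0 * vfc)
                    Fb[i, j] = vfc + dt * rhs / Cf
                else:
                    Fb[i, j] = Fa[i, j]

                if take_snap:
                    snap_vm[snap_ptr, i, j] = V
                    if do_vf_snap:
                        snap_vf[snap_ptr, i, j] = Fa[i, j]

        if take_snap:
            snap_ptr += 1
        if probe_every > 0 and (step_offset + k) % probe_every == 0:
            rec = (step_offset + k) // probe_every
            if rec < probe_buf.shape[0]:
                for p in range(probe_i.shape[0]):
                    probe_buf[rec, p] = Va[probe_i[p], probe_j[p]]

    return 0, n_steps % 2, -1.0, -1, -1
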