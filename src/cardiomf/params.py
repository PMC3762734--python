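"""Model constants for the human ventricular myocyte and the passive fibroblast.

The myocyte is the ten Tusscher-Noble-Noble-Panfilov (TNNP, 2004) epicardial
cell.  All constants are exposed on :class:`MyocyteParams` and may be
overridden; they are packed into a flat float64 vector for the numba kernels.

Units follow the cardiac-modelling convention: time in ms, voltage in mV,
current densities in pA/pF, conductances in nS/pF (cell model) or nS
(junctions), concentrations in mM, capacitance in pF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

# Physical constants
R_GAS = 8314.472  # mJ/(mol K)
TEMP = 310.0  # K
FARADAY = 96485.3415  # C/mol
RTONF = R_GAS * TEMP / FARADAY  # mV


@dataclass(frozen=True)
class MyocyteParams:
    """TNNP-2004 epicardial parameter set (overridable)."""

    # Maximal conductances, nS/pF
    g_Na: float = 14.838
    g_CaL: float = 1.75e-4  # L-type channel permeability factor
    g_to: float = 0.294  # epicardial transient outward
    g_Ks: float = 0.245  # epicardial slow delayed rectifier
    g_Kr: float = 0.096
    g_K1: float = 5.405
    g_pCa: float = 0.825
    g_pK: float = 0.0146
    g_bNa: float = 2.9e-4
    g_bCa: float = 5.92e-4
    # Na/K pump and Na/Ca exchanger
    P_NaK: float = 1.362
    K_mK: float = 1.0
    K_mNa: float = 40.0
    k_NaCa: float = 1000.0
    K_mNai: float = 87.5
    K_mCa: float = 1.38
    k_sat: float = 0.1
    alpha_NaCa: float = 2.5
    gamma_NaCa: float = 0.35
    # External ion concentrations, mM
    Na_o: float = 140.0
    K_o: float = 5.4
    Ca_o: float = 2.0
    p_KNa: float = 0.03
    # Calcium handling
    a_rel: float = 0.016464
    b_rel: float = 0.25
    c_rel: float = 0.008232
    V_maxup: float = 4.25e-4
    K_up: float = 2.5e-4
    V_leak: float = 8.0e-5
    tau_g: float = 2.0
    tau_fCa: float = 2.0
    Buf_c: float = 0.15
    K_bufc: float = 0.001
    Buf_sr: float = 10.0
    K_bufsr: float = 0.3
    K_pCa: float = 5.0e-4
    # Cell geometry / capacitance
    C_m: float = 185.0  # total cellular capacitance, pF
    V_c: float = 0.016404  # cytoplasmic volume factor (CellML units)
    V_sr: float = 0.001094  # SR volume factor

    def pack(self) -> np.ndarray:
        """Flat float64 parameter vector consumed by the numba kernels."""
        pa = np.empty(N_PARAMS, dtype=np.float64)
        pa[P_GNA] = self.g_Na
        pa[P_GCAL] = self.g_CaL
        pa[P_GTO] = self.g_to
        pa[P_GKS] = self.g_Ks
        pa[P_GKR] = self.g_Kr
        pa[P_GK1] = self.g_K1
        pa[P_GPCA] = self.g_pCa
        pa[P_GPK] = self.g_pK
        pa[P_GBNA] = self.g_bNa
        pa[P_GBCA] = self.g_bCa
        pa[P_PNAK] = self.P_NaK
        pa[P_KMK] = self.K_mK
        pa[P_KMNA] = self.K_mNa
        pa[P_KNACA] = self.k_NaCa
        pa[P_KMNAI] = self.K_mNai
        pa[P_KMCA] = self.K_mCa
        pa[P_KSAT] = self.k_sat
        pa[P_ALPHA] = self.alpha_NaCa
        pa[P_GAMMA] = self.gamma_NaCa
        pa[P_NAO] = self.Na_o
        pa[P_KO] = self.K_o
        pa[P_CAO] = self.Ca_o
        pa[P_PKNA] = self.p_KNa
        pa[P_AREL] = self.a_rel
        pa[P_BREL] = self.b_rel
        pa[P_CREL] = self.c_rel
        pa[P_VMAXUP] = self.V_maxup
        pa[P_KUP] = self.K_up
        pa[P_VLEAK] = self.V_leak
        pa[P_TAUG] = self.tau_g
        pa[P_TAUFCA] = self.tau_fCa
        pa[P_BUFC] = self.Buf_c
        pa[P_KBUFC] = self.K_bufc
        pa[P_BUFSR] = self.Buf_sr
        pa[P_KBUFSR] = self.K_bufsr
        pa[P_KPCA] = self.K_pCa
        pa[P_RTONF] = RTONF
        pa[P_F] = FARADAY
        # Cm/(V_c F): converts pA/pF to mM/ms for the bulk cytoplasm
        pa[P_CONVCONC] = self.C_m * 1e-3 / (self.V_c * FARADAY)
        pa[P_VCOVERVSR] = self.V_c / self.V_sr
        pa[P_CM] = self.C_m
        return pa

    def with_overrides(self, **kwargs) -> "MyocyteParams":
        return replace(self, **kwargs)


# Parameter-vector indices (compile-time constants for numba)
(P_GNA, P_GCAL, P_GTO, P_GKS, P_GKR, P_GK1, P_GPCA, P_GPK, P_GBNA, P_GBCA,
 P_PNAK, P_KMK, P_KMNA, P_KNACA, P_KMNAI, P_KMCA, P_KSAT, P_ALPHA, P_GAMMA,
 P_NAO, P_KO, P_CAO, P_PKNA, P_AREL, P_BREL, P_CREL, P_VMAXUP, P_KUP,
 P_VLEAK, P_TAUG, P_TAUFCA, P_BUFC, P_KBUFC, P_BUFSR, P_KBUFSR, P_KPCA,
 P_RTONF, P_F, P_CONVCONC, P_VCOVERVSR, P_CM) = range(41)
N_PARAMS = 41

# State-vector layout (17 variables)
STATE_NAMES = (
    "V_m", "m", "h", "j", "d", "f", "fCa", "r", "s",
    "xr1", "xr2", "xs", "g", "Na_i", "K_i", "Ca_i", "Ca_SR",
)
(IV, IM, IH, IJ, ID, IF, IFCA, IR, IS,
 IXR1, IXR2, IXS, IG, INAI, IKI, ICAI, ICASR) = range(17)
N_STATE = 17

#: Published TNNP-2004 epicardial initial conditions (quiescent cell).
INITIAL_STATE = np.array([
    -86.2,   # V_m
    0.0,     # m
    0.75,    # h
    0.75,    # j
    0.0,     # d
    1.0,     # f
    1.0,     # fCa
    0.0,     # r
    1.0,     # s
    0.0,     # xr1
    1.0,     # xr2
    0.0,     # xs
    1.0,     # g
    11.6,    # Na_i, mM
    138.3,   # K_i, mM
    2.0e-4,  # Ca_i, mM
    0.2,     # Ca_SR, mM
], dtype=np.float64)

GATE_NAMES = ("m", "h", "j", "d", "f", "r", "s", "xr1", "xr2", "xs")

CURRENT_NAMES = (
    "I_Na", "I_CaL", "I_to", "I_Ks", "I_Kr", "I_K1",
    "I_NaCa", "I_NaK", "I_pCa", "I_pK", "I_bNa", "I_bCa",
)


@dataclass(frozen=True)
class FibroblastParams:
    """Passive (RC) fibroblast: capacitance, conductance, resting potential."""

    C_f: float = 6.3  # pF
    G_f: float = 4.0  # nS
    E_f: float = -49.0  # mV

    def __post_init__(self):
        if not self.C_f > 0:
            raise ValueError(f"C_f must be positive, got {self.C_f}")
        if self.G_f < 0:
            raise ValueError(f"G_f must be non-negative, got {self.G_f}")
        if not -100.0 <= self.E_f <= 20.0:
            raise ValueError(
                f"E_f={self.E_f} mV outside the physiological window [-100, 20] mV")

    @property
    def tau(self) -> float:
        """Membrane time constant C_f/G_f in ms (inf for G_f = 0)."""
        return self.C_f / self.G_f if self.G_f > 0 else float("inf")
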