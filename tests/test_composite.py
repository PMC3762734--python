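"""Myocyte-fibroblast composite: the N_f reduction, gap-junction bookkeeping,
AP morphology measurement and the coupling-dependent regimes."""

import math
import warnings

import numpy as np
import pytest

from cardiomf.composite import (CompositeConfig, classify_regime,
                                delta_vs_uncoupled, measure_ap_morphology,
                                run_single_cell, step_composite)
from cardiomf.ionic import MyocyteState, resting_state
from cardiomf.params import INITIAL_STATE, FibroblastParams


def explicit_multifibroblast_vm(n_f, g_j, fib, t_end, dt=0.02):
    """Oracle: integrate the myocyte with n_f *separate* fibroblast ODEs
    (plain Python; identical fibroblasts kept as distinct state variables)."""
    from cardiomf import _model
    from cardiomf.params import MyocyteParams
    pa = MyocyteParams().pack()
    y = INITIAL_STATE.copy()
    vfs = [fib.E_f] * n_f
    out = [y[0]]
    n = int(round(t_end / dt))
    for k in range(n):
        t = k * dt
        istim = -52.0 if 50.0 <= t < 53.0 else 0.0
        igap_total = sum(g_j * (y[0] - vf) for vf in vfs)
        vfs = [vf + dt * (-(fib.G_f * (vf - fib.E_f)) + g_j * (y[0] - vf))
               / fib.C_f for vf in vfs]
        _model.step_cell(y, dt, istim, igap_total / 185.0, pa, _model.GATE_RL)
        out.append(y[0])
    return np.array(out)


class TestNfReduction:
    def test_lumped_run_equals_explicit_fibroblasts(self):
        """The (N_f C_f, N_f G_f, N_f g_j) lumped fibroblast reproduces the
        explicit 3-fibroblast system through an entire AP upstroke."""
        fib = FibroblastParams(C_f=6.3, G_f=4.0, E_f=-29.0)
        vm_oracle = explicit_multifibroblast_vm(3, 8.0, fib, t_end=80.0)
        cfg = CompositeConfig(N_f=3, g_j=8.0, fib=fib)
        res = run_single_cell(cfg, t_end=80.0)
        assert np.abs(res.V_m - vm_oracle).max() < 1e-6

    def test_equivalent_parameterizations_identical(self):
        """(N_f=4, g_j=2) with unit fibroblasts == (N_f=1, g_j=8) with the
        4-fold lumped fibroblast, bitwise."""
        a = CompositeConfig(N_f=4, g_j=2.0,
                            fib=FibroblastParams(6.3, 4.0, -29.0))
        b = CompositeConfig(N_f=1, g_j=8.0,
                            fib=FibroblastParams(25.2, 16.0, -29.0))
        ra = run_single_cell(a, t_end=300.0)
        rb = run_single_cell(b, t_end=300.0)
        assert np.array_equal(ra.V_m, rb.V_m)

    def test_aggregate_conductance(self):
        cfg = CompositeConfig(N_f=5, g_j=1.6)
        assert cfg.G_gap == pytest.approx(8.0)


class TestGapJunction:
    def test_zero_driving_force_decouples(self):
        cfg = CompositeConfig(N_f=1, g_j=8.0,
                              fib=FibroblastParams(6.3, 4.0, -49.0))
        m = resting_state()
        m2, vf, igap = step_composite(m, m.V_m, cfg, dt=0.02)
        assert igap == 0.0

    def test_gap_current_arithmetic_and_sign(self):
        # G_gap = 8 nS, V_m = -84, V_f = -24 -> I_gap = -480 pA: the
        # depolarized fibroblast sources current into the myocyte
        cfg = CompositeConfig(N_f=1, g_j=8.0,
                              fib=FibroblastParams(6.3, 4.0, -24.0))
        m = resting_state()
        m.V_m = -84.0
        _, _, igap = step_composite(m, -24.0, cfg, dt=0.02)
        assert igap == pytest.approx(-480.0)

    def test_junction_charge_conservation(self):
        """The fibroblast receives exactly the current the myocyte loses."""
        cfg = CompositeConfig(N_f=1, g_j=8.0,
                              fib=FibroblastParams(6.3, 4.0, -49.0))
        m = resting_state()
        vf0 = -60.0
        _, vf1, igap = step_composite(m, vf0, cfg, dt=0.02)
        # fibroblast-side update with the opposite-sign junction current
        expected = vf0 + 0.02 * (-(4.0 * (vf0 + 49.0)) + igap) / 6.3
        assert vf1 == pytest.approx(expected, abs=1e-12)


class TestMorphology:
    def test_piecewise_linear_ap_measured_exactly(self):
        """Synthetic triangle AP with known vertices: every metric has a
        closed form."""
        dt = 0.1
        t = np.arange(0.0, 400.0, dt)
        v = np.full_like(t, -80.0)
        up0, up1 = 50.0, 52.0      # upstroke -80 -> 20 mV
        down1 = 300.0              # linear repolarization 20 -> -80 mV
        rise = (t >= up0) & (t < up1)
        v[rise] = -80.0 + (t[rise] - up0) / (up1 - up0) * 100.0
        fall = (t >= up1) & (t < down1)
        v[fall] = 20.0 - (t[fall] - up1) / (down1 - up1) * 100.0
        v[t >= down1] = -80.0
        levels = {70: -50.0, 80: -60.0, 90: -70.0}
        m = measure_ap_morphology(t, v, level_voltages=levels)
        t_up = t[np.argmax(np.diff(v))]
        for p, lvl in levels.items():
            # crossing time of the linear repolarization segment
            t_cross = up1 + (20.0 - lvl) / 100.0 * (down1 - up1)
            assert getattr(m, f"APD{p}") == pytest.approx(t_cross - t_up,
                                                          abs=dt)
        assert m.V_max == pytest.approx(20.0, abs=0.5)
        assert m.V_rest == pytest.approx(-80.0)
        assert m.dVdt_max == pytest.approx(100.0 / (up1 - up0), rel=0.05)

    def test_flat_trace_reports_undefined_apds(self):
        t = np.arange(0.0, 100.0, 0.1)
        v = np.full_like(t, -86.0)
        m = measure_ap_morphology(t, v)
        assert math.isnan(m.APD90) and m.regime == "excitable"

    def test_apd_ordering_and_rest_bounds(self):
        cfg = CompositeConfig(N_f=0)
        r = run_single_cell(cfg, t_end=2000.0)
        m = measure_ap_morphology(r.t, r.V_m, search_from=50.0)
        assert m.APD70 <= m.APD80 <= m.APD90
        assert m.V_rest <= m.V_notch <= m.V_max
        assert m.V_plateau <= m.V_max


@pytest.fixture(scope="module")
def sweep():
    out = {}
    for ef in (-9.0, -39.0):
        for gg in (0.0, 4.0, 8.0):
            cfg = CompositeConfig(N_f=1, g_j=gg,
                                  fib=FibroblastParams(6.3, 4.0, ef))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[(ef, gg)] = delta_vs_uncoupled(cfg)
    return out


class TestCouplingTrends:

    def test_deltas_vanish_when_uncoupled(self, sweep):
        d = sweep[(-9.0, 0.0)]
        assert d.dAPD90 == 0.0 and d.dVdt_max == 0.0 and d.dV_rest == 0.0

    def test_resting_potential_rises_with_coupling(self, sweep):
        for ef in (-9.0, -39.0):
            vals = [sweep[(ef, g)].dV_rest for g in (0.0, 4.0, 8.0)]
            assert vals[0] <= vals[1] <= vals[2]

    def test_upstroke_velocity_falls_with_coupling(self, sweep):
        for ef in (-9.0, -39.0):
            vals = [sweep[(ef, g)].dVdt_max for g in (0.0, 4.0, 8.0)]
            assert vals[0] >= vals[1] >= vals[2]

    def test_apd_sign_structure(self, sweep):
        # depolarized fibroblasts prolong the AP; polarized ones shorten it
        assert sweep[(-9.0, 8.0)].dAPD90 > 0
        assert sweep[(-39.0, 8.0)].dAPD90 < 0
        assert sweep[(-39.0, 4.0)].dAPD90 > sweep[(-39.0, 8.0)].dAPD90

    def test_autorhythmic_composite_detected_and_flagged(self):
        cfg = CompositeConfig(N_f=2, g_j=20.0,
                              fib=FibroblastParams(6.3, 4.0, -9.0),
                              stimulus=())
        r = run_single_cell(cfg, t_end=5000.0, record_every=5)
        assert classify_regime(r.t, r.V_m) == "autorhythmic"

    def test_oscillatory_classification_on_subthreshold_oscillation(self):
        t = np.arange(0.0, 2000.0, 0.5)
        v = -70.0 + 3.0 * np.sin(2 * np.pi * t / 400.0)
        assert classify_regime(t, v) == "oscillatory"
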