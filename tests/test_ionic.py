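"""Single-cell ionic model: resting behavior, current breakdown, the
fibroblast RC element, and excitability."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiomf.composite import CompositeConfig, run_single_cell
from cardiomf.ionic import (MyocyteState, NumericalError, fibroblast_current,
                            fibroblast_relaxation, myocyte_currents,
                            resting_state)
from cardiomf.params import CURRENT_NAMES, FibroblastParams, MyocyteParams
from cardiomf import _model

R, T, F = 8314.472, 310.0, 96485.3415


class TestMyocyteCurrents:
    def test_settled_resting_state_is_a_fixed_point(self):
        st_ = resting_state(settle_ms=5000.0)
        cb = myocyte_currents(st_)
        assert abs(cb.I_ion) < 1e-3  # |dV/dt| < 1e-3 mV/ms at rest

    def test_breakdown_sums_to_total(self):
        st_ = resting_state()
        st_.V_m = -20.0  # arbitrary off-rest point
        cb = myocyte_currents(st_)
        assert cb.I_ion == pytest.approx(
            sum(getattr(cb, n) for n in CURRENT_NAMES), abs=1e-12)

    def test_closed_m_gate_silences_sodium_current(self):
        st_ = resting_state()
        st_.m = 0.0
        assert myocyte_currents(st_).I_Na == 0.0

    def test_sodium_current_matches_independent_formula(self):
        # independent scalar evaluation of I_Na = g_Na m^3 h j (V - E_Na)
        st_ = resting_state()
        st_.V_m = 0.0
        st_.m = 0.9
        cb = myocyte_currents(st_)
        e_na = R * T / F * math.log(140.0 / st_.Na_i)
        expected = 14.838 * 0.9 ** 3 * st_.h * st_.j * (0.0 - e_na)
        assert cb.I_Na == pytest.approx(expected, rel=1e-12)
        assert cb.I_Na < 0 and abs(cb.I_Na) > 50.0  # large inward surge

    def test_nonfinite_state_raises_named_error(self):
        st_ = resting_state()
        st_.Ca_i = float("nan")
        with pytest.raises(NumericalError, match="Ca_i"):
            myocyte_currents(st_)

    def test_gate_bounds_validated(self):
        st_ = resting_state()
        st_.h = 1.7
        with pytest.raises(ValueError, match="h"):
            st_.validate()

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=-100.0, max_value=60.0))
    def test_gate_rates_well_posed(self, V):
        inf, tau = _model.gate_rates(V)
        assert np.all(inf >= 0.0) and np.all(inf <= 1.0)
        assert np.all(tau > 0.0)


class TestFibroblast:
    def test_zero_driving_force(self):
        p = FibroblastParams(C_f=6.3, G_f=4.0, E_f=-49.0)
        assert fibroblast_current(-49.0, p) == 0.0

    def test_linear_arithmetic(self):
        p = FibroblastParams(C_f=6.3, G_f=4.0, E_f=-49.0)
        assert fibroblast_current(0.0, p) == pytest.approx(196.0)  # pA

    def test_rc_relaxation_matches_closed_form(self):
        # forward-Euler fibroblast vs analytic exponential, dt = 0.02 ms;
        # the Euler error scales as dt/(2 tau), so a mid-range membrane
        # conductance (G_f = 1 nS, tau = 6.3 ms) is used for the 1e-3 bound
        assert FibroblastParams(C_f=6.3, G_f=4.0, E_f=-49.0).tau \
            == pytest.approx(1.575)
        p = FibroblastParams(C_f=6.3, G_f=1.0, E_f=-49.0)
        dt, v0, n = 0.02, 0.0, 1500
        v = v0
        trace = [v]
        for _ in range(n):
            v += dt * (-p.G_f * (v - p.E_f)) / p.C_f
            trace.append(v)
        t = dt * np.arange(n + 1)
        exact = fibroblast_relaxation(v0, t, p)
        rel = np.abs(np.array(trace) - exact) / abs(v0 - p.E_f)
        assert rel.max() < 1e-3

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            FibroblastParams(C_f=-1.0)
        with pytest.raises(ValueError):
            FibroblastParams(E_f=40.0)


class TestExcitability:
    def test_unstimulated_myocyte_holds_resting_potential(self):
        from cardiomf.ionic import resting_state
        cfg = CompositeConfig(N_f=0, stimulus=())
        y0 = resting_state(settle_ms=5000.0).to_array()
        res = run_single_cell(cfg, t_end=1000.0, record_every=50, y0=y0)
        assert np.abs(res.V_m - res.V_m[0]).max() < 0.5

    def test_all_or_none_response(self):
        strong = CompositeConfig(N_f=0, stimulus=((50.0, 3.0, -52.0),))
        weak = CompositeConfig(N_f=0, stimulus=((50.0, 3.0, -0.52),))
        r1 = run_single_cell(strong, t_end=600.0, record_every=10)
        r2 = run_single_cell(weak, t_end=600.0, record_every=10)
        ups1 = int(((r1.V_m[:-1] < 0) & (r1.V_m[1:] >= 0)).sum())
        assert ups1 == 1
        assert r2.V_m.max() < -60.0
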