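"""Spiral protocols on the desk-scale (200x200, quarter-diffusion) domain:
initiation, determinism, tip statistics and period-estimator consistency."""

import numpy as np
import pytest

from cardiomf.analysis import (beat_statistics, rotation_period, track_tip,
                               track_tip_isopotential)
from cardiomf.ionic import NumericalError
from cardiomf.protocols import (SpiralInitProtocol, initiate_spiral,
                                mesh_mask)
from cardiomf.tissue import CouplingConfig, run_tissue

from conftest import make_grid


class TestSpiralFixture:
    def test_one_persistent_tip(self, control_spiral_run):
        """The control spiral holds a single reentrant tip for the whole
        analysis window (every frame has a tip; the typical count is one)."""
        res, dx = control_spiral_run
        traj = track_tip(res.t_snap, res.snap_INa, dx)
        assert (traj.counts >= 1).mean() >= 0.95
        assert int(np.median(traj.counts)) == 1

    def test_period_estimators_agree(self, control_spiral_run):
        """Probe inter-beat interval vs tip revolution time: within 5%."""
        res, dx = control_spiral_run
        bs = beat_statistics(res.probes[:, 0], res.t_probe[1] - res.t_probe[0])
        p_ibi, _ = rotation_period(bs)
        traj = track_tip(res.t_snap, res.snap_INa, dx)
        p_tip, _ = rotation_period(traj)
        assert len(bs.ibi) >= 3
        assert abs(p_tip - p_ibi) / p_ibi < 0.05

    def test_trackers_locate_the_same_core(self, control_spiral_run):
        """The sodium-current tracker and the isopotential cross-check orbit
        the same rotation center (within 3 nodes)."""
        res, dx = control_spiral_run
        a = track_tip(res.t_snap, res.snap_INa, dx)
        b = track_tip_isopotential(res.t_snap, res.snap_Vm, dx)
        _, xa, ya = a.valid()
        _, xb, yb = b.valid()
        assert len(xa) > 20 and len(xb) > 20
        d = np.hypot(xa.mean() - xb.mean(), ya.mean() - yb.mean())
        assert d < 3.0 * dx

    def test_runs_are_deterministic(self, spiral_state):
        state, t0, proto = spiral_state
        coup = CouplingConfig(mode="zero_sided", D=proto.D)
        outs = []
        for _ in range(2):
            g = make_grid(state, t0)
            run_tissue(g, coup, [], t_end=20.0)
            outs.append((g.Vm.copy(), g.Vf.copy()))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])


class TestInitiation:
    def test_s2_during_absolute_refractory_phase_yields_no_spiral(self):
        """An S2 outside the vulnerable window (domain still refractory
        behind the S1 front) produces no wave break: zero tips."""
        from dataclasses import replace
        proto = replace(SpiralInitProtocol.scaled(120), s2_time=150.0,
                        t_init=350.0)
        grid, tips = initiate_spiral(proto)
        assert tips == 0

    def test_missing_wave_raises(self):
        # S2 so late that the S1 wave has left the domain entirely
        from dataclasses import replace
        proto = replace(SpiralInitProtocol.scaled(80), s2_time=700.0,
                        t_init=900.0)
        with pytest.raises(NumericalError, match="wave back"):
            initiate_spiral(proto, verify=False)


class TestControlMesh:
    def test_mesh_geometry(self):
        m = mesh_mask(201, 201, 4)
        # 5 horizontal + 5 vertical one-node lines, minus 25 intersections
        assert m.sum() == 5 * 201 + 5 * 201 - 25
        assert m[0, :].all() and m[50, :].all()
        assert m[25, :].sum() == 5  # off-line rows meet the 5 vertical lines
        with pytest.raises(ValueError):
            mesh_mask(10, 10, 0)
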