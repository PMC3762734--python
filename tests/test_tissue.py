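"""Bilayer tissue: stencil, boundaries, coupling-mode reductions and
conservation properties."""

import numpy as np
import pytest

from cardiomf.ionic import NumericalError
from cardiomf.params import FibroblastParams
from cardiomf.tissue import (BilayerGrid, CouplingConfig, InhomogeneitySpec,
                             StimulusEvent, laplacian_noflux, run_tissue,
                             set_patch, stability_limit)


class TestLaplacian:
    def test_constant_field_has_zero_laplacian(self):
        f = np.full((12, 15), 3.7)
        assert np.all(laplacian_noflux(f, 0.225) == 0.0)

    def test_interior_spike_stencil_weights(self):
        f = np.zeros((9, 9))
        f[4, 4] = 1.0
        dx = 0.5
        lap = laplacian_noflux(f, dx)
        assert lap[4, 4] == pytest.approx(-4.0 / dx ** 2)
        for i, j in ((3, 4), (5, 4), (4, 3), (4, 5)):
            assert lap[i, j] == pytest.approx(1.0 / dx ** 2)

    def test_pure_diffusion_conserves_mass(self):
        """No-flux diffusion (reactions off) conserves the field integral to
        relative 1e-10 over 1000 steps."""
        rng = np.random.default_rng(7)
        f = rng.normal(size=(20, 24))
        total0 = f.sum()
        alpha = 0.2  # D dt / dx^2, stable
        for _ in range(1000):
            p = np.pad(f, 1, mode="edge")
            f = f + alpha * (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2]
                             + p[1:-1, 2:] - 4.0 * f)
        assert abs(f.sum() - total0) / abs(total0) < 1e-10

    def test_radial_pulse_decays_without_loss(self):
        f = np.zeros((21, 21))
        f[10, 10] = 100.0
        total0 = f.sum()
        for _ in range(500):
            f = f + 0.2 * laplacian_noflux(f, 1.0)
        assert f.max() < 1.0  # spread out
        assert f.sum() == pytest.approx(total0, rel=1e-10)


def _small_grid(fib_on=True, G_gap=0.0, n=16):
    mask = np.ones((n, n), np.uint8) if fib_on else np.zeros((n, n), np.uint8)
    g = BilayerGrid(n, n, dx=0.225, fib=FibroblastParams(6.3, 4.0, -49.0),
                    fib_mask=mask, G_gap=G_gap)
    return g


def _poke(grid):
    return StimulusEvent.rectangle((grid.ny, grid.nx), 1.0, 3.0, -52.0,
                                   rows=slice(0, 4), cols=slice(0, 4))


class TestCouplingModes:
    def test_zero_gap_bitwise_equals_myocyte_only_control(self):
        ga = _small_grid(fib_on=True, G_gap=0.0)
        gb = _small_grid(fib_on=False)
        coup = CouplingConfig(mode="zero_sided", D=0.00154)
        run_tissue(ga, coup, [_poke(ga)], t_end=30.0)
        run_tissue(gb, coup, [_poke(gb)], t_end=30.0)
        assert np.array_equal(ga.Vm, gb.Vm)
        assert np.array_equal(ga.G, gb.G)

    def test_two_sided_with_zero_cross_equals_one_sided(self):
        ga = _small_grid(G_gap=4.0)
        gb = _small_grid(G_gap=4.0)
        one = CouplingConfig(mode="one_sided", D=0.00154, G_ff=3.0)
        two = CouplingConfig(mode="two_sided", D=0.00154, G_ff=3.0,
                             G_mf=0.0, G_fm=0.0)
        run_tissue(ga, one, [_poke(ga)], t_end=30.0)
        run_tissue(gb, two, [_poke(gb)], t_end=30.0)
        assert np.array_equal(ga.Vm, gb.Vm)
        assert np.array_equal(ga.Vf, gb.Vf)

    def test_cross_coupling_currents_conserve_charge(self):
        """One step with and without the layer couplings: the coupling terms
        move charge between layers without creating any."""
        rng = np.random.default_rng(3)
        base = _small_grid(G_gap=5.0)
        base.Vf += rng.uniform(-20.0, 20.0, base.Vf.shape)
        on = base.copy()
        off = base.copy()
        off.ggap[:] = 0.0
        coup_on = CouplingConfig(mode="two_sided", D=0.0, G_ff=3.0,
                                 G_mf=2.0, G_fm=2.0,
                                 fib=FibroblastParams(6.3, 0.0, -49.0))
        coup_off = CouplingConfig(mode="zero_sided", D=0.0,
                                  fib=FibroblastParams(6.3, 0.0, -49.0))
        dt = 0.02
        run_tissue(on, coup_on, [], t_end=dt, dt=dt)
        run_tissue(off, coup_off, [], t_end=dt, dt=dt)
        # G_f = 0 and D = 0, so the only difference is junctional exchange
        dq_m = 185.0 * (on.Vm - off.Vm).sum()
        dq_f = 6.3 * (on.Vf - off.Vf).sum()
        scale = 185.0 * np.abs(on.Vm).sum()
        assert abs(dq_m + dq_f) / scale < 1e-12

    def test_coupling_mode_invariants_enforced(self):
        with pytest.raises(ValueError):
            CouplingConfig(mode="zero_sided", G_ff=1.0)
        with pytest.raises(ValueError):
            CouplingConfig(mode="one_sided", G_mf=1.0, G_fm=1.0)
        with pytest.raises(ValueError):
            CouplingConfig(mode="two_sided", G_mf=1.0, G_fm=0.0)
        with pytest.raises(ValueError):
            CouplingConfig(mode="two_sided", G_mf=1.0, G_fm=2.0)


class TestNumerics:
    def test_stability_bound_enforced(self):
        g = _small_grid()
        coup = CouplingConfig(mode="zero_sided", D=0.00154)
        with pytest.raises(ValueError, match="stability"):
            run_tissue(g, coup, [], t_end=1.0, dt=0.2)
        assert stability_limit(0.00154, 0.225) == pytest.approx(0.0822, rel=1e-3)

    def test_nonfinite_field_aborts_with_location(self):
        g = _small_grid()
        g.Vm[3, 5] = np.inf
        coup = CouplingConfig(mode="zero_sided", D=0.00154)
        with pytest.raises(NumericalError, match=r"i=3, j=5"):
            run_tissue(g, coup, [], t_end=1.0)


class TestPatch:
    def test_patch_node_geometry(self):
        g = BilayerGrid(420, 420, dx=0.225)
        spec = InhomogeneitySpec(corner=(56.25, 56.25), side=33.75,
                                 G_gap=8.0)
        set_patch(g, spec)
        i0, j0, n = spec.node_box(g.dx)
        assert (i0, j0, n) == (250, 250, 150)
        assert g.fib_mask.sum() == 150 * 150
        assert g.fib_mask[250, 250] == 1 and g.fib_mask[249, 250] == 0
        assert g.ggap[300, 300] == 8.0 and g.ggap[0, 0] == 0.0

    def test_zero_side_patch_leaves_grid_unchanged(self):
        g = BilayerGrid(20, 20, dx=0.225)
        mask0 = g.fib_mask.copy()
        set_patch(g, InhomogeneitySpec(corner=(1.0, 1.0), side=0.0))
        assert np.array_equal(g.fib_mask, mask0)

    def test_out_of_bounds_patch_rejected(self):
        g = BilayerGrid(50, 50, dx=0.225)
        with pytest.raises(ValueError, match="exceeds"):
            set_patch(g, InhomogeneitySpec(corner=(9.0, 9.0), side=9.0))
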