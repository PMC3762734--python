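"""Analysis suite on constructed inputs with closed-form answers."""

import math

import numpy as np
import pytest

from cardiomf.analysis import (BeatSeries, beat_statistics,
                               classify_inhomogeneity_dynamics, measure_cv,
                               measure_cv_probes, rotation_period, track_tip)
from cardiomf.io import generate_fixture


class TestConductionVelocity:
    def test_constructed_front_one_node_per_frame(self):
        """A front advancing one node per frame has CV = dx/dt exactly."""
        n, ny, nx, dx, dtf = 32, 5, 30, 0.25, 1.0
        t = dtf * np.arange(n)
        stack = np.full((n, ny, nx), -85.0, np.float32)
        for k in range(n):
            stack[k, :, :k + 1] = 20.0
        r = measure_cv(t, stack, dx)
        assert not r.failed
        assert r.cv == pytest.approx(dx / dtf * 100.0, rel=1e-6)

    def test_conduction_failure_when_far_probe_silent(self):
        t = np.arange(50.0)
        v1 = np.where(t > 5, 20.0, -85.0)
        v2 = np.full_like(t, -85.0)
        r = measure_cv_probes(t, v1, v2, 10.0)
        assert r.failed and math.isnan(r.t_second)

    def test_simultaneous_crossing_flagged_as_nonpropagating(self):
        t = np.arange(50.0)
        v = np.where(t > 5, 20.0, -85.0)
        r = measure_cv_probes(t, v, np.roll(v, 1), 50.0)
        assert r.failed  # implied velocity far beyond plausibility bounds


class TestTipTracking:
    def test_synthetic_rotor_core_recovered(self):
        arch = generate_fixture("synthetic-rotor-field", size=80, frames=10)
        core = arch.config["core"]
        traj = track_tip(arch.t, arch.fields["I_Na"], arch.dx, threshold=100.0)
        t, x, y = traj.valid()
        assert len(x) >= 5  # tip found in most frames
        err = np.hypot(x - core[0], y - core[1])
        assert np.median(err) < 2.5 * arch.dx

    def test_plane_wave_has_no_tip(self):
        arch = generate_fixture("plane-wave-strip", size=80, frames=8)
        traj = track_tip(arch.t, arch.fields["I_Na"], arch.dx)
        assert traj.counts.sum() == 0

    def test_quiescent_frames_yield_empty_trajectory(self):
        t = 8.0 * np.arange(5)
        stack = np.zeros((5, 30, 30), np.float32)
        traj = track_tip(t, stack, 0.225, threshold=50.0)
        assert np.all(np.isnan(traj.x))


class TestBeats:
    def test_sinusoid_peak_frequency(self):
        f0 = 4.0  # Hz
        dts = 1.0  # ms
        t = np.arange(0.0, 4000.0, dts)
        v = -60.0 + 10.0 * np.sin(2 * np.pi * f0 * t * 1e-3)
        bs = beat_statistics(v, dts)
        assert bs.peak_frequency == pytest.approx(f0, abs=1.0 / 4.0)

    def test_frequency_resolution(self):
        # 400000 samples at 0.02 ms -> 1/(N dt) = 0.125 Hz
        bs = beat_statistics(np.zeros(400000), 0.02)
        assert bs.freq[1] == pytest.approx(0.125)

    def test_known_upstroke_train(self):
        dts = 0.5
        t = np.arange(0.0, 2000.0, dts)
        v = np.full_like(t, -80.0)
        for t0 in (100.0, 350.0, 600.0, 850.0):
            m = (t >= t0) & (t < t0 + 120.0)
            v[m] = 20.0
        bs = beat_statistics(v, dts)
        assert len(bs.upstrokes) == 4
        assert np.allclose(bs.ibi, 250.0, atol=dts)
        # fundamental line vs mean-ibi consistency, within one bin
        assert bs.peak_frequency == pytest.approx(1000.0 / bs.mean_ibi,
                                                  abs=bs.freq[1])

    def test_rotation_period_from_constructed_rotor(self):
        period = 180.0
        t = np.arange(0.0, 1000.0, 8.0)
        ang = 2 * np.pi * t / period
        from cardiomf.analysis import TipTrajectory
        traj = TipTrajectory(t, 10 + 3 * np.cos(ang), 10 + 3 * np.sin(ang),
                             np.ones(t.size, int))
        p, s = rotation_period(traj)
        assert p == pytest.approx(period, abs=8.0)

    def test_rotation_period_from_beats(self):
        bs = BeatSeries(np.array([0.0, 250.0, 500.0]),
                        np.array([250.0, 250.0]),
                        np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        p, s = rotation_period(bs)
        assert p == 250.0 and s == 0.0


class TestClassification:
    def _beats(self, ibis, n=4096, dts=1.0, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n) * dts
        v = np.full(n, -80.0)
        t0 = 50.0
        ups = []
        for ib in ibis:
            ups.append(t0)
            k = int(t0 / dts)
            v[k:k + 60] = 10.0
            t0 += ib + jitter * rng.standard_normal()
        return beat_statistics(v, dts)

    def test_homogeneous_periodic_not_anchored(self):
        bs = self._beats([250.0] * 12)
        out = classify_inhomogeneity_dynamics(bs, bs)
        assert out["inside"] == "periodic" and out["outside"] == "periodic"
        assert out["anchored"] is False

    def test_irregular_beats_nonperiodic(self):
        rng = np.random.default_rng(1)
        ibis = rng.uniform(150.0, 420.0, size=10)
        bs = self._beats(list(ibis))
        out = classify_inhomogeneity_dynamics(bs, bs)
        assert out["inside"] == "nonperiodic"

    def test_anchoring_from_tip_centroid(self):
        from cardiomf.analysis import TipTrajectory
        t = np.arange(0.0, 400.0, 8.0)
        traj = TipTrajectory(t, 12 + np.cos(t / 30), 12 + np.sin(t / 30),
                             np.ones(t.size, int))
        bs = self._beats([250.0] * 12)
        out = classify_inhomogeneity_dynamics(bs, bs, traj,
                                              (10.0, 10.0, 14.0, 14.0))
        assert out["anchored"] is True
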