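"""Agent engine: diffusion statistics, binding rules, motor stepping,
boundaries, determinism, and the spatial-hash contract."""

import numpy as np
import pytest

from mtseq import _kernels
from mtseq.engine import (KineticParams, run_agent_sim, run_maturation_sim,
                          uniform_positions_in_sphere)
from mtseq.geometry import MicrotubuleSet, MaturationSchedule, build_aster

BIND_THRESHOLD = 0.0125 + 0.005 + 0.0008  # R_M + r + d0 = 18.3 nm


def _empty_mts():
    return MicrotubuleSet(np.empty((0, 3)), np.empty((0, 3)), np.empty(0, int),
                          [[0.0, 0.0, 0.0]])


class TestFreeDiffusion:
    def test_zero_diffusion_keeps_positions(self):
        kin = KineticParams(D_C=0.0, V=0.0)
        init = np.array([[1.0, 2.0, 3.0], [0.0, -4.0, 0.5]])
        res = run_agent_sim(_empty_mts(), kin, init, 0.01, seed=0,
                            snapshot_stride=10)
        np.testing.assert_array_equal(res.positions[-1], init)

    def test_msd_matches_einstein_relation(self):
        # 6*D*t for 3D Brownian motion, far from any boundary
        n, t, D = 10_000, 0.1, 2.0
        kin = KineticParams(D_C=D, V=0.0)
        init = np.zeros((n, 3))
        res = run_agent_sim(_empty_mts(), kin, init, t, seed=7,
                            snapshot_stride=1000, cell_radius=1e6,
                            binding_enabled=False)
        msd = (res.positions[-1] ** 2).sum(axis=1).mean()
        expect = 6 * D * t
        # var(|dx|^2) = 6 (2Dt)^2 for a 3D Gaussian; allow 3 sigma of the mean
        sigma = np.sqrt(6.0) * 2 * D * t / np.sqrt(n)
        assert abs(msd - expect) < 3 * sigma

    def test_reflecting_cell_boundary(self):
        kin = KineticParams(D_C=2.0)
        init = uniform_positions_in_sphere(100, 9.9, np.random.default_rng(0))
        res = run_agent_sim(_empty_mts(), kin, init, 1.0, seed=1,
                            snapshot_stride=1, cell_radius=10.0)
        r = np.linalg.norm(res.positions, axis=2)
        assert r.max() <= 10.0 + 1e-9  # one million particle-steps, all inside

    def test_pure_diffusion_equilibrium_is_uniform(self):
        # with no filaments the long-time radial distribution is uniform in
        # the sphere: chi-square over equal-volume shells
        n = 10_000
        kin = KineticParams(D_C=2.0)
        init = uniform_positions_in_sphere(n, 10.0, np.random.default_rng(3))
        res = run_agent_sim(_empty_mts(), kin, init, 0.5, seed=3,
                            snapshot_stride=5000, cell_radius=10.0)
        r = np.linalg.norm(res.positions[-1], axis=1)
        shells = 10.0 * (np.arange(11) / 10.0) ** (1 / 3)
        counts, _ = np.histogram(r, bins=shells)
        chi2 = ((counts - n / 10) ** 2 / (n / 10)).sum()
        assert chi2 < 27.9  # chi2_{0.999, df=9}


class TestBinding:
    def test_binds_exactly_at_threshold(self, single_mt):
        kin = KineticParams(D_C=0.0, V=0.0)
        init = np.array([[BIND_THRESHOLD, 0.0, 0.0]])
        res = run_agent_sim(single_mt, kin, init, 0.001, seed=0, snapshot_stride=1)
        assert res.states[-1][0] == 1

    def test_stays_free_beyond_threshold(self, single_mt):
        kin = KineticParams(D_C=0.0, V=0.0)
        init = np.array([[0.0200, 0.0, 0.0]])
        res = run_agent_sim(single_mt, kin, init, 0.001, seed=0, snapshot_stride=1)
        assert (res.states == 0).all()

    def test_no_microtubules_stays_free(self):
        kin = KineticParams()
        res = run_agent_sim(_empty_mts(), kin, np.zeros((5, 3)), 0.01, seed=0,
                            snapshot_stride=10)
        assert (res.states == 0).all()

    def test_bound_position_is_axis_point(self, single_mt):
        kin = KineticParams(D_C=0.0, V=0.0, D_M=0.0, k=0.0)
        init = np.array([[0.01, 0.0, 1.25]])
        res = run_agent_sim(single_mt, kin, init, 0.001, seed=0, snapshot_stride=1)
        np.testing.assert_allclose(res.positions[-1][0], [0.0, 0.0, 1.25], atol=1e-12)

    def test_tie_break_lowest_id(self):
        # two identical filaments: the lower id wins
        mts = MicrotubuleSet(
            minus=[[0, 0, -5], [0, 0, -5]], plus=[[0, 0, 5], [0, 0, 5]],
            pole_id=[0, 1], pole_positions=[[0, 0, -5], [0, 0, 5]])
        kin = KineticParams(D_C=0.0, V=0.0, k=0.0)
        res = run_agent_sim(mts, kin, np.array([[0.005, 0.0, 0.0]]), 0.001,
                            seed=0, snapshot_stride=1)
        assert res.host_pole[-1][0] == 0


class TestBoundMotion:
    def test_dynein_walks_toward_minus_end(self, single_mt):
        # D_M = 0, k = 0: arc length decreases by exactly V*dt per step
        kin = KineticParams(D_C=0.0, D_M=0.0, k=0.0, V=1.0)
        init = np.array([[0.0, 0.0, 1.0]])  # binds at arc 6.0
        res = run_agent_sim(single_mt, kin, init, 0.01, seed=0, snapshot_stride=1)
        z = res.positions[:, 0, 2]
        steps = np.diff(z)
        np.testing.assert_allclose(steps[1:], -1e-4, atol=1e-12)

    def test_kinesin_walks_toward_plus_end(self, single_mt):
        kin = KineticParams(D_C=0.0, D_M=0.0, k=0.0, V=1.0)
        init = np.array([[0.0, 0.0, 1.0]])
        res = run_agent_sim(single_mt, kin, init, 0.01, seed=0,
                            snapshot_stride=1, motor="kinesin")
        z = res.positions[:, 0, 2]
        assert z[-1] > z[1]

    def test_zero_k_never_unbinds(self, single_mt):
        # with k = 0 a dynein that binds stays bound (some walkers may never
        # find the single filament; none may lose it)
        kin = KineticParams(k=0.0, D_C=0.5)
        init = np.array([[0.01, 0.0, 0.0]] * 10)
        res = run_agent_sim(single_mt, kin, init, 0.5, seed=2, snapshot_stride=1000)
        transitions = np.diff(res.states.astype(int), axis=0)
        assert (transitions >= 0).all()
        assert (res.states[-1] == 1).any()

    def test_unbinding_rate_matches_k(self, calibration_point_5nm):
        # mean bound interval must equal 1/k_off within 3 sigma (binomial)
        pt = calibration_point_5nm
        se = 1.0 / np.sqrt(pt.n_bind_events)
        assert abs(pt.mean_bound_interval - 1.0) < 3 * se

    def test_minus_end_reflection_keeps_particle_on_filament(self, single_mt):
        kin = KineticParams(D_C=0.0, D_M=0.0, k=0.0, V=1.0)
        init = np.array([[0.0, 0.0, -4.9]])  # binds near the minus end
        res = run_agent_sim(single_mt, kin, init, 0.5, seed=0, snapshot_stride=1000)
        assert (res.states[-1] == 1).all()
        # parked at the minus end (reflecting pole), not expelled
        assert res.positions[-1][0, 2] == pytest.approx(-5.0, abs=1e-3)

    def test_plus_end_detach_policy(self, single_mt):
        kin = KineticParams(D_C=0.0, D_M=0.0, k=0.0, V=1.0)
        init = np.array([[0.0, 0.0, 4.9995]])
        res = run_agent_sim(single_mt, kin, init, 0.01, seed=0,
                            snapshot_stride=1, motor="kinesin")
        # walked off the plus end at least once (it rebinds immediately with
        # D_C = 0 since it is released on the axis) and never passes the tip
        assert (res.states == 0).any()
        assert res.positions[:, 0, 2].max() <= 5.0 + 1e-12

    def test_plus_end_reflect_policy(self, single_mt):
        kin = KineticParams(D_C=0.0, D_M=0.0, k=0.0, V=1.0,
                            plus_end_policy="reflect")
        init = np.array([[0.0, 0.0, 4.9995]])
        res = run_agent_sim(single_mt, kin, init, 0.01, seed=0,
                            snapshot_stride=1, motor="kinesin")
        assert res.states[-1][0] == 1
        assert res.positions[-1][0, 2] <= 5.0 + 1e-12


class TestRunContract:
    def test_particle_count_conserved(self, fig1_equilibrium):
        results, _ = fig1_equilibrium
        for res in results.values():
            assert res.positions.shape[1] == 200
            assert np.isfinite(res.positions).all()
            assert set(np.unique(res.states)) <= {0, 1}

    def test_outside_cell_rejected(self):
        with pytest.raises(ValueError):
            run_agent_sim(_empty_mts(), KineticParams(), np.array([[20.0, 0, 0]]),
                          0.01, seed=0)

    def test_unknown_motor_rejected(self):
        with pytest.raises(ValueError):
            run_agent_sim(_empty_mts(), KineticParams(), np.zeros((1, 3)),
                          0.01, seed=0, motor="myosin")

    def test_seeded_determinism(self, small_spindle):
        kin = KineticParams()
        init = uniform_positions_in_sphere(50, 10.0, np.random.default_rng(5))
        a = run_agent_sim(small_spindle, kin, init, 0.2, seed=11, snapshot_stride=100)
        b = run_agent_sim(small_spindle, kin, init, 0.2, seed=11, snapshot_stride=100)
        c = run_agent_sim(small_spindle, kin, init, 0.2, seed=12, snapshot_stride=100)
        assert a.snapshot_hash() == b.snapshot_hash()
        assert a.snapshot_hash() != c.snapshot_hash()

    def test_dynein_drift_is_toward_minus_ends(self, fig1_equilibrium):
        # bound dyneins end up at minus ends: mean distance to the poles of
        # bound particles is near the nucleation radius
        results, _ = fig1_equilibrium
        res = next(iter(results.values()))
        bound = res.states[-1] == 1
        pos = res.positions[-1][bound]
        d = np.linalg.norm(pos[:, None, :] - res.pole_positions[None], axis=2).min(axis=1)
        assert d.mean() < 1.5

    def test_dt_warning_when_enlarged(self):
        with pytest.warns(UserWarning):
            KineticParams(dt=1e-3)


class TestSpatialHashContract:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        mts = build_aster((0, 0, 0), 60, seed=4)
        origin = np.full(3, -10.5)
        dims = np.array([84, 84, 84], np.int64)
        h = 0.25
        start, entries = _kernels.build_segment_hash(mts.minus, mts.plus,
                                                     origin, h, dims)
        active = np.ones(len(mts), bool)
        pts = uniform_positions_in_sphere(300, 10.0, rng)
        for p in pts:
            jh, dh, th = _kernels.nearest_segment(
                p[0], p[1], p[2], mts.minus, mts.direction, mts.length,
                active, origin, h, dims, start, entries)
            jb, db, tb = _kernels.nearest_segment_brute(
                p[0], p[1], p[2], mts.minus, mts.direction, mts.length, active)
            # the hash query must agree whenever the true distance is within
            # one grid cell (the binding regime); beyond that it may miss
            if db <= h:
                assert jh == jb
                assert dh == pytest.approx(db, abs=1e-12)
                assert th == pytest.approx(tb, abs=1e-12)


class TestMaturationRun:
    def test_growth_and_conservation(self):
        sched = MaturationSchedule(
            count_schedules=[([0.0, 2.0], [20, 80]), ([0.0, 2.0], [5, 5])],
            trajectories=[([0.0, 2.0], [[-5, 0, 0], [-5, 0, 0]]),
                          ([0.0, 2.0], [[-4, 0, 0], [4, 0, 0]])],
            seed=1)
        kin = KineticParams()
        init = uniform_positions_in_sphere(30, 10.0, np.random.default_rng(9))
        res = run_maturation_sim(sched, kin, init, 2.0, seed=1,
                                 snapshot_stride=1000, rebuild_interval=0.5)
        assert res.positions.shape[1] == 30
        assert np.isfinite(res.positions).all()
        r = np.linalg.norm(res.positions, axis=2)
        assert r.max() <= 10.0 + 1e-6
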