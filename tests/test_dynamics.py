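"""Integrators, thermostat statistics, minimization, trajectory plumbing."""

import numpy as np
import pytest

from ravmd.averaging import AveragingSchedule
from ravmd.dynamics import (
    ACC,
    KB,
    EnsembleState,
    langevin_step,
    maxwell_velocities,
    minimize,
    nve_step,
    run_trajectory,
)
from ravmd.geometry import CGChain
from ravmd.potential import PotentialConfig


def _free_force(coords, step):
    return np.zeros(coords.shape[0]), np.zeros_like(coords)


def _state(coords, vels, masses=1.0, temps=300.0):
    m = np.broadcast_to(np.asarray(masses, float), (coords.shape[1],)).copy()
    t = np.full(coords.shape[0], float(temps))
    return EnsembleState(coords=coords.copy(), velocities=vels.copy(), masses=m,
                         temperatures=t)


class TestNveStep:
    def test_free_particle_straight_line(self):
        coords = np.zeros((1, 2, 3))
        vels = np.array([[[0.01, 0.0, 0.0], [0.0, -0.02, 0.0]]])
        st = _state(coords, vels)
        ek0 = st.kinetic_energy()[0]
        for _ in range(100):
            nve_step(st, _free_force, dt=1.0)
        assert np.allclose(st.coords, coords + 100.0 * vels)
        assert st.kinetic_energy()[0] == pytest.approx(ek0, rel=1e-14)

    def test_harmonic_oscillator_energy_bounded_no_drift(self):
        """1D oscillator: VV energy error stays O(dt^2) over 1e5 steps."""
        k, m, dt = 1.0, 1.0, 0.05 / np.sqrt(ACC)  # omega*dt ~ 0.05

        def force(c, step):
            e = 0.5 * k * c[0, 0, 0] ** 2
            f = np.zeros_like(c)
            f[0, 0, 0] = -k * c[0, 0, 0]
            return np.array([e]), f

        st = _state(np.zeros((1, 1, 3)), np.zeros((1, 1, 3)), masses=m)
        st.coords[0, 0, 0] = 1.0
        energies = []
        epot, forces = force(st.coords, 0)
        for _ in range(100_000):
            epot, forces = nve_step(st, force, dt, forces=forces)
            energies.append(epot[0] + st.kinetic_energy()[0])
        energies = np.asarray(energies)
        e0 = 0.5 * k  # exact initial total energy
        assert np.abs(energies - e0).max() / e0 < (0.05**2)  # O((w dt)^2)
        first, last = energies[:1000].mean(), energies[-1000:].mean()
        assert abs(last - first) / e0 < 1e-5  # no secular drift


class TestLangevinStep:
    def test_zero_friction_identical_to_nve(self, chain10):
        from ravmd.potential import energy_and_forces

        cfg = PotentialConfig()

        def force(c, step):
            return energy_and_forces(c, cfg)

        rng = np.random.default_rng(0)
        vels = 0.001 * rng.standard_normal((1, 10, 3))
        st_a = _state(chain10.ca[None], vels, masses=110.0)
        st_b = _state(chain10.ca[None], vels, masses=110.0)
        for _ in range(50):
            nve_step(st_a, force, 2.0)
            langevin_step(st_b, force, 2.0, friction=0.0,
                          rng=np.random.default_rng(1))
        assert np.array_equal(st_a.coords, st_b.coords)
        assert np.array_equal(st_a.velocities, st_b.velocities)

    def test_free_particle_equipartition(self):
        """Long OU relaxation reaches kT/2 per degree of freedom within 3 sigma."""
        temp, mass, friction, dt = 300.0, 110.0, 0.05, 2.0
        rng = np.random.default_rng(12)
        st = _state(np.zeros((4, 5, 3)), np.zeros((4, 5, 3)), masses=mass,
                    temps=temp)
        samples = []
        for i in range(4000):
            langevin_step(st, _free_force, dt, friction, rng)
            if i > 500:
                samples.append(st.kinetic_energy().sum())
        ndof = 4 * 5 * 3
        mean_ke_dof = np.mean(samples) / ndof
        expected = 0.5 * KB * temp
        stderr = np.std(samples) / np.sqrt(len(samples) / 50) / ndof  # rough ESS
        assert abs(mean_ke_dof - expected) < 3 * stderr + 1e-4

    def test_same_seed_identical_trajectory(self, chain10):
        from ravmd.potential import energy_and_forces

        cfg = PotentialConfig()

        def force(c, step):
            return energy_and_forces(c, cfg)

        outs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            st = _state(chain10.ca[None], np.zeros((1, 10, 3)), masses=110.0)
            for _ in range(30):
                langevin_step(st, force, 2.0, 0.01, rng)
            outs.append(st.coords.copy())
        assert np.array_equal(outs[0], outs[1])


class TestMinimize:
    def test_start_at_minimum_is_noop(self):
        cfg = PotentialConfig(k_theta=0.0, eps_rep=0.0)
        coords = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0.0, 0.1]])
        out, info = minimize(coords, cfg)
        assert info["energy"] == pytest.approx(0.0, abs=1e-12)

    def test_stretched_dimer_converges_to_d0(self):
        cfg = PotentialConfig(k_theta=0.0, eps_rep=0.0)
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        out, info = minimize(coords, cfg)
        assert np.linalg.norm(out[1] - out[0]) == pytest.approx(3.8, abs=1e-6)
        assert info["converged"]

    def test_energy_never_increases(self, rng):
        from ravmd.geometry import build_random_chain
        from ravmd.potential import energy_and_forces

        cfg = PotentialConfig()
        chain = build_random_chain(20, 5, 4.0)
        start = CGChain(ca=chain.ca + 0.4 * rng.standard_normal((20, 3)))
        e0, _ = energy_and_forces(start.ca, cfg)
        out, info = minimize(start, cfg)
        assert info["energy"] <= e0


class TestRunTrajectory:
    def test_snapshot_and_full_update_counts(self, chain10):
        sched = AveragingSchedule(n_ave=100, n_exch=1000, n_snap=100)
        res = run_trajectory(chain10.ca, PotentialConfig(), None, n_steps=1000,
                             dt=1.0, mode="nvt", seed=3, schedule=sched)
        assert res.snapshots.shape[0] == 10
        assert list(res.snapshot_steps) == [100 * k for k in range(1, 11)]

    def test_determinism(self, chain10, mixed_restraints):
        sched = AveragingSchedule(n_ave=50, n_exch=100, n_snap=100)
        runs = [run_trajectory(np.stack([chain10.ca] * 2), PotentialConfig(),
                               mixed_restraints, n_steps=300, dt=1.0, mode="nvt",
                               seed=9, schedule=sched) for _ in range(2)]
        assert np.array_equal(runs[0].snapshots, runs[1].snapshots)
        assert runs[0].energy_log.equals(runs[1].energy_log)

    def test_full_updates_every_n_ave(self, chain10, mixed_restraints):
        sched = AveragingSchedule(n_ave=100, n_exch=1000, n_snap=1000)
        res = run_trajectory(np.stack([chain10.ca] * 3), PotentialConfig(),
                             mixed_restraints, n_steps=1000, dt=0.5, mode="nvt",
                             seed=1, schedule=sched)
        assert list(res.full_update_steps) == [100 * k for k in range(1, 10)]


class TestCompiledKernel:
    def test_matches_numpy_path(self, rng):
        """Compiled force kernel reproduces the vectorized implementation."""
        from ravmd._kernels import force_kernel
        from ravmd.averaging import ReplicaRestraintEngine
        from ravmd.fixtures import make_two_state_fixture, random_start
        from ravmd.potential import energy_and_forces

        fx = make_two_state_fixture(n_res=12, seed=3)
        eng = ReplicaRestraintEngine(fx.restraints, 3, 12)
        for trial in range(5):
            coords = np.stack([random_start(12, 70 + 3 * trial + k, fx.potential)
                               for k in range(3)])
            coords += 0.1 * rng.standard_normal(coords.shape)
            eng.full_update(coords, 100)
            coords = coords + 0.05 * rng.standard_normal(coords.shape)
            for averaged in (False, True):
                eb, er, f = force_kernel(coords, fx.potential, eng, averaged, False)
                e2, f2 = energy_and_forces(coords, fx.potential)
                er2, fr2 = eng.energy_forces(coords, averaged=averaged)
                assert np.abs(eb - e2).max() < 1e-10
                assert np.abs(er - er2).max() < 1e-10
                assert np.abs(f - (f2 + fr2)).max() < 1e-10

    def test_trajectory_paths_agree_statistically(self, rng):
        """Short trajectories via kernel and numpy paths stay numerically close."""
        from ravmd.averaging import AveragingSchedule
        from ravmd.fixtures import make_two_state_fixture, random_start

        fx = make_two_state_fixture(n_res=12, seed=3)
        starts = np.stack([random_start(12, 80 + k, fx.potential) for k in range(2)])
        outs = []
        for kernel in ("numba", "numpy"):
            res = run_trajectory(starts, fx.potential, fx.restraints,
                                 n_steps=200, dt=2.0, mode="nvt", friction=0.003,
                                 schedule=AveragingSchedule(100, 200, 100),
                                 averaging=True, seed=4, kernel=kernel)
            outs.append(res.snapshots)
        assert np.abs(outs[0] - outs[1]).max() < 1e-6
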