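"""Inverse-power replica averaging, partial updates, gradients, weights."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ravmd.averaging import (
    AveragingSchedule,
    ReplicaRestraintEngine,
    averaged_gradient,
    dihedral_average,
    full_average,
    partial_average,
    temperature_weights,
)
from ravmd.errors import ConfigError, DegenerateAverageError, NumericError
from ravmd.geometry import CGChain
from ravmd.remd import LADDER_SETS, make_ladder
from ravmd.restraints import DistanceRestraint, RestraintSet


def brute_average(values, m):
    return (np.mean([v ** (-m) for v in values])) ** (-1.0 / m)


class TestFullAverage:
    def test_constant_values(self):
        for m in (3, -1, 6):
            assert full_average([2.7, 2.7, 2.7], m) == pytest.approx(2.7, rel=1e-12)

    def test_two_distance_oracle(self):
        assert full_average([2.0, 4.0], 3) == pytest.approx(
            ((2.0**-3 + 4.0**-3) / 2) ** (-1 / 3), rel=1e-14)
        assert full_average([2.0, 4.0], 3) == pytest.approx(2.42283, abs=1e-5)

    def test_m_minus_one_is_arithmetic_mean(self):
        assert full_average([2.0, 4.0], -1) == pytest.approx(3.0, rel=1e-14)

    def test_single_value_identity(self):
        assert full_average([5.4], 3) == 5.4

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(NumericError):
            full_average([2.0, -1.0], 3)

    @given(st.lists(st.floats(0.5, 20.0), min_size=2, max_size=8),
           st.sampled_from([3, 6, -1]))
    @settings(deadline=None, derandomize=True)
    def test_permutation_invariance_and_power_mean_bounds(self, values, m):
        a = full_average(values, m)
        b = full_average(values[::-1], m)
        assert a == pytest.approx(b, rel=1e-12)
        assert min(values) - 1e-9 <= a <= max(values) + 1e-9
        if m == 3:
            assert a <= np.mean(values) + 1e-9  # short distances dominate

    def test_matches_brute_force_many(self, rng):
        for _ in range(100):
            vals = rng.uniform(0.5, 15.0, rng.integers(2, 9))
            m = rng.choice([3, 6, -1])
            assert full_average(vals, m) == pytest.approx(
                brute_average(vals, m), rel=1e-12)


class TestDihedralAverage:
    def test_constant(self):
        assert dihedral_average([1.1, 1.1]) == pytest.approx(1.1, rel=1e-12)

    def test_wrap_correct_average(self):
        got = dihedral_average(np.deg2rad([170.0, -170.0]))
        assert abs(got) == pytest.approx(np.pi, abs=1e-12)

    def test_antipodal_degenerate(self):
        with pytest.raises(DegenerateAverageError):
            dihedral_average([0.0, np.pi])

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            angles = rng.uniform(-np.pi, np.pi, rng.integers(2, 7))
            s, c = np.mean(np.sin(angles)), np.mean(np.cos(angles))
            if np.hypot(s, c) < 1e-6:
                continue
            assert dihedral_average(angles) == pytest.approx(
                np.arctan2(s, c), abs=1e-12)


class TestPartialAverage:
    def test_consistency_with_full_average(self):
        vals = [2.0, 4.0, 5.5]
        s_foreign = sum(v**-3 for v in vals[1:])
        assert partial_average(s_foreign, vals[0], 3, 3) == pytest.approx(
            full_average(vals, 3), rel=1e-14)

    def test_two_replica_oracle(self):
        assert partial_average(4.0**-3, 2.0, 2, 3) == pytest.approx(
            brute_average([2.0, 4.0], 3), rel=1e-14)

    def test_single_replica_identity(self):
        assert partial_average(0.0, 3.3, 1, 3) == 3.3


class TestAveragedGradient:
    def test_single_replica_passthrough(self):
        g = np.array([1.0, -2.0, 0.5])
        assert np.array_equal(averaged_gradient(2.0, 2.0, g, 1, 3), g)

    def test_two_replica_factor(self):
        ybar = brute_average([2.0, 4.0], 3)
        factor = 0.5 * (ybar / 2.0) ** 4
        got = averaged_gradient(2.0, ybar, np.ones(3), 2, 3)
        assert np.allclose(got, factor)
        assert factor == pytest.approx(1.07681, abs=1e-5)

    def test_matches_finite_difference_of_partial_average(self, rng):
        h = 1e-6
        for _ in range(60):
            m = int(rng.choice([3, 6, -1]))
            n_rep = int(rng.integers(2, 8))
            others = rng.uniform(1.0, 10.0, n_rep - 1)
            y = rng.uniform(1.0, 10.0)
            s = np.sum(others ** (-float(m)))
            fd = (partial_average(s, y + h, n_rep, m) -
                  partial_average(s, y - h, n_rep, m)) / (2 * h)
            ybar = partial_average(s, y, n_rep, m)
            an = averaged_gradient(y, ybar, np.array([1.0]), n_rep, m)[0]
            assert an == pytest.approx(fd, rel=1e-5, abs=1e-9)


class TestTemperatureWeights:
    @pytest.mark.parametrize("name", sorted(LADDER_SETS))
    def test_indicator_weights_normalized_for_published_ladders(self, name):
        ladder = make_ladder(name)
        temps = np.asarray(ladder.temperatures)
        assignment = temps[ladder.initial_assignment()]
        w = temperature_weights(assignment, temps, ladder.multiplexing)
        sums = w.weights.sum(axis=0)
        assert np.allclose(sums, 1.0)
        nz = np.count_nonzero(w.weights, axis=0)
        assert np.all(nz == ladder.multiplexing)
        assert set(np.unique(w.weights)) == {0.0, 1.0 / ladder.multiplexing}

    def test_weight_support_follows_swap(self):
        temps = [300.0, 320.0]
        assignment = np.array([300.0, 300.0, 320.0, 320.0])
        w0 = temperature_weights(assignment, temps, 2)
        assignment2 = assignment.copy()
        assignment2[[0, 2]] = assignment[[2, 0]]
        w1 = temperature_weights(assignment2, temps, 2)
        assert w0.at(300.0)[0] > 0 and w1.at(300.0)[0] == 0
        assert w1.at(300.0)[2] > 0

    def test_unequal_multiplexing_rejected(self):
        with pytest.raises(ConfigError):
            temperature_weights([300.0, 300.0, 320.0], [300.0, 320.0], 2)


class TestSchedule:
    def test_divisibility_enforced(self):
        with pytest.raises(ConfigError):
            AveragingSchedule(n_ave=300, n_exch=1000)
        AveragingSchedule(n_ave=100, n_exch=10_000)  # paper defaults valid


class TestEngineCoreMechanism:
    def test_average_inside_window_zeroes_penalty_and_forces(self):
        """Two replicas individually violate the window; their m=3 average does not."""
        r = DistanceRestraint(1, 3, 3.5, 4.5)
        c1 = np.array([[0, 0, 0], [1.9, 3.0, 0], [3.0, 0, 0]], float)
        c2 = np.array([[0, 0, 0], [3.5, 2.0, 0], [7.0, 0, 0]], float)
        coords = np.stack([c1, c2])
        eng = ReplicaRestraintEngine(RestraintSet([r]), 2, 3)
        eng.full_update(coords, 100)
        avg = brute_average([3.0, 7.0], 3)
        assert 3.5 < avg < 4.5
        e_avg, f_avg = eng.energy_forces(coords, averaged=True)
        assert np.all(e_avg == 0.0) and np.all(f_avg == 0.0)
        e_plain, _ = eng.energy_forces(coords, averaged=False)
        assert np.all(e_plain > 0.0)

    def test_extended_energy_force_consistency(self, chain10, mixed_restraints, rng):
        """Averaged forces are exact gradients of the frozen-foreign extended energy."""
        m_rep = 4
        coords = np.stack([
            chain10.ca + 0.15 * rng.standard_normal(chain10.ca.shape)
            for _ in range(m_rep)])
        eng = ReplicaRestraintEngine(mixed_restraints, m_rep, chain10.n_res)
        eng.full_update(coords, 100)
        coords2 = coords + 0.03 * rng.standard_normal(coords.shape)
        e, f = eng.energy_forces(coords2, averaged=True, scale_energy=True)
        h = 1e-6
        for j in (0, 2):
            for i in (0, 4, 9):
                for k in range(3):
                    cp = coords2.copy()
                    cp[j, i, k] += h
                    cm = coords2.copy()
                    cm[j, i, k] -= h
                    fd = -(eng.energy_forces(cp, True, True)[0][j] -
                           eng.energy_forces(cm, True, True)[0][j]) / (2 * h)
                    assert f[j, i, k] == pytest.approx(fd, rel=2e-5, abs=1e-7)

    def test_partial_equals_full_at_update_step(self, chain10, mixed_restraints, rng):
        coords = np.stack([chain10.ca + 0.1 * rng.standard_normal(chain10.ca.shape)
                           for _ in range(3)])
        eng = ReplicaRestraintEngine(mixed_restraints, 3, chain10.n_res)
        eng.full_update(coords, 0)
        d, th, ga = eng.observe_all(coords)
        e, _ = eng.energy_forces(coords, averaged=True)
        # recompute penalty directly from the synchronized full averages
        from ravmd.restraints import v_ang, v_dist
        expected = np.zeros(3)
        for i, r in enumerate(mixed_restraints.distances):
            ybar = brute_average(d[:, i], r.m)
            expected += v_dist(ybar, r.lower, r.upper, r.amplitude, r.sigma, r.kappa)
        for i, r in enumerate(mixed_restraints.thetas):
            ybar = brute_average(th[:, i], r.m)
            expected += v_ang(ybar, r.lower, r.upper, r.amplitude)
        for i, r in enumerate(mixed_restraints.gammas):
            ybar = dihedral_average(ga[:, i])
            expected += v_ang(ybar, r.lower, r.upper, r.amplitude)
        assert np.allclose(e, expected, rtol=1e-12)
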