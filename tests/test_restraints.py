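"""Flat-bottom penalty functionals, their derivatives and restraint forces."""

import numpy as np
import pytest

from ravmd.errors import ConfigError, MappingError
from ravmd.geometry import CGChain
from ravmd.restraints import (
    DistanceRestraint,
    RestraintSet,
    observe,
    restraint_energy_forces,
    v_ang,
    v_ang_deriv,
    v_dist,
    v_dist_deriv,
    wrap_delta,
)


class TestVDist:
    def test_flat_bottom_zero(self):
        assert v_dist(3.0, 2.5, 4.0) == 0.0
        assert v_dist(2.5, 2.5, 4.0) == 0.0
        assert v_dist(4.0, 2.5, 4.0) == 0.0

    def test_one_angstrom_excess_closed_form(self):
        # A x^4/(sigma^4+x^4) (1 + kappa ln cosh x) at x = 1, A=5, sigma=1, kappa=0.01
        expected = 5.0 * 0.5 * (1.0 + 0.01 * np.log(np.cosh(1.0)))
        assert v_dist(5.0, 2.5, 4.0, 5.0, 1.0, 0.01) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.5108, abs=2e-4)

    def test_asymptotic_slope_is_a_kappa(self):
        d_u, a, kappa = 4.0, 5.0, 0.01
        slope = v_dist_deriv(d_u + 50.0, 0.0, d_u, a, 1.0, kappa)
        assert slope == pytest.approx(a * kappa, rel=0.01)

    def test_mirror_symmetry(self):
        for x in np.linspace(0.1, 6.0, 23):
            low = v_dist(2.5 - x, 2.5, 4.0, 5.0, 1.0, 0.01)
            high = v_dist(4.0 + x, 2.5, 4.0, 5.0, 1.0, 0.01)
            assert low == pytest.approx(high, rel=1e-12)

    def test_nonnegative_and_increasing_beyond_upper(self):
        d = np.linspace(4.0, 30.0, 400)
        v = v_dist(d, 2.5, 4.0)
        assert np.all(v >= 0)
        assert np.all(np.diff(v) > -1e-14)

    def test_deriv_matches_finite_difference(self, rng):
        h = 1e-6
        for _ in range(50):
            lo = rng.uniform(1.0, 4.0)
            hi = lo + rng.uniform(0.2, 3.0)
            a = rng.uniform(1.0, 8.0)
            sig = rng.uniform(0.5, 2.0)
            kap = rng.uniform(0.0, 0.1)
            d = rng.uniform(0.2, hi + 6.0)
            if abs(d - lo) < 1e-3 or abs(d - hi) < 1e-3:
                continue
            fd = (v_dist(d + h, lo, hi, a, sig, kap) -
                  v_dist(d - h, lo, hi, a, sig, kap)) / (2 * h)
            an = v_dist_deriv(d, lo, hi, a, sig, kap)
            assert an == pytest.approx(fd, rel=1e-6, abs=1e-9)

    def test_deriv_zero_inside_and_at_boundary(self):
        assert v_dist_deriv(3.2, 2.5, 4.0) == 0.0
        assert v_dist_deriv(4.0, 2.5, 4.0) == 0.0
        assert v_dist_deriv(2.5, 2.5, 4.0) == 0.0


class TestWrapDelta:
    def test_midpoint_zero(self):
        assert wrap_delta(0.5, 0.2, 0.8) == pytest.approx(0.0, abs=1e-15)

    def test_wraps_into_window(self):
        # x = 350 deg against window [-10, 10] deg: wrapped offset is -10 deg
        d = wrap_delta(np.deg2rad(350.0), np.deg2rad(-10.0), np.deg2rad(10.0))
        assert d == pytest.approx(np.deg2rad(-10.0), abs=1e-12)

    def test_periodicity(self, rng):
        for _ in range(20):
            x = rng.uniform(-10, 10)
            lo = rng.uniform(-3, 0)
            hi = lo + rng.uniform(0, 5.0)
            assert wrap_delta(x + 2 * np.pi, lo, hi) == pytest.approx(
                wrap_delta(x, lo, hi), abs=1e-9)

    def test_vacuous_window_rejected(self):
        with pytest.raises(ConfigError):
            wrap_delta(0.0, 0.0, 2 * np.pi + 0.1)


class TestVAng:
    def test_inside_window_zero(self):
        assert v_ang(1.3, 1.2, 1.5, 1.0) == 0.0

    def test_excess_quartic_value(self):
        # delta = h + 0.2 -> amplitude * 0.2^4 / 4
        h = 0.15
        x = (1.2 + 1.5) / 2 + h + 0.2
        assert v_ang(x, 1.2, 1.5, 1.0) == pytest.approx(0.2**4 / 4.0, rel=1e-10)

    def test_continuity_at_boundary(self):
        for eps in (1e-9, -1e-9):
            assert v_ang(1.5 + eps, 1.2, 1.5, 1.0) < 1e-20

    def test_printed_convention_is_discontinuous(self):
        inside = v_ang(1.5 - 1e-9, 1.2, 1.5, 1.0, convention="printed")
        outside = v_ang(1.5 + 1e-9, 1.2, 1.5, 1.0, convention="printed")
        h = (1.5 - 1.2) / 2
        assert inside == 0.0
        assert outside == pytest.approx(h**4 / 4.0, rel=1e-4)

    def test_joint_2pi_shift_invariance(self, rng):
        for _ in range(20):
            x = rng.uniform(-3, 3)
            lo = rng.uniform(-2, 0)
            hi = lo + rng.uniform(0.1, 2.0)
            assert v_ang(x + 2 * np.pi, lo + 2 * np.pi, hi + 2 * np.pi, 2.0) == \
                pytest.approx(v_ang(x, lo, hi, 2.0), abs=1e-10)

    def test_deriv_matches_finite_difference(self, rng):
        h = 1e-7
        for _ in range(40):
            lo = rng.uniform(-2, 0)
            hi = lo + rng.uniform(0.2, 2.0)
            x = rng.uniform(lo - 2.0, hi + 2.0)
            delta_edge = abs(abs(wrap_delta(x, lo, hi)) - (hi - lo) / 2)
            if delta_edge < 1e-3:
                continue
            fd = (v_ang(x + h, lo, hi, 3.0) - v_ang(x - h, lo, hi, 3.0)) / (2 * h)
            assert v_ang_deriv(x, lo, hi, 3.0) == pytest.approx(fd, rel=1e-5, abs=1e-10)


class TestObserve:
    def test_simple_distance(self):
        ca = np.array([[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0, 5, 0]], float)
        rs = RestraintSet([DistanceRestraint(1, 3, 2.0, 8.0)])
        got = observe(CGChain(ca=ca), rs)
        assert got[0] == pytest.approx(np.hypot(3.8, 3.8))

    def test_matches_brute_force_on_random_chain(self, chain10, mixed_restraints):
        from ravmd.geometry import virtual_bond_angles, virtual_bond_dihedrals

        got = observe(chain10, mixed_restraints)
        for val, r in zip(got, mixed_restraints):
            if isinstance(r, DistanceRestraint):
                expected = np.linalg.norm(chain10.ca[r.j_res - 1] - chain10.ca[r.i_res - 1])
            elif r.kind == "theta":
                expected = virtual_bond_angles(chain10.ca)[r.index - 1]
            else:
                expected = virtual_bond_dihedrals(chain10.ca)[r.index - 1]
            assert val == pytest.approx(expected, abs=1e-12)

    def test_unresolvable_site_raises(self, chain10):
        rs = RestraintSet([DistanceRestraint(1, 99, 2.0, 8.0)])
        with pytest.raises(MappingError):
            observe(chain10, rs)

    def test_sc_site_requires_side_chains(self, chain10):
        rs = RestraintSet([DistanceRestraint(1, 3, 2.0, 8.0, j_site="SC")])
        with pytest.raises(MappingError):
            observe(chain10, rs)


class TestRestraintForces:
    def test_zero_inside_windows(self):
        ca = np.array([[0, 0, 0], [3.8, 0, 0], [5.0, 3.0, 0], [1.0, 4.5, 0]], float)
        chain = CGChain(ca=ca)
        d13 = np.linalg.norm(ca[2] - ca[0])
        rs = RestraintSet([DistanceRestraint(1, 3, d13 - 1, d13 + 1)])
        e, f = restraint_energy_forces(chain, rs)
        assert e == 0.0
        assert np.all(f == 0.0)

    def test_two_body_newton_third_law(self, chain10):
        rs = RestraintSet([DistanceRestraint(1, 6, 1.0, 2.0)])  # certainly violated
        e, f = restraint_energy_forces(chain10, rs)
        assert e > 0
        fi, fj = f[0], f[5]
        assert np.allclose(fi + fj, 0.0, atol=1e-12)
        u = chain10.ca[5] - chain10.ca[0]
        cross = np.cross(fj, u)
        assert np.linalg.norm(cross) < 1e-10 * np.linalg.norm(fj) * np.linalg.norm(u) + 1e-14
        assert np.abs(f[1:5]).max() == 0.0

    def test_forces_match_finite_difference(self, chain10, mixed_restraints):
        from tests.conftest import finite_difference_forces

        e, f = restraint_energy_forces(chain10, mixed_restraints)
        fd = finite_difference_forces(
            lambda c: restraint_energy_forces(CGChain(ca=c), mixed_restraints)[0],
            chain10.ca)
        scale = max(np.abs(fd).max(), 1.0)
        assert np.abs(f - fd).max() / scale < 1e-6


class TestValidation:
    def test_inverted_bounds_rejected(self):
        with pytest.raises(ConfigError):
            DistanceRestraint(1, 2, 5.0, 4.0)

    def test_bad_site_kind_rejected(self):
        with pytest.raises(ConfigError):
            DistanceRestraint(1, 2, 1.0, 2.0, i_site="CB")
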