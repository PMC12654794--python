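import numpy as np
import pytest

from ravmd.geometry import CGChain, build_random_chain
from ravmd.potential import PotentialConfig
from ravmd.restraints import AngleRestraint, DistanceRestraint, RestraintSet


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def chain10() -> CGChain:
    """A mildly perturbed self-avoiding 10-mer used across force tests."""
    rng = np.random.default_rng(7)
    chain = build_random_chain(10, 3, 4.0)
    return CGChain(ca=chain.ca + 0.2 * rng.standard_normal(chain.ca.shape))


@pytest.fixture(scope="session")
def mixed_restraints() -> RestraintSet:
    """Distance + theta + gamma restraints with deliberately violated windows."""
    return RestraintSet([
        DistanceRestraint(1, 5, 3.0, 4.0),
        DistanceRestraint(2, 9, 5.0, 6.0),
        DistanceRestraint(3, 10, 2.0, 3.0),
        DistanceRestraint(4, 8, 6.0, 9.0),
        AngleRestraint("theta", 2, 1.2, 1.5),
        AngleRestraint("theta", 5, 2.0, 2.2),
        AngleRestraint("gamma", 1, -0.5, 0.5),
        AngleRestraint("gamma", 4, 2.5, 3.0),
    ])


@pytest.fixture(scope="session")
def default_potential() -> PotentialConfig:
    return PotentialConfig()


def finite_difference_forces(energy_fn, coords, h=1e-6):
    """Central finite differences of a scalar energy over (n, 3) coordinates."""
    coords = np.asarray(coords, dtype=float)
    out = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for k in range(3):
            cp = coords.copy()
            cp[i, k] += h
            cm = coords.copy()
            cm[i, k] -= h
            out[i, k] = -(energy_fn(cp) - energy_fn(cm)) / (2.0 * h)
    return out
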