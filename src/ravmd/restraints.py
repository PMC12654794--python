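"""Flat-bottom restraint penalties for coarse-grained chains.

Experimental (NMR-style) information enters the simulation as penalty terms
added to the baseline energy,

    U = U_baseline + V_dist + V_theta + V_gamma.

Distance restraints use a quartic-wall flat-bottom well with a log-cosh factor
giving an asymptotically *linear* tail of slope A*kappa, so badly violated
restraints pull gently instead of catastrophically:

    V(d) = 0                                         for d_l <= d <= d_u
    V(d) = A x^4/(sigma^4 + x^4) * (1 + kappa ln cosh x),  x = d - d_u (or d - d_l)

The well is mirror-symmetric about the flat bottom, and both the value and the
first derivative vanish at the boundaries (quartic tangency).  Default
parameters: A = 5 kcal/mol, sigma = 1 A, kappa = 0.01.

Angular restraints on virtual-bond angles theta and dihedrals gamma penalize
the signed offset delta of the observable from the window midpoint, wrapped to
(-pi, pi].  The default ("excess") convention is amplitude*(|delta|-h)^4/4
outside the half-width h, which is continuous with a continuous first
derivative at the window edge; the discontinuous delta^4/4 variant is kept
behind ``convention="printed"`` for cross-checks against other codes.
Default amplitudes: A_theta = 1, A_gamma = 5 kcal/mol.

Interproton distances are abstracted behind a :class:`SiteMapping`: a restraint
between residues resolves to a pair of coarse-grained sites (Calpha or
side-chain center).  A backend estimating proton positions analytically from
the coarse-grained geometry can be plugged in behind the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, MappingError, NumericError, SizeError
from .geometry import (
    CGChain,
    dihedral_gradients,
    theta_gradients,
    virtual_bond_angles,
    virtual_bond_dihedrals,
    wrap_angle,
)

# defaults for the penalty parameters
DEFAULT_A = 5.0        # kcal/mol, distance well depth
DEFAULT_SIGMA = 1.0    # A, wall thickness
DEFAULT_KAPPA = 0.01   # dimensionless, asymptotic slope factor
DEFAULT_A_THETA = 1.0  # kcal/mol
DEFAULT_A_GAMMA = 5.0  # kcal/mol
DEFAULT_M_DIST = 3     # replica-averaging exponent for distances
DEFAULT_M_ANGLE = -1   # replica-averaging exponent for angles


@dataclass(frozen=True)
class DistanceRestraint:
    """Flat-bottom distance restraint between two mapped sites.

    Residue indices are 1-based (as in restraint files); `i_site`/`j_site` are
    'CA' or 'SC'.
    """

    i_res: int
    j_res: int
    lower: float
    upper: float
    i_site: str = "CA"
    j_site: str = "CA"
    amplitude: float = DEFAULT_A
    sigma: float = DEFAULT_SIGMA
    kappa: float = DEFAULT_KAPPA
    m: int = DEFAULT_M_DIST

    kind = "dist"

    def __post_init__(self):
        if not 0.0 <= self.lower <= self.upper:
            raise ConfigError(
                f"need 0 <= lower <= upper, got ({self.lower}, {self.upper})"
            )
        if self.amplitude <= 0 or self.sigma <= 0 or self.kappa < 0:
            raise ConfigError("need amplitude, sigma > 0 and kappa >= 0")
        if self.i_site not in ("CA", "SC") or self.j_site not in ("CA", "SC"):
            raise ConfigError("site kind must be CA or SC")


@dataclass(frozen=True)
class AngleRestraint:
    """Window restraint on a virtual-bond angle (theta) or dihedral (gamma).

    `index` is the 1-based internal-coordinate index (theta_i spans residues
    i..i+2, gamma_i spans residues i..i+3).  Boundaries in radians; the window
    width x_u - x_l must lie in [0, 2 pi).
    """

    kind: str  # 'theta' | 'gamma'
    index: int
    lower: float
    upper: float
    amplitude: float = None  # type: ignore[assignment]
    m: int = DEFAULT_M_ANGLE

    def __post_init__(self):
        if self.kind not in ("theta", "gamma"):
            raise ConfigError(f"unknown angle restraint kind {self.kind!r}")
        if self.amplitude is None:
            object.__setattr__(
                self, "amplitude",
                DEFAULT_A_THETA if self.kind == "theta" else DEFAULT_A_GAMMA,
            )
        if self.amplitude <= 0:
            raise ConfigError("amplitude must be > 0")
        width = self.upper - self.lower
        if not 0.0 <= width < 2.0 * np.pi:
            raise ConfigError(f"window width must be in [0, 2pi), got {width}")


Restraint = DistanceRestraint | AngleRestraint


@dataclass
class RestraintSet:
    """Ordered collection of distance and angular restraints."""

    restraints: list[Restraint] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    def __getitem__(self, i):
        return self.restraints[i]

    @property
    def distances(self) -> list[DistanceRestraint]:
        return [r for r in self.restraints if isinstance(r, DistanceRestraint)]

    @property
    def thetas(self) -> list[AngleRestraint]:
        return [r for r in self.restraints
                if isinstance(r, AngleRestraint) and r.kind == "theta"]

    @property
    def gammas(self) -> list[AngleRestraint]:
        return [r for r in self.restraints
                if isinstance(r, AngleRestraint) and r.kind == "gamma"]


class SiteMapping:
    """Default mapping: a restraint's site selectors resolve to CA or SC sites.

    ``site_position(chain, res, kind)`` returns the coordinates of the mapped
    site; ``site_index`` its row index (CA sites index the Calpha array; SC
    requires the chain to carry side-chain centers).
    """

    def site_position(self, chain: CGChain, res: int, kind: str) -> np.ndarray:
        return chain.ca[self._check(chain, res, kind)] if kind == "CA" else \
            chain.sc[self._check(chain, res, kind)]

    def _check(self, chain: CGChain, res: int, kind: str) -> int:
        if not 1 <= res <= chain.n_res:
            raise MappingError(f"residue {res} outside chain of {chain.n_res} residues")
        if kind == "SC" and chain.sc is None:
            raise MappingError(f"restraint maps residue {res} to SC but chain has no side-chain sites")
        return res - 1

    def pair_indices(self, chain: CGChain, r: DistanceRestraint) -> tuple[int, str, int, str]:
        return (self._check(chain, r.i_res, r.i_site), r.i_site,
                self._check(chain, r.j_res, r.j_site), r.j_site)


DEFAULT_MAPPING = SiteMapping()


# ---------------------------------------------------------------------------
# penalty functionals (vectorized in the observable)

def v_dist(d, lower, upper, amplitude=DEFAULT_A, sigma=DEFAULT_SIGMA,
           kappa=DEFAULT_KAPPA):
    """Flat-bottom distance penalty (kcal/mol); vectorized in all arguments."""
    d = np.asarray(d, dtype=float)
    x = np.where(d > upper, d - upper, np.where(d < lower, d - lower, 0.0))
    x4 = x**4
    val = amplitude * x4 / (np.asarray(sigma, dtype=float) ** 4 + x4) * (
        1.0 + kappa * _ln_cosh(x)
    )
    return val if val.ndim else float(val)


def v_dist_deriv(d, lower, upper, amplitude=DEFAULT_A, sigma=DEFAULT_SIGMA,
                 kappa=DEFAULT_KAPPA):
    """Exact dV/dd of :func:`v_dist`; zero inside the flat bottom and at its edges."""
    d = np.asarray(d, dtype=float)
    x = np.where(d > upper, d - upper, np.where(d < lower, d - lower, 0.0))
    s4 = np.asarray(sigma, dtype=float) ** 4
    x4 = x**4
    p = x4 / (s4 + x4)
    dp = 4.0 * s4 * x**3 / (s4 + x4) ** 2
    q = 1.0 + kappa * _ln_cosh(x)
    dq = kappa * np.tanh(x)
    val = amplitude * (dp * q + p * dq)
    return val if val.ndim else float(val)


def _ln_cosh(x):
    """log(cosh(x)) computed without overflow for large |x|."""
    ax = np.abs(x)
    return ax + np.log1p(np.exp(-2.0 * ax)) - np.log(2.0)


def v_dist_val_deriv(d, lower, upper, amplitude=DEFAULT_A, sigma=DEFAULT_SIGMA,
                     kappa=DEFAULT_KAPPA):
    """(value, derivative) of :func:`v_dist` sharing the intermediate terms.

    Identical results to calling :func:`v_dist` and :func:`v_dist_deriv`
    separately; used in force loops where both are needed every step.
    """
    d = np.asarray(d, dtype=float)
    x = np.where(d > upper, d - upper, np.where(d < lower, d - lower, 0.0))
    s4 = np.asarray(sigma, dtype=float) ** 4
    x4 = x**4
    denom = s4 + x4
    p = x4 / denom
    lc = _ln_cosh(x)
    q = 1.0 + kappa * lc
    val = amplitude * p * q
    dp = 4.0 * s4 * x**3 / denom**2
    dq = kappa * np.tanh(x)
    der = amplitude * (dp * q + p * dq)
    return val, der


def wrap_delta(x, lower, upper):
    """Signed offset of angle x from the window midpoint, wrapped to (-pi, pi]."""
    width = np.asarray(upper, dtype=float) - np.asarray(lower, dtype=float)
    if np.any(width < 0) or np.any(width >= 2.0 * np.pi):
        raise ConfigError("window width must be in [0, 2pi)")
    return wrap_angle(np.asarray(x, dtype=float) - 0.5 * (np.asarray(lower) + np.asarray(upper)))


def v_ang(x, lower, upper, amplitude, convention="excess"):
    """Angular window penalty (kcal/mol).

    'excess' (default): amplitude*(|delta|-h)^4/4 outside the half-width h —
    continuous value and slope at the window edge.  'printed': amplitude*
    delta^4/4 outside the window (discontinuous at the edge; kept only for
    cross-checks).
    """
    delta = wrap_delta(x, lower, upper)
    h = 0.5 * (np.asarray(upper, dtype=float) - np.asarray(lower, dtype=float))
    out = np.abs(delta) > h
    if convention == "excess":
        excess = np.where(out, np.abs(delta) - h, 0.0)
        val = np.asarray(amplitude) * excess**4 / 4.0
    elif convention == "printed":
        val = np.where(out, np.asarray(amplitude) * delta**4 / 4.0, 0.0)
    else:
        raise ConfigError(f"unknown convention {convention!r}")
    return val if val.ndim else float(val)


def v_ang_deriv(x, lower, upper, amplitude, convention="excess"):
    """Exact dV/dx of :func:`v_ang` (dδ/dx = 1 almost everywhere)."""
    delta = wrap_delta(x, lower, upper)
    h = 0.5 * (np.asarray(upper, dtype=float) - np.asarray(lower, dtype=float))
    out = np.abs(delta) > h
    if convention == "excess":
        excess = np.where(out, np.abs(delta) - h, 0.0)
        val = np.asarray(amplitude) * excess**3 * np.sign(delta)
    elif convention == "printed":
        val = np.where(out, np.asarray(amplitude) * delta**3, 0.0)
    else:
        raise ConfigError(f"unknown convention {convention!r}")
    return val if val.ndim else float(val)


# ---------------------------------------------------------------------------
# observation and forces on a chain

def observe(chain: CGChain, restraints: RestraintSet,
            mapping: SiteMapping = DEFAULT_MAPPING) -> np.ndarray:
    """Observable value for each restraint, in restraint order.

    Distances in Angstrom (Euclidean between mapped sites), angles in radians
    (from the chain's internal coordinates).
    """
    thetas = gammas = None
    out = np.empty(len(restraints))
    for k, r in enumerate(restraints):
        if isinstance(r, DistanceRestraint):
            pi = mapping.site_position(chain, r.i_res, r.i_site)
            pj = mapping.site_position(chain, r.j_res, r.j_site)
            out[k] = np.linalg.norm(pj - pi)
        elif r.kind == "theta":
            if thetas is None:
                thetas = virtual_bond_angles(chain.ca)
            if not 1 <= r.index <= thetas.shape[0]:
                raise MappingError(f"theta index {r.index} out of range")
            out[k] = thetas[r.index - 1]
        else:
            if gammas is None:
                gammas = wrap_angle(virtual_bond_dihedrals(chain.ca))
            if not 1 <= r.index <= gammas.shape[0]:
                raise MappingError(f"gamma index {r.index} out of range")
            out[k] = gammas[r.index - 1]
    return out


def restraint_energy_forces(
    chain: CGChain,
    restraints: RestraintSet,
    mapping: SiteMapping = DEFAULT_MAPPING,
    convention: str = "excess",
) -> tuple[float, np.ndarray]:
    """Total penalty energy and forces on the Calpha sites of a single chain.

    Forces are exact negative gradients of the summed penalties through the
    site positions and internal coordinates.  Restraints mapped to SC sites
    are supported for energies/observables only if the chain carries
    side-chain centers; forces on SC sites are returned folded onto nothing —
    use CA-mapped restraints for dynamics.
    """
    from .averaging import ReplicaRestraintEngine

    eng = ReplicaRestraintEngine(restraints, n_replicas=1, mapping=mapping,
                                 convention=convention, n_chain=chain.n_res)
    e, f = eng.energy_forces(chain.ca[None], averaged=False)
    return float(e[0]), f[0]
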