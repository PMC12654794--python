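"""Surrogate coarse-grained baseline potential.

Restrained dynamics needs a well-posed baseline energy for the Calpha trace.
This module provides a simple, swappable one mirroring the usual term taxonomy
of coarse-grained protein force fields: harmonic virtual bonds, harmonic
virtual-bond angles, an optional cosine-series torsional term, and a soft
excluded-volume repulsion between non-bonded sites.  Any backend exposing the
same ``energy_and_forces(coords, cfg)`` contract (exact negative gradients) can
be substituted.  The defaults are deliberately generic: they keep chains
connected, semi-rigid and self-avoiding without favoring any particular fold,
so conformational preferences in restrained runs come from the restraints.

Harmonic terms use the 1/2 k (x - x0)^2 convention.  The potential is
temperature-independent, which fixes the replica-exchange acceptance rule to
the standard Metropolis form.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import NumericError
from .geometry import CGChain, bond_vectors, dihedrals_and_gradients

__all__ = ["PotentialConfig", "energy_and_forces"]


@dataclass
class PotentialConfig:
    """Parameters of the surrogate potential.

    k_bond : kcal/(mol A^2); d0 : A; k_theta : kcal/(mol rad^2); theta0 : rad;
    eps_rep : kcal/mol; r_rep : A (repulsion switched off beyond this radius);
    torsion_coeffs : optional cosine-series coefficients (a_1, a_2, ...) of a
    torsional term sum_k a_k cos(k * gamma) applied to every dihedral (a
    two-term series produces a double well).
    torsion_wells : optional (gamma1, gamma2, B); product-form double well
    B (1 - cos(gamma - gamma1)) (1 - cos(gamma - gamma2)) with exact minima at
    the two designated rotamer states (the asymmetric placement breaks the
    mirror degeneracy a pure cosine series cannot).
    dihedral_coupling : J >= 0; nearest-neighbor dihedral correlation term
    -J sum_i cos(gamma_{i+1} - gamma_i), the minimal analog of the
    local-interaction coupling real coarse-grained force fields need to make
    conformational states cooperative; a state boundary between the two
    torsion wells costs roughly J (1 - cos(gamma1 - gamma2)).
    """

    k_bond: float = 100.0
    d0: float = 3.8
    k_theta: float = 10.0
    theta0: float = np.deg2rad(105.0)
    eps_rep: float = 2.0
    r_rep: float = 4.0
    torsion_coeffs: tuple[float, ...] | None = None
    torsion_wells: tuple[float, float, float] | None = None
    torsion_well_bias: float = 0.0
    dihedral_coupling: float = 0.0

    def __post_init__(self) -> None:
        if min(self.k_bond, self.k_theta, self.eps_rep) < 0:
            raise ValueError("stiffnesses must be >= 0")
        if self.r_rep <= 0:
            raise ValueError("r_rep must be positive")
        if self.torsion_wells is not None and self.torsion_wells[2] < 0:
            raise ValueError("torsion well strength must be >= 0")


@lru_cache(maxsize=32)
def _pair_scatter(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Non-bonded pair indices (separation >= 2) and their +/- incidence matrix."""
    i, j = np.triu_indices(n, k=2)
    s = np.zeros((n, i.size))
    s[j, np.arange(i.size)] = 1.0
    s[i, np.arange(i.size)] = -1.0
    return i, j, s


def _angle_energy_forces(coords, k_theta, theta0):
    """Harmonic virtual-bond-angle term, vectorized over leading axes."""
    b = bond_vectors(coords)
    u = -b[..., :-1, :]
    v = b[..., 1:, :]
    nu = np.sqrt(np.einsum("...i,...i->...", u, u))
    nv = np.sqrt(np.einsum("...i,...i->...", v, v))
    uh = u / nu[..., None]
    vh = v / nv[..., None]
    cos = np.clip(np.einsum("...i,...i->...", uh, vh), -1.0, 1.0)
    theta = np.arccos(cos)
    sin = np.sqrt(np.clip(1.0 - cos * cos, 1e-16, None))
    e = 0.5 * k_theta * np.sum((theta - theta0) ** 2, axis=-1)
    dth = k_theta * (theta - theta0)  # dE/dtheta
    # gradients of theta w.r.t. the outer atoms of each triplet
    g1 = (cos[..., None] * uh - vh) / (nu * sin)[..., None]
    g3 = (cos[..., None] * vh - uh) / (nv * sin)[..., None]
    w1 = dth[..., None] * g1
    w3 = dth[..., None] * g3
    f = np.zeros_like(coords)
    n_ang = theta.shape[-1]
    f[..., 0:n_ang, :] -= w1
    f[..., 1:n_ang + 1, :] += w1 + w3
    f[..., 2:n_ang + 2, :] -= w3
    return e, f


def energy_and_forces(
    chain: CGChain | np.ndarray, cfg: PotentialConfig
) -> tuple[np.ndarray | float, np.ndarray]:
    """Energy (kcal/mol) and forces (kcal/(mol A)) of the surrogate potential.

    Accepts a single chain, an (n, 3) array, or a stacked (M, n, 3) ensemble;
    in the stacked case energies have shape (M,) and forces (M, n, 3).  Forces
    are exact negative gradients; total force and torque vanish.
    """
    coords = chain.ca if isinstance(chain, CGChain) else np.asarray(chain, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise NumericError("non-finite coordinates")
    single = coords.ndim == 2
    c = coords[None] if single else coords
    n = c.shape[-2]
    f = np.zeros_like(c)

    # bonds
    b = bond_vectors(c)
    d = np.sqrt(np.einsum("...i,...i->...", b, b))
    e = 0.5 * cfg.k_bond * np.sum((d - cfg.d0) ** 2, axis=-1)
    fb = (cfg.k_bond * (d - cfg.d0) / d)[..., None] * b
    f[..., :-1, :] += fb
    f[..., 1:, :] -= fb

    # angles
    if n >= 3 and cfg.k_theta > 0:
        ea, fa = _angle_energy_forces(c, cfg.k_theta, cfg.theta0)
        e = e + ea
        f += fa

    # torsional terms (optional): cosine series, two-well form, neighbor coupling
    has_torsion = cfg.torsion_coeffs or cfg.torsion_wells is not None \
        or cfg.dihedral_coupling
    if n >= 4 and has_torsion:
        gam, grads = dihedrals_and_gradients(c)
        dde = np.zeros_like(gam)  # dE/dgamma per dihedral
        if cfg.torsion_coeffs:
            for k, a in enumerate(cfg.torsion_coeffs, start=1):
                if a == 0.0:
                    continue
                e = e + a * np.sum(np.cos(k * gam), axis=-1)
                dde += -a * k * np.sin(k * gam)
        if cfg.torsion_wells is not None:
            g1, g2, big_b = cfg.torsion_wells
            u1 = 1.0 - np.cos(gam - g1)
            u2 = 1.0 - np.cos(gam - g2)
            e = e + big_b * np.sum(u1 * u2, axis=-1)
            dde += big_b * (np.sin(gam - g1) * u2 + u1 * np.sin(gam - g2))
            if cfg.torsion_well_bias:
                # relative well depth: adds `bias` at gamma1 and 0 at gamma2
                norm = 1.0 - np.cos(g1 - g2)
                e = e + cfg.torsion_well_bias * np.sum(u2, axis=-1) / norm
                dde += cfg.torsion_well_bias * np.sin(gam - g2) / norm
        if cfg.dihedral_coupling and gam.shape[-1] >= 2:
            j = cfg.dihedral_coupling
            diff = gam[..., 1:] - gam[..., :-1]
            e = e - j * np.sum(np.cos(diff), axis=-1)
            s = j * np.sin(diff)
            dde[..., :-1] += -s
            dde[..., 1:] += s
        n_dih = gam.shape[-1]
        for off, g in enumerate(grads):
            f[..., off:off + n_dih, :] -= dde[..., None] * g

    # excluded volume: WCA-style shifted Lennard-Jones wall, zero beyond r_rep,
    # value and first derivative continuous at the cutoff
    if n >= 3 and cfg.eps_rep > 0:
        i, j, s = _pair_scatter(n)
        rij = c[..., j, :] - c[..., i, :]
        r = np.sqrt(np.einsum("...i,...i->...", rij, rij))
        inside = r < cfg.r_rep
        sr6 = np.where(inside, (cfg.r_rep / r) ** 6, 1.0)
        e = e + cfg.eps_rep * np.sum(sr6 * sr6 - 2.0 * sr6 + 1.0, axis=-1)
        # dE/dr = -12 eps (sr^12 - sr^6)/r ; force on j points along +rij
        mag = np.where(inside, 12.0 * cfg.eps_rep * (sr6 * sr6 - sr6) / (r * r), 0.0)
        fv = mag[..., None] * rij
        f += np.einsum("np,...pk->...nk", s, fv)

    if single:
        return float(e[0]), f[0]
    return e, f
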