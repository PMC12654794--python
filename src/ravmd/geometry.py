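"""Coarse-grained chain geometry.

A polypeptide is reduced to its Calpha trace (one site per residue, consecutive
sites joined by virtual bonds of ~3.8 A) plus optional side-chain center
pseudo-atoms.  Internal coordinates of the trace are the virtual-bond lengths
d_i, the virtual-bond angles theta_i over three consecutive Calphas, and the
virtual-bond dihedrals gamma_i over four consecutive Calphas.  This module is
pure geometry: construction, internal coordinates, Kabsch superposition/RMSD,
and self-avoiding random chain generation.  All lengths are in Angstrom and all
angles in radians; degrees appear only at file boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError, NumericError, SizeError

CA_BOND_LENGTH = 3.8  # canonical trans Calpha-Calpha virtual-bond length, A


@dataclass
class CGChain:
    """A coarse-grained chain: Calpha trace plus optional side-chain centers.

    Parameters
    ----------
    ca : (n_res, 3) array
        Calpha coordinates in Angstrom.
    sc : (n_res, 3) array, optional
        Side-chain center coordinates (one per residue; for glycine-like
        residues conventionally equal to the Calpha position).
    sequence : str, optional
        One-letter amino-acid codes, length n_res.
    """

    ca: np.ndarray
    sc: np.ndarray | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        if self.ca.ndim != 2 or self.ca.shape[1] != 3:
            raise SizeError(f"ca must be (n_res, 3), got {self.ca.shape}")
        if not np.all(np.isfinite(self.ca)):
            raise NumericError("ca coordinates must be finite")
        if self.ca.shape[0] >= 2:
            d = np.linalg.norm(np.diff(self.ca, axis=0), axis=1)
            if np.any(d <= 0.0):
                raise NumericError("consecutive Calpha sites must be distinct")
        if self.sc is not None:
            self.sc = np.asarray(self.sc, dtype=float)
            if self.sc.shape != self.ca.shape:
                raise SizeError("sc must match ca shape")
            if not np.all(np.isfinite(self.sc)):
                raise NumericError("sc coordinates must be finite")
        if self.sequence is not None and len(self.sequence) != self.ca.shape[0]:
            raise SizeError("sequence length must equal n_res")

    @property
    def n_res(self) -> int:
        return self.ca.shape[0]

    def with_ca(self, ca: np.ndarray) -> "CGChain":
        """Copy of this chain with replaced Calpha coordinates."""
        return CGChain(ca=np.array(ca, dtype=float), sc=None if self.sc is None else self.sc.copy(),
                       sequence=self.sequence)


@dataclass
class InternalCoords:
    """Internal coordinates of a Calpha trace.

    bond_lengths has n_res-1 entries (A); thetas n_res-2 entries in [0, pi];
    gammas n_res-3 entries wrapped to (-pi, pi].
    """

    bond_lengths: np.ndarray
    thetas: np.ndarray
    gammas: np.ndarray


def wrap_angle(x):
    """Wrap angle(s) to the interval (-pi, pi]."""
    x = np.asarray(x, dtype=float)
    out = -((-x + np.pi) % (2.0 * np.pi) - np.pi)
    return out if out.ndim else float(out)


def bond_vectors(coords: np.ndarray) -> np.ndarray:
    """Virtual-bond vectors r_{i+1}-r_i along the last-but-one axis."""
    return coords[..., 1:, :] - coords[..., :-1, :]


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # np.cross spends most of its time in axis bookkeeping; this is ~4x faster
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def virtual_bond_angles(coords: np.ndarray) -> np.ndarray:
    """Angles theta_i over consecutive Calpha triplets; supports leading batch axes."""
    b = bond_vectors(coords)
    u = -b[..., :-1, :]  # from central atom back to previous
    v = b[..., 1:, :]    # from central atom forward to next
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    cos = np.einsum("...i,...i->...", u, v) / (nu * nv)
    return np.arccos(np.clip(cos, -1.0, 1.0))


def virtual_bond_dihedrals(coords: np.ndarray) -> np.ndarray:
    """Dihedrals gamma_i over consecutive Calpha quadruplets (IUPAC sign, (-pi, pi])."""
    b = bond_vectors(coords)
    b1 = b[..., :-2, :]
    b2 = b[..., 1:-1, :]
    b3 = b[..., 2:, :]
    n1 = _cross3(b1, b2)
    n2 = _cross3(b2, b3)
    b2n = b2 / np.sqrt(np.einsum("...i,...i->...", b2, b2))[..., None]
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", _cross3(n1, n2), b2n)
    return np.arctan2(y, x)


def theta_gradients(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of every virtual-bond angle w.r.t. its three atoms.

    Returns (g1, g2, g3), each shaped (..., n_res-2, 3); g_k is
    d theta_t / d r_{t+k-1}.  Degenerate (collinear) triplets are guarded by a
    floor on sin(theta); gradients there are not meaningful.
    """
    b = bond_vectors(coords)
    u = -b[..., :-1, :]
    v = b[..., 1:, :]
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    uh = u / nu[..., None]
    vh = v / nv[..., None]
    cos = np.clip(np.einsum("...i,...i->...", uh, vh), -1.0, 1.0)
    sin = np.sqrt(np.clip(1.0 - cos * cos, 1e-16, None))
    g1 = (cos[..., None] * uh - vh) / (nu * sin)[..., None]
    g3 = (cos[..., None] * vh - uh) / (nv * sin)[..., None]
    return g1, -(g1 + g3), g3


def dihedral_gradients(coords: np.ndarray) -> tuple[np.ndarray, ...]:
    """Gradients of every virtual-bond dihedral w.r.t. its four atoms.

    Returns (g1, g2, g3, g4), each shaped (..., n_res-3, 3); g_k is
    d gamma_t / d r_{t+k-1}.  Consistent with the atan2 sign convention of
    :func:`virtual_bond_dihedrals`.
    """
    return dihedrals_and_gradients(coords)[1]


def dihedrals_and_gradients(coords: np.ndarray):
    """Dihedral values and their four per-atom gradients in one pass.

    Shares the bond vectors and plane normals between the value and gradient
    computations (the force loops need both every step).
    """
    b = bond_vectors(coords)
    b1 = b[..., :-2, :]
    b2 = b[..., 1:-1, :]
    b3 = b[..., 2:, :]
    n1 = _cross3(b1, b2)
    n2 = _cross3(b2, b3)
    nb = np.sqrt(np.einsum("...i,...i->...", b2, b2))
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", _cross3(n1, n2), b2 / nb[..., None])
    gam = np.arctan2(y, x)
    n1sq = np.einsum("...i,...i->...", n1, n1)
    n2sq = np.einsum("...i,...i->...", n2, n2)
    a = (-nb / n1sq)[..., None] * n1
    d = (nb / n2sq)[..., None] * n2
    c1 = (np.einsum("...i,...i->...", b1, b2) / nb**2)[..., None]
    c3 = (np.einsum("...i,...i->...", b3, b2) / nb**2)[..., None]
    g2 = -(1.0 + c1) * a + c3 * d
    g3 = c1 * a - (1.0 + c3) * d
    return gam, (a, g2, g3, d)


def internal_coordinates(chain: CGChain | np.ndarray) -> InternalCoords:
    """Compute all internal coordinates (d_i, theta_i, gamma_i) of a Calpha trace.

    Requires at least 2 residues for bond lengths, 3 for angles and 4 for
    dihedrals; raises :class:`SizeError` below 4 residues.
    """
    coords = chain.ca if isinstance(chain, CGChain) else np.asarray(chain, dtype=float)
    n = coords.shape[0]
    if n < 4:
        raise SizeError(f"need >= 4 residues for full internal coordinates, got {n}")
    b = bond_vectors(coords)
    d = np.linalg.norm(b, axis=-1)
    thetas = virtual_bond_angles(coords)
    gammas = wrap_angle(virtual_bond_dihedrals(coords))
    return InternalCoords(bond_lengths=d, thetas=thetas, gammas=np.asarray(gammas))


def chain_from_internal(bond_lengths, thetas, gammas) -> np.ndarray:
    """Rebuild Cartesian Calpha coordinates from internal coordinates (NeRF).

    The first three sites are placed in a canonical frame: site 0 at the
    origin, site 1 along +x, site 2 in the xy plane.  Inverse of
    :func:`internal_coordinates` up to rigid motion.
    """
    d = np.asarray(bond_lengths, dtype=float)
    th = np.asarray(thetas, dtype=float)
    ga = np.asarray(gammas, dtype=float)
    n = d.size + 1
    if th.size != n - 2 or ga.size != n - 3:
        raise SizeError("inconsistent internal-coordinate counts")
    coords = np.zeros((n, 3))
    coords[1] = (d[0], 0.0, 0.0)
    if n > 2:
        coords[2] = coords[1] + d[1] * np.array(
            [-np.cos(th[0]), np.sin(th[0]), 0.0]
        )
    for i in range(3, n):
        a, bb, c = coords[i - 3], coords[i - 2], coords[i - 1]
        coords[i] = _nerf_place(a, bb, c, d[i - 1], th[i - 2], ga[i - 3])
    return coords


def _nerf_place(a, b, c, bond, theta, gamma):
    """Place atom D given A,B,C and internal coordinates (bond CD, angle BCD, dihedral ABCD)."""
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_hat)
    n_hat = n / np.linalg.norm(n)
    m = np.cross(n_hat, bc_hat)
    # local displacement in the (bc, m, n) frame
    d2 = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(gamma), np.sin(theta) * np.sin(gamma)]
    )
    return c + d2[0] * bc_hat + d2[1] * m + d2[2] * n_hat


def kabsch_rotation(ref: np.ndarray, mob: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation R and centroids aligning `mob` onto `ref` (least squares)."""
    ref = np.asarray(ref, dtype=float)
    mob = np.asarray(mob, dtype=float)
    cref = ref.mean(axis=0)
    cmob = mob.mean(axis=0)
    h = (mob - cmob).T @ (ref - cref)
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, sign])
    rot = vt.T @ corr @ u.T
    return rot, cref, cmob


def superpose_rmsd(ref: np.ndarray | CGChain, mob: np.ndarray | CGChain) -> float:
    """Minimal least-squares Calpha RMSD over rigid rotations and translations.

    Kabsch superposition (SVD of the covariance, reflection-corrected).
    Symmetric in its arguments and invariant under rigid motion of either.
    """
    ref = ref.ca if isinstance(ref, CGChain) else np.asarray(ref, dtype=float)
    mob = mob.ca if isinstance(mob, CGChain) else np.asarray(mob, dtype=float)
    if ref.shape != mob.shape:
        raise SizeError(f"point counts differ: {ref.shape} vs {mob.shape}")
    if ref.shape[0] < 3:
        raise SizeError("need >= 3 points for superposition")
    rot, cref, cmob = kabsch_rotation(ref, mob)
    moved = (mob - cmob) @ rot.T + cref
    return float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=-1))))


def pairwise_rmsd_matrix(ensemble: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise superposition RMSDs over a (K, n, 3) stack."""
    ensemble = np.asarray(ensemble, dtype=float)
    k = ensemble.shape[0]
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = superpose_rmsd(ensemble[i], ensemble[j])
    return out


def build_random_chain(
    n_res: int,
    seed: int | np.random.Generator,
    min_sep: float = 4.0,
    *,
    theta_range: tuple[float, float] = (np.deg2rad(75.0), np.deg2rad(160.0)),
    max_restarts: int = 50,
    max_tries_per_site: int = 60,
) -> CGChain:
    """Grow a self-avoiding Calpha trace with fixed 3.8 A virtual bonds.

    Virtual-bond angles are drawn uniformly in `theta_range`, dihedrals
    uniformly in (-pi, pi]; each placement is rejected if any non-bonded pair
    (sequence separation >= 2) comes within `min_sep`.  Deterministic per seed.
    """
    if n_res < 2:
        raise SizeError("n_res must be >= 2")
    if min_sep <= 0:
        raise GenerationError("min_sep must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = theta_range
    for _ in range(max_restarts):
        coords = np.zeros((n_res, 3))
        coords[1] = (CA_BOND_LENGTH, 0.0, 0.0)
        ok = True
        i = 2
        while i < n_res:
            placed = False
            for _ in range(max_tries_per_site):
                theta = rng.uniform(lo, hi)
                if i == 2:
                    cand = coords[1] + CA_BOND_LENGTH * np.array(
                        [-np.cos(theta), np.sin(theta), 0.0]
                    )
                else:
                    gamma = rng.uniform(-np.pi, np.pi)
                    cand = _nerf_place(
                        coords[i - 3], coords[i - 2], coords[i - 1],
                        CA_BOND_LENGTH, theta, gamma,
                    )
                dists = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                if np.all(dists >= min_sep):
                    coords[i] = cand
                    placed = True
                    break
            if not placed:
                ok = False
                break
            i += 1
        if ok:
            return CGChain(ca=coords)
    raise GenerationError(
        f"failed to grow a self-avoiding {n_res}-mer with min_sep={min_sep}; "
        "try a smaller min_sep"
    )
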