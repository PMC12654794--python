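"""Replica averaging of restrained observables.

The maximum-entropy way to impose ensemble-averaged experimental data is to
restrain the *average* of each observable over M simultaneously running
replicas rather than each replica individually.  The inverse-power average of
observable y_i over replicas j is

    ybar_i = [ (1/M) sum_j y_ji^{-m} ]^{-1/m}

with m = 3 for distances (short distances dominate, mirroring NOE intensity
scaling) and m = -1 (arithmetic mean) for angle-dependent quantities.
Dihedrals are averaged on the circle: the means of sin(gamma) and cos(gamma)
are combined with atan2.

Full synchronization of the replicas is expensive, so the complete average is
recomputed only every N_ave steps (a *full update* at step t_K); between full
updates each replica J updates the average with its own current value only,
keeping the other replicas' power sums frozen:

    ybar^(J) = [ (1/M) ( S_i^(J) + y_Ji^{-m} ) ]^{-1/m},
    S_i^(J)  = sum_{j != J} y_ji(t_K)^{-m}.

With the foreign sums frozen, ybar^(J) depends only on replica J's own
coordinates, so its gradient is analytic:

    grad ybar^(J) = (1/M) (ybar^(J) / y_J)^{m+1} grad y_J,

and the per-replica dynamics is conservative between full updates
("segment-symplectic": the total energy may jump only at full-update steps).
Because this gradient carries a 1/M factor, restraint forces are scaled up by
M in production; in microcanonical validation runs the restraint energy is
scaled by the same factor so that energy and forces stay consistent.

When replicas run at several temperatures (replica exchange), averaging groups
are the replicas currently sharing a temperature; the per-replica weights are
the indicator weights w_jT = 1/M for the M replicas at T and 0 otherwise,
which are normalized to 1 at every temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DegenerateAverageError, MappingError, NumericError
from .geometry import dihedral_gradients, theta_gradients, virtual_bond_angles, \
    virtual_bond_dihedrals, wrap_angle
from .restraints import (
    DEFAULT_MAPPING,
    AngleRestraint,
    DistanceRestraint,
    RestraintSet,
    SiteMapping,
    v_ang,
    v_ang_deriv,
    v_dist,
    v_dist_deriv,
    v_dist_val_deriv,
)

__all__ = [
    "full_average",
    "partial_average",
    "dihedral_average",
    "averaged_gradient",
    "temperature_weights",
    "TemperatureWeights",
    "ReplicaRestraintEngine",
]


@dataclass(frozen=True)
class AveragingSchedule:
    """Update cadence: full averages every n_ave steps, exchange attempts every
    n_exch steps (n_ave must divide n_exch), snapshots every n_snap steps."""

    n_ave: int = 100
    n_exch: int = 10_000
    n_snap: int = 10_000

    def __post_init__(self):
        if self.n_ave < 1 or self.n_exch < 1 or self.n_snap < 1:
            raise ConfigError("schedule intervals must be positive")
        if self.n_exch % self.n_ave != 0:
            raise ConfigError(
                f"n_ave={self.n_ave} must divide n_exch={self.n_exch}"
            )


def full_average(values, m: int | float):
    """Inverse-power replica average [ (1/M) sum y^-m ]^(-1/m).

    m = -1 reduces to the arithmetic mean; a single value is returned
    unchanged.  Values must be positive when m > 0.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ConfigError("need at least one value")
    if m > 0 and np.any(values <= 0.0):
        raise NumericError("nonpositive observable with positive averaging exponent")
    if values.size == 1:
        return float(values.reshape(-1)[0])
    return float(np.mean(values ** (-float(m))) ** (-1.0 / float(m)))


def partial_average(s_foreign: float, y_own: float, n_replicas: int, m: int | float):
    """Per-replica average with the other replicas' power sum frozen."""
    if n_replicas < 1:
        raise ConfigError("n_replicas must be >= 1")
    if n_replicas == 1:
        return float(y_own)
    if m > 0 and y_own <= 0.0:
        raise NumericError("nonpositive observable with positive averaging exponent")
    return float(((s_foreign + float(y_own) ** (-float(m))) / n_replicas) ** (-1.0 / float(m)))


def dihedral_average(angles):
    """Circular mean of dihedrals via atan2 of the sine and cosine means.

    Raises :class:`DegenerateAverageError` when both means vanish (antipodal
    cancellation) and the average direction is undefined.
    """
    angles = np.asarray(angles, dtype=float)
    s = np.mean(np.sin(angles))
    c = np.mean(np.cos(angles))
    if abs(s) < 1e-12 and abs(c) < 1e-12:
        raise DegenerateAverageError("sine and cosine means both vanish")
    out = float(np.arctan2(s, c))
    # atan2 returns [-pi, pi]; map -pi to +pi for the (-pi, pi] convention
    return np.pi if out == -np.pi else out


def averaged_gradient(y_own, ybar, grad_y_own, n_replicas: int, m: int | float):
    """Gradient of the partial average: (1/M) (ybar/y_own)^(m+1) grad y_own."""
    grad_y_own = np.asarray(grad_y_own, dtype=float)
    if n_replicas == 1:
        return grad_y_own.copy()
    factor = (ybar / y_own) ** (float(m) + 1.0) / n_replicas
    return factor * grad_y_own


@dataclass
class TemperatureWeights:
    """Indicator averaging weights w_jT: rows are replicas, columns ladder temperatures."""

    temperatures: np.ndarray  # (N_T,)
    weights: np.ndarray       # (R, N_T)

    def at(self, temperature: float) -> np.ndarray:
        (idx,) = np.where(np.isclose(self.temperatures, temperature))
        if idx.size != 1:
            raise ConfigError(f"temperature {temperature} not on the ladder")
        return self.weights[:, idx[0]]


def temperature_weights(assignment, ladder_temperatures, n_multiplex: int) -> TemperatureWeights:
    """Indicator weights: 1/M for the M replicas currently at T, else 0.

    `assignment` maps replica index -> current temperature (array-like of
    length R).  Every ladder temperature must hold exactly `n_multiplex`
    replicas; otherwise the indicator scheme is ill-defined and a
    :class:`ConfigError` is raised.  Columns sum to exactly 1.
    """
    assignment = np.asarray(assignment, dtype=float)
    temps = np.asarray(ladder_temperatures, dtype=float)
    w = np.zeros((assignment.size, temps.size))
    for t, temp in enumerate(temps):
        members = np.isclose(assignment, temp)
        if members.sum() != n_multiplex:
            raise ConfigError(
                f"temperature {temp} holds {int(members.sum())} replicas, "
                f"expected {n_multiplex}"
            )
        w[members, t] = 1.0 / n_multiplex
    return TemperatureWeights(temperatures=temps, weights=w)


# ---------------------------------------------------------------------------

class ReplicaRestraintEngine:
    """Vectorized replica-averaged restraint energies and forces.

    Operates on a stacked coordinate array (M, n, 3) of Calpha traces.  All
    distance restraints must map to CA sites (side-chain sites are not
    dynamical).  Averaging groups are given by `group_ids` (replicas sharing a
    group id average together); groups must have equal size.  The frozen
    foreign power sums are refreshed by :meth:`full_update`; between full
    updates :meth:`energy_forces` applies the per-replica partial update.
    """

    def __init__(
        self,
        restraints: RestraintSet,
        n_replicas: int,
        n_chain: int,
        mapping: SiteMapping = DEFAULT_MAPPING,
        convention: str = "excess",
        group_ids=None,
    ):
        self.n_replicas = int(n_replicas)
        self.n_chain = int(n_chain)
        self.convention = convention
        self.mapping = mapping
        if group_ids is None:
            group_ids = np.zeros(self.n_replicas, dtype=int)
        self.set_groups(group_ids)

        dist = [r for r in restraints if isinstance(r, DistanceRestraint)]
        for r in dist:
            if r.i_site != "CA" or r.j_site != "CA":
                raise MappingError(
                    "replica-averaged dynamics supports CA-mapped distance restraints only"
                )
            if not (1 <= r.i_res <= n_chain and 1 <= r.j_res <= n_chain):
                raise MappingError(f"restraint {r} outside chain of {n_chain} residues")
        th = [r for r in restraints
              if isinstance(r, AngleRestraint) and r.kind == "theta"]
        ga = [r for r in restraints
              if isinstance(r, AngleRestraint) and r.kind == "gamma"]
        for r in th:
            if not 1 <= r.index <= n_chain - 2:
                raise MappingError(f"theta index {r.index} out of range")
        for r in ga:
            if not 1 <= r.index <= n_chain - 3:
                raise MappingError(f"gamma index {r.index} out of range")

        self._di = np.array([r.i_res - 1 for r in dist], dtype=int)
        self._dj = np.array([r.j_res - 1 for r in dist], dtype=int)
        self._dlo = np.array([r.lower for r in dist])
        self._dhi = np.array([r.upper for r in dist])
        self._dA = np.array([r.amplitude for r in dist])
        self._dsig = np.array([r.sigma for r in dist])
        self._dkap = np.array([r.kappa for r in dist])
        self._dm = np.array([float(r.m) for r in dist])
        # scatter matrix: force on j along +u gets -coef, on i +coef
        s = np.zeros((n_chain, len(dist)))
        if dist:
            cols = np.arange(len(dist))
            np.add.at(s, (self._dj, cols), 1.0)
            np.add.at(s, (self._di, cols), -1.0)
        self._dscat = s

        self._ti = np.array([r.index - 1 for r in th], dtype=int)
        self._tlo = np.array([r.lower for r in th])
        self._thi = np.array([r.upper for r in th])
        self._tA = np.array([r.amplitude for r in th])
        self._tm = np.array([float(r.m) for r in th])

        self._gi = np.array([r.index - 1 for r in ga], dtype=int)
        self._glo = np.array([r.lower for r in ga])
        self._ghi = np.array([r.upper for r in ga])
        self._gA = np.array([r.amplitude for r in ga])

        self.n_dist = len(dist)
        self.n_theta = len(th)
        self.n_gamma = len(ga)

        self.active = False
        self.t_full = None
        self._pw_group_d = None   # (G, Rd) group power sums at t_K
        self._pw_own_d = None     # (M, Rd) own power terms at t_K
        self._pw_group_t = None
        self._pw_own_t = None
        self._sc_group_g = None   # (G, Rg, 2) group sin/cos sums at t_K
        self._sc_own_g = None     # (M, Rg, 2)

    # -- group management ---------------------------------------------------

    def set_groups(self, group_ids) -> None:
        group_ids = np.asarray(group_ids, dtype=int)
        if group_ids.shape != (self.n_replicas,):
            raise ConfigError("group_ids must have one entry per replica")
        uniq, counts = np.unique(group_ids, return_counts=True)
        if counts.min() != counts.max():
            raise ConfigError("averaging groups must have equal size")
        self.group_ids = group_ids
        self.n_groups = uniq.size
        self.group_size = int(counts[0])
        # remap ids to 0..G-1
        self._gid = np.searchsorted(uniq, group_ids)

    # -- observables --------------------------------------------------------

    def _distances(self, coords):
        rij = coords[:, self._dj, :] - coords[:, self._di, :]
        y = np.sqrt(np.einsum("mpi,mpi->mp", rij, rij))
        return y, rij

    def observe_all(self, coords):
        """Raw observables per replica: (dist (M,Rd), theta (M,Rt), gamma (M,Rg))."""
        d = self._distances(coords)[0] if self.n_dist else np.zeros((coords.shape[0], 0))
        if self.n_theta:
            th = virtual_bond_angles(coords)[:, self._ti]
        else:
            th = np.zeros((coords.shape[0], 0))
        if self.n_gamma:
            ga = wrap_angle(virtual_bond_dihedrals(coords))[:, self._gi]
        else:
            ga = np.zeros((coords.shape[0], 0))
        return d, th, ga

    # -- schedule -----------------------------------------------------------

    def full_update(self, coords, step: int) -> None:
        """Recompute group power sums from all replicas (full average at t_K)."""
        d, th, ga = self.observe_all(coords)
        g = self._gid
        if self.n_dist:
            pw = d ** (-self._dm)
            sums = np.zeros((self.n_groups, self.n_dist))
            np.add.at(sums, g, pw)
            self._pw_group_d, self._pw_own_d = sums, pw
        if self.n_theta:
            pw = th ** (-self._tm)
            sums = np.zeros((self.n_groups, self.n_theta))
            np.add.at(sums, g, pw)
            self._pw_group_t, self._pw_own_t = sums, pw
        if self.n_gamma:
            sc = np.stack([np.sin(ga), np.cos(ga)], axis=-1)
            sums = np.zeros((self.n_groups, self.n_gamma, 2))
            np.add.at(sums, g, sc)
            self._sc_group_g, self._sc_own_g = sums, sc
        self.active = True
        self.t_full = step

    # -- energy and forces --------------------------------------------------

    def energy_forces(self, coords, averaged=True, scale_energy=False):
        """Penalty energy (M,) and forces (M, n, 3) for the replica stack.

        With `averaged` False (or before the first full update, or with group
        size 1) plain per-replica penalties are applied with no force scaling;
        this path is the exact M = 1 reduction.  Otherwise penalties are
        evaluated at the partial averages, the gradient factor of the partial
        average is applied, and forces are scaled by the group size M; the
        reported energy is also scaled when `scale_energy` is set.
        """
        coords = np.asarray(coords, dtype=float)
        m_rep = coords.shape[0]
        if m_rep != self.n_replicas:
            raise ConfigError("coordinate stack does not match replica count")
        use_avg = averaged and self.active and self.group_size > 1
        scale = float(self.group_size) if use_avg else 1.0
        g = self._gid
        e = np.zeros(m_rep)
        f = np.zeros_like(coords)

        if self.n_dist:
            y, rij = self._distances(coords)
            if use_avg:
                pw = y ** (-self._dm)
                tot = self._pw_group_d[g] - self._pw_own_d + pw
                ybar = (tot / self.group_size) ** (-1.0 / self._dm)
                dfac = (ybar / y) ** (self._dm + 1.0) / self.group_size
            else:
                ybar, dfac = y, 1.0
            vals, dv = v_dist_val_deriv(ybar, self._dlo, self._dhi, self._dA,
                                        self._dsig, self._dkap)
            e += np.sum(vals, axis=-1)
            coef = scale * dv * dfac / y  # dE/dr_j = coef * rij
            contrib = coef[..., None] * rij
            f -= np.einsum("np,mpk->mnk", self._dscat, contrib)

        if self.n_theta:
            th_all = virtual_bond_angles(coords)
            y = th_all[:, self._ti]
            if use_avg:
                pw = y ** (-self._tm)
                tot = self._pw_group_t[g] - self._pw_own_t + pw
                ybar = (tot / self.group_size) ** (-1.0 / self._tm)
                dfac = (ybar / y) ** (self._tm + 1.0) / self.group_size
            else:
                ybar, dfac = y, 1.0
            e += np.sum(v_ang(ybar, self._tlo, self._thi, self._tA, self.convention), axis=-1)
            dv = v_ang_deriv(ybar, self._tlo, self._thi, self._tA, self.convention)
            coef = scale * dv * dfac
            grads = theta_gradients(coords)
            for off, gr in enumerate(grads):
                sel = gr[:, self._ti, :]
                np.add.at(f, (slice(None), self._ti + off, slice(None)),
                          -coef[..., None] * sel)

        if self.n_gamma:
            ga_all = wrap_angle(virtual_bond_dihedrals(coords))
            y = ga_all[:, self._gi]
            if use_avg:
                sin, cos = np.sin(y), np.cos(y)
                s_tot = self._sc_group_g[g, :, 0] - self._sc_own_g[:, :, 0] + sin
                c_tot = self._sc_group_g[g, :, 1] - self._sc_own_g[:, :, 1] + cos
                sbar = s_tot / self.group_size
                cbar = c_tot / self.group_size
                norm2 = sbar**2 + cbar**2
                if np.any(norm2 < 1e-24):
                    raise DegenerateAverageError("dihedral replica average undefined")
                ybar = np.arctan2(sbar, cbar)
                dfac = (cbar * cos + sbar * sin) / (self.group_size * norm2)
            else:
                ybar, dfac = y, 1.0
            e += np.sum(v_ang(ybar, self._glo, self._ghi, self._gA, self.convention), axis=-1)
            dv = v_ang_deriv(ybar, self._glo, self._ghi, self._gA, self.convention)
            coef = scale * dv * dfac
            grads = dihedral_gradients(coords)
            for off, gr in enumerate(grads):
                sel = gr[:, self._gi, :]
                np.add.at(f, (slice(None), self._gi + off, slice(None)),
                          -coef[..., None] * sel)

        if scale_energy and use_avg:
            e = e * scale
        return e, f
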