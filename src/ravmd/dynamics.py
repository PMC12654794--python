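"""Molecular-dynamics integrators and local minimization.

Units: lengths in Angstrom, time in femtoseconds, energies in kcal/mol,
masses in amu, temperatures in Kelvin.  With these units the acceleration of
a site is F * ACC / m with ACC = 4.184e-4 (exact, since 1 amu = 1/N_A gram).

NVE propagation uses velocity Verlet.  NVT propagation uses the BAOAB
splitting of Langevin dynamics (half kick, half drift, exact
Ornstein-Uhlenbeck velocity refresh, half drift, half kick), which samples the
configurational Boltzmann distribution accurately and reduces *exactly* to
velocity Verlet at zero friction.  All randomness flows through an explicit
numpy Generator, so trajectories are bitwise reproducible per seed.

Replica-averaged restraints enter through a :class:`ReplicaRestraintEngine`
whose frozen foreign sums are refreshed every ``n_ave`` steps; between
refreshes each replica's restraint force is the exact negative gradient of its
own extended energy, so per-replica total energy is conserved segment-wise in
NVE mode (checked at 1e-5 relative tolerance in the tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize as _scipy_minimize

from .averaging import AveragingSchedule, ReplicaRestraintEngine
from .errors import ConfigError, MinimizationError, NumericError
from .geometry import CGChain
from .potential import PotentialConfig, energy_and_forces
from .restraints import DEFAULT_MAPPING, RestraintSet, SiteMapping

KB = 1.987204e-3          # Boltzmann constant, kcal/(mol K)
ACC = 4.184e-4            # (kcal/(mol A))/amu -> A/fs^2
DEFAULT_MASS = 110.0      # amu per residue site (average residue mass)


@dataclass
class EnsembleState:
    """Coordinates and velocities of a stack of replicas.

    coords, velocities : (M, n, 3) in A and A/fs; masses : (n,) amu;
    temperatures : (M,) thermostat targets (NVT only); step : MD step index.
    """

    coords: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    temperatures: np.ndarray
    step: int = 0

    @property
    def n_replicas(self) -> int:
        return self.coords.shape[0]

    def kinetic_energy(self) -> np.ndarray:
        """Per-replica kinetic energy, kcal/mol."""
        v2 = np.sum(self.velocities**2, axis=-1)
        return 0.5 * np.sum(self.masses * v2, axis=-1) / ACC

    def kinetic_temperature(self) -> np.ndarray:
        """Instantaneous kinetic temperature per replica, K."""
        ndof = 3 * self.coords.shape[1]
        return 2.0 * self.kinetic_energy() / (ndof * KB)


def maxwell_velocities(n_replicas, n_sites, masses, temperature, rng) -> np.ndarray:
    """Maxwell-Boltzmann velocities (A/fs); temperature may be scalar or (M,)."""
    masses = np.broadcast_to(np.asarray(masses, dtype=float), (n_sites,))
    temp = np.broadcast_to(np.asarray(temperature, dtype=float), (n_replicas,))
    sigma = np.sqrt(KB * temp[:, None] * ACC / masses[None, :])
    return rng.standard_normal((n_replicas, n_sites, 3)) * sigma[..., None]


def _kick(vel, forces, masses, half_dt):
    vel += (half_dt * ACC / masses[None, :, None]) * forces


def langevin_step(state: EnsembleState, force_fn, dt: float, friction: float,
                  rng: np.random.Generator | None = None, forces=None):
    """One BAOAB Langevin step (friction in 1/fs); friction=0 is exact NVE.

    `force_fn(coords, step)` returns (potential energies (M,), forces
    (M, n, 3)).  Returns (potential_energies, forces) at the new coordinates;
    the state is advanced in place.
    """
    if friction < 0:
        raise ConfigError("friction must be >= 0")
    if forces is None:
        _, forces = force_fn(state.coords, state.step)
    m = state.masses[None, :, None]
    _kick(state.velocities, forces, state.masses, 0.5 * dt)
    state.coords += 0.5 * dt * state.velocities
    if friction > 0.0:
        if rng is None:
            raise ConfigError("Langevin dynamics needs an rng")
        c1 = np.exp(-friction * dt)
        sigma = np.sqrt((1.0 - c1 * c1) * KB * state.temperatures[:, None, None] * ACC / m)
        state.velocities *= c1
        state.velocities += sigma * rng.standard_normal(state.velocities.shape)
    state.coords += 0.5 * dt * state.velocities
    epot, forces = force_fn(state.coords, state.step + 1)
    if not np.all(np.isfinite(forces)):
        raise NumericError(f"non-finite force at step {state.step + 1}")
    _kick(state.velocities, forces, state.masses, 0.5 * dt)
    state.step += 1
    return epot, forces


def nve_step(state: EnsembleState, force_fn, dt: float, forces=None):
    """One velocity-Verlet microcanonical step (zero-friction Langevin)."""
    return langevin_step(state, force_fn, dt, friction=0.0, rng=None, forces=forces)


def minimize(
    chain: CGChain | np.ndarray,
    potential_cfg: PotentialConfig,
    restraints: RestraintSet | None = None,
    mapping: SiteMapping = DEFAULT_MAPPING,
    convention: str = "excess",
    gtol: float = 1e-4,
    maxiter: int = 2000,
):
    """Local minimization (L-BFGS-B) of surrogate + optional restraint energy.

    Returns (minimized chain/coords, info dict with keys energy, grad_norm,
    n_iter, converged).  Convergence target: force max-norm below `gtol`
    kcal/(mol A).
    """
    from ._kernels import force_kernel, kernel_supported

    is_chain = isinstance(chain, CGChain)
    coords0 = chain.ca if is_chain else np.asarray(chain, dtype=float)
    n = coords0.shape[0]
    engine = None
    if restraints is not None and len(restraints):
        engine = ReplicaRestraintEngine(restraints, 1, n, mapping=mapping,
                                        convention=convention)
    use_kernel = kernel_supported(potential_cfg, engine)

    def fun(x):
        c = x.reshape(1, n, 3)
        if use_kernel:
            eb, er, f = force_kernel(c, potential_cfg, engine, False, False)
            return float(eb[0] + er[0]), -f[0].ravel()
        e, f = energy_and_forces(c, potential_cfg)
        if engine is not None:
            er, fr = engine.energy_forces(c, averaged=False)
            e = e + er
            f = f + fr
        return float(e[0]), -f[0].ravel()

    res = _scipy_minimize(fun, coords0.ravel(), jac=True, method="L-BFGS-B",
                          options={"maxiter": maxiter, "gtol": gtol * 0.1,
                                   "ftol": 1e-14})
    if not np.all(np.isfinite(res.x)):
        raise MinimizationError("minimization diverged to non-finite coordinates")
    coords = res.x.reshape(n, 3)
    grad_norm = float(np.max(np.abs(res.jac)))
    info = {"energy": float(res.fun), "grad_norm": grad_norm,
            "n_iter": int(res.nit), "converged": grad_norm < gtol}
    out = chain.with_ca(coords) if is_chain else coords
    return out, info


@dataclass
class TrajectoryResult:
    """Snapshots, energy log and final state of a run."""

    snapshots: np.ndarray          # (S, M, n, 3)
    snapshot_steps: np.ndarray     # (S,)
    energy_log: pd.DataFrame       # step, replica, e_kin, e_pot, e_restraint, e_total, temperature
    state: EnsembleState
    full_update_steps: np.ndarray


def run_trajectory(
    initial_coords,
    potential_cfg: PotentialConfig,
    restraints: RestraintSet | None = None,
    *,
    n_steps: int,
    dt: float = 4.89,
    mode: str = "nvt",
    temperature: float = 300.0,
    friction: float = 0.05,
    schedule: AveragingSchedule | None = None,
    averaging: bool = True,
    scale_energy: bool = False,
    seed: int = 0,
    masses: float | np.ndarray = DEFAULT_MASS,
    mapping: SiteMapping = DEFAULT_MAPPING,
    convention: str = "excess",
    group_ids=None,
    energy_log_every: int | None = None,
    initial_velocities: np.ndarray | None = None,
    kernel: str = "auto",
) -> TrajectoryResult:
    """Run restrained (replica-averaged) dynamics on a replica stack.

    `initial_coords` is (n, 3) for a single trajectory or (M, n, 3) for M
    replicas averaging together (use `group_ids` for several independent
    averaging groups in one stack).  `mode` is 'nve' or 'nvt'; initial
    velocities default to a Maxwell-Boltzmann draw at `temperature`.
    Deterministic per seed.
    """
    coords = np.array(initial_coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    m_rep, n_sites = coords.shape[0], coords.shape[1]
    if mode not in ("nve", "nvt"):
        raise ConfigError(f"unknown mode {mode!r}")
    schedule = schedule or AveragingSchedule()
    rng = np.random.default_rng(seed)
    masses_arr = np.broadcast_to(np.asarray(masses, dtype=float), (n_sites,)).copy()

    engine = None
    if restraints is not None and len(restraints):
        engine = ReplicaRestraintEngine(restraints, m_rep, n_sites, mapping=mapping,
                                        convention=convention, group_ids=group_ids)

    if initial_velocities is None:
        vel = maxwell_velocities(m_rep, n_sites, masses_arr, temperature, rng)
    else:
        vel = np.array(initial_velocities, dtype=float)
    state = EnsembleState(coords=coords, velocities=vel, masses=masses_arr,
                          temperatures=np.full(m_rep, float(temperature)), step=0)

    friction_eff = 0.0 if mode == "nve" else friction
    do_avg = averaging and engine is not None and m_rep > 1

    from ._kernels import force_kernel, kernel_supported

    if kernel not in ("auto", "numba", "numpy"):
        raise ConfigError(f"unknown kernel {kernel!r}")
    use_kernel = kernel != "numpy" and kernel_supported(potential_cfg, engine)
    if kernel == "numba" and not use_kernel:
        raise ConfigError("compiled kernel does not support this setup")

    def force_fn(c, step):
        if use_kernel:
            return force_kernel(c, potential_cfg, engine, do_avg, scale_energy)
        e, f = energy_and_forces(c, potential_cfg)
        if engine is not None:
            er, fr = engine.energy_forces(c, averaged=do_avg,
                                          scale_energy=scale_energy)
            return e, er, f + fr
        return e, np.zeros(m_rep), f

    epot, erest, forces = force_fn(state.coords, 0)

    n_snaps = n_steps // schedule.n_snap
    snapshots = np.empty((n_snaps, m_rep, n_sites, 3))
    snapshot_steps = np.empty(n_snaps, dtype=int)
    log_rows = []
    full_updates = []

    def log_energies(step, epot, erest):
        ekin = state.kinetic_energy()
        temp = state.kinetic_temperature()
        for j in range(m_rep):
            log_rows.append((step, j, ekin[j], epot[j], erest[j],
                             ekin[j] + epot[j] + erest[j], temp[j]))

    # wrap the three-output force function for the integrator
    box = {}

    def ff(c, step):
        e, er, f = force_fn(c, step)
        box["epot"], box["erest"] = e, er
        return e + er, f

    isnap = 0
    for s in range(n_steps):
        if do_avg and s > 0 and s % schedule.n_ave == 0:
            engine.full_update(state.coords, s)
            full_updates.append(s)
            epot, erest, forces = force_fn(state.coords, s)
        # energies are logged at the top of the step, after any full update,
        # so rows at update steps carry the refreshed extended energy and the
        # jumps fall exactly on multiples of n_ave
        if energy_log_every and s % energy_log_every == 0:
            log_energies(s, epot, erest)
        _, forces = langevin_step(state, ff, dt, friction_eff, rng, forces=forces)
        epot, erest = box["epot"], box["erest"]
        t = s + 1
        if t % schedule.n_snap == 0 and isnap < n_snaps:
            snapshots[isnap] = state.coords
            snapshot_steps[isnap] = t
            isnap += 1
    if energy_log_every and n_steps % energy_log_every == 0:
        log_energies(n_steps, epot, erest)

    log = pd.DataFrame(
        log_rows,
        columns=["step", "replica", "e_kin", "e_pot", "e_restraint", "e_total",
                 "temperature"],
    )
    return TrajectoryResult(snapshots=snapshots, snapshot_steps=snapshot_steps,
                            energy_log=log, state=state,
                            full_update_steps=np.array(full_updates, dtype=int))
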