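"""Multiplexed temperature replica exchange (MREMD) with replica averaging.

M replicas run at each of N_T ladder temperatures (N_T x M replicas total).
Every n_exch steps, neighboring temperature levels attempt Metropolis swaps of
their temperatures; under multiplexing each replica at the lower level is
paired with a randomly chosen distinct partner at the upper level, and
neighbor pairs alternate even/odd across attempts.  Because the baseline
potential here is temperature-independent, the standard acceptance rule

    P(accept) = min(1, exp[(beta_a - beta_b)(E_a - E_b)])

applies, with E the extended potential energy (baseline + restraint penalty)
of each replica.  Replica-averaging groups are always the replicas *currently*
sharing a temperature, so after an accepted swap the averaging partners
change; full averages are recomputed right after each exchange round (n_ave
divides n_exch, so exchange steps are full-update steps).

Execution is sequential and deterministic per seed; the results contract is
order-independence at the synchronization points, standing in for an MPI
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .averaging import AveragingSchedule, ReplicaRestraintEngine
from .dynamics import KB, DEFAULT_MASS, EnsembleState, langevin_step, maxwell_velocities
from .errors import ConfigError
from .potential import PotentialConfig, energy_and_forces
from .restraints import DEFAULT_MAPPING, RestraintSet, SiteMapping

# published temperature ladders (K); the name encodes N_T x multiplexing
LADDER_SETS: dict[str, tuple[tuple[int, ...], int]] = {
    "24x2": ((262, 264, 267, 270, 274, 277, 279, 282, 285, 288, 290, 292,
              295, 298, 301, 305, 308, 315, 327, 333, 340, 355, 362, 370), 2),
    "12x4": ((262, 267, 274, 279, 285, 290, 295, 301, 308, 333, 355, 370), 4),
    "8x6": ((274, 279, 285, 290, 295, 301, 308, 333), 6),
    "6x8": ((279, 285, 290, 295, 301, 308), 8),
}


@dataclass(frozen=True)
class Ladder:
    """Temperature ladder with uniform multiplexing M per level."""

    temperatures: tuple[float, ...]
    multiplexing: int

    def __post_init__(self):
        if self.multiplexing < 1:
            raise ConfigError("multiplexing must be >= 1")
        if len(self.temperatures) < 1:
            raise ConfigError("need at least one temperature")
        if any(t <= 0 for t in self.temperatures):
            raise ConfigError("temperatures must be positive")

    @property
    def n_temperatures(self) -> int:
        return len(self.temperatures)

    @property
    def n_replicas(self) -> int:
        return len(self.temperatures) * self.multiplexing

    def initial_assignment(self) -> np.ndarray:
        """Replica -> temperature-level index; replicas blocked by level."""
        return np.repeat(np.arange(self.n_temperatures), self.multiplexing)


def make_ladder(name_or_temps, multiplexing: int | None = None) -> Ladder:
    """Build a named ladder ('24x2', '12x4', '8x6', '6x8') or a custom one."""
    if isinstance(name_or_temps, str):
        if name_or_temps not in LADDER_SETS:
            raise ConfigError(
                f"unknown ladder set {name_or_temps!r}; known: {sorted(LADDER_SETS)}"
            )
        temps, m = LADDER_SETS[name_or_temps]
        if multiplexing is not None and multiplexing != m:
            raise ConfigError(
                f"ladder {name_or_temps} has multiplexing {m}, got {multiplexing}"
            )
        return Ladder(temperatures=tuple(float(t) for t in temps), multiplexing=m)
    if multiplexing is None:
        raise ConfigError("custom ladder needs an explicit multiplexing")
    return Ladder(temperatures=tuple(float(t) for t in name_or_temps),
                  multiplexing=multiplexing)


def exchange_probability(temp_a: float, temp_b: float, e_a: float, e_b: float) -> float:
    """Metropolis acceptance probability for swapping two temperatures."""
    beta_a = 1.0 / (KB * temp_a)
    beta_b = 1.0 / (KB * temp_b)
    arg = (beta_a - beta_b) * (e_a - e_b)
    return 1.0 if arg >= 0.0 else float(np.exp(arg))


def attempt_exchange(temp_a: float, temp_b: float, e_a: float, e_b: float,
                     rng: np.random.Generator) -> bool:
    """Draw a Metropolis decision for a temperature swap."""
    p = exchange_probability(temp_a, temp_b, e_a, e_b)
    return bool(rng.random() < p)


@dataclass
class MREMDResult:
    """Snapshot streams tagged by temperature, plus the exchange record."""

    snapshots: np.ndarray        # (S, R, n, 3)
    snapshot_steps: np.ndarray   # (S,)
    snapshot_level: np.ndarray   # (S, R) temperature-level index per replica
    ladder: Ladder
    assignment: np.ndarray       # final replica -> level
    exchange_record: list        # (step, level_a, level_b, replica_a, replica_b, accepted)
    acceptance_rate: float

    def at_temperature(self, temperature: float) -> np.ndarray:
        """All snapshots collected while running at the given temperature, (K, n, 3)."""
        (lvl,) = np.where(np.isclose(self.ladder.temperatures, temperature))
        if lvl.size != 1:
            raise ConfigError(f"{temperature} K is not on the ladder")
        mask = self.snapshot_level == lvl[0]
        return self.snapshots[mask]


def run_mremd(
    initial_coords,
    potential_cfg: PotentialConfig,
    restraints: RestraintSet | None,
    ladder: Ladder,
    *,
    n_steps: int,
    dt: float = 4.89,
    friction: float = 0.05,
    schedule: AveragingSchedule | None = None,
    averaging: bool = True,
    seed: int = 0,
    masses=DEFAULT_MASS,
    mapping: SiteMapping = DEFAULT_MAPPING,
    convention: str = "excess",
) -> MREMDResult:
    """Replica-averaged MREMD run; deterministic per seed.

    `initial_coords` is (R, n, 3) with R = ladder.n_replicas (replicas blocked
    by temperature level, coldest first).  Averaging groups follow the current
    temperature assignment; full averages every n_ave steps; exchange attempts
    every n_exch steps with alternating even/odd neighbor-level pairing.
    """
    schedule = schedule or AveragingSchedule()
    coords = np.array(initial_coords, dtype=float)
    r_tot = ladder.n_replicas
    if coords.shape[0] != r_tot:
        raise ConfigError(f"need {r_tot} replicas, got {coords.shape[0]}")
    n_sites = coords.shape[1]
    temps = np.asarray(ladder.temperatures, dtype=float)
    assignment = ladder.initial_assignment()
    rng = np.random.default_rng(seed)
    masses_arr = np.broadcast_to(np.asarray(masses, dtype=float), (n_sites,)).copy()

    engine = None
    if restraints is not None and len(restraints):
        engine = ReplicaRestraintEngine(restraints, r_tot, n_sites, mapping=mapping,
                                        convention=convention, group_ids=assignment)
    do_avg = averaging and engine is not None and ladder.multiplexing > 1

    vel = maxwell_velocities(r_tot, n_sites, masses_arr, temps[assignment], rng)
    state = EnsembleState(coords=coords, velocities=vel, masses=masses_arr,
                          temperatures=temps[assignment].copy(), step=0)

    last_energy = np.zeros(r_tot)

    def force_fn(c, step):
        e, f = energy_and_forces(c, potential_cfg)
        if engine is not None:
            er, fr = engine.energy_forces(c, averaged=do_avg)
            last_energy[:] = e + er
            return e + er, f + fr
        last_energy[:] = e
        return e, f

    _, forces = force_fn(state.coords, 0)

    n_snaps = n_steps // schedule.n_snap
    snapshots = np.empty((n_snaps, r_tot, n_sites, 3))
    snapshot_steps = np.empty(n_snaps, dtype=int)
    snapshot_level = np.empty((n_snaps, r_tot), dtype=int)
    record = []
    n_acc = n_att = 0
    isnap = 0

    for s in range(n_steps):
        if s > 0 and s % schedule.n_exch == 0:
            # exchange round: alternating even/odd neighbor-level pairs
            parity = (s // schedule.n_exch - 1) % 2
            for la in range(parity, ladder.n_temperatures - 1, 2):
                lb = la + 1
                (ra,) = np.where(assignment == la)
                (rb,) = np.where(assignment == lb)
                rb = rng.permutation(rb)
                for a, b in zip(ra, rb):
                    acc = attempt_exchange(temps[la], temps[lb],
                                           last_energy[a], last_energy[b], rng)
                    n_att += 1
                    record.append((s, la, lb, int(a), int(b), acc))
                    if acc:
                        n_acc += 1
                        assignment[a], assignment[b] = lb, la
                        scale_a = np.sqrt(temps[lb] / temps[la])
                        state.velocities[a] *= scale_a
                        state.velocities[b] /= scale_a
            state.temperatures = temps[assignment].copy()
            if engine is not None:
                engine.set_groups(assignment)
        if do_avg and s > 0 and s % schedule.n_ave == 0:
            engine.full_update(state.coords, s)
            _, forces = force_fn(state.coords, s)
        _, forces = langevin_step(state, force_fn, dt, friction, rng, forces=forces)
        t = s + 1
        if t % schedule.n_snap == 0 and isnap < n_snaps:
            snapshots[isnap] = state.coords
            snapshot_steps[isnap] = t
            snapshot_level[isnap] = assignment
            isnap += 1

    return MREMDResult(
        snapshots=snapshots, snapshot_steps=snapshot_steps,
        snapshot_level=snapshot_level, ladder=ladder, assignment=assignment,
        exchange_record=record,
        acceptance_rate=(n_acc / n_att) if n_att else float("nan"),
    )
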