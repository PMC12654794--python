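"""Synthetic two-state validation benchmark.

The cleanest probe of replica averaging is a restraint set derived from two
known parent conformations: distance restraints are synthesized as
inverse-sixth-power averages of the distances measured on the parents,

    d_avg = [ w1 d1^-6 + w2 d2^-6 ]^(-1/6),   bounds  d_avg -/+ tol,

with equal weights by default.  Where the parents agree the bounds pin the
common geometry for every replica; where they disagree the averaged bound sits
between d1 and d2, so (for small tol) it is violated by *both* parents
individually and can only be satisfied on average across simultaneously
running replicas — the mechanism under test.

The two parents are the two homogeneous backbone states of the benchmark
potential: helical conformers wound at the two torsional rotamer wells
(gamma = 50 deg, a compact helix, versus gamma = 120 deg, a more open one),
sharing bond and angle geometry.  This makes the parents exactly isoenergetic
under the baseline potential (populations are then decided by the restraints,
not the baseline), makes the conflicting restraint differences small enough
(mostly 0.5-3 A) to stay inside the responsive wall of the flat-bottom
penalty, and gives a cooperative, funnel-like two-state landscape through the
nearest-neighbor dihedral coupling.  Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .averaging import AveragingSchedule
from .errors import ConfigError, GenerationError, NumericError
from .geometry import CGChain, build_random_chain, chain_from_internal, superpose_rmsd
from .potential import PotentialConfig
from .restraints import DistanceRestraint, RestraintSet

DEFAULT_N_RES = 12
DEFAULT_TOL = 0.5              # A, half-width of the synthetic restraint window
DEFAULT_SEPARATION = 4.0       # A, minimum parent1-parent2 Calpha RMSD
DEFAULT_MAX_PAIR_DIST = 12.0   # A, NOE-like short-range pair selection
DEFAULT_MIN_SEQ_SEP = 2
BENCHMARK_TEMPERATURE = 300.0  # K, canonical two-state runs
BENCHMARK_DT = 4.89            # fs
BENCHMARK_FRICTION = 0.003     # 1/fs, near the Kramers turnover for state flips
BENCHMARK_STEPS = 1_000_000
BENCHMARK_N_SNAP = 2_000
TRAJECTORIES_PER_BATCH = 8     # 3 batches of 8/n_replicas runs mirror the design

# torsional rotamer wells of the benchmark chain (rad) and their geometry
GAMMA_COMPACT = np.deg2rad(50.0)
GAMMA_OPEN = np.deg2rad(120.0)
THETA_BENCH = np.deg2rad(105.0)


def benchmark_potential() -> PotentialConfig:
    """Baseline potential used by the two-state benchmark.

    Stiff virtual bonds and angles (so the thermal cloud of a conformer stays
    well inside the 3 A assignment radius), a two-well torsion with minima at
    the compact- and open-helix rotamers (~2 kcal/mol barrier), a
    nearest-neighbor dihedral coupling that makes the backbone states
    cooperative, and a WCA excluded-volume wall.
    """
    return PotentialConfig(
        k_bond=100.0, d0=3.8,
        k_theta=150.0, theta0=THETA_BENCH,
        eps_rep=3.0, r_rep=4.2,
        torsion_wells=(GAMMA_COMPACT, GAMMA_OPEN, 120.0),
        dihedral_coupling=3.0,
    )


@dataclass
class TwoStateFixture:
    """Two parent conformations plus the restraints averaged over them."""

    parent1: CGChain
    parent2: CGChain
    restraints: RestraintSet
    potential: PotentialConfig
    seed: int
    tol: float
    separation: float  # achieved parent1-parent2 RMSD, A

    @property
    def n_restraints(self) -> int:
        return len(self.restraints)


def make_parents(
    n_res: int = DEFAULT_N_RES,
    seed: int = 0,
    potential_cfg: PotentialConfig | None = None,
    min_separation: float = DEFAULT_SEPARATION,
    max_attempts: int = 10,
) -> tuple[CGChain, CGChain, float]:
    """Two energy-minimized, isoenergetic parent conformations.

    Parent 1 is the compact helix (all dihedrals in the 50 deg well), parent 2
    the open helix (120 deg well) of the same chain; a small seeded jitter is
    applied before relaxation, so the construction is deterministic per seed.
    Returns (parent1, parent2, rmsd); raises :class:`GenerationError` if the
    required separation cannot be reached.
    """
    from .dynamics import minimize

    if n_res < 8:
        raise ConfigError("need n_res >= 8 for a meaningful two-state fixture")
    cfg = potential_cfg or benchmark_potential()
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(max_attempts):
        rng = np.random.default_rng(child)
        chains = []
        ok = True
        for gamma in (GAMMA_COMPACT, GAMMA_OPEN):
            raw = chain_from_internal(
                np.full(n_res - 1, cfg.d0),
                np.full(n_res - 2, cfg.theta0),
                np.full(n_res - 3, gamma),
            )
            raw = raw + 0.01 * rng.standard_normal(raw.shape)
            chain, info = minimize(CGChain(ca=raw), cfg)
            if not info["converged"]:
                ok = False
                break
            chains.append(chain)
        if not ok:
            continue
        rmsd = superpose_rmsd(chains[0], chains[1])
        if rmsd >= min_separation:
            return chains[0], chains[1], rmsd
    raise GenerationError(
        f"could not generate parents {min_separation} A apart in {max_attempts} attempts"
    )


def default_pair_selection(
    parent1: CGChain,
    parent2: CGChain,
    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP,
    max_dist: float = DEFAULT_MAX_PAIR_DIST,
) -> list[tuple[int, int]]:
    """CA-CA pairs (1-based) with sequence separation >= min_seq_sep that are
    within `max_dist` in at least one parent (short-range NOE-like bias)."""
    n = parent1.n_res
    pairs = []
    for i in range(n):
        for j in range(i + min_seq_sep, n):
            d1 = np.linalg.norm(parent1.ca[j] - parent1.ca[i])
            d2 = np.linalg.norm(parent2.ca[j] - parent2.ca[i])
            if min(d1, d2) <= max_dist:
                pairs.append((i + 1, j + 1))
    return pairs


def synthesize_restraints(
    parent1: CGChain,
    parent2: CGChain,
    weights: tuple[float, float] = (0.5, 0.5),
    pairs: list[tuple[int, int]] | None = None,
    tol: float = DEFAULT_TOL,
) -> RestraintSet:
    """Distance restraints from the r^-6 average over the two parents.

    One restraint per pair with bounds [max(0, d_avg - tol), d_avg + tol].
    """
    if tol <= 0:
        raise ConfigError("tol must be positive")
    w1, w2 = weights
    if w1 < 0 or w2 < 0 or w1 + w2 <= 0:
        raise ConfigError("weights must be >= 0 with positive sum")
    w1, w2 = w1 / (w1 + w2), w2 / (w1 + w2)
    if pairs is None:
        pairs = default_pair_selection(parent1, parent2)
    out = []
    for i, j in pairs:
        d1 = float(np.linalg.norm(parent1.ca[j - 1] - parent1.ca[i - 1]))
        d2 = float(np.linalg.norm(parent2.ca[j - 1] - parent2.ca[i - 1]))
        if d1 <= 0.0 or d2 <= 0.0:
            raise NumericError(f"coincident sites for pair ({i}, {j})")
        d_avg = (w1 * d1**-6 + w2 * d2**-6) ** (-1.0 / 6.0)
        out.append(DistanceRestraint(i_res=i, j_res=j,
                                     lower=max(0.0, d_avg - tol),
                                     upper=d_avg + tol))
    return RestraintSet(out)


def make_two_state_fixture(
    n_res: int = DEFAULT_N_RES,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    potential_cfg: PotentialConfig | None = None,
) -> TwoStateFixture:
    """Parents plus synthetic restraints in one deterministic call."""
    cfg = potential_cfg or benchmark_potential()
    p1, p2, rmsd = make_parents(n_res, seed, cfg)
    rs = synthesize_restraints(p1, p2, tol=tol)
    return TwoStateFixture(parent1=p1, parent2=p2, restraints=rs, potential=cfg,
                           seed=seed, tol=tol, separation=rmsd)


def random_start(
    n_res: int,
    seed: int,
    potential_cfg: PotentialConfig | None = None,
    restraints: RestraintSet | None = None,
) -> np.ndarray:
    """Random self-avoiding coil relaxed to a local minimum.

    The benchmark's starting-structure protocol: grow a random chain, then
    energy-minimize it under the extended energy (baseline plus the plain
    restraint penalties when a restraint set is given — restrained runs start
    from minima of the energy function they propagate, as restrained dynamics
    protocols do).  Each dihedral falls into one of the rotamer wells, so
    starts are random points of the model's discrete state space.
    """
    cfg = potential_cfg or benchmark_potential()
    from .dynamics import minimize

    chain = build_random_chain(n_res, seed, min_sep=4.0)
    relaxed, _ = minimize(chain, cfg, restraints)
    return relaxed.ca


@dataclass(frozen=True)
class BenchmarkRun:
    """One run of the replica-count benchmark: n_replicas averaging together."""

    n_replicas: int
    batch: int
    run: int
    seed: int                  # drives dynamics noise
    start_seeds: tuple[int, ...]  # one random start per replica
    n_steps: int
    temperature: float
    dt: float
    friction: float
    schedule: AveragingSchedule
    averaging: bool


def benchmark_config(
    n_replicas: int,
    seed: int,
    n_steps: int = BENCHMARK_STEPS,
    batches: int = 3,
    n_snap: int = BENCHMARK_N_SNAP,
) -> list[list[BenchmarkRun]]:
    """Run plan for the population-vs-replica-count experiment.

    Mirrors the study design: 8 trajectories per batch partitioned into
    independent runs of `n_replicas` each (n_replicas = 1 means canonical runs
    with no averaging; 8 means one averaged run per batch), canonical dynamics
    at 300 K, full averages every 100 steps.  Returns one list of
    :class:`BenchmarkRun` per batch with distinct seeds derived from `seed`.
    """
    if n_replicas not in (1, 2, 4, 8):
        raise ConfigError("n_replicas must be one of 1, 2, 4, 8")
    runs_per_batch = TRAJECTORIES_PER_BATCH // n_replicas
    # no exchanges in this benchmark; n_exch just has to satisfy the invariant
    schedule = AveragingSchedule(n_ave=100, n_exch=((n_steps + 99) // 100) * 100,
                                 n_snap=n_snap)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(batches * runs_per_batch * (1 + n_replicas))
    seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in children]
    plan = []
    k = 0
    for b in range(batches):
        batch = []
        for r in range(runs_per_batch):
            dyn_seed = seeds[k]
            start_seeds = tuple(seeds[k + 1:k + 1 + n_replicas])
            k += 1 + n_replicas
            batch.append(BenchmarkRun(
                n_replicas=n_replicas, batch=b, run=r, seed=dyn_seed,
                start_seeds=start_seeds, n_steps=n_steps,
                temperature=BENCHMARK_TEMPERATURE, dt=BENCHMARK_DT,
                friction=BENCHMARK_FRICTION, schedule=schedule,
                averaging=n_replicas > 1,
            ))
        plan.append(batch)
    return plan


def run_benchmark_batch(
    fixture: TwoStateFixture,
    runs: list[BenchmarkRun],
):
    """Execute one batch of the two-state benchmark; returns second-half snapshots.

    Runs of the same batch are stacked into one vectorized trajectory call per
    run (replicas of a run average together; independent runs do not).
    Returns an (K, n_res, 3) array of the pooled second-half snapshots.
    """
    from .dynamics import run_trajectory

    halves = []
    for run in runs:
        starts = np.stack([
            random_start(fixture.parent1.n_res, s, fixture.potential,
                         fixture.restraints)
            for s in run.start_seeds])
        res = run_trajectory(
            starts, fixture.potential, fixture.restraints,
            n_steps=run.n_steps, dt=run.dt, mode="nvt",
            temperature=run.temperature, friction=run.friction,
            schedule=run.schedule, averaging=run.averaging, seed=run.seed)
        snaps = res.snapshots  # (S, M, n, 3)
        halves.append(snaps[snaps.shape[0] // 2:].reshape(-1, fixture.parent1.n_res, 3))
    return np.concatenate(halves, axis=0)
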