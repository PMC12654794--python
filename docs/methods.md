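# Methods

`ravmd` implements replica-averaged experimental restraints for
coarse-grained polypeptide dynamics: the restraint functionals and their
analytic gradients, the inverse-power replica-averaging machinery with
scheduled full/partial updates, molecular-dynamics integrators, multiplexed
temperature replica exchange, ensemble-compatibility metrics, and a synthetic
two-state benchmark that validates the whole pipeline.  This note records the
model, the parameters that matter, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## Chain model

A polypeptide is reduced to its Calpha trace: `n` sites joined by virtual
bonds of ~3.8 A, with optional side-chain-center pseudo-atoms carried for
bookkeeping (they are not dynamical).  Internal coordinates are the
virtual-bond lengths `d_i`, the virtual-bond angles `theta_i` over three
consecutive sites (in [0, pi]) and the virtual-bond dihedrals `gamma_i` over
four consecutive sites (IUPAC sign, wrapped to (-pi, pi]).  Superposition RMSD
uses Kabsch least squares on Calpha coordinates only, with the reflection
correction.  Units are Angstrom, radians, femtoseconds, amu and kcal/mol
throughout; degrees appear only in files.  k_B = 1.987204e-3 kcal/(mol K);
1 kcal/(mol A)/amu = 4.184e-4 A/fs^2 exactly.

## Baseline potential

The restraint machinery is defined on top of *any* baseline potential exposing
`energy_and_forces(coords, cfg)` with exact negative gradients.  The shipped
surrogate mirrors the usual term taxonomy of coarse-grained protein force
fields:

| term | form | default |
|---|---|---|
| virtual bond | 1/2 k (d - d0)^2 | k = 100 kcal/(mol A^2), d0 = 3.8 A |
| virtual-bond angle | 1/2 k (theta - theta0)^2 | k = 10, theta0 = 105 deg |
| excluded volume | WCA shifted LJ, zero beyond r_rep | eps = 2 kcal/mol, r_rep = 4.0 A |
| torsion (optional) | cosine series, or product double well B(1-cos(g-g1))(1-cos(g-g2)) | off |
| torsion well bias (optional) | raises well g1 by `bias` relative to g2 | 0 |
| dihedral coupling (optional) | -J sum cos(g_{i+1} - g_i) | 0 |

The two-well torsion places rotamer states at arbitrary dihedral values (a
pure cosine series cannot, because it is even in gamma and would create
mirror-degenerate minima).  The nearest-neighbor dihedral coupling is the
minimal analog of the local-correlation terms real coarse-grained force
fields need to make backbone states cooperative; a boundary between the two
rotamer states costs roughly J(1 - cos(g1 - g2)).  The surrogate is
temperature independent, which keeps the replica-exchange acceptance rule in
its standard Metropolis form.

## Restraint functionals

Distance restraints use a flat-bottom well with a quartic wall of thickness
`sigma` and a log-cosh factor that makes the tail asymptotically linear with
slope `A*kappa`:

    V(d) = A x^4/(sigma^4 + x^4) (1 + kappa ln cosh x),  x = d - d_u (or d - d_l),

zero inside [d_l, d_u], mirror-symmetric, with value and first derivative
vanishing at the boundaries.  Defaults: A = 5 kcal/mol, sigma = 1 A,
kappa = 0.01.  The gentle tail (0.05 kcal/(mol A)) means badly violated
restraints steer rather than tear; the responsive region of the wall is
roughly the first 2-3 A beyond a boundary.

Angular restraints penalize the wrapped offset `delta` of theta or gamma from
the window midpoint.  The printed form of this penalty in the source
literature evaluates to delta^4/4 immediately outside the window, which is
discontinuous at the window edge; the package default is the continuous
excess form amplitude*(|delta| - h)^4/4 (h the half-width), which is C1 at the
edge and therefore usable in symplectic dynamics.  The discontinuous variant
is available behind `convention="printed"` for cross-checks.  Defaults:
A_theta = 1, A_gamma = 5 kcal/mol.

Interproton-distance estimation from coarse-grained geometry is abstracted
behind a `SiteMapping`; the default maps restraints to Calpha (or side-chain
center) sites.  An analytical proton-position estimator can be plugged in
behind the same contract without touching the restraint code.

## Replica averaging

The averaged observable over M replicas is the inverse-power mean
`[ (1/M) sum_j y_j^-m ]^(-1/m)` with m = 3 for distances and m = -1
(arithmetic mean) for angles; dihedrals are averaged on the circle via the
atan2 of sine/cosine means.  Full synchronization happens every `n_ave` steps
(default 100); between full updates each replica updates the average with its
own current value only, keeping the other replicas' power sums frozen.  The
gradient of this partial average is analytic,

    grad ybar^(J) = (1/M) (ybar^(J)/y_J)^(m+1) grad y_J,

and restraint forces are scaled by M so they do not vanish at large replica
counts.  In production only forces are scaled; in microcanonical validation
runs the energy is scaled by the same factor, making each replica's total
energy exactly conserved between full updates ("segment-symplectic": the
energy staircase may jump only at update steps).  Before the first full
update (step n_ave) plain non-averaged penalties act, unscaled — scaling
non-averaged forces by M would double-count.

The M = 1 case short-circuits (average := own value, gradient factor := 1,
scale := 1) rather than evaluating `((y^-m)/1)^(-1/m)`, so a single-replica
"averaged" run is bitwise identical to a non-averaged one.

Under temperature replica exchange, averaging groups are the replicas
*currently* sharing a ladder temperature, with indicator weights 1/M that are
normalized to one at every temperature; groups are rebuilt after every
exchange round (n_ave divides n_exch, so exchange steps coincide with full
updates).

## Dynamics

NVE propagation is velocity Verlet; NVT is the BAOAB splitting of Langevin
dynamics with the exact Ornstein-Uhlenbeck velocity refresh, which reduces to
velocity Verlet identically at zero friction.  Masses default to 110 amu per
site (an average residue mass; a surrogate-scale choice that sets timescales,
not correctness).  The module-level friction default is 0.05 fs^-1, a
placeholder carried over from the interface design and not a physical value;
the benchmark uses 0.003 fs^-1 (see below).  Minimization is L-BFGS-B on the
combined baseline + restraint energy with analytic gradients, targeting a
force max-norm of 1e-4 kcal/(mol A).

The common fast path (Calpha-only chains, distance restraints) runs through
a numba-compiled force kernel that reproduces the vectorized reference
implementation to float reordering accuracy (a regression test holds the two
within 1e-10); setups the kernel does not cover fall back to the numpy path
automatically.

Multiplexed REMD pairs neighboring temperature levels in alternating
even/odd order per attempt, with a random permutation of the M replicas at
the upper level choosing partners; accepted swaps exchange temperatures (and
rescale velocities by sqrt(T_new/T_old)).  Execution is sequential and
deterministic per seed; order-independence at the synchronization points is
the contract that an MPI implementation would honor.

## Ensemble analysis

Ensemble-averaged distances are inverse-sixth-power weighted means.
Compatibility with the upper distance boundaries is summarized by rho_u+, the
RMS positive excess over the upper bounds; the percentage of restraints
satisfied within their bounds; the violation count (upper bounds only, with
lower-bound violations tallied separately); and the gross-violation count
(excess >= 2 A, inclusive).  Two-state populations assign each snapshot to
the nearer of two references when its Calpha RMSD is strictly below 3 A (ties
and everything farther stay unassigned).  Ward minimum-variance clustering on
the pairwise Calpha-RMSD matrix dissects an ensemble into representative
families; each family is represented by its member with the lowest restraint
penalty, carrying the family's cumulative weight.

## The synthetic two-state benchmark

The benchmark emulates, at desk scale, the validation protocol in which
distance restraints are synthesized from two known parent conformations as
equal-weight r^-6 averages with bounds d_avg +/- tol (tol = 0.5 A), and
replica-averaged runs must recover an ensemble split between the parents.

The benchmark chain is a 12-residue Calpha trace under a purpose-built
instance of the surrogate: k_bond = 100, k_theta = 150 kcal/(mol rad^2),
theta0 = 105 deg, WCA repulsion (eps = 3, r_rep = 4.2 A), a two-well torsion
at gamma = 50 deg and 120 deg with B = 120 (about a 3.9 kcal/mol barrier
between adjacent wells and ~5 deg thermal width inside a well), and dihedral
coupling J = 3.  The parents are the two homogeneous backbone states — the compact
helix (all gamma = 50 deg) and the open helix (all gamma = 120 deg) — which
are exactly isoenergetic by construction, are separated by 4.2 A Calpha RMSD,
and differ on most restrained pairs by 0.5-3 A, i.e. inside the responsive
wall of the penalty.  These choices are deliberate:

- isoenergetic parents mean the recovered populations are decided by the
  restraints, not the baseline;
- conflicts at the wall scale keep sorting forces alive at desk-scale run
  lengths (tail-scale conflicts of ~0.05 kcal/(mol A) would need production
  scale runs to act);
- the stiff bonds/angles and moderate torsion wells give a parent-centered
  thermal cloud of ~0.6 A RMSD, well inside the 3 A assignment radius;
- the dihedral coupling makes the two backbone states cooperative, so
  partially-switched chains are penalized and the landscape is two-state.

Starting structures are self-avoiding random coils relaxed to a local
minimum of the extended energy (baseline plus the plain restraint penalties,
as restrained-dynamics protocols minimize the energy function they
propagate); each dihedral falls into a rotamer well, so starts are random
points of the model's discrete state space biased toward restraint
consistency.
Benchmark runs are canonical (300 K) Langevin dynamics, dt = 4.89 fs,
friction 0.003 fs^-1 (near the Kramers turnover for dihedral flips in this
model — heavier damping slows state sorting roughly in proportion), full
averages every 100 steps, 1,000,000 steps per trajectory with snapshots every
2,000 steps, populations measured over the second half.  The study design is
3 batches of 8 trajectories: one 8-replica averaged run per batch, or 8
independent canonical trajectories per batch for the no-averaging reference.

What passing shows: with 8 replicas the averaged restraints recover both
parent states (assigned populations summing to >= 0.9, both states >= 0.1)
from random starts, which no single restrained conformation can do.  Under
these conditions the assigned-population sum reaches 0.98-1.00 per batch
(the residual being brief crossing excursions), with the open state holding
a quarter to a third of the population.  What it does not show: behavior of real proteins under a real force
field — the surrogate landscape is vastly simpler (two homogeneous states, no
side chains, no solvent), restraint counts are small, runs are ~50x shorter
than production scale, and proton positions are represented by Calpha sites.

A known limitation of the surrogate benchmark is the *canonical* reference
branch: because r^-6 averaging centers every synthetic window near the
shorter of the two parent distances, the best single-structure fit is unique
(a near-compact conformation), and the fluid landscape lets every
non-averaged trajectory find it.  Canonical runs are therefore highly
reproducible here, whereas with a rugged real force field they scatter across
basins and batch-to-batch dispersion is large.  The qualitative claim
"dispersion shrinks as the replica count grows" consequently cannot be
reproduced by this surrogate at desk scale; the corresponding check in the
acceptance suite documents this honestly (see the decisions record outside
the package for the design survey that led here).

## Numerical choices and degenerate inputs

- Dihedral gradients use the standard two-normal formulation; collinear
  triplets are guarded by a floor on sin(theta) (gradients there are not
  meaningful, and the angle restraint windows keep dynamics away from the
  poles).
- The circular average raises a degenerate-average error when the sine and
  cosine means both vanish (antipodal cancellation).
- Energy logging happens at the top of each step after any full update, so
  the energy staircase jumps land exactly on multiples of n_ave.
- `pandas.read_csv(float_precision="round_trip")` keeps restraint files
  bit-identical through write/read/write.
- Random-chain growth rejects placements within 4 A of any non-bonded site,
  with bounded retries and restarts; failure raises a generation error
  suggesting a smaller separation.
- All randomness flows through explicit numpy Generators seeded from run
  configuration; trajectories, fixtures and benchmark plans are bitwise
  reproducible per seed.
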