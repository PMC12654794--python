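"""Ensemble-restraint compatibility metrics and ensemble dissection.

An ensemble satisfies NOE-style distance restraints *on average*: the
ensemble-averaged distance for restraint i is the inverse-sixth-power weighted
mean

    dbar_i = [ sum_k w_k d_{k,i}^-6 ]^(-1/6),

reflecting the r^-6 scaling of NOE intensities.  Compatibility with the upper
boundaries d_u is summarized by the root-mean-square positive excess

    rho_u+ = sqrt( (1/N_d) sum_i delta_i^2 ),
    delta_i = dbar_i - d_i^u  if dbar_i > d_i^u, else 0,

together with the percentage of restraints satisfied within their bounds, the
count of upper-bound violations (nviol) and the count of gross violations
(Nviol, excess >= 2 A).  Lower-bound violations are tallied separately; they
do not enter nviol.

Two-state benchmarks are scored by assigning each snapshot to the nearer of
two reference structures when its Calpha RMSD is below a cutoff (3 A by
default; ties and everything farther stay unassigned), giving per-state
populations.  Ensembles are dissected into representative families by Ward
minimum-variance clustering on the pairwise Calpha-RMSD matrix; each family is
represented by its member with the lowest restraint penalty, carrying the
family's cumulative weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ConfigError, NumericError, SizeError
from .geometry import CGChain, pairwise_rmsd_matrix, superpose_rmsd
from .restraints import DEFAULT_MAPPING, RestraintSet, SiteMapping, observe, \
    restraint_energy_forces

GROSS_VIOLATION_CUTOFF = 2.0  # A; a violation this large or larger is "gross"
ASSIGN_CUTOFF = 3.0           # A; default RMSD cutoff for state assignment


@dataclass
class EnsembleMetrics:
    """Restraint-compatibility summary for one ensemble."""

    rho_u_plus: float      # A, rms positive excess over upper bounds
    pct_satisfied: float   # % of restraints with dbar within [d_l, d_u]
    nviol: int             # upper-bound violations
    nviol_gross: int       # violations >= 2 A
    nviol_lower: int       # lower-bound violations (reported separately)
    n_restraints: int


@dataclass
class PopulationSummary:
    """Fractions of snapshots assigned to each of two reference states."""

    p1: float
    p2: float
    p_unassigned: float
    n1: int
    n2: int
    n_unassigned: int
    n_total: int


def ensemble_average_distances(distances, weights=None, exponent: float = 6.0):
    """Inverse-power weighted ensemble average of distances.

    `distances` is (K, R): K conformations by R restraints (or a 1-D array for
    a single restraint).  Weights are normalized internally; a single
    conformation returns its own distances.
    """
    d = np.atleast_2d(np.asarray(distances, dtype=float))
    if np.any(d <= 0.0):
        raise NumericError("distances must be positive")
    k = d.shape[0]
    if weights is None:
        w = np.full(k, 1.0 / k)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (k,):
            raise SizeError("one weight per conformation required")
        if np.any(w < 0.0) or w.sum() <= 0.0:
            raise ConfigError("weights must be >= 0 with positive sum")
        w = w / w.sum()
    out = (w @ d ** (-exponent)) ** (-1.0 / exponent)
    return out


def compute_metrics(dbar, d_upper, d_lower=None) -> EnsembleMetrics:
    """Score ensemble-averaged distances against restraint boundaries."""
    dbar = np.asarray(dbar, dtype=float)
    d_upper = np.asarray(d_upper, dtype=float)
    if dbar.shape != d_upper.shape:
        raise SizeError("dbar and d_upper must have equal length")
    if d_lower is None:
        d_lower = np.zeros_like(d_upper)
    else:
        d_lower = np.asarray(d_lower, dtype=float)
        if d_lower.shape != dbar.shape:
            raise SizeError("d_lower length mismatch")
    excess = np.where(dbar > d_upper, dbar - d_upper, 0.0)
    nviol = int(np.count_nonzero(dbar > d_upper))
    gross = int(np.count_nonzero(excess >= GROSS_VIOLATION_CUTOFF))
    low = int(np.count_nonzero(dbar < d_lower))
    within = np.count_nonzero((dbar >= d_lower) & (dbar <= d_upper))
    n = dbar.size
    rho = float(np.sqrt(np.mean(excess**2))) if n else 0.0
    return EnsembleMetrics(
        rho_u_plus=rho,
        pct_satisfied=100.0 * within / n if n else 100.0,
        nviol=nviol,
        nviol_gross=gross,
        nviol_lower=low,
        n_restraints=n,
    )


def metrics_from_ensemble(
    ensemble,
    restraints: RestraintSet,
    weights=None,
    mapping: SiteMapping = DEFAULT_MAPPING,
    exponent: float = 6.0,
) -> EnsembleMetrics:
    """Observe all distance restraints on each conformation, average, score."""
    dist = restraints.distances
    if not dist:
        raise ConfigError("restraint set contains no distance restraints")
    sub = RestraintSet(list(dist))
    obs = np.stack([observe(_as_chain(c), sub, mapping) for c in ensemble])
    dbar = ensemble_average_distances(obs, weights, exponent)
    return compute_metrics(dbar, np.array([r.upper for r in dist]),
                           np.array([r.lower for r in dist]))


def assign_state(rmsd1: float, rmsd2: float, cutoff: float = ASSIGN_CUTOFF) -> int:
    """0 = state 1, 1 = state 2, -1 = unassigned (ties or beyond cutoff)."""
    if rmsd1 < 0 or rmsd2 < 0:
        raise ConfigError("RMSDs must be >= 0")
    if rmsd1 < rmsd2 and rmsd1 < cutoff:
        return 0
    if rmsd2 < rmsd1 and rmsd2 < cutoff:
        return 1
    return -1


def population_summary(ensemble, ref1, ref2,
                       cutoff: float = ASSIGN_CUTOFF) -> PopulationSummary:
    """Assign every conformation to the nearer reference (below cutoff)."""
    ens = _as_coords_stack(ensemble)
    if ens.shape[0] == 0:
        raise SizeError("empty ensemble")
    r1 = _as_coords(ref1)
    r2 = _as_coords(ref2)
    n1 = n2 = nu = 0
    for c in ens:
        s = assign_state(superpose_rmsd(r1, c), superpose_rmsd(r2, c), cutoff)
        if s == 0:
            n1 += 1
        elif s == 1:
            n2 += 1
        else:
            nu += 1
    n = ens.shape[0]
    return PopulationSummary(p1=n1 / n, p2=n2 / n, p_unassigned=nu / n,
                            n1=n1, n2=n2, n_unassigned=nu, n_total=n)


def rmsd_map(ensemble, ref1, ref2, bins=40, range_=None):
    """Joint (RMSD1, RMSD2) histogram over the ensemble.

    Returns (counts, rmsd1_edges, rmsd2_edges); counts sum to the ensemble
    size.
    """
    ens = _as_coords_stack(ensemble)
    r1 = _as_coords(ref1)
    r2 = _as_coords(ref2)
    v1 = np.array([superpose_rmsd(r1, c) for c in ens])
    v2 = np.array([superpose_rmsd(r2, c) for c in ens])
    counts, e1, e2 = np.histogram2d(v1, v2, bins=bins, range=range_)
    return counts, e1, e2


@dataclass
class FamilyRepresentatives:
    """Ward-clustering dissection of an ensemble into representative families."""

    labels: np.ndarray            # (K,) family index, 0-based
    representatives: np.ndarray   # (k_fam,) indices into the ensemble
    weights: np.ndarray           # (k_fam,) cumulative member weights
    penalties: np.ndarray         # (k_fam,) representative restraint penalty


def cluster_families(
    ensemble,
    restraints: RestraintSet,
    weights=None,
    k: int = 20,
    mapping: SiteMapping = DEFAULT_MAPPING,
) -> FamilyRepresentatives:
    """Dissect an ensemble into k families by Ward clustering on Calpha RMSD.

    The representative of each family is the member with the lowest total
    restraint penalty; its weight is the sum of the member weights.
    Invariant to reordering of the ensemble (up to family relabeling).
    """
    ens = _as_coords_stack(ensemble)
    n = ens.shape[0]
    if n < k:
        raise SizeError(f"ensemble of {n} cannot form {k} families")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    if k == n:
        labels = np.arange(n)
    else:
        dmat = pairwise_rmsd_matrix(ens)
        z = linkage(squareform(dmat, checks=False), method="ward")
        labels = fcluster(z, t=k, criterion="maxclust") - 1
    penalty = np.array([
        restraint_energy_forces(_as_chain(c), restraints, mapping)[0] for c in ens
    ])
    reps = np.empty(k, dtype=int)
    cw = np.empty(k)
    for fam in range(k):
        (members,) = np.where(labels == fam)
        reps[fam] = members[np.argmin(penalty[members])]
        cw[fam] = w[members].sum()
    return FamilyRepresentatives(labels=labels, representatives=reps,
                                 weights=cw, penalties=penalty[reps])


def _as_coords(x) -> np.ndarray:
    return x.ca if isinstance(x, CGChain) else np.asarray(x, dtype=float)


def _as_chain(x) -> CGChain:
    return x if isinstance(x, CGChain) else CGChain(ca=np.asarray(x, dtype=float))


def _as_coords_stack(ensemble) -> np.ndarray:
    if isinstance(ensemble, np.ndarray):
        return ensemble
    return np.stack([_as_coords(c) for c in ensemble])
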