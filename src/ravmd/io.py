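"""File formats: coarse-grained PDB, restraint TSV, run configuration, manifests.

Structures are exchanged as standard PDB files with one ``CA`` atom per
residue and, optionally, one side-chain pseudo-atom named ``SC`` (``CB`` is
accepted as a fallback on input).  Multi-model files carry ensembles in model
order.  Restraints travel as a documented TSV dialect with columns

    kind  i_res  i_site  j_res  j_site  lower  upper  amplitude  sigma  kappa  m

where kind is ``dist``, ``theta`` or ``gamma``; angle rows put the internal
coordinate index in ``i_res`` and leave the ``j`` columns empty; angles are in
degrees in files and radians in memory.  Omitted optional columns fall back to
the package defaults (A = 5 kcal/mol, sigma = 1 A, kappa = 0.01, A_theta = 1,
A_gamma = 5 kcal/mol, m = 3 for distances and -1 for angles).  Parsers reject
malformed input rather than repairing it.

Run configurations are single declarative YAML files; every run can emit a
JSON manifest (config hash, seeds, package version) so silent nondeterminism
is detectable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .averaging import AveragingSchedule
from .errors import ConfigError, ParseError
from .geometry import CGChain
from .potential import PotentialConfig
from .restraints import (
    DEFAULT_M_ANGLE,
    DEFAULT_M_DIST,
    AngleRestraint,
    DistanceRestraint,
    RestraintSet,
)

RESTRAINT_COLUMNS = ["kind", "i_res", "i_site", "j_res", "j_site", "lower",
                     "upper", "amplitude", "sigma", "kappa", "m"]


# ---------------------------------------------------------------------------
# PDB

def _chain_to_atoms(chain: CGChain) -> struc.AtomArray:
    n = chain.n_res
    has_sc = chain.sc is not None
    n_atoms = n * (2 if has_sc else 1)
    arr = struc.AtomArray(n_atoms)
    coords = np.empty((n_atoms, 3))
    names = np.empty(n_atoms, dtype="U4")
    res_ids = np.empty(n_atoms, dtype=int)
    k = 0
    seq = chain.sequence or "A" * n
    res_names = []
    one_to_three = {"A": "ALA", "G": "GLY", "C": "CYS", "D": "ASP", "E": "GLU",
                    "F": "PHE", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
                    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
                    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR"}
    for i in range(n):
        coords[k] = chain.ca[i]
        names[k] = "CA"
        res_ids[k] = i + 1
        res_names.append(one_to_three.get(seq[i], "ALA"))
        k += 1
        if has_sc:
            coords[k] = chain.sc[i]
            names[k] = "SC"
            res_ids[k] = i + 1
            res_names.append(one_to_three.get(seq[i], "ALA"))
            k += 1
    arr.coord = coords
    arr.atom_name = names
    arr.res_id = res_ids
    arr.res_name = np.array(res_names)
    arr.chain_id = np.full(n_atoms, "A")
    arr.element = np.full(n_atoms, "C")
    arr.hetero = np.zeros(n_atoms, dtype=bool)
    return arr


def write_pdb(chains: CGChain | list[CGChain], path) -> None:
    """Write one chain or an ensemble (multi-model) as a PDB file."""
    if isinstance(chains, CGChain):
        chains = [chains]
    stack = struc.stack([_chain_to_atoms(c) for c in chains]) if len(chains) > 1 \
        else _chain_to_atoms(chains[0])
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


_THREE_TO_ONE = {"ALA": "A", "GLY": "G", "CYS": "C", "ASP": "D", "GLU": "E",
                 "PHE": "F", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
                 "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
                 "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y"}


def _atoms_to_chain(arr: struc.AtomArray, path) -> CGChain:
    res_ids = np.unique(arr.res_id)
    ca_list, sc_list, seq = [], [], []
    any_sc = False
    for rid in res_ids:
        sub = arr[arr.res_id == rid]
        ca = sub[sub.atom_name == "CA"]
        if ca.array_length() != 1:
            raise ParseError(f"{path}: residue {rid} lacks a unique CA record")
        ca_list.append(ca.coord[0])
        sc = sub[(sub.atom_name == "SC") | (sub.atom_name == "CB")]
        if sc.array_length() >= 1:
            any_sc = True
            sc_list.append(sc.coord[0])
        else:
            sc_list.append(ca.coord[0])  # glycine-like fallback
        seq.append(_THREE_TO_ONE.get(str(ca.res_name[0]), "A"))
    return CGChain(ca=np.array(ca_list),
                   sc=np.array(sc_list) if any_sc else None,
                   sequence="".join(seq))


def read_pdb(path) -> list[CGChain]:
    """Read a (possibly multi-model) coarse-grained PDB file into chains."""
    try:
        f = pdb.PDBFile.read(str(path))
        structure = f.get_structure()
    except ParseError:
        raise
    except Exception as exc:  # biotite raises various parse errors
        raise ParseError(f"{path}: {exc}") from exc
    if isinstance(structure, struc.AtomArrayStack):
        return [_atoms_to_chain(structure[i], path)
                for i in range(structure.stack_depth())]
    return [_atoms_to_chain(structure, path)]


# ---------------------------------------------------------------------------
# restraint TSV

def write_restraints(restraints: RestraintSet, path) -> None:
    """Write restraints to TSV (angles in degrees)."""
    rows = []
    for r in restraints:
        if isinstance(r, DistanceRestraint):
            rows.append(("dist", int(r.i_res), r.i_site, int(r.j_res), r.j_site,
                         float(r.lower), float(r.upper), float(r.amplitude),
                         float(r.sigma), float(r.kappa), int(r.m)))
        else:
            rows.append((r.kind, int(r.index), "", "", "",
                         float(np.rad2deg(r.lower)), float(np.rad2deg(r.upper)),
                         float(r.amplitude), "", "", int(r.m)))
    df = pd.DataFrame(rows, columns=RESTRAINT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_restraints(path) -> RestraintSet:
    """Read the restraint TSV dialect; validates every row."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"kind": str},
                         float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if "kind" not in df.columns or "lower" not in df.columns or "upper" not in df.columns:
        raise ParseError(f"{path}: header must name at least kind, lower, upper")

    def get(row, col, default=None):
        if col not in df.columns or pd.isna(row[col]) or row[col] == "":
            return default
        return row[col]

    out = []
    for pos, row in df.iterrows():
        rownum = pos + 2  # 1-based, after the header line
        kind = str(row["kind"]).strip()
        try:
            lower = float(row["lower"])
            upper = float(row["upper"])
            if kind == "dist":
                if lower > upper:
                    raise ConfigError(f"lower {lower} > upper {upper}")
                kwargs = {}
                for col in ("amplitude", "sigma", "kappa"):
                    v = get(row, col)
                    if v is not None:
                        kwargs[col] = float(v)
                m = get(row, "m")
                out.append(DistanceRestraint(
                    i_res=int(row["i_res"]), j_res=int(row["j_res"]),
                    i_site=str(get(row, "i_site", "CA")),
                    j_site=str(get(row, "j_site", "CA")),
                    lower=lower, upper=upper,
                    m=int(m) if m is not None else DEFAULT_M_DIST, **kwargs))
            elif kind in ("theta", "gamma"):
                amp = get(row, "amplitude")
                m = get(row, "m")
                out.append(AngleRestraint(
                    kind=kind, index=int(row["i_res"]),
                    lower=np.deg2rad(lower), upper=np.deg2rad(upper),
                    amplitude=float(amp) if amp is not None else None,
                    m=int(m) if m is not None else DEFAULT_M_ANGLE))
            else:
                raise ConfigError(f"unknown restraint kind {kind!r}")
        except (ValueError, TypeError, KeyError, ConfigError) as exc:
            raise ParseError(f"{path}: row {rownum}: {exc}") from exc
    return RestraintSet(out)


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Declarative description of one run; one file fully determines a run."""

    mode: str = "nvt"                      # nve | nvt | mremd
    n_steps: int = 100_000
    dt: float = 4.89                       # fs
    temperature: float = 300.0             # K (single-temperature modes)
    friction: float = 0.05                 # 1/fs
    n_replicas: int = 1
    averaging: bool = True
    scale_energy: bool = False
    seed: int = 0
    schedule: AveragingSchedule = field(default_factory=AveragingSchedule)
    potential: PotentialConfig = field(default_factory=PotentialConfig)
    restraint_file: str | None = None
    structure_file: str | None = None
    ladder: str | list[float] | None = None   # mremd only
    multiplexing: int | None = None

    def __post_init__(self):
        if self.mode not in ("nve", "nvt", "mremd"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.n_steps < 1 or self.dt <= 0:
            raise ConfigError("n_steps must be >= 1 and dt > 0")
        if self.n_replicas < 1:
            raise ConfigError("n_replicas must be >= 1")


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, validating schedule invariants."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    sched = AveragingSchedule(**raw.pop("schedule", {}))
    pot_raw = raw.pop("potential", {})
    if "torsion_coeffs" in pot_raw and pot_raw["torsion_coeffs"] is not None:
        pot_raw["torsion_coeffs"] = tuple(pot_raw["torsion_coeffs"])
    pot = PotentialConfig(**pot_raw)
    try:
        cfg = RunConfig(schedule=sched, potential=pot, **raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    for key in ("restraint_file", "structure_file"):
        val = getattr(cfg, key)
        if val is not None:
            p = Path(path).parent / val
            if not p.exists():
                raise ConfigError(f"{path}: {key} {val!r} does not exist")
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    d = {
        "mode": cfg.mode, "n_steps": cfg.n_steps, "dt": cfg.dt,
        "temperature": cfg.temperature, "friction": cfg.friction,
        "n_replicas": cfg.n_replicas, "averaging": cfg.averaging,
        "scale_energy": cfg.scale_energy, "seed": cfg.seed,
        "schedule": {"n_ave": cfg.schedule.n_ave, "n_exch": cfg.schedule.n_exch,
                     "n_snap": cfg.schedule.n_snap},
        "potential": {
            "k_bond": cfg.potential.k_bond, "d0": cfg.potential.d0,
            "k_theta": cfg.potential.k_theta, "theta0": float(cfg.potential.theta0),
            "eps_rep": cfg.potential.eps_rep, "r_rep": cfg.potential.r_rep,
            "torsion_coeffs": list(cfg.potential.torsion_coeffs)
            if cfg.potential.torsion_coeffs else None,
        },
        "restraint_file": cfg.restraint_file,
        "structure_file": cfg.structure_file,
        "ladder": cfg.ladder, "multiplexing": cfg.multiplexing,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# energy logs and manifests

def write_energy_log(log: pd.DataFrame, path) -> None:
    """Energy log TSV: step, replica, e_kin, e_pot, e_restraint, e_total, temperature."""
    log.to_csv(path, sep="\t", index=False)


def write_manifest(path, config_path=None, seeds=None, extra=None) -> None:
    """JSON manifest: config hash, seeds and package version for reproducibility."""
    from . import __version__

    manifest = {"package": "ravmd", "version": __version__}
    if config_path is not None:
        digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
        manifest["config"] = str(config_path)
        manifest["config_sha256"] = digest
    if seeds is not None:
        manifest["seeds"] = list(np.asarray(seeds).tolist()) \
            if not np.isscalar(seeds) else [int(seeds)]
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
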