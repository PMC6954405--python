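"""Replica-exchange Monte Carlo docking of a flexible peptide.

The peptide is fully flexible: its CA trace moves by single-residue
displacements and two-residue crankshaft rotations, plus rigid-body
translations/rotations of the whole chain; side pseudo-atoms (CB, SC) are
re-placed from the CA trace after every move, and the peptide-bond centers
are kept at CA midpoints.  The receptor fluctuates by small CA jitter moves
tethered harmonically to its input coordinates — no large-scale receptor
rearrangements are modelled.

Several replicas run at a geometric temperature ladder; neighbouring
replicas periodically attempt configuration swaps with the standard
exchange criterion ``min(1, exp((1/T_i - 1/T_j) (E_i - E_j)))``.  Snapshots
are collected from *all* replicas: the downstream energy filter presupposes
a heterogeneous pool of models.

The contact-restraint term is part of the Monte Carlo target throughout the
run (it is not ramped or switched off in any stage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from pepdock.cg_model import (
    CGComplex,
    CGResidue,
    build_peptide_from_sequence,
    place_side_pseudoatoms,
    read_cg_models,
    update_cp_midpoints,
    write_cg_models,
)
from pepdock.forcefield import EnergyBreakdown, ForceFieldParams, excluded_volume, total_energy
from pepdock.restraints import RestraintSet, restraint_distance


class SamplerError(RuntimeError):
    pass


@dataclass
class ReplicaLadder:
    """Geometric temperature ladder for replica exchange."""

    n_replicas: int = 10
    t_min: float = 1.0
    t_max: float = 3.0
    exchange_interval: int = 10  # sweeps between exchange attempts

    def __post_init__(self) -> None:
        if self.n_replicas < 2:
            raise ValueError("replica ladder needs at least 2 replicas")
        if not (0 < self.t_min < self.t_max):
            raise ValueError("need 0 < t_min < t_max")

    @property
    def temperatures(self) -> np.ndarray:
        return np.geomspace(self.t_min, self.t_max, self.n_replicas)


@dataclass
class DockingConfig:
    n_models_total: int = 10_000
    ladder: ReplicaLadder = field(default_factory=ReplicaLadder)
    snapshot_interval: int = 2   # sweeps between snapshots
    burn_in: int = 20            # sweeps before the first snapshot
    placement_margin: float = 10.0  # Å beyond the receptor surface radius
    max_local_step: float = 0.7     # Å, single-residue displacement
    max_crank_angle: float = 45.0   # degrees, crankshaft rotation
    max_rigid_step: float = 2.0     # Å, rigid peptide translation
    max_rigid_angle: float = 30.0   # degrees, rigid peptide rotation
    max_receptor_step: float = 0.3  # Å, receptor CA jitter
    k_tether: float = 1.0           # energy/Å^2, receptor positional tether
    forcefield: ForceFieldParams = field(default_factory=ForceFieldParams)


@dataclass
class TrajectoryModel:
    complex: CGComplex
    energy: EnergyBreakdown
    replica: int
    sweep: int
    restraint_distances: list[float] = field(default_factory=list)


@dataclass
class Trajectory:
    models: list[TrajectoryModel] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i: int) -> TrajectoryModel:
        return self.models[i]

    def subset(self, indices: Sequence[int]) -> "Trajectory":
        return Trajectory([self.models[i] for i in indices])


# -----------------------------------------------------------------------------
# initial placement
# -----------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _as_receptor_chains(receptor: CGComplex | Sequence[list[CGResidue]]
                        ) -> list[list[CGResidue]]:
    if isinstance(receptor, CGComplex):
        return receptor.receptor_chains
    return list(receptor)


def random_initial_placement(receptor: CGComplex | Sequence[list[CGResidue]],
                             peptide: list[CGResidue],
                             rng_seed: int | np.random.Generator = 0,
                             margin: float = 10.0,
                             params: ForceFieldParams | None = None) -> CGComplex:
    """Place the peptide at a random clash-free position around the receptor.

    The peptide centroid lands uniformly on a sphere of radius
    ``R_surface + margin`` around the receptor centroid (``R_surface`` is
    the largest receptor CA distance from the centroid), with a uniform
    random orientation.  Placements with non-zero excluded-volume energy
    are rejected; up to 1000 attempts are made.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    if params is None:
        params = ForceFieldParams()
    chains = _as_receptor_chains(receptor)
    rec_ca = np.concatenate([[r.ca for r in c] for c in chains])
    center = rec_ca.mean(axis=0)
    radius = float(np.max(np.linalg.norm(rec_ca - center, axis=1))) + margin

    pep_ca = np.array([r.ca for r in peptide])
    pep_center = pep_ca.mean(axis=0)
    for _ in range(1000):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        rot = _random_rotation(rng)
        target = center + radius * direction
        new_ca = (pep_ca - pep_center) @ rot.T + target
        placed = [r.copy() for r in peptide]
        for res, ca in zip(placed, new_ca):
            res.ca = ca
        place_side_pseudoatoms(placed)
        update_cp_midpoints(placed)
        cplx = CGComplex(receptor_chains=[[r.copy() for r in c] for c in chains],
                         peptide=placed)
        if excluded_volume(cplx, params) == 0.0:
            return cplx
    raise SamplerError(
        "could not find a clash-free initial placement in 1000 tries; "
        "try a larger placement margin")


# -----------------------------------------------------------------------------
# Monte Carlo moves
# -----------------------------------------------------------------------------

class _Replica:
    """Mutable simulation state of one replica."""

    def __init__(self, cplx: CGComplex, config: DockingConfig,
                 restraints: RestraintSet | None, ss: str | None):
        self.cplx = cplx
        self.config = config
        self.restraints = restraints
        self.ss = ss
        self.receptor_residues = list(cplx.receptor_residues())
        self.ref_receptor_ca = np.array([r.ca for r in self.receptor_residues])
        self.energy = total_energy(cplx, restraints, config.forcefield, ss)
        self.tether = 0.0

    # the Metropolis target: docking energy plus the receptor tether
    @property
    def target(self) -> float:
        return self.energy.total + self.tether

    def _refresh(self) -> None:
        self.energy = total_energy(self.cplx, self.restraints,
                                   self.config.forcefield, self.ss)
        ca = np.array([r.ca for r in self.receptor_residues])
        self.tether = float(self.config.k_tether
                            * np.sum((ca - self.ref_receptor_ca) ** 2))

    def _set_peptide_ca(self, ca: np.ndarray) -> None:
        for res, pos in zip(self.cplx.peptide, ca):
            res.ca = pos.copy()
        place_side_pseudoatoms(self.cplx.peptide)
        update_cp_midpoints(self.cplx.peptide)

    def propose_peptide_ca(self, new_ca: np.ndarray, temperature: float,
                           rng: np.random.Generator) -> bool:
        old_ca = np.array([r.ca for r in self.cplx.peptide])
        old_energy, old_tether = self.energy, self.tether
        self._set_peptide_ca(new_ca)
        self._refresh()
        if metropolis_accept(self.target - (old_energy.total + old_tether),
                             temperature, rng):
            return True
        self._set_peptide_ca(old_ca)
        self.energy, self.tether = old_energy, old_tether
        return False

    def propose_receptor_jitter(self, index: int, delta: np.ndarray,
                                temperature: float, rng: np.random.Generator) -> bool:
        res = self.receptor_residues[index]
        saved = (res.ca.copy(), None if res.cb is None else res.cb.copy(),
                 res.sc.copy(), None if res.cp is None else res.cp.copy())
        old_energy, old_tether = self.energy, self.tether
        res.ca = res.ca + delta
        res.sc = res.sc + delta
        if res.cb is not None:
            res.cb = res.cb + delta
        if res.cp is not None:
            res.cp = res.cp + delta
        self._refresh()
        if metropolis_accept(self.target - (old_energy.total + old_tether),
                             temperature, rng):
            return True
        res.ca, res.cb, res.sc, res.cp = saved
        self.energy, self.tether = old_energy, old_tether
        return False


def metropolis_accept(delta_e: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Standard Metropolis criterion with k_B = 1."""
    if delta_e <= 0:
        return True
    if not math.isfinite(temperature) or temperature <= 0:
        return not math.isfinite(temperature) and temperature > 0
    return rng.random() < math.exp(-delta_e / temperature)


def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle_rad) * k + (1 - math.cos(angle_rad)) * (k @ k)


def _random_in_ball(radius: float, rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.uniform(-radius, radius, size=3)
        if np.dot(v, v) <= radius * radius:
            return v


def mc_sweep(replica: _Replica, temperature: float,
             rng: np.random.Generator) -> dict[str, float]:
    """One Monte Carlo sweep; returns per-move-type acceptance counts.

    A sweep is N_pep local peptide moves (single-residue displacement or
    two-residue crankshaft), one rigid-body peptide move, and
    ceil(N_receptor / 10) receptor jitter moves.
    """
    cfg = replica.config
    n_pep = len(replica.cplx.peptide)
    stats = {"local_tried": 0, "local_accepted": 0,
             "rigid_tried": 0, "rigid_accepted": 0,
             "receptor_tried": 0, "receptor_accepted": 0}

    for _ in range(n_pep):
        ca = np.array([r.ca for r in replica.cplx.peptide])
        use_crank = n_pep >= 4 and rng.random() < 0.5
        if use_crank:
            i = int(rng.integers(0, n_pep - 3))
            axis = ca[i + 3] - ca[i]
            angle = math.radians(rng.uniform(-cfg.max_crank_angle, cfg.max_crank_angle))
            rot = _rotation_about_axis(axis, angle)
            new_ca = ca.copy()
            for j in (i + 1, i + 2):
                new_ca[j] = ca[i] + rot @ (ca[j] - ca[i])
        else:
            i = int(rng.integers(0, n_pep))
            new_ca = ca.copy()
            new_ca[i] = ca[i] + _random_in_ball(cfg.max_local_step, rng)
        stats["local_tried"] += 1
        stats["local_accepted"] += replica.propose_peptide_ca(new_ca, temperature, rng)

    # one rigid-body move of the whole peptide
    ca = np.array([r.ca for r in replica.cplx.peptide])
    if rng.random() < 0.5:
        new_ca = ca + _random_in_ball(cfg.max_rigid_step, rng)
    else:
        centroid = ca.mean(axis=0)
        axis = rng.normal(size=3)
        angle = math.radians(rng.uniform(-cfg.max_rigid_angle, cfg.max_rigid_angle))
        rot = _rotation_about_axis(axis, angle)
        new_ca = (ca - centroid) @ rot.T + centroid
    stats["rigid_tried"] += 1
    stats["rigid_accepted"] += replica.propose_peptide_ca(new_ca, temperature, rng)

    n_rec_moves = max(1, math.ceil(len(replica.receptor_residues) / 10))
    for _ in range(n_rec_moves):
        idx = int(rng.integers(0, len(replica.receptor_residues)))
        delta = _random_in_ball(cfg.max_receptor_step, rng)
        stats["receptor_tried"] += 1
        stats["receptor_accepted"] += replica.propose_receptor_jitter(
            idx, delta, temperature, rng)
    return stats


# -----------------------------------------------------------------------------
# the docking run
# -----------------------------------------------------------------------------

def run_docking(receptor: CGComplex | Sequence[list[CGResidue]],
                peptide_sequence: str,
                ss: str | None = None,
                restraints: RestraintSet | None = None,
                config: DockingConfig | None = None,
                rng_seed: int = 0) -> Trajectory:
    """Dock a peptide sequence onto a receptor and return the sampled pool.

    Every replica builds its own random peptide conformation and placement.
    Snapshots are taken from all replicas at fixed sweep intervals until
    ``config.n_models_total`` models are collected; each snapshot records
    the energy breakdown and the current SC-SC distance of every restraint.
    Bit-reproducible for a fixed ``rng_seed``.
    """
    if config is None:
        config = DockingConfig()
    chains = _as_receptor_chains(receptor)
    ladder = config.ladder
    temperatures = ladder.temperatures
    n_rep = ladder.n_replicas

    seed_seq = np.random.SeedSequence(rng_seed)
    rep_seeds = seed_seq.spawn(n_rep + 1)
    master_rng = np.random.default_rng(rep_seeds[-1])

    replicas: list[_Replica] = []
    rngs: list[np.random.Generator] = []
    for k in range(n_rep):
        rng = np.random.default_rng(rep_seeds[k])
        peptide = build_peptide_from_sequence(
            peptide_sequence, ss, rng_seed=int(rng.integers(2**31)))
        cplx = random_initial_placement(chains, peptide, rng,
                                        margin=config.placement_margin,
                                        params=config.forcefield)
        replicas.append(_Replica(cplx, config, restraints, ss))
        rngs.append(rng)

    snaps_per_replica = math.ceil(config.n_models_total / n_rep)
    total_sweeps = config.burn_in + snaps_per_replica * config.snapshot_interval

    trajectory = Trajectory()
    for sweep in range(1, total_sweeps + 1):
        for k, replica in enumerate(replicas):
            mc_sweep(replica, temperatures[k], rngs[k])

        if sweep % ladder.exchange_interval == 0:
            start = (sweep // ladder.exchange_interval) % 2
            for i in range(start, n_rep - 1, 2):
                beta_diff = 1.0 / temperatures[i] - 1.0 / temperatures[i + 1]
                e_diff = replicas[i].target - replicas[i + 1].target
                if master_rng.random() < min(1.0, math.exp(min(700.0, beta_diff * e_diff))):
                    replicas[i], replicas[i + 1] = replicas[i + 1], replicas[i]

        past_burn_in = sweep - config.burn_in
        if past_burn_in > 0 and past_burn_in % config.snapshot_interval == 0:
            for k, replica in enumerate(replicas):
                if len(trajectory) >= config.n_models_total:
                    break
                snapshot = replica.cplx.copy()
                dists = ([restraint_distance(snapshot, r) for r in restraints]
                         if restraints else [])
                trajectory.models.append(TrajectoryModel(
                    complex=snapshot,
                    energy=total_energy(snapshot, restraints, config.forcefield, ss),
                    replica=k, sweep=sweep, restraint_distances=dists))
    trajectory.models = trajectory.models[: config.n_models_total]
    return trajectory


# -----------------------------------------------------------------------------
# trajectory serialization: multi-model CG PDB + CSV sidecar
# -----------------------------------------------------------------------------

def write_trajectory(trajectory: Trajectory, pdb_path: str | Path,
                     csv_path: str | Path) -> None:
    write_cg_models([m.complex for m in trajectory], pdb_path)
    n_restraints = max((len(m.restraint_distances) for m in trajectory), default=0)
    rows = []
    for i, m in enumerate(trajectory):
        row = {"model": i, "replica": m.replica, "sweep": m.sweep,
               "interaction": m.energy.interaction,
               "intra_peptide": m.energy.intra_peptide,
               "excluded_volume": m.energy.excluded_volume,
               "restraint": m.energy.restraint, "total": m.energy.total}
        for j in range(n_restraints):
            row[f"restraint_dist_{j}"] = (m.restraint_distances[j]
                                          if j < len(m.restraint_distances) else np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(csv_path, index=False)


def read_trajectory(pdb_path: str | Path, csv_path: str | Path) -> Trajectory:
    complexes = read_cg_models(pdb_path)
    table = pd.read_csv(csv_path)
    if len(table) != len(complexes):
        raise SamplerError("trajectory PDB and CSV sidecar disagree on model count")
    dist_cols = [c for c in table.columns if c.startswith("restraint_dist_")]
    models = []
    for cplx, (_, row) in zip(complexes, table.iterrows()):
        energy = EnergyBreakdown(interaction=row["interaction"],
                                 intra_peptide=row["intra_peptide"],
                                 excluded_volume=row["excluded_volume"],
                                 restraint=row["restraint"])
        dists = [row[c] for c in dist_cols if np.isfinite(row[c])]
        models.append(TrajectoryModel(complex=cplx, energy=energy,
                                      replica=int(row["replica"]),
                                      sweep=int(row["sweep"]),
                                      restraint_distances=dists))
    return Trajectory(models)
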