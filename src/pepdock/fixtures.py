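"""Deterministic toy receptor-peptide systems for testing and benchmarking.

The generator builds a small "sheet-like" receptor: antiparallel straight
CA strands (3.8 Å spacing) connected by single-residue turns, with the two
strands flanking the central one raised to form a shallow groove.  Side
pseudo-atoms of the central (floor) strand point up into the groove; a
peptide is laid along the groove with a chosen number of side chains
reaching down to the floor, giving an exactly known set of native SC-SC
contacts (< 5 Å).  An "unbound" receptor variant jitters the receptor
coordinates to a prescribed CA RMSD, emulating a bound/unbound benchmark
pair at toy scale.

These systems are caricatures: they have no real secondary-structure
packing, sequence diversity, or realistic side-chain geometry, but every
coordinate and contact is controlled, which is what the tests need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pepdock.cg_model import (
    CGComplex,
    CGResidue,
    PEPTIDE_CHAIN_ID,
)
from pepdock.forcefield import EnergyBreakdown, ForceFieldParams, excluded_volume
from pepdock.restraints import (
    RestraintSet,
    extract_native_contacts,
    restraint_distance,
    total_restraint_energy,
)
from pepdock.sampler import Trajectory, TrajectoryModel, _random_rotation

RECEPTOR_CHAIN_ID = "R"

STRAND_SPACING = 4.8       # Å between neighbouring strands (x)
CA_BOND = 3.8              # Å along a strand (z)
FLOOR_SC_OFFSET = 1.9      # Å, floor side chains point +y
CONTACT_DISTANCE = 4.2     # Å, planted SC-SC distance (< 5 Å native cutoff)
PEPTIDE_HEIGHT = 7.2       # Å, peptide CA plane above the floor CA plane
PEPTIDE_ZIGZAG = 0.6       # Å, lateral CA zigzag amplitude of the peptide
NONCONTACT_SC_OFFSET = 1.5  # Å, non-planted peptide side chains point +y


class ToyConstructionError(RuntimeError):
    pass


@dataclass
class ToySystemSpec:
    receptor_size: int = 60
    pocket_depth: float = 3.0        # Å, how far the groove rims are raised
    peptide_length: int = 6
    n_planted_contacts: int = 3
    unbound_jitter: float = 1.0      # Å, CA RMSD of the unbound receptor
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.peptide_length < 3:
            raise ToyConstructionError("peptide_length must be at least 3")
        if not (0 <= self.n_planted_contacts <= self.peptide_length):
            raise ToyConstructionError(
                "n_planted_contacts must be between 0 and peptide_length")
        if self.receptor_size < 30:
            raise ToyConstructionError("receptor_size must be at least 30")


def _build_receptor(spec: ToySystemSpec) -> tuple[list[CGResidue], int]:
    """Strand/turn receptor; returns residues and the floor-strand index."""
    n_strands = max(3, min(5, spec.receptor_size // 14))
    per_strand = (spec.receptor_size - (n_strands - 1)) // n_strands
    extra = spec.receptor_size - (n_strands - 1) - n_strands * per_strand
    floor_strand = n_strands // 2
    rim_strands = {floor_strand - 1, floor_strand + 1}

    residues: list[CGResidue] = []
    number = 1
    strand_top = (per_strand - 1) * CA_BOND
    prev_end: np.ndarray | None = None
    aa_cycle = "SLEKVDTN"  # arbitrary mixed composition for the receptor
    for s in range(n_strands):
        n_res = per_strand + (extra if s == n_strands - 1 else 0)
        x = s * STRAND_SPACING
        y = spec.pocket_depth if s in rim_strands else 0.0
        direction = 1 if s % 2 == 0 else -1
        z0 = 0.0 if direction == 1 else strand_top
        if prev_end is not None:
            # single-residue turn: two 3.8 Å bonds bridging the 4.8 Å strand
            # gap, with the apex past the shared strand end
            apex_y = 0.5 * (prev_end[1] + y)
            dy_half = apex_y - prev_end[1]
            rise = float(np.sqrt(CA_BOND**2 - (STRAND_SPACING / 2.0) ** 2
                                 - dy_half**2))
            apex_z = prev_end[2] + (rise if prev_end[2] > strand_top / 2 else -rise)
            apex = np.array([x - STRAND_SPACING / 2.0, apex_y, apex_z])
            residues.append(CGResidue(
                chain_id=RECEPTOR_CHAIN_ID, residue_number=number,
                aa_type="G", ca=apex, cb=None, sc=apex.copy()))
            number += 1
        for j in range(n_res):
            ca = np.array([x, y, z0 + direction * j * CA_BOND])
            aa = aa_cycle[(number - 1) % len(aa_cycle)]
            if s == floor_strand:
                side = np.array([0.0, FLOOR_SC_OFFSET, 0.0])   # into the groove
            else:
                side = np.array([0.0, -FLOOR_SC_OFFSET, 0.0])  # away from it
            residues.append(CGResidue(
                chain_id=RECEPTOR_CHAIN_ID, residue_number=number, aa_type=aa,
                ca=ca, cb=ca + side * (1.53 / FLOOR_SC_OFFSET), sc=ca + side))
            number += 1
            prev_end = ca
    # peptide-bond centers as CA midpoints
    for i, res in enumerate(residues[:-1]):
        res.cp = 0.5 * (res.ca + residues[i + 1].ca)
    return residues, floor_strand


def _build_pocket_peptide(spec: ToySystemSpec, receptor: list[CGResidue],
                          floor_strand_x: float, floor_z: np.ndarray
                          ) -> tuple[list[CGResidue], list[int]]:
    """Peptide along the groove; planted side chains reach the floor SCs."""
    n = spec.peptide_length
    # peptide z spacing matches the strand grid exactly, so every planted
    # side chain sits right above its target SC (virtual bond 3.98 Å)
    dz = CA_BOND
    z_mid = 0.5 * (floor_z.min() + floor_z.max())
    z_start = z_mid - dz * (n - 1) / 2.0
    # snap onto the floor-strand z grid so planted side chains sit nearly on
    # top of their target SC and clear of its along-strand neighbours
    grid = np.sort(floor_z)
    z_start = float(grid[np.argmin(np.abs(grid - z_start))])
    planted = sorted(set(np.linspace(0, n - 1, spec.n_planted_contacts,
                                     dtype=int).tolist())) if spec.n_planted_contacts else []
    if len(planted) != spec.n_planted_contacts:
        raise ToyConstructionError(
            f"cannot plant {spec.n_planted_contacts} distinct contacts on a "
            f"{n}-residue peptide")

    floor_res = [r for r in receptor
                 if abs(r.ca[0] - floor_strand_x) < 0.1 and r.aa_type != "G"]
    floor_sc = np.array([r.sc for r in floor_res])

    residues: list[CGResidue] = []
    used_targets: set[int] = set()
    for i in range(n):
        ca = np.array([floor_strand_x + PEPTIDE_ZIGZAG * (1 if i % 2 == 0 else -1),
                       PEPTIDE_HEIGHT, z_start + i * dz])
        if i in planted:
            order = np.argsort(np.abs(floor_sc[:, 2] - ca[2]))
            target_idx = next(int(t) for t in order if int(t) not in used_targets)
            used_targets.add(target_idx)
            target = floor_sc[target_idx]
            to_target = target - ca
            reach = np.linalg.norm(to_target)
            sc = ca + to_target * (reach - CONTACT_DISTANCE) / reach
            aa = "L"
        else:
            sc = ca + np.array([0.0, NONCONTACT_SC_OFFSET, 0.0])
            aa = "A"
        cb = ca + (sc - ca) * (1.53 / max(np.linalg.norm(sc - ca), 1e-9))
        residues.append(CGResidue(chain_id=PEPTIDE_CHAIN_ID, residue_number=i + 1,
                                  aa_type=aa, ca=ca, cb=cb, sc=sc))
    for i, res in enumerate(residues[:-1]):
        res.cp = 0.5 * (res.ca + residues[i + 1].ca)
    residues[-1].cp = None
    return residues, planted


def _jitter_to_rmsd(residues: list[CGResidue], rmsd: float,
                    rng: np.random.Generator) -> list[CGResidue]:
    """Displace every residue so the CA RMSD to the input equals ``rmsd``."""
    out = [r.copy() for r in residues]
    noise = rng.normal(size=(len(out), 3))
    noise *= rmsd / np.sqrt(np.mean(np.sum(noise**2, axis=1)))
    for res, delta in zip(out, noise):
        res.ca = res.ca + delta
        res.sc = res.sc + delta
        if res.cb is not None:
            res.cb = res.cb + delta
        if res.cp is not None:
            res.cp = res.cp + delta
    return out


def make_toy_complex(spec: ToySystemSpec | None = None
                     ) -> tuple[CGComplex, CGComplex, list]:
    """Build a bound toy complex, an unbound receptor, and its native contacts.

    Returns ``(bound_reference, unbound_receptor_only, contacts)`` where
    ``contacts`` is the output of :func:`extract_native_contacts` on the
    bound reference — exactly ``spec.n_planted_contacts`` SC-SC pairs below
    5 Å, by construction.  The whole system is given a random rigid
    orientation per seed; the unbound receptor is the bound receptor
    jittered to ``spec.unbound_jitter`` Å CA RMSD.
    """
    if spec is None:
        spec = ToySystemSpec()
    rng = np.random.default_rng(spec.rng_seed)

    receptor, floor_strand = _build_receptor(spec)
    floor_x = floor_strand * STRAND_SPACING
    floor_z = np.array([r.ca[2] for r in receptor
                        if abs(r.ca[0] - floor_x) < 0.1 and r.aa_type != "G"])
    peptide, _planted = _build_pocket_peptide(spec, receptor, floor_x, floor_z)

    bound = CGComplex(receptor_chains=[receptor], peptide=peptide)
    rotation = _random_rotation(rng)
    translation = rng.uniform(-5.0, 5.0, size=3)
    bound = bound.transformed(rotation, translation)

    contacts = extract_native_contacts(bound)
    if len(contacts) != spec.n_planted_contacts:
        raise ToyConstructionError(
            f"toy construction produced {len(contacts)} native contacts, "
            f"expected {spec.n_planted_contacts}")
    if excluded_volume(bound, ForceFieldParams()) > 0.0:
        raise ToyConstructionError("toy construction produced steric clashes")

    unbound_receptor = _jitter_to_rmsd(
        [r for r in bound.receptor_residues()], spec.unbound_jitter, rng)
    unbound = CGComplex(receptor_chains=[unbound_receptor], peptide=[])
    return bound, unbound, contacts


def peptide_sequence(cplx: CGComplex) -> str:
    """One-letter sequence of the peptide chain."""
    return "".join(r.aa_type for r in cplx.peptide)


# -----------------------------------------------------------------------------
# synthetic trajectories
# -----------------------------------------------------------------------------

DEFAULT_NOISE_SCALES = {
    "peptide_sigma": 0.5,   # Å, per-residue Gaussian noise of near-native poses
    "decoy_margin": 10.0,   # Å, shell margin for random decoy placements
    "energy_sigma": 1.0,    # spread of the synthetic interaction energies
    "energy_margin": 3.0,   # how much lower near-native energies sit on average
}


def make_synthetic_trajectory(reference: CGComplex, n_models: int = 1000,
                              fraction_near_native: float = 0.3,
                              noise_scales: dict[str, float] | None = None,
                              rng_seed: int = 0,
                              restraints: RestraintSet | None = None) -> Trajectory:
    """Mixture of near-native poses and random decoys with synthetic energies.

    Each model is near-native with probability ``fraction_near_native``
    (peptide perturbed by small per-residue noise) and a far random rigid
    placement otherwise.  Synthetic interaction energies are Gaussian with
    the near-native population shifted down by ``energy_margin``, so energy
    filtering enriches near-native poses the way a docking force field
    would.  Restraint distances are recorded when restraints are supplied.
    """
    scales = dict(DEFAULT_NOISE_SCALES)
    if noise_scales:
        scales.update(noise_scales)
    rng = np.random.default_rng(rng_seed)

    rec_ca = reference.receptor_ca()
    center = rec_ca.mean(axis=0)
    shell = float(np.max(np.linalg.norm(rec_ca - center, axis=1))) + scales["decoy_margin"]
    pep_ca = reference.peptide_ca()
    pep_center = pep_ca.mean(axis=0)

    models = []
    for i in range(n_models):
        near_native = rng.random() < fraction_near_native
        cplx = reference.copy()
        if near_native:
            noise = rng.normal(scale=scales["peptide_sigma"], size=(len(cplx.peptide), 3))
            for res, delta in zip(cplx.peptide, noise):
                res.ca = res.ca + delta
                res.sc = res.sc + delta
                if res.cb is not None:
                    res.cb = res.cb + delta
                if res.cp is not None:
                    res.cp = res.cp + delta
            energy = rng.normal(-scales["energy_margin"], scales["energy_sigma"])
        else:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            rot = _random_rotation(rng)
            target = center + shell * direction
            for res in cplx.peptide:
                for attr in ("ca", "cb", "sc", "cp"):
                    coord = getattr(res, attr)
                    if coord is not None:
                        setattr(res, attr, rot @ (coord - pep_center) + target)
            energy = rng.normal(0.0, scales["energy_sigma"])
        restraint_e = (total_restraint_energy(cplx, restraints) if restraints else 0.0)
        dists = ([restraint_distance(cplx, r) for r in restraints]
                 if restraints else [])
        models.append(TrajectoryModel(
            complex=cplx,
            energy=EnergyBreakdown(interaction=float(energy), intra_peptide=0.0,
                                   excluded_volume=0.0, restraint=restraint_e),
            replica=0, sweep=i, restraint_distances=dists))
    return Trajectory(models)
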