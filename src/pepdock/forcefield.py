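"""Simplified coarse-grained energy for protein-peptide docking.

The docking energy has four additive components:

``interaction``
    Receptor-peptide contact energy: a residue-type-dependent square well
    on the SC-SC distance.  A pair contributes ``e(a, b)`` when its SC-SC
    distance falls inside ``[contact_min, contact_max]`` (default
    [4.0, 6.5] Å) and zero otherwise.  The default 20x20 well-depth table
    shipped with the package is a smooth hydrophobicity-derived contact
    scale (all wells attractive, hydrophobic-hydrophobic deepest); it is a
    plain-text matrix and can be swapped for any other symmetric scale.
``intra_peptide``
    Harmonic restoring terms on the peptide's CA-CA virtual bonds (target
    3.8 Å) and a flat-bottom penalty on pseudo-bond angles outside
    [75°, 150°]; an optional secondary-structure bias nudges pseudo-angles
    and pseudo-dihedrals into helical (H) or extended (E) windows.
``excluded_volume``
    Soft-core quadratic repulsion between CA-CA and SC-SC pairs closer
    than their clash radii.
``restraint``
    The contact-restraint penalty (see :mod:`pepdock.restraints`).

Energies are dimensionless simulation units; the Monte Carlo temperatures
are expressed in the same units (k_B = 1).

Receptor-receptor interaction energy is intentionally absent: the receptor
moves only by small tethered fluctuations during sampling, so its internal
energy would be a near-constant offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.distance import cdist

from pepdock.cg_model import CGComplex, CGResidue
from pepdock.restraints import RestraintSet, total_restraint_energy


class ForceFieldError(ValueError):
    """Raised for invalid parameter tables or configuration."""


def load_contact_table(path: str | Path) -> dict[tuple[str, str], float]:
    """Load a 20x20 well-depth matrix: header row of one-letter codes,
    one labelled row per residue type."""
    lines = [ln.split() for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    header = lines[0]
    table: dict[tuple[str, str], float] = {}
    for row in lines[1:]:
        a = row[0]
        for b, value in zip(header, row[1:]):
            table[(a, b)] = float(value)
    for a, b in table:
        if abs(table[(a, b)] - table.get((b, a), np.nan)) > 1e-9:
            raise ForceFieldError(f"contact table is not symmetric at ({a}, {b})")
    return table


def default_contact_table() -> dict[tuple[str, str], float]:
    with resources.as_file(resources.files("pepdock.data") / "contact_table.txt") as p:
        return load_contact_table(p)


@dataclass
class ForceFieldParams:
    """All tunable constants of the energy model, with defaults."""

    contact_min: float = 4.0      # Å, inner edge of the interaction well
    contact_max: float = 6.5      # Å, outer edge of the interaction well
    r_clash_ca: float = 3.5       # Å, CA-CA clash radius
    r_clash_sc: float = 3.0       # Å, SC-SC clash radius
    k_clash: float = 10.0         # energy/Å^2, soft-core stiffness
    k_bond: float = 5.0           # energy/Å^2, CA-CA virtual-bond stiffness
    bond_target: float = 3.8      # Å
    k_angle: float = 10.0         # energy/rad^2, outside the allowed window
    angle_min: float = 75.0       # degrees
    angle_max: float = 150.0      # degrees
    w_ss: float = 0.5             # energy/rad^2, secondary-structure bias
    contact_table: dict[tuple[str, str], float] = field(default_factory=default_contact_table)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ForceFieldParams":
        """Load constants from a YAML key/value file; missing keys keep defaults.

        The optional key ``contact_table`` names a matrix file (resolved
        relative to the YAML file)."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        table_path = raw.pop("contact_table", None)
        params = cls(**raw)
        if table_path is not None:
            resolved = Path(path).parent / table_path
            params.contact_table = load_contact_table(
                resolved if resolved.exists() else table_path)
        return params


def pair_well_depth(a: str, b: str, table: dict[tuple[str, str], float]) -> float:
    try:
        return table[(a, b)]
    except KeyError:
        raise ForceFieldError(f"contact table has no entry for pair ({a}, {b})") from None


@dataclass
class EnergyBreakdown:
    interaction: float
    intra_peptide: float
    excluded_volume: float
    restraint: float
    total: float = 0.0

    def __post_init__(self) -> None:
        self.total = (self.interaction + self.intra_peptide
                      + self.excluded_volume + self.restraint)


def interaction_energy(cplx: CGComplex, params: ForceFieldParams) -> float:
    """Receptor-peptide square-well contact energy over SC-SC pairs."""
    if not cplx.peptide:
        return 0.0
    rec = list(cplx.receptor_residues())
    rec_sc = np.array([r.sc for r in rec])
    pep_sc = cplx.peptide_sc()
    dist = cdist(rec_sc, pep_sc)
    in_well = (dist >= params.contact_min) & (dist <= params.contact_max)
    if not in_well.any():
        return 0.0
    total = 0.0
    table = params.contact_table
    for i, j in zip(*np.nonzero(in_well)):
        total += pair_well_depth(rec[i].aa_type, cplx.peptide[j].aa_type, table)
    return total


def _chain_clash(coords_a: np.ndarray, coords_b: np.ndarray,
                 r_clash: float, k: float, same_chain: bool) -> float:
    """Soft-core energy between two coordinate sets; skips bonded/self pairs."""
    d = cdist(coords_a, coords_b)
    if same_chain:
        n = len(coords_a)
        idx = np.arange(n)
        bonded = np.abs(idx[:, None] - idx[None, :]) <= 1
        d = np.where(bonded, np.inf, d)
        d = np.triu(d, k=1) + np.tril(np.full_like(d, np.inf), k=0)
    close = d < r_clash
    if not close.any():
        return 0.0
    return float(k * np.sum((r_clash - d[close]) ** 2))


def excluded_volume(cplx: CGComplex, params: ForceFieldParams) -> float:
    """Soft-core repulsion over CA-CA and SC-SC pairs.

    Covers all inter-chain pairs and intra-chain pairs separated by more
    than one residue (virtual bonds are handled by the bonded terms).
    """
    chains = [c for c in cplx.receptor_chains]
    if cplx.peptide:
        chains = chains + [cplx.peptide]
    energy = 0.0
    arrays = [(np.array([r.ca for r in c]), np.array([r.sc for r in c])) for c in chains]
    for i in range(len(chains)):
        ca_i, sc_i = arrays[i]
        energy += _chain_clash(ca_i, ca_i, params.r_clash_ca, params.k_clash, True)
        energy += _chain_clash(sc_i, sc_i, params.r_clash_sc, params.k_clash, True)
        for j in range(i + 1, len(chains)):
            ca_j, sc_j = arrays[j]
            energy += _chain_clash(ca_i, ca_j, params.r_clash_ca, params.k_clash, False)
            energy += _chain_clash(sc_i, sc_j, params.r_clash_sc, params.k_clash, False)
    return energy


def _pseudo_angles(ca: np.ndarray) -> np.ndarray:
    """Bond angle at each interior CA, degrees."""
    u = ca[:-2] - ca[1:-1]
    v = ca[2:] - ca[1:-1]
    cosang = np.sum(u * v, axis=1) / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _pseudo_dihedrals(ca: np.ndarray) -> np.ndarray:
    """Torsion of each 4-CA window, degrees in (-180, 180]."""
    b1 = ca[1:-2] - ca[:-3]
    b2 = ca[2:-1] - ca[1:-2]
    b3 = ca[3:] - ca[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(m1 * n2, axis=1)
    return np.degrees(np.arctan2(y, x))


def _window_penalty(values_deg: np.ndarray, lo: float, hi: float, k: float) -> float:
    """Quadratic penalty (in radians) for values outside [lo, hi] degrees."""
    below = np.clip(lo - values_deg, 0.0, None)
    above = np.clip(values_deg - hi, 0.0, None)
    excess = np.radians(below + above)
    return float(k * np.sum(excess ** 2))


# circular windows (degrees) biased toward by the ss term
_SS_ANGLE_WINDOW = {"H": (80.0, 105.0), "E": (110.0, 145.0)}
_SS_DIHEDRAL_WINDOW = {"H": (35.0, 70.0), "E": (150.0, 210.0)}


def intra_peptide_energy(peptide: list[CGResidue], params: ForceFieldParams,
                         ss: str | None = None) -> float:
    """Bonded peptide energy: bond + angle terms and optional ss bias."""
    ca = np.array([r.ca for r in peptide])
    bonds = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    energy = float(params.k_bond * np.sum((bonds - params.bond_target) ** 2))
    angles = _pseudo_angles(ca)
    energy += _window_penalty(angles, params.angle_min, params.angle_max, params.k_angle)

    if ss is not None and params.w_ss > 0:
        ss = ss.upper()
        dihedrals = _pseudo_dihedrals(ca) if len(ca) >= 4 else np.empty(0)
        # angle i is centred on residue i+1; dihedral i spans residues i..i+3
        for i, ang in enumerate(angles):
            window = _SS_ANGLE_WINDOW.get(ss[i + 1])
            if window:
                energy += _window_penalty(np.array([ang]), *window, k=params.w_ss)
        for i, dih in enumerate(dihedrals):
            code = ss[i + 1] if ss[i + 1] == ss[i + 2] else None
            window = _SS_DIHEDRAL_WINDOW.get(code) if code else None
            if window:
                # dihedrals are circular: fold into [window center - 180, +180)
                center = 0.5 * (window[0] + window[1])
                folded = (dih - center + 180.0) % 360.0 - 180.0 + center
                energy += _window_penalty(np.array([folded]), *window, k=params.w_ss)
    return energy


def total_energy(cplx: CGComplex, restraints: RestraintSet | None = None,
                 params: ForceFieldParams | None = None,
                 ss: str | None = None) -> EnergyBreakdown:
    """Full additive energy of a complex; components are independently computable."""
    if params is None:
        params = ForceFieldParams()
    restraint = total_restraint_energy(cplx, restraints) if restraints else 0.0
    return EnergyBreakdown(
        interaction=interaction_energy(cplx, params),
        intra_peptide=intra_peptide_energy(cplx.peptide, params, ss) if cplx.peptide else 0.0,
        excluded_volume=excluded_volume(cplx, params),
        restraint=restraint,
    )
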