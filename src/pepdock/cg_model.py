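"""Coarse-grained residue representation and conversion from all-atom PDB.

Each residue is reduced to up to four pseudo-atoms:

* ``ca`` — the alpha carbon,
* ``cb`` — the beta carbon (absent for glycine),
* ``sc`` — the unweighted center of mass of the side-chain heavy atoms
  (CB and beyond; for glycine ``sc`` coincides with ``ca``),
* ``cp`` — the center of the peptide bond to the next residue (midpoint of
  the carbonyl C and the next amide N; absent for the chain-terminal
  residue).

The peptide chain of a :class:`CGComplex` carries the reserved chain label
``"PEP"``; on disk it is written as PDB chain ``P``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

PEPTIDE_CHAIN_ID = "PEP"
#: one-character chain id used when a peptide chain is written to PDB
PEPTIDE_PDB_CHAIN = "P"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Selenomethionine is read as methionine; everything else under HETATM is skipped.
HET_ALIASES = {"MSE": "MET"}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "OT1", "OT2"}

#: distance (Å) from CA to the side-chain center used when a peptide is built
#: from sequence alone; rough per-residue side-chain sizes.
SC_OFFSET = {
    "A": 1.53, "R": 4.10, "N": 2.50, "D": 2.50, "C": 2.10,
    "Q": 3.10, "E": 3.10, "G": 0.00, "H": 3.10, "I": 2.30,
    "L": 2.60, "K": 3.50, "M": 2.90, "F": 3.40, "P": 1.90,
    "S": 1.90, "T": 1.90, "V": 2.00, "W": 3.90, "Y": 3.80,
}
CB_OFFSET = 1.53  # Å, CA->CB distance

CA_BOND = 3.8          # Å, virtual CA-CA bond length of a built peptide
ANGLE_MIN = 75.0       # degrees, pseudo-bond-angle lower bound
ANGLE_MAX = 150.0      # degrees, pseudo-bond-angle upper bound
SELF_AVOID_MIN = 3.6   # Å, minimum CA-CA separation in a built peptide


class CGError(ValueError):
    """Raised for malformed structures or sequences."""


@dataclass
class CGResidue:
    """One coarse-grained residue.

    Coordinates are float64 3-vectors in Å.  ``cb`` is ``None`` for glycine;
    ``cp`` is ``None`` for the last residue of a chain.
    """

    chain_id: str
    residue_number: int
    aa_type: str
    ca: np.ndarray
    cb: np.ndarray | None
    sc: np.ndarray
    cp: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.aa_type not in ONE_TO_THREE:
            raise CGError(f"unknown amino-acid type {self.aa_type!r}")
        self.ca = np.asarray(self.ca, dtype=float)
        self.sc = np.asarray(self.sc, dtype=float)
        if self.cb is not None:
            self.cb = np.asarray(self.cb, dtype=float)
        if self.cp is not None:
            self.cp = np.asarray(self.cp, dtype=float)

    def copy(self) -> "CGResidue":
        return replace(
            self,
            ca=self.ca.copy(),
            cb=None if self.cb is None else self.cb.copy(),
            sc=self.sc.copy(),
            cp=None if self.cp is None else self.cp.copy(),
        )


@dataclass
class CGComplex:
    """A receptor (one or more chains) plus a single peptide chain."""

    receptor_chains: list[list[CGResidue]]
    peptide: list[CGResidue] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.peptide and len(self.peptide) < 3:
            raise CGError("peptide must have at least 3 residues")
        for chain in list(self.receptor_chains) + ([self.peptide] if self.peptide else []):
            numbers = [r.residue_number for r in chain]
            if len(set(numbers)) != len(numbers):
                cid = chain[0].chain_id if chain else "?"
                raise CGError(f"duplicate residue numbers in chain {cid!r}")

    # -- convenience accessors -------------------------------------------------

    def receptor_residues(self) -> Iterator[CGResidue]:
        for chain in self.receptor_chains:
            yield from chain

    @property
    def n_receptor(self) -> int:
        return sum(len(c) for c in self.receptor_chains)

    def find_receptor_residue(self, residue_number: int, chain_id: str) -> CGResidue:
        for chain in self.receptor_chains:
            for res in chain:
                if res.residue_number == residue_number and res.chain_id == chain_id:
                    return res
        raise CGError(f"receptor residue {residue_number}:{chain_id} not found")

    def find_peptide_residue(self, residue_number: int) -> CGResidue:
        for res in self.peptide:
            if res.residue_number == residue_number:
                return res
        raise CGError(f"peptide residue {residue_number} not found")

    def receptor_ca(self) -> np.ndarray:
        return np.array([r.ca for r in self.receptor_residues()])

    def receptor_sc(self) -> np.ndarray:
        return np.array([r.sc for r in self.receptor_residues()])

    def peptide_ca(self) -> np.ndarray:
        return np.array([r.ca for r in self.peptide])

    def peptide_sc(self) -> np.ndarray:
        return np.array([r.sc for r in self.peptide])

    def copy(self) -> "CGComplex":
        return CGComplex(
            receptor_chains=[[r.copy() for r in chain] for chain in self.receptor_chains],
            peptide=[r.copy() for r in self.peptide],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CGComplex":
        """Return a copy with ``x -> R x + t`` applied to every pseudo-atom."""
        out = self.copy()
        for res in list(out.receptor_residues()) + out.peptide:
            res.ca = rotation @ res.ca + translation
            res.sc = rotation @ res.sc + translation
            if res.cb is not None:
                res.cb = rotation @ res.cb + translation
            if res.cp is not None:
                res.cp = rotation @ res.cp + translation
        return out


# -----------------------------------------------------------------------------
# conversion from all-atom structures
# -----------------------------------------------------------------------------

def _best_altloc(atoms: Iterable[gemmi.Atom]) -> dict[str, gemmi.Atom]:
    """Pick one atom per name: highest occupancy, ties broken by file order."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in atoms:
        if atom.is_hydrogen():
            continue
        prev = chosen.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            chosen[atom.name] = atom
    return chosen

def _pos(atom: gemmi.Atom) -> np.ndarray:
    return np.array([atom.pos.x, atom.pos.y, atom.pos.z])

def _convert_residue(res: gemmi.Residue, chain_id: str,
                     name_map: dict[str, str]) -> tuple[CGResidue, np.ndarray | None, np.ndarray | None]:
    """Convert one residue; also returns its carbonyl C and amide N positions."""
    name = name_map.get(res.name, res.name)
    if name not in THREE_TO_ONE:
        raise CGError(f"unknown residue name {res.name!r} at {chain_id}/{res.seqid.num}"
                      " (supply a 3-to-1 mapping override)")
    one = THREE_TO_ONE[name]
    atoms = _best_altloc(res)
    if "CA" not in atoms:
        raise CGError(f"missing CA atom in residue {chain_id}/{res.seqid.num} ({res.name})")
    ca = _pos(atoms["CA"])
    cb = _pos(atoms["CB"]) if "CB" in atoms else None
    side = [_pos(a) for n, a in atoms.items() if n not in BACKBONE_ATOMS]
    sc = np.mean(side, axis=0) if side else ca.copy()
    cg_res = CGResidue(chain_id=chain_id, residue_number=res.seqid.num,
                       aa_type=one, ca=ca, cb=cb, sc=sc)
    c = _pos(atoms["C"]) if "C" in atoms else None
    n = _pos(atoms["N"]) if "N" in atoms else None
    return cg_res, c, n


def _chain_sequence(residues: Sequence[CGResidue]) -> str:
    return "".join(r.aa_type for r in residues)


def coarse_grain(structure: gemmi.Structure | str | Path,
                 peptide_chain_selector: str | None = None,
                 name_map: dict[str, str] | None = None) -> CGComplex:
    """Reduce an all-atom structure to the coarse-grained representation.

    Parameters
    ----------
    structure
        A parsed ``gemmi.Structure`` or a path to a PDB file.  Only the
        first model is used.  HETATM records are skipped, except
        selenomethionine which is read as methionine.
    peptide_chain_selector
        Either a chain id naming the peptide chain, or the peptide's
        one-letter sequence (matched against chain sequences); ``None``
        treats every chain as receptor (no peptide).
    name_map
        Extra three-letter -> three-letter residue-name overrides for
        non-standard residues.

    Returns
    -------
    CGComplex
        All non-peptide protein chains as receptor, the selected chain as
        peptide (relabelled ``"PEP"``).
    """
    if isinstance(structure, (str, Path)):
        structure = gemmi.read_structure(str(structure), format=gemmi.CoorFormat.Pdb)
    full_map = dict(HET_ALIASES)
    if name_map:
        full_map.update(name_map)

    model = structure[0]
    chains: dict[str, list[CGResidue]] = {}
    for chain in model:
        converted: list[tuple[CGResidue, np.ndarray | None, np.ndarray | None]] = []
        for res in chain:
            if res.het_flag == "H" and res.name not in full_map:
                continue  # waters, ligands
            if res.name not in THREE_TO_ONE and res.name not in full_map:
                if res.het_flag == "H":
                    continue
                raise CGError(f"unknown residue name {res.name!r} in chain {chain.name}")
            converted.append(_convert_residue(res, chain.name, full_map))
        if not converted:
            continue
        # peptide-bond centers: midpoint of C(i) and N(i+1); CA-midpoint fallback
        residues = []
        for i, (cg_res, c_i, _) in enumerate(converted):
            if i + 1 < len(converted):
                nxt_res, _, n_next = converted[i + 1]
                if c_i is not None and n_next is not None:
                    cg_res.cp = 0.5 * (c_i + n_next)
                else:
                    cg_res.cp = 0.5 * (cg_res.ca + nxt_res.ca)
            residues.append(cg_res)
        chains[chain.name] = residues

    if not chains:
        raise CGError("structure contains no protein chains")

    if peptide_chain_selector is None:
        return CGComplex(receptor_chains=list(chains.values()), peptide=[])

    # resolve the peptide chain
    pep_id = None
    if peptide_chain_selector in chains:
        pep_id = peptide_chain_selector
    else:
        seq = peptide_chain_selector.upper()
        matches = [cid for cid, res in chains.items() if _chain_sequence(res) == seq]
        if len(matches) != 1:
            raise CGError(
                f"peptide selector {peptide_chain_selector!r} matches "
                f"{len(matches)} chains (chain ids: {sorted(chains)})")
        pep_id = matches[0]

    peptide = chains.pop(pep_id)
    for res in peptide:
        res.chain_id = PEPTIDE_CHAIN_ID
    return CGComplex(receptor_chains=list(chains.values()), peptide=peptide)


# -----------------------------------------------------------------------------
# peptide construction from sequence
# -----------------------------------------------------------------------------

def _side_direction(ca: np.ndarray, i: int) -> np.ndarray:
    """Unit vector from CA(i) pointing away from the local backbone."""
    n = len(ca)
    if n == 1:
        return np.array([0.0, 0.0, 1.0])
    if i == 0:
        u = ca[1] - ca[0]
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(u / np.linalg.norm(u), ref)) > 0.99:
            ref = np.array([0.0, 1.0, 0.0])
        d = np.cross(u, ref)
    elif i == n - 1:
        u = ca[n - 2] - ca[n - 1]
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(u / np.linalg.norm(u), ref)) > 0.99:
            ref = np.array([0.0, 1.0, 0.0])
        d = np.cross(u, ref)
    else:
        u = ca[i - 1] - ca[i]
        v = ca[i + 1] - ca[i]
        d = -(u + v)
        if np.linalg.norm(d) < 1e-8:
            d = np.cross(u, np.array([0.0, 0.0, 1.0]))
    return d / np.linalg.norm(d)


def place_side_pseudoatoms(residues: list[CGResidue]) -> None:
    """(Re)place CB and SC of each residue along its local side direction."""
    ca = np.array([r.ca for r in residues])
    for i, res in enumerate(residues):
        d = _side_direction(ca, i)
        if res.aa_type == "G":
            res.cb = None
            res.sc = res.ca.copy()
        else:
            res.cb = res.ca + CB_OFFSET * d
            res.sc = res.ca + SC_OFFSET[res.aa_type] * d


def update_cp_midpoints(residues: list[CGResidue]) -> None:
    """Set each cp to the CA midpoint with the next residue (built chains)."""
    for i, res in enumerate(residues):
        if i + 1 < len(residues):
            res.cp = 0.5 * (res.ca + residues[i + 1].ca)
        else:
            res.cp = None


def _grow_ca_trace(n: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding CA trace: 3.8 Å bonds, pseudo-angles in [75, 150] deg."""
    for _restart in range(100):
        ca = np.zeros((n, 3))
        ca[1] = [CA_BOND, 0.0, 0.0]
        ok = True
        for i in range(2, n):
            placed = False
            for _try in range(300):
                theta = math.radians(rng.uniform(ANGLE_MIN, ANGLE_MAX))
                phi = rng.uniform(0.0, 2.0 * math.pi)
                # frame at ca[i-1] with x along the previous bond
                ez = ca[i - 1] - ca[i - 2]
                ez /= np.linalg.norm(ez)
                ref = np.array([0.0, 0.0, 1.0])
                if abs(np.dot(ez, ref)) > 0.99:
                    ref = np.array([0.0, 1.0, 0.0])
                ex = np.cross(ref, ez)
                ex /= np.linalg.norm(ex)
                ey = np.cross(ez, ex)
                # bond angle theta between (ca[i-2]-ca[i-1]) and (ca[i]-ca[i-1])
                direction = (-math.cos(theta) * ez
                             + math.sin(theta) * (math.cos(phi) * ex + math.sin(phi) * ey))
                cand = ca[i - 1] + CA_BOND * direction
                if i >= 2 and np.min(np.linalg.norm(ca[: i - 1] - cand, axis=1)) < SELF_AVOID_MIN:
                    continue
                ca[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return ca
    raise CGError(f"failed to grow a self-avoiding {n}-residue CA trace")


def build_peptide_from_sequence(sequence: str, ss: str | None = None,
                                rng_seed: int = 0) -> list[CGResidue]:
    """Build a random self-avoiding coarse-grained peptide chain.

    The CA trace has 3.8 Å virtual bonds and pseudo-bond angles within
    [75°, 150°]; CB and SC sit on a per-residue-type offset along the local
    side direction.  Deterministic for a fixed ``rng_seed``.

    ``ss`` (per-residue string over H/E/C) is validated here and consumed by
    the force field's secondary-structure bias; it does not change the
    starting geometry.
    """
    sequence = sequence.upper()
    if len(sequence) < 3:
        raise CGError("peptide sequence must have at least 3 residues")
    for i, letter in enumerate(sequence):
        if letter not in AMINO_ACIDS:
            raise CGError(f"invalid amino-acid letter {letter!r} at position {i + 1}")
    if ss is not None:
        if len(ss) != len(sequence):
            raise CGError("secondary-structure string length must match sequence")
        bad = set(ss.upper()) - set("HEC")
        if bad:
            raise CGError(f"invalid secondary-structure codes: {sorted(bad)}")

    rng = np.random.default_rng(rng_seed)
    for _attempt in range(100):
        ca = _grow_ca_trace(len(sequence), rng)
        residues = [
            CGResidue(chain_id=PEPTIDE_CHAIN_ID, residue_number=i + 1,
                      aa_type=aa, ca=ca[i].copy(), cb=None, sc=ca[i].copy())
            for i, aa in enumerate(sequence)
        ]
        place_side_pseudoatoms(residues)
        update_cp_midpoints(residues)
        if _self_clash_free(residues):
            return residues
    raise CGError("failed to build a clash-free peptide conformation")


def _self_clash_free(residues: list[CGResidue],
                     r_ca: float = 3.5, r_sc: float = 3.0) -> bool:
    """No non-bonded CA-CA pair below ``r_ca`` and SC-SC pair below ``r_sc``."""
    ca = np.array([r.ca for r in residues])
    sc = np.array([r.sc for r in residues])
    n = len(residues)
    for coords, r_min in ((ca, r_ca), (sc, r_sc)):
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        idx = np.arange(n)
        mask = np.abs(idx[:, None] - idx[None, :]) > 1
        if np.any(d[mask] < r_min):
            return False
    return True


# -----------------------------------------------------------------------------
# CG PDB input/output
# -----------------------------------------------------------------------------

def _complex_to_gemmi_model(cplx: CGComplex, num: int) -> gemmi.Model:
    model = gemmi.Model(num)
    serial = 1

    def add_chain(residues: list[CGResidue], chain_name: str) -> None:
        nonlocal serial
        chain = gemmi.Chain(chain_name)
        for res in residues:
            g_res = gemmi.Residue()
            g_res.name = ONE_TO_THREE[res.aa_type]
            g_res.seqid = gemmi.SeqId(res.residue_number, " ")
            for name, coord, element in (
                ("CA", res.ca, "C"), ("CB", res.cb, "C"),
                ("SC", res.sc, "C"), ("CP", res.cp, "C"),
            ):
                if coord is None:
                    continue
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(element)
                atom.pos = gemmi.Position(*coord)
                atom.occ = 1.0
                atom.serial = serial
                serial += 1
                g_res.add_atom(atom)
            chain.add_residue(g_res)
        model.add_chain(chain)

    for residues in cplx.receptor_chains:
        add_chain(residues, residues[0].chain_id)
    if cplx.peptide:
        add_chain(cplx.peptide, PEPTIDE_PDB_CHAIN)
    return model


def write_cg_models(complexes: Sequence[CGComplex], path: str | Path) -> None:
    """Write coarse-grained complexes as a (multi-)model PDB file.

    Pseudo-atoms are named CA/CB/SC/CP; the peptide chain is written with
    chain id ``P``.
    """
    structure = gemmi.Structure()
    structure.name = "pepdock CG models"
    for i, cplx in enumerate(complexes):
        structure.add_model(_complex_to_gemmi_model(cplx, i + 1))
    structure.write_pdb(str(path))


def read_cg_models(path: str | Path,
                   peptide_chain: str = PEPTIDE_PDB_CHAIN) -> list[CGComplex]:
    """Read CG models written by :func:`write_cg_models`."""
    structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    out: list[CGComplex] = []
    for model in structure:
        receptor_chains: list[list[CGResidue]] = []
        peptide: list[CGResidue] = []
        for chain in model:
            residues = []
            is_pep = chain.name == peptide_chain
            for res in chain:
                atoms = {a.name: _pos(a) for a in res}
                if "CA" not in atoms:
                    raise CGError(f"CG model missing CA in {chain.name}/{res.seqid.num}")
                one = THREE_TO_ONE.get(res.name)
                if one is None:
                    raise CGError(f"unknown residue {res.name!r} in CG model")
                residues.append(CGResidue(
                    chain_id=PEPTIDE_CHAIN_ID if is_pep else chain.name,
                    residue_number=res.seqid.num, aa_type=one,
                    ca=atoms["CA"], cb=atoms.get("CB"),
                    sc=atoms.get("SC", atoms["CA"]), cp=atoms.get("CP"),
                ))
            if is_pep:
                peptide = residues
            else:
                receptor_chains.append(residues)
        out.append(CGComplex(receptor_chains=receptor_chains, peptide=peptide))
    return out
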