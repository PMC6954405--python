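"""Model-quality assessment against a reference complex.

Two standard accuracy measures for peptide docking are implemented:

* **peptide-RMSD** — RMSD over peptide CA atoms, computed after optimally
  superposing the model's receptor CA atoms onto the reference receptor
  (the peptide itself is *not* refitted).  Accuracy categories:
  high < 3 Å, medium 3-5.5 Å (inclusive), low > 5.5 Å.
* **i-RMSD** — interface RMSD in the CAPRI convention: interface residues
  are receptor residues with any pseudo-atom within 10 Å of any reference
  peptide pseudo-atom, plus all peptide residues; the RMSD is over their
  CA atoms after superposition on those same atoms.  Categories:
  sub-Ångström ≤ 1 Å, near-native 1-2 Å, not acceptable > 2 Å.

Peptide residues are paired by sequence position (modelled peptides are
built from sequence, so author numbering is not meaningful); receptor
residues are paired by (chain, residue number).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from pepdock.cg_model import CGComplex, CGResidue
from pepdock.restraints import RestraintSet, restraint_distance
from pepdock.sampler import Trajectory

HIGH_ACCURACY_MAX = 3.0      # Å, peptide-RMSD strictly below => high accuracy
MEDIUM_ACCURACY_MAX = 5.5    # Å, inclusive upper bound of medium accuracy
SUB_ANGSTROM_MAX = 1.0       # Å, i-RMSD
NEAR_NATIVE_MAX = 2.0        # Å, i-RMSD
INTERFACE_CUTOFF = 10.0      # Å, receptor-to-peptide pseudo-atom distance


class EvaluationError(ValueError):
    pass


@dataclass
class QualityReport:
    peptide_rmsd: float
    i_rmsd: float | None
    violations: list[float]
    category_rmsd: str
    category_irmsd: str | None


# -----------------------------------------------------------------------------
# superposition
# -----------------------------------------------------------------------------

def superpose(mobile: np.ndarray, target: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``target``; the rotation
    is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise EvaluationError("coordinate sets must be matching (n, 3) arrays")
    if len(mobile) < 3:
        raise EvaluationError("superposition needs at least 3 points")
    mob_center = mobile.mean(axis=0)
    tgt_center = target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(target - tgt_center, mobile - mob_center)
    rotation = rot.as_matrix()
    translation = tgt_center - rotation @ mob_center
    rmsd = rssd / np.sqrt(len(mobile))
    return rotation, translation, float(rmsd)


def _match_receptor(model: CGComplex, reference: CGComplex
                    ) -> tuple[list[CGResidue], list[CGResidue]]:
    ref_index = {(r.chain_id, r.residue_number): r for r in reference.receptor_residues()}
    pairs_m, pairs_r, unmatched = [], [], []
    for res in model.receptor_residues():
        ref = ref_index.get((res.chain_id, res.residue_number))
        if ref is None:
            unmatched.append(f"{res.residue_number}:{res.chain_id}")
        else:
            pairs_m.append(res)
            pairs_r.append(ref)
    if unmatched:
        raise EvaluationError(f"receptor residues missing from reference: {unmatched}")
    if not pairs_m:
        raise EvaluationError("no shared receptor residues")
    return pairs_m, pairs_r


def peptide_rmsd(model: CGComplex, reference: CGComplex) -> float:
    """RMSD over peptide CA atoms in the reference receptor frame.

    The model receptor CAs are superposed onto the reference receptor CAs;
    that transform is applied to the model peptide and the peptide CA RMSD
    is computed without further fitting.
    """
    if len(model.peptide) != len(reference.peptide):
        raise EvaluationError(
            f"peptide length mismatch: model {len(model.peptide)} vs "
            f"reference {len(reference.peptide)}")
    rec_m, rec_r = _match_receptor(model, reference)
    rotation, translation, _ = superpose(np.array([r.ca for r in rec_m]),
                                         np.array([r.ca for r in rec_r]))
    pep_m = model.peptide_ca() @ rotation.T + translation
    pep_r = reference.peptide_ca()
    return float(np.sqrt(np.mean(np.sum((pep_m - pep_r) ** 2, axis=1))))


def _residue_pseudoatoms(res: CGResidue) -> np.ndarray:
    coords = [res.ca, res.sc]
    if res.cb is not None:
        coords.append(res.cb)
    if res.cp is not None:
        coords.append(res.cp)
    return np.array(coords)


def interface_rmsd(model: CGComplex, reference: CGComplex,
                   interface_cutoff: float = INTERFACE_CUTOFF) -> float | None:
    """CAPRI-style interface RMSD over CA atoms; ``None`` if no interface.

    The interface comprises reference receptor residues with any
    pseudo-atom within ``interface_cutoff`` of any reference peptide
    pseudo-atom, plus every peptide residue; superposition is done on
    exactly those CA atoms.
    """
    if len(model.peptide) != len(reference.peptide):
        raise EvaluationError("peptide length mismatch")
    pep_atoms = np.concatenate([_residue_pseudoatoms(r) for r in reference.peptide])
    interface_keys = []
    for res in reference.receptor_residues():
        atoms = _residue_pseudoatoms(res)
        dmin = np.min(np.linalg.norm(atoms[:, None, :] - pep_atoms[None, :, :], axis=2))
        if dmin <= interface_cutoff:
            interface_keys.append((res.chain_id, res.residue_number))
    if not interface_keys:
        return None

    ref_index = {(r.chain_id, r.residue_number): r for r in reference.receptor_residues()}
    mod_index = {(r.chain_id, r.residue_number): r for r in model.receptor_residues()}
    missing = [k for k in interface_keys if k not in mod_index]
    if missing:
        raise EvaluationError(f"model lacks interface residues: {missing}")
    mob = np.array([mod_index[k].ca for k in interface_keys]
                   + [r.ca for r in model.peptide])
    tgt = np.array([ref_index[k].ca for k in interface_keys]
                   + [r.ca for r in reference.peptide])
    _, _, rmsd = superpose(mob, tgt)
    return rmsd


# -----------------------------------------------------------------------------
# categories and reports
# -----------------------------------------------------------------------------

def classify_peptide_rmsd(value: float) -> str:
    if value < HIGH_ACCURACY_MAX:
        return "high"
    if value <= MEDIUM_ACCURACY_MAX:
        return "medium"
    return "low"


def classify_irmsd(value: float) -> str:
    if value <= SUB_ANGSTROM_MAX:
        return "sub_angstrom"
    if value <= NEAR_NATIVE_MAX:
        return "near_native"
    return "not_acceptable"


def classify_quality(peptide_rmsd_value: float,
                     i_rmsd_value: float | None = None,
                     violations: list[float] | None = None) -> QualityReport:
    """Assign accuracy categories from the RMSD measures."""
    if peptide_rmsd_value < 0:
        raise EvaluationError("peptide-RMSD must be non-negative")
    return QualityReport(
        peptide_rmsd=peptide_rmsd_value,
        i_rmsd=i_rmsd_value,
        violations=violations or [],
        category_rmsd=classify_peptide_rmsd(peptide_rmsd_value),
        category_irmsd=None if i_rmsd_value is None else classify_irmsd(i_rmsd_value),
    )


def evaluate_model(model: CGComplex, reference: CGComplex,
                   restraints: RestraintSet | None = None) -> QualityReport:
    """Full quality report for one model against the reference complex."""
    violations = []
    if restraints:
        for r in restraints:
            d = restraint_distance(model, r)
            violations.append(max(0.0, d - r.d0))
    return classify_quality(peptide_rmsd(model, reference),
                            interface_rmsd(model, reference), violations)


def summarize_benchmark(case_reports: list[dict[str, list[QualityReport]]]
                        ) -> dict[str, dict[str, float]]:
    """Fractions of cases whose *best* model reaches each accuracy category.

    ``case_reports`` holds one dict per benchmark case mapping a set name
    (e.g. ``"all"``, ``"top10"``) to that case's model reports.  For each
    set, the best (lowest peptide-RMSD) model decides the case's category;
    the output maps set name -> {category: fraction of cases}.
    """
    out: dict[str, dict[str, float]] = {}
    set_names = sorted({name for case in case_reports for name in case})
    for name in set_names:
        counts = {"high": 0, "medium": 0, "low": 0}
        n_cases = 0
        for case in case_reports:
            reports = case.get(name)
            if not reports:
                continue
            n_cases += 1
            best = min(r.peptide_rmsd for r in reports)
            counts[classify_peptide_rmsd(best)] += 1
        out[name] = {cat: (c / n_cases if n_cases else 0.0)
                     for cat, c in counts.items()}
    return out


def violation_profile(trajectory: Trajectory,
                      restraints: RestraintSet) -> np.ndarray:
    """Per-model, per-restraint violation distances max(0, d - d0).

    Zero encodes "within the cutoff"; the matrix has one row per model and
    one column per restraint (shape (n_models, n_restraints)).
    """
    rlist = list(restraints)
    profile = np.zeros((len(trajectory), len(rlist)))
    for i, model in enumerate(trajectory):
        for j, r in enumerate(rlist):
            d = (model.restraint_distances[j]
                 if j < len(model.restraint_distances)
                 else restraint_distance(model.complex, r))
            profile[i, j] = max(0.0, d - r.d0)
    return profile
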