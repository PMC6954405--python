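import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pepdock.evaluate import (
    EvaluationError,
    classify_irmsd,
    classify_peptide_rmsd,
    classify_quality,
    evaluate_model,
    interface_rmsd,
    peptide_rmsd,
    summarize_benchmark,
    superpose,
    violation_profile,
)
from pepdock.fixtures import make_synthetic_trajectory
from pepdock.postprocess import filter_by_contact
from pepdock.restraints import ContactRestraint, RestraintSet


def _displace_peptide(reference, delta):
    moved = reference.copy()
    for res in moved.peptide:
        for attr in ("ca", "cb", "sc", "cp"):
            coord = getattr(res, attr)
            if coord is not None:
                setattr(res, attr, coord + np.asarray(delta, float))
    return moved


class TestSuperpose:
    def test_identical_sets_zero_rmsd_identity_transform(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        rot, trans, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(rot, np.eye(3), atol=1e-9)
        assert np.allclose(trans, 0.0, atol=1e-9)

    def test_rotated_set_recovers_zero_rmsd(self):
        pts = np.random.default_rng(1).normal(size=(8, 3))
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        _r, _t, rmsd = superpose(pts @ rot90.T, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_proper_rotation_even_for_mirrored_input(self):
        pts = np.random.default_rng(2).normal(size=(10, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        rot, _t, _rmsd = superpose(mirrored, pts)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_optimal_versus_random_transform_search(self):
        rng = np.random.default_rng(3)
        mobile = rng.normal(size=(10, 3))
        target = rng.normal(size=(10, 3))
        _r, _t, best = superpose(mobile, target)
        mob_c = mobile - mobile.mean(axis=0)
        tgt_c = target - target.mean(axis=0)
        for _ in range(2000):
            rot = Rotation.random(random_state=rng).as_matrix()
            rmsd = np.sqrt(np.mean(np.sum((mob_c @ rot.T - tgt_c) ** 2, axis=1)))
            assert best <= rmsd + 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(EvaluationError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestPeptideRMSD:
    def test_identical_model_is_zero(self, bound_reference):
        assert peptide_rmsd(bound_reference, bound_reference) == pytest.approx(0.0)

    def test_pure_translation_closed_form(self, bound_reference):
        moved = _displace_peptide(bound_reference, [2.0, 0.0, 0.0])
        assert peptide_rmsd(moved, bound_reference) == pytest.approx(2.0, abs=1e-9)

    def test_known_displacements_arithmetic_oracle(self, bound_reference):
        rng = np.random.default_rng(4)
        deltas = rng.normal(scale=1.5, size=(len(bound_reference.peptide), 3))
        moved = bound_reference.copy()
        for res, d in zip(moved.peptide, deltas):
            res.ca = res.ca + d
        expected = float(np.sqrt(np.mean(np.sum(deltas ** 2, axis=1))))
        assert peptide_rmsd(moved, bound_reference) == pytest.approx(expected, abs=1e-9)

    def test_joint_rigid_motion_invariance(self, bound_reference):
        moved = _displace_peptide(bound_reference, [3.0, -1.0, 0.5])
        rot = Rotation.from_euler("xyz", [15, 75, -40], degrees=True).as_matrix()
        both_moved = moved.transformed(rot, np.array([5.0, 6.0, -2.0]))
        assert peptide_rmsd(both_moved, bound_reference) == pytest.approx(
            peptide_rmsd(moved, bound_reference), abs=1e-6)

    def test_length_mismatch_is_error(self, bound_reference):
        shorter = bound_reference.copy()
        shorter.peptide = shorter.peptide[:-1]
        with pytest.raises(EvaluationError, match="length"):
            peptide_rmsd(shorter, bound_reference)


class TestInterfaceRMSD:
    def test_identical_structures_zero(self, bound_reference):
        assert interface_rmsd(bound_reference, bound_reference) == pytest.approx(
            0.0, abs=1e-6)

    def test_no_interface_returns_none(self, bound_reference):
        far = _displace_peptide(bound_reference, [500.0, 0.0, 0.0])
        assert interface_rmsd(far, far) is None

    def test_interface_selection_matches_brute_force(self, bound_reference):
        cutoff = 10.0
        pep_atoms = []
        for r in bound_reference.peptide:
            pep_atoms.extend([r.ca, r.sc] + ([r.cb] if r.cb is not None else [])
                             + ([r.cp] if r.cp is not None else []))
        pep_atoms = np.array(pep_atoms)
        expected = set()
        for res in bound_reference.receptor_residues():
            atoms = [res.ca, res.sc] + ([res.cb] if res.cb is not None else []) \
                + ([res.cp] if res.cp is not None else [])
            dmin = min(np.min(np.linalg.norm(pep_atoms - a, axis=1)) for a in atoms)
            if dmin <= cutoff:
                expected.add((res.chain_id, res.residue_number))
        assert expected  # the toy pocket has interface residues
        # a model whose interface residues moved changes i-RMSD; others do not
        moved_out = bound_reference.copy()
        for res in moved_out.receptor_residues():
            if (res.chain_id, res.residue_number) not in expected:
                res.ca = res.ca + np.array([0.0, 0.0, 50.0])
        assert interface_rmsd(moved_out, bound_reference) == pytest.approx(
            0.0, abs=1e-6)


class TestCategories:
    @pytest.mark.parametrize("value, category", [
        (2.41, "high"),    # restrained docking top-10 example value
        (2.999, "high"),
        (3.0, "medium"),   # boundary inclusive
        (5.5, "medium"),
        (5.501, "low"),
        (13.47, "low"),    # unrestrained docking top-10 example value
    ])
    def test_peptide_rmsd_boundaries(self, value, category):
        assert classify_peptide_rmsd(value) == category
        assert classify_quality(value).category_rmsd == category

    @pytest.mark.parametrize("value, category", [
        (0.5, "sub_angstrom"), (1.0, "sub_angstrom"),
        (1.001, "near_native"), (2.0, "near_native"),
        (2.001, "not_acceptable"), (8.0, "not_acceptable"),
    ])
    def test_irmsd_boundaries(self, value, category):
        assert classify_irmsd(value) == category

    def test_partition_has_no_gaps_or_overlaps(self):
        grid = np.concatenate([np.linspace(0, 20, 4001),
                               [3.0 - 1e-12, 3.0, 5.5, 5.5 + 1e-12]])
        for value in grid:
            cats = [c for c in ("high", "medium", "low")
                    if classify_peptide_rmsd(float(value)) == c]
            assert len(cats) == 1
        assert classify_quality(-1e-9 + 1e-9).category_rmsd == "high"
        with pytest.raises(EvaluationError):
            classify_quality(-0.1)


class TestBenchmarkSummary:
    def test_two_case_arithmetic(self):
        cases = [{"top10": [classify_quality(2.0)]},
                 {"top10": [classify_quality(6.0)]}]
        out = summarize_benchmark(cases)
        assert out["top10"] == {"high": 0.5, "medium": 0.0, "low": 0.5}

    def test_all_high(self):
        cases = [{"all": [classify_quality(v)]} for v in (0.5, 1.0, 2.9)]
        assert summarize_benchmark(cases)["all"] == {
            "high": 1.0, "medium": 0.0, "low": 0.0}

    def test_matches_hand_enumeration(self):
        rng = np.random.default_rng(6)
        cases = []
        best_values = []
        for _ in range(10):
            values = rng.uniform(0.5, 12.0, size=8)
            cases.append({"all": [classify_quality(float(v)) for v in values]})
            best_values.append(values.min())
        out = summarize_benchmark(cases)["all"]
        expected = {"high": 0.0, "medium": 0.0, "low": 0.0}
        for v in best_values:
            expected[classify_peptide_rmsd(v)] += 0.1
        for cat in expected:
            assert out[cat] == pytest.approx(expected[cat])


class TestViolationProfile:
    def test_zero_when_within_cutoff(self, bound_reference):
        rs = RestraintSet([ContactRestraint((1, "R"), 1, d0=5.0)])
        traj = make_synthetic_trajectory(bound_reference, n_models=40,
                                         fraction_near_native=0.5,
                                         rng_seed=7, restraints=rs)
        profile = violation_profile(traj, rs)
        assert profile.shape == (40, 1)
        for i, model in enumerate(traj):
            d = model.restraint_distances[0]
            assert profile[i, 0] == pytest.approx(max(0.0, d - 5.0))

    def test_nonzero_exactly_where_contact_filter_drops(self, toy_system):
        bound, _unbound, contacts = toy_system
        rs = RestraintSet([ContactRestraint(contacts[0][0], contacts[0][1])])
        traj = make_synthetic_trajectory(bound, n_models=100,
                                         fraction_near_native=0.4,
                                         rng_seed=8, restraints=rs)
        profile = violation_profile(traj, rs)
        kept = filter_by_contact(traj, rs)
        kept_sweeps = {m.sweep for m in kept}
        for i, model in enumerate(traj):
            assert (profile[i, 0] == 0.0) == (model.sweep in kept_sweeps)

    def test_worked_examples(self, bound_reference):
        rs = RestraintSet([ContactRestraint((1, "R"), 1, d0=5.0)])
        # d=4.2 -> 0; d=8.0 -> 3.0
        traj = make_synthetic_trajectory(bound_reference, n_models=2,
                                         fraction_near_native=1.0,
                                         rng_seed=0, restraints=rs)
        traj[0].restraint_distances = [4.2]
        traj[1].restraint_distances = [8.0]
        profile = violation_profile(traj, rs)
        assert profile[0, 0] == 0.0
        assert profile[1, 0] == pytest.approx(3.0)
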