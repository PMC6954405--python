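import numpy as np
import pytest

from pepdock.fixtures import make_synthetic_trajectory
from pepdock.forcefield import EnergyBreakdown
from pepdock.postprocess import (
    FilterConfig,
    cluster_models,
    filter_by_contact,
    filter_by_energy,
    pairwise_peptide_rmsd,
    run_pipeline,
)
from pepdock.restraints import ContactRestraint, RestraintSet
from pepdock.sampler import Trajectory, TrajectoryModel


def _traj_with_distances(distance_lists, energies=None):
    """Trajectory of dummy models carrying recorded restraint distances."""
    models = []
    for i, dists in enumerate(distance_lists):
        energy = EnergyBreakdown(
            interaction=(energies[i] if energies else 0.0),
            intra_peptide=0.0, excluded_volume=0.0,
            restraint=sum(max(0.0, d - 5.0) for d in dists))
        models.append(TrajectoryModel(complex=None, energy=energy, replica=0,
                                      sweep=i, restraint_distances=list(dists)))
    return Trajectory(models)


def _restraints(n):
    return RestraintSet([ContactRestraint((i + 1, "A"), i + 1) for i in range(n)])


class TestContactFilter:
    def test_empty_restraints_is_identity(self):
        traj = _traj_with_distances([[4.0], [9.0]])
        assert filter_by_contact(traj, RestraintSet()).models is traj.models \
            or len(filter_by_contact(traj, RestraintSet())) == 2

    def test_boundary_inclusive_at_cutoff(self):
        traj = _traj_with_distances([[4.9], [5.0], [5.1], [7.0], [2.0]])
        kept = filter_by_contact(traj, _restraints(1))
        assert [m.restraint_distances[0] for m in kept] == [4.9, 5.0, 2.0]

    def test_all_vs_any_truth_table(self):
        # satisfaction patterns TT, TF, FT, FF for two restraints
        traj = _traj_with_distances([[4, 4], [4, 9], [9, 4], [9, 9]])
        assert len(filter_by_contact(traj, _restraints(2), mode="all")) == 1
        assert len(filter_by_contact(traj, _restraints(2), mode="any")) == 3

    def test_idempotent(self):
        traj = _traj_with_distances([[4.9], [5.0], [5.1], [7.0], [2.0]])
        once = filter_by_contact(traj, _restraints(1))
        twice = filter_by_contact(once, _restraints(1))
        assert [m.sweep for m in once] == [m.sweep for m in twice]

    def test_empty_result_warns_and_falls_back(self):
        traj = _traj_with_distances([[9.0], [8.0], [7.0]])
        with pytest.warns(UserWarning, match="contact criterion"):
            kept = filter_by_contact(traj, _restraints(1))
        assert len(kept) == 0
        with pytest.warns(UserWarning, match="falling back"):
            fallback = filter_by_contact(traj, _restraints(1), fallback_n=2)
        # least-violating models first: distances 7 then 8
        assert [m.restraint_distances[0] for m in fallback] == [7.0, 8.0]


class TestEnergyFilter:
    def test_keeps_lowest_interaction_energies(self):
        traj = _traj_with_distances([[]] * 100,
                                    energies=list(range(100, 0, -1)))
        kept = filter_by_energy(traj, n_keep=10)
        assert len(kept) == 10
        assert sorted(m.energy.interaction for m in kept) == list(range(1, 11))

    def test_order_statistic_boundary(self):
        rng = np.random.default_rng(0)
        energies = list(rng.normal(size=200))
        traj = _traj_with_distances([[]] * 200, energies=energies)
        kept = filter_by_energy(traj, n_keep=50)
        kept_e = [m.energy.interaction for m in kept]
        dropped = sorted(set(range(200)) - {m.sweep for m in kept})
        assert max(kept_e) <= min(energies[i] for i in dropped)

    def test_small_input_kept_with_warning(self):
        traj = _traj_with_distances([[]] * 5, energies=[1, 2, 3, 4, 5])
        with pytest.warns(UserWarning, match="keeping all"):
            kept = filter_by_energy(traj, n_keep=10)
        assert len(kept) == 5

    def test_idempotent(self):
        traj = _traj_with_distances([[]] * 30, energies=list(range(30)))
        once = filter_by_energy(traj, n_keep=10)
        twice = filter_by_energy(once, n_keep=10)
        assert [m.sweep for m in once] == [m.sweep for m in twice]


def _pose_trajectory(reference, displacements, rng_seed=0):
    """Models that are the reference with the peptide rigidly displaced."""
    models = []
    for i, delta in enumerate(displacements):
        cplx = reference.copy()
        for res in cplx.peptide:
            for attr in ("ca", "cb", "sc", "cp"):
                coord = getattr(res, attr)
                if coord is not None:
                    setattr(res, attr, coord + np.asarray(delta, float))
        models.append(TrajectoryModel(
            complex=cplx,
            energy=EnergyBreakdown(interaction=0.0, intra_peptide=0.0,
                                   excluded_volume=0.0, restraint=0.0),
            replica=0, sweep=i, restraint_distances=[]))
    return Trajectory(models)


class TestClustering:
    def test_recovers_well_separated_pose_groups(self, bound_reference):
        rng = np.random.default_rng(1)
        displacements = []
        labels = []
        for g, base in enumerate([[0, 0, 0], [20, 0, 0], [0, 20, 0]]):
            for _ in range(6):
                displacements.append(np.asarray(base, float)
                                     + rng.normal(scale=0.2, size=3))
                labels.append(g)
        traj = _pose_trajectory(bound_reference, displacements)
        report = cluster_models(traj, k=3)
        assert len(report.clusters) == 3
        found = [frozenset(c.members) for c in report.clusters]
        expected = [frozenset(np.nonzero(np.array(labels) == g)[0].tolist())
                    for g in range(3)]
        assert set(found) == set(expected)

    def test_identical_models_single_cluster_density_is_size(self, bound_reference):
        traj = _pose_trajectory(bound_reference, [[0, 0, 0]] * 5)
        report = cluster_models(traj, k=1)
        assert len(report.clusters) == 1
        assert report.clusters[0].density == 5.0

    def test_matches_exhaustive_kmedoids_on_six_models(self, bound_reference):
        from itertools import combinations
        rng = np.random.default_rng(3)
        traj = _pose_trajectory(
            bound_reference, [rng.uniform(-15, 15, size=3) for _ in range(6)])
        dist = pairwise_peptide_rmsd(traj)
        best_cost = min(
            np.sum(np.min(dist[:, list(pair)], axis=1))
            for pair in combinations(range(6), 2))
        report = cluster_models(traj, k=2)
        medoids = sorted(c.medoid for c in report.clusters)
        cost = np.sum(np.min(dist[:, medoids], axis=1))
        assert cost == pytest.approx(best_cost)

    def test_k_reduced_with_warning_when_too_few_models(self, bound_reference):
        traj = _pose_trajectory(bound_reference, [[0, 0, 0], [9, 0, 0]])
        with pytest.warns(UserWarning, match="reducing k"):
            report = cluster_models(traj, k=5)
        assert len(report.clusters) == 2

    def test_final_models_sorted_by_density(self, bound_reference):
        rng = np.random.default_rng(5)
        displacements = ([rng.normal(scale=0.1, size=3) for _ in range(8)]
                         + [np.array([25.0, 0, 0]) + rng.normal(scale=2.0, size=3)
                            for _ in range(4)])
        traj = _pose_trajectory(bound_reference, displacements)
        report = cluster_models(traj, k=2)
        densities = [c.density for c in report.clusters]
        order = [report.clusters[i].density
                 for i in np.argsort([-c.density for c in report.clusters])]
        assert report.final_models[0] == max(
            report.clusters, key=lambda c: c.density).medoid
        assert order == sorted(densities, reverse=True)


class TestPipeline:
    def test_stage_composition_and_provenance(self, bound_reference):
        rs = _restraints(0)  # empty: contact stage inert
        traj = make_synthetic_trajectory(bound_reference, n_models=300,
                                         fraction_near_native=0.3, rng_seed=2)
        report, prov = run_pipeline(traj, None,
                                    FilterConfig(n_keep_energy=100), k=5)
        assert prov.n_input == 300
        assert prov.n_after_contact == 300
        assert prov.n_after_energy == 100
        assert prov.n_clusters == 5
        assert len(report.final_models) == 5

    def test_contact_filter_composes_with_energy_filter(self, toy_system):
        bound, _unbound, contacts = toy_system
        (rec, pep_num, _d) = contacts[0]
        rs = RestraintSet([ContactRestraint(rec, pep_num)])
        traj = make_synthetic_trajectory(bound, n_models=400,
                                         fraction_near_native=0.5,
                                         rng_seed=3, restraints=rs)
        report, prov = run_pipeline(traj, rs, FilterConfig(n_keep_energy=100), k=5)
        assert prov.n_after_contact < prov.n_input
        assert prov.n_after_energy == min(100, prov.n_after_contact)
        # every final model satisfies the contact criterion
        for idx in report.final_models:
            model = report.models[idx]
            assert model.restraint_distances[0] <= rs.restraints[0].d0

    def test_deterministic(self, bound_reference):
        traj = make_synthetic_trajectory(bound_reference, n_models=200,
                                         fraction_near_native=0.3, rng_seed=4)
        r1, _ = run_pipeline(traj, None, FilterConfig(n_keep_energy=80), k=4)
        r2, _ = run_pipeline(traj, None, FilterConfig(n_keep_energy=80), k=4)
        assert r1.final_models == r2.final_models
        assert [c.members for c in r1.clusters] == [c.members for c in r2.clusters]
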