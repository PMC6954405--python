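"""Filtering, clustering and scoring of docking trajectories.

The pipeline runs three fixed stages:

1. **contact filtering** — models whose recorded restraint distance exceeds
   the cutoff ``d0`` (i.e. models outside the zero-energy region of the
   restraint) are discarded; with several restraints either *all* (default)
   or *any* of them must be satisfied,
2. **energy filtering** — the ``n_keep_energy`` (default 1000) models with
   the lowest receptor-peptide interaction energy are kept,
3. **clustering** — k-medoids (default k = 10) on the matrix of pairwise
   peptide-RMSD values; clusters are scored by density
   (size / mean intra-cluster pairwise RMSD) and the cluster medoids,
   ordered by density, are the final models.

If contact filtering removes every model, the pipeline falls back to the
models with the smallest total restraint energy (i.e. the least-violating
poses) and emits a warning rather than failing: hard targets with barely
accessible binding sites may never fully satisfy a strict contact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from pepdock.evaluate import superpose
from pepdock.restraints import RestraintSet, restraint_distance
from pepdock.sampler import Trajectory

EXHAUSTIVE_MEDOID_LIMIT = 5000  # max number of medoid subsets to enumerate


@dataclass
class FilterConfig:
    n_keep_energy: int = 1000
    contact_mode: str = "all"  # one of {"off", "all", "any"}

    def __post_init__(self) -> None:
        if self.contact_mode not in ("off", "all", "any"):
            raise ValueError(f"contact_mode must be off/all/any, got {self.contact_mode!r}")


@dataclass
class Cluster:
    members: list[int]          # indices into the clustered trajectory
    medoid: int                 # index into the clustered trajectory
    density: float


@dataclass
class ClusterReport:
    clusters: list[Cluster]
    final_models: list[int]     # medoid indices ordered by density descending
    models: Trajectory          # the clustered subset the indices refer to


@dataclass
class PipelineProvenance:
    n_input: int = 0
    n_after_contact: int = 0
    n_after_energy: int = 0
    n_clusters: int = 0
    contact_fallback_used: bool = False
    warnings: list[str] = field(default_factory=list)


# -----------------------------------------------------------------------------
# filters
# -----------------------------------------------------------------------------

def _model_distances(model, restraints: RestraintSet) -> list[float]:
    rlist = list(restraints)
    if len(model.restraint_distances) >= len(rlist):
        return model.restraint_distances[: len(rlist)]
    return [restraint_distance(model.complex, r) for r in rlist]


def model_satisfies_contacts(model, restraints: RestraintSet, mode: str = "all") -> bool:
    """A restraint is satisfied iff its recorded SC-SC distance is <= d0."""
    flags = [d <= r.d0 for d, r in zip(_model_distances(model, restraints), restraints)]
    return all(flags) if mode == "all" else any(flags)


def filter_by_contact(trajectory: Trajectory, restraints: RestraintSet | None,
                      mode: str = "all",
                      fallback_n: int | None = None) -> Trajectory:
    """Drop models that do not satisfy the contact criterion.

    ``mode="all"`` keeps models satisfying every restraint, ``"any"`` at
    least one, ``"off"`` (or an empty restraint set) disables the filter.
    With an empty result: if ``fallback_n`` is given, the ``fallback_n``
    models with the smallest total restraint energy are returned instead
    (with a warning); otherwise the empty subset is returned.
    """
    if mode == "off" or not restraints:
        return trajectory
    keep = [i for i, m in enumerate(trajectory)
            if model_satisfies_contacts(m, restraints, mode)]
    if not keep:
        warnings.warn("no model satisfies the contact criterion"
                      + ("; falling back to least-violating models" if fallback_n else ""))
        if fallback_n:
            order = sorted(range(len(trajectory)),
                           key=lambda i: (trajectory[i].energy.restraint, i))
            return trajectory.subset(order[:fallback_n])
    return trajectory.subset(keep)


def filter_by_energy(trajectory: Trajectory, n_keep: int = 1000) -> Trajectory:
    """Keep the ``n_keep`` models with the lowest interaction energy.

    Ties are broken by model index ascending; if the input is already
    smaller than ``n_keep`` everything is kept (with a warning).
    """
    if len(trajectory) <= n_keep:
        if len(trajectory) < n_keep:
            warnings.warn(f"only {len(trajectory)} models available for an "
                          f"energy filter of {n_keep}; keeping all")
        return trajectory
    order = sorted(range(len(trajectory)),
                   key=lambda i: (trajectory[i].energy.interaction, i))
    return trajectory.subset(sorted(order[:n_keep]))


# -----------------------------------------------------------------------------
# clustering
# -----------------------------------------------------------------------------

def pairwise_peptide_rmsd(trajectory: Trajectory) -> np.ndarray:
    """Pairwise peptide-CA RMSD matrix in a common receptor frame.

    Each model's receptor CAs are superposed onto the first model's
    receptor; pairwise RMSD is then computed over the transformed peptide
    CAs with no further fitting.
    """
    n = len(trajectory)
    ref_rec = trajectory[0].complex.receptor_ca()
    peptides = np.empty((n, len(trajectory[0].complex.peptide), 3))
    for i, model in enumerate(trajectory):
        rot, trans, _ = superpose(model.complex.receptor_ca(), ref_rec)
        peptides[i] = model.complex.peptide_ca() @ rot.T + trans
    diff = peptides[:, None, :, :] - peptides[None, :, :, :]
    return np.sqrt(np.mean(np.sum(diff ** 2, axis=3), axis=2))


def _assignment_cost(dist: np.ndarray, medoids: tuple[int, ...]) -> float:
    return float(np.sum(np.min(dist[:, list(medoids)], axis=1)))


def _kmedoids(dist: np.ndarray, k: int) -> list[int]:
    """Deterministic k-medoids: exhaustive for tiny inputs, else
    farthest-point seeding plus PAM-style swaps."""
    n = len(dist)
    if comb(n, k) <= EXHAUSTIVE_MEDOID_LIMIT:
        best = min(combinations(range(n), k),
                   key=lambda m: (_assignment_cost(dist, m), m))
        return list(best)
    # seed: most central point first, then farthest-point
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        d_to_near = np.min(dist[:, medoids], axis=1)
        medoids.append(int(np.argmax(d_to_near)))
    # PAM swap phase
    improved = True
    cost = _assignment_cost(dist, tuple(medoids))
    while improved:
        improved = False
        for mi in range(k):
            for cand in range(n):
                if cand in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = cand
                trial_cost = _assignment_cost(dist, tuple(trial))
                if trial_cost < cost - 1e-12:
                    medoids, cost, improved = trial, trial_cost, True
    return sorted(medoids)


def cluster_models(models: Trajectory, k: int = 10, rng_seed: int = 0) -> ClusterReport:
    """k-medoids clustering of docking models with density scoring.

    The distance is pairwise peptide-RMSD; each cluster is scored by
    ``size / mean intra-cluster pairwise RMSD`` (score = size when the
    cluster is a singleton or has zero spread) and the medoids, ordered by
    density descending, form the ``final_models`` list.  The algorithm is
    fully deterministic (``rng_seed`` is accepted for interface stability
    but not consumed).
    """
    n = len(models)
    if n == 0:
        raise ValueError("cannot cluster an empty model set")
    if n < k:
        warnings.warn(f"only {n} models for k={k}; reducing k to {n}")
        k = n
    dist = pairwise_peptide_rmsd(models)
    medoids = _kmedoids(dist, k)
    assign = np.argmin(dist[:, medoids], axis=1)

    clusters = []
    for ci, medoid in enumerate(medoids):
        members = [int(i) for i in np.nonzero(assign == ci)[0]]
        size = len(members)
        if size > 1:
            sub = dist[np.ix_(members, members)]
            mean_rmsd = float(np.sum(sub) / (size * (size - 1)))
        else:
            mean_rmsd = 0.0
        density = size / mean_rmsd if mean_rmsd > 1e-12 else float(size)
        # medoid := member minimizing summed distance within the cluster
        best_medoid = min(members, key=lambda i: (dist[i, members].sum(), i))
        clusters.append(Cluster(members=members, medoid=int(best_medoid),
                                density=density))
    order = sorted(range(len(clusters)),
                   key=lambda i: (-clusters[i].density, i))
    final = [clusters[i].medoid for i in order]
    return ClusterReport(clusters=clusters, final_models=final, models=models)


# -----------------------------------------------------------------------------
# the full postprocessing pipeline
# -----------------------------------------------------------------------------

def run_pipeline(trajectory: Trajectory, restraints: RestraintSet | None = None,
                 filter_config: FilterConfig | None = None,
                 k: int = 10, rng_seed: int = 0
                 ) -> tuple[ClusterReport, PipelineProvenance]:
    """Contact filter -> energy filter -> clustering, with provenance."""
    if filter_config is None:
        filter_config = FilterConfig()
    prov = PipelineProvenance(n_input=len(trajectory))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        contact_kept = filter_by_contact(trajectory, restraints,
                                         filter_config.contact_mode,
                                         fallback_n=filter_config.n_keep_energy)
        prov.n_after_contact = len(contact_kept)
        prov.contact_fallback_used = any(
            "falling back" in str(w.message) for w in caught)
        energy_kept = filter_by_energy(contact_kept, filter_config.n_keep_energy)
        prov.n_after_energy = len(energy_kept)
        report = cluster_models(energy_kept, k=k, rng_seed=rng_seed)
        prov.warnings = [str(w.message) for w in caught]
    for message in prov.warnings:
        warnings.warn(message)
    prov.n_clusters = len(report.clusters)
    return report, prov
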