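"""Medoid clustering, k selection, transition graphs."""

from itertools import combinations

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from quadgeom.clustering import (
    ClusterModel,
    DistanceMatrix,
    TransitionGraph,
    cluster_medoids,
    distance_matrix,
    isolated_clusters,
    select_k,
    transition_graph,
)
from quadgeom.geometry import rmsd
from quadgeom.structures import Ensemble
from quadgeom.synthetic import (
    PerturbationSpec,
    TrajectorySpec,
    backbone_ic_table,
    build_chain,
    copy_structure,
    generate_trajectories,
    make_cluster_centers,
    perturb_ensemble,
)


def small_chain(seed=12, n=5):
    rng = np.random.default_rng(seed)
    torsions = [
        {k: float(rng.uniform(-170, 170))
         for k in ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi")}
        for _ in range(n)
    ]
    return build_chain(backbone_ic_table(torsions, names=["DG"] * n))


def planted_ensemble(n_centers=3, schedule=None, noise=0.05, seed=5):
    ref = small_chain()
    centers = make_cluster_centers(ref, n_centers, deform_sigma=2.0, seed=seed)
    spec = TrajectorySpec(
        noise_sigma=noise,
        schedule=schedule or ((0,) * 10 + (1,) * 10, (2,) * 10 + (0,) * 10, (1,) * 10 + (2,) * 10),
        seed=seed,
    )
    planted = [c for traj in spec.schedule for c in traj]
    return generate_trajectories(centers, spec), spec, planted


def brute_force_optimum(d: np.ndarray, k: int) -> float:
    return min(
        float(d[:, list(sub)].min(axis=1).sum())
        for sub in combinations(range(d.shape[0]), k)
    )


class TestDistanceMatrix:
    def test_identical_frames_give_zero_matrix(self):
        chain = small_chain()
        ens = Ensemble(members=[copy_structure(chain, model_id=i) for i in range(1, 4)])
        dm = distance_matrix(ens)
        assert np.allclose(dm.values, 0.0, atol=1e-9)

    def test_entries_match_geometry_rmsd(self):
        ens = perturb_ensemble(small_chain(), PerturbationSpec(sigma_profile=0.5,
                                                               n_members=4, seed=3))
        dm = distance_matrix(ens, fit=True)
        a = np.array([at.position for r in ens[0].residues() for at in r.atoms])
        b = np.array([at.position for r in ens[2].residues() for at in r.atoms])
        assert dm.values[0, 2] == pytest.approx(rmsd(a, b, fit=True), abs=1e-12)

    def test_symmetry_and_zero_diagonal_on_random_frames(self):
        ens = perturb_ensemble(small_chain(), PerturbationSpec(sigma_profile=0.4,
                                                               n_members=20, seed=8))
        dm = distance_matrix(ens)
        assert np.allclose(dm.values, dm.values.T, atol=1e-9)
        assert np.allclose(np.diag(dm.values), 0.0)
        assert np.all(dm.values >= 0)

    def test_frame_labels_carry_trajectories(self):
        ens, _, _ = planted_ensemble()
        dm = distance_matrix(ens)
        assert dm.frame_labels[0] == ("0", 0)
        assert dm.frame_labels[-1] == ("2", 19)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(values=np.array([[0.0, 1.0], [2.0, 0.0]]),
                           frame_labels=(("0", 0), ("0", 1)))


class TestClusterMedoids:
    def test_k_equals_n_gives_singletons(self):
        ens, _, _ = planted_ensemble()
        dm = distance_matrix(ens)
        model = cluster_medoids(dm, k=dm.n, seed=0)
        assert sorted(model.medoid_indices) == list(range(dm.n))
        assert model.populations == tuple([1.0 / dm.n] * dm.n)

    def test_planted_partition_recovered_exactly(self):
        ens, _, planted = planted_ensemble()
        dm = distance_matrix(ens)
        model = cluster_medoids(dm, k=3, seed=0)
        assert adjusted_rand_score(planted, model.labels) == pytest.approx(1.0)

    def test_pam_heuristic_matches_brute_force_on_tiny_problems(self):
        """The iterative PAM path (exact search disabled) still reaches the
        global optimum on small planted data."""
        ens, _, _ = planted_ensemble(schedule=((0, 0, 1), (1, 2, 2), (0, 1, 2)))
        dm = distance_matrix(ens)  # n = 9
        optimum = brute_force_optimum(dm.values, 3)
        model = cluster_medoids(dm, k=3, seed=0, exact_below=0)
        objective = float(dm.values[:, list(model.medoid_indices)].min(axis=1).sum())
        assert objective == pytest.approx(optimum, abs=1e-10)

    def test_exact_branch_matches_brute_force(self):
        ens, _, _ = planted_ensemble(schedule=((0, 1, 2, 0, 1, 2, 0, 1),))
        dm = distance_matrix(ens)  # n = 8
        for k in (2, 3):
            model = cluster_medoids(dm, k=k, seed=1)
            objective = float(dm.values[:, list(model.medoid_indices)].min(axis=1).sum())
            assert objective == pytest.approx(brute_force_optimum(dm.values, k), abs=1e-12)

    def test_medoid_property_reverified_post_hoc(self):
        ens, _, _ = planted_ensemble()
        dm = distance_matrix(ens)
        model = cluster_medoids(dm, k=3, seed=0)
        for cid, medoid in enumerate(model.medoid_indices):
            members = np.flatnonzero(model.labels == cid)
            sums = dm.values[np.ix_(members, members)].sum(axis=1)
            assert dm.values[medoid, members].sum() == pytest.approx(float(sums.min()))

    def test_deterministic_under_seed_and_stable_across_seeds(self):
        ens, _, planted = planted_ensemble()
        dm = distance_matrix(ens)
        a = cluster_medoids(dm, k=3, seed=7, exact_below=0)
        b = cluster_medoids(dm, k=3, seed=7, exact_below=0)
        assert np.array_equal(a.labels, b.labels)
        # on well-separated data every seed finds the planted partition
        for seed in (1, 2, 3):
            c = cluster_medoids(dm, k=3, seed=seed, exact_below=0)
            assert adjusted_rand_score(a.labels, c.labels) == pytest.approx(1.0)

    def test_k_out_of_range_rejected(self):
        ens, _, _ = planted_ensemble(schedule=((0, 1, 2),))
        dm = distance_matrix(ens)
        with pytest.raises(ValueError):
            cluster_medoids(dm, k=dm.n + 1)


class TestSelectK:
    def test_three_separated_clusters_found(self):
        ens, _, _ = planted_ensemble()
        dm = distance_matrix(ens)
        assert select_k(dm, k_max=10, seed=0) == 3

    def test_single_blob_flagged_weak(self):
        ens = perturb_ensemble(small_chain(), PerturbationSpec(sigma_profile=0.2,
                                                               n_members=12, seed=4))
        dm = distance_matrix(ens)
        with pytest.warns(UserWarning, match="weak structure"):
            k = select_k(dm, k_max=6, seed=0)
        assert k >= 2

    def test_kmax_two_forces_two(self):
        ens, _, _ = planted_ensemble()
        dm = distance_matrix(ens)
        assert select_k(dm, k_max=2, seed=0) == 2

    def test_too_few_frames_rejected(self):
        ens, _, _ = planted_ensemble(schedule=((0, 1),))
        dm = distance_matrix(ens)
        with pytest.raises(ValueError):
            select_k(dm, k_max=5)


def model_from_labels(labels, k):
    labels = np.asarray(labels)
    medoids = tuple(int(np.flatnonzero(labels == c)[0]) for c in range(k))
    pops = tuple(float(np.sum(labels == c)) / len(labels) for c in range(k))
    return ClusterModel(k=k, labels=labels, medoid_indices=medoids, populations=pops)


class TestTransitions:
    def test_single_trajectory_single_switch(self):
        model = model_from_labels([0, 0, 1], k=2)
        graph = transition_graph(model, [("0", 0), ("0", 1), ("0", 2)])
        assert graph.counts[0, 1] == 1
        assert graph.total_transitions == 1

    def test_no_cross_trajectory_transitions(self):
        model = model_from_labels([0, 1], k=2)
        graph = transition_graph(model, [("a", 0), ("b", 0)])
        assert graph.total_transitions == 0

    def test_planted_switch_count_recovered(self):
        ens, spec, planted = planted_ensemble()
        dm = distance_matrix(ens)
        model = cluster_medoids(dm, k=3, seed=0)
        graph = transition_graph(model, dm.frame_labels)
        assert graph.total_transitions == spec.n_switches

    def test_block_permutation_leaves_totals_unchanged(self):
        ens, spec, _ = planted_ensemble()
        dm = distance_matrix(ens)
        model = cluster_medoids(dm, k=3, seed=0)
        ref = transition_graph(model, dm.frame_labels).total_transitions
        relabeled = [(f"traj-{t}", i) for t, i in dm.frame_labels]
        assert transition_graph(model, relabeled).total_transitions == ref
        # permute whole-trajectory blocks
        order = sorted(range(len(dm.frame_labels)),
                       key=lambda i: (dm.frame_labels[i][0] != "2", i))
        permuted_labels = [dm.frame_labels[i] for i in order]
        permuted_model = model_from_labels(model.labels[order], model.k)
        assert transition_graph(permuted_model, permuted_labels).total_transitions == ref

    def test_single_frame_trajectories_give_zero(self):
        ref = small_chain()
        centers = make_cluster_centers(ref, 2, seed=0)
        ens = generate_trajectories(centers, TrajectorySpec(schedule=((0,), (1,)), seed=0))
        dm = distance_matrix(ens)
        model = cluster_medoids(dm, k=2, seed=0)
        assert transition_graph(model, dm.frame_labels).total_transitions == 0


class TestIsolated:
    def _graph(self, k, edges):
        counts = np.zeros((k, k), dtype=int)
        for i, j in edges:
            counts[i, j] = 1
        connectivity = {frozenset(e) for e in edges}
        return TransitionGraph(counts=counts, connectivity=connectivity)

    def test_fully_connected_has_none(self):
        g = self._graph(4, [(i, j) for i in range(4) for j in range(4) if i != j])
        assert isolated_clusters(g) == []

    def test_star_reports_all_leaves(self):
        g = self._graph(5, [(0, j) for j in range(1, 5)])
        assert isolated_clusters(g) == [1, 2, 3, 4]

    def test_chain_topology_reports_ends(self):
        g = self._graph(3, [(0, 1), (1, 2)])
        assert isolated_clusters(g) == [0, 2]
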