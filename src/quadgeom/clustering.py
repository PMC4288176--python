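"""Medoid clustering of conformational ensembles and transition graphs.

Frames are compared by pairwise least-squares-fitted RMSD; the resulting
dissimilarity matrix is clustered with PAM-style k-medoids (the medoid of a
cluster is the member whose summed dissimilarity to the rest of the cluster
is minimal — it is always a physical frame). The number of clusters is
chosen by mean silhouette over k = 2..k_max with ties resolved toward the
smaller k. Transitions are counted between consecutive frames of the same
trajectory only, so stitching multiple runs together can never fabricate a
transition across a run boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.metrics import silhouette_score

from .geometry import rmsd as _rmsd
from .structures import Atom, Ensemble, Residue

__all__ = [
    "DistanceMatrix",
    "ClusterModel",
    "TransitionGraph",
    "distance_matrix",
    "cluster_medoids",
    "select_k",
    "transition_graph",
    "isolated_clusters",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric frame-by-frame dissimilarities (Angstrom RMSD)."""

    values: np.ndarray
    frame_labels: tuple[tuple[str, int], ...]  # (trajectory id, frame index)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.frame_labels) != v.shape[0]:
            raise ValueError("frame_labels must pair 1:1 with rows")
        if not np.allclose(v, v.T, atol=1e-9) or np.any(np.diag(v) > 1e-9) or np.any(v < -1e-12):
            raise ValueError("matrix must be symmetric, nonnegative, zero-diagonal")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ClusterModel:
    k: int
    labels: np.ndarray
    medoid_indices: tuple[int, ...]
    populations: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        assert abs(sum(self.populations) - 1.0) < 1e-9
        for cid, m in enumerate(self.medoid_indices):
            assert self.labels[m] == cid, "each medoid must belong to its own cluster"


@dataclass
class TransitionGraph:
    counts: np.ndarray  # k x k, off-diagonal = observed transitions
    connectivity: set[frozenset] = field(default_factory=set)

    @property
    def total_transitions(self) -> int:
        return int(self.counts.sum() - np.trace(self.counts))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.counts.shape[0]))
        for pair in self.connectivity:
            a, b = sorted(pair)
            g.add_edge(a, b, count=int(self.counts[a, b] + self.counts[b, a]))
        return g


def distance_matrix(
    ensemble: Ensemble,
    selection=None,
    fit: bool = True,
) -> DistanceMatrix:
    """Pairwise (optionally fitted) RMSD over an atom selection.

    ``selection`` is a callable ``(residue, atom) -> bool``; default all
    atoms. Frame labels carry the ensemble's source (trajectory) labels.
    """
    ensemble.assert_shared_layout()

    def coords(structure) -> np.ndarray:
        pts = [
            a.position
            for r in structure.residues()
            for a in r.atoms
            if selection is None or selection(r, a)
        ]
        return np.array(pts, dtype=float)

    frames = [coords(m) for m in ensemble]
    if any(f.shape != frames[0].shape for f in frames):
        raise ValueError("selection yields differing atom counts across members")
    n = len(frames)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = _rmsd(frames[i], frames[j], fit=fit)
    if ensemble.source_labels is not None:
        labels, counters = [], {}
        for src in ensemble.source_labels:
            idx = counters.get(src, 0)
            counters[src] = idx + 1
            labels.append((src, idx))
    else:
        labels = [("0", i) for i in range(n)]
    return DistanceMatrix(values=values, frame_labels=tuple(labels))


def _init_medoids(d: np.ndarray, k: int, rng: np.random.Generator) -> list[int]:
    """k-medoids++ style seeding: spread initial medoids apart."""
    n = d.shape[0]
    medoids = [int(rng.integers(n))]
    while len(medoids) < k:
        dist_to_nearest = d[:, medoids].min(axis=1)
        dist_to_nearest[medoids] = 0.0
        total = dist_to_nearest.sum()
        if total <= 0:  # all remaining frames coincide with a medoid
            choices = [i for i in range(n) if i not in medoids]
            medoids.append(int(choices[rng.integers(len(choices))]))
            continue
        probs = dist_to_nearest**2
        probs /= probs.sum()
        medoids.append(int(rng.choice(n, p=probs)))
    return medoids


def _n_subsets(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


def _finalize(d: np.ndarray, medoids: list[int]) -> ClusterModel:
    labels = np.argmin(d[:, medoids], axis=1)
    for cid, m in enumerate(medoids):
        labels[m] = cid
    n = d.shape[0]
    populations = tuple(float(np.sum(labels == cid)) / n for cid in range(len(medoids)))
    return ClusterModel(
        k=len(medoids), labels=labels,
        medoid_indices=tuple(int(m) for m in medoids), populations=populations,
    )


def _exhaustive_medoids(dm: DistanceMatrix, k: int) -> ClusterModel:
    from itertools import combinations

    d = dm.values
    best, best_obj = None, np.inf
    for subset in combinations(range(dm.n), k):
        obj = float(d[:, subset].min(axis=1).sum())
        if obj < best_obj - 1e-12:
            best, best_obj = subset, obj
    return _finalize(d, list(best))


def cluster_medoids(
    dm: DistanceMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    exact_below: int = 2000,
) -> ClusterModel:
    """PAM-style k-medoids on a precomputed dissimilarity matrix.

    Seeded k-medoids++ initialization, then alternating assignment (nearest
    medoid, ties to the lowest cluster id) and medoid update (member with
    minimal summed within-cluster dissimilarity, ties to the lowest frame
    index) until the labels stop changing. Deterministic for a fixed seed.
    Problems with at most ``exact_below`` candidate medoid subsets are
    solved exactly by enumeration instead (globally optimal objective).
    """
    n = dm.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    d = dm.values
    if _n_subsets(n, k) <= exact_below:
        return _exhaustive_medoids(dm, k)
    rng = np.random.default_rng(seed)
    medoids = _init_medoids(d, k, rng)
    labels = np.argmin(d[:, medoids], axis=1)
    for _ in range(max_iter):
        for cid in range(k):
            members = np.flatnonzero(labels == cid)
            if len(members) == 0:
                # re-seed an empty cluster on the frame farthest from any medoid
                far = int(np.argmax(d[:, medoids].min(axis=1)))
                medoids[cid] = far
                continue
            within = d[np.ix_(members, members)].sum(axis=1)
            medoids[cid] = int(members[np.argmin(within)])
        new_labels = np.argmin(d[:, medoids], axis=1)
        # keep each medoid in its own cluster even under distance ties
        for cid, m in enumerate(medoids):
            new_labels[m] = cid
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    populations = tuple(float(np.sum(labels == cid)) / n for cid in range(k))
    return ClusterModel(
        k=k, labels=labels, medoid_indices=tuple(int(m) for m in medoids),
        populations=populations,
    )


def select_k(
    dm: DistanceMatrix,
    k_max: int = 10,
    seed: int = 0,
    weak_threshold: float = 0.25,
) -> int:
    """Pick k in [2, k_max] by best mean silhouette (ties -> smaller k).

    A best silhouette below ``weak_threshold`` triggers a "weak structure"
    warning: the data do not support clear clusters and the returned k is a
    formality.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if dm.n < 3:
        raise ValueError("need at least 3 frames to choose k")
    best_k, best_score = 2, -np.inf
    for k in range(2, min(k_max, dm.n - 1) + 1):
        model = cluster_medoids(dm, k, seed=seed)
        if len(set(model.labels.tolist())) < 2:
            continue
        score = float(
            silhouette_score(dm.values, model.labels, metric="precomputed")
        )
        if score > best_score + 1e-12:
            best_k, best_score = k, score
    if best_score < weak_threshold:
        warnings.warn(
            f"weak structure: best silhouette {best_score:.3f} at k={best_k}",
            stacklevel=2,
        )
    return best_k


def transition_graph(model: ClusterModel, frame_labels) -> TransitionGraph:
    """Count same-trajectory transitions between consecutive frames.

    For each trajectory independently, consecutive frames with differing
    cluster ids increment ``counts[from, to]``; frame pairs spanning a
    trajectory boundary contribute nothing, so no artificial transitions
    between runs are created.
    """
    frame_labels = tuple(frame_labels)
    if len(frame_labels) != len(model.labels):
        raise ValueError("frame_labels must align with cluster labels")
    counts = np.zeros((model.k, model.k), dtype=int)
    by_traj: dict[str, list[tuple[int, int]]] = {}
    for i, (traj, idx) in enumerate(frame_labels):
        by_traj.setdefault(traj, []).append((idx, i))
    for frames in by_traj.values():
        frames.sort()
        for (ia, a), (ib, b) in zip(frames, frames[1:]):
            ca, cb = int(model.labels[a]), int(model.labels[b])
            if ca != cb:
                counts[ca, cb] += 1
    connectivity = {
        frozenset((i, j))
        for i in range(model.k)
        for j in range(model.k)
        if i != j and (counts[i, j] or counts[j, i])
    }
    return TransitionGraph(counts=counts, connectivity=connectivity)


def isolated_clusters(graph: TransitionGraph) -> list[int]:
    """Cluster ids linked to at most one other cluster in the transition graph."""
    g = graph.to_networkx()
    return sorted(node for node in g.nodes if g.degree(node) <= 1)
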