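"""Conformational clustering: k-hybrid microstates, Ward macrostates, k-NN
cross-motor state assignment.

The microstate definition follows the k-hybrid scheme: a k-centers pass adds
centers (farthest-point style) until every frame lies within a fixed cluster
radius of some center, followed by rounds of k-medoids refinement that
propose random in-cluster medoid swaps and keep those that lower the total
within-cluster distance.  Macrostates are formed by Ward agglomeration of
microstate representatives, and conformations of other systems are assigned
to the macrostates of a reference system by majority vote of their k nearest
labeled neighbors (k = 5; results are insensitive for k in 3..15 on
well-separated states).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist


@dataclass
class Clustering:
    """Result of microstate clustering.

    center_indices are frame indices (into the pooled feature array) of the
    medoids; assignments give each frame's nearest-center index.
    """

    center_indices: np.ndarray
    assignments: np.ndarray
    distances: np.ndarray
    cluster_radius: float
    n_states: int

    @property
    def total_distance(self) -> float:
        return float(self.distances.sum())


@dataclass
class MacroMapping:
    """Total map from microstate index to macrostate label (A–E)."""

    micro_to_macro: np.ndarray  # array of labels, len == n_micro
    labels: tuple = ("A", "B", "C", "D", "E")

    def __post_init__(self):
        self.micro_to_macro = np.asarray(self.micro_to_macro)

    @property
    def n_macro(self) -> int:
        return len(self.labels)

    def label_index(self, label) -> int:
        return self.labels.index(label)

    def macro_indices(self) -> np.ndarray:
        """micro→macro as integer indices into ``labels``."""
        lut = {lab: i for i, lab in enumerate(self.labels)}
        return np.array([lut[m] for m in self.micro_to_macro], dtype=np.int64)

    def apply(self, micro_assignments: np.ndarray) -> np.ndarray:
        """Map a frame-level microstate sequence to macrostate indices."""
        micro_assignments = np.asarray(micro_assignments, dtype=np.int64)
        if micro_assignments.max(initial=-1) >= len(self.micro_to_macro):
            raise ValueError("assignment refers to a microstate outside the mapping")
        return self.macro_indices()[micro_assignments]


def _assign(X: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = cdist(X, centers)
    a = d.argmin(axis=1)
    return a, d[np.arange(len(X)), a]


def khybrid(features: np.ndarray, cluster_radius: float, n_medoid_rounds: int = 5,
            seed: int = 0) -> Clustering:
    """k-hybrid clustering: k-centers to a radius, then k-medoids refinement.

    Parameters
    ----------
    features : (n_frames, d) array
        Pooled feature vectors (Euclidean metric).
    cluster_radius : float
        k-centers stops once every frame is within this distance of a center.
    n_medoid_rounds : int
        Rounds of seeded random medoid-swap proposals (one proposal per
        cluster per round), accepted when total within-cluster distance drops.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("features must be a non-empty (n_frames, d) array")
    if not cluster_radius > 0:
        raise ValueError("cluster_radius must be positive")
    rng = np.random.default_rng(seed)

    # k-centers pass: first center is frame 0, then repeatedly promote the
    # frame farthest from its current center.
    center_idx = [0]
    dist = np.linalg.norm(X - X[0], axis=1)
    assign = np.zeros(len(X), dtype=np.int64)
    while dist.max() > cluster_radius:
        new = int(dist.argmax())
        center_idx.append(new)
        d_new = np.linalg.norm(X - X[new], axis=1)
        closer = d_new < dist
        assign[closer] = len(center_idx) - 1
        dist[closer] = d_new[closer]

    center_idx = np.array(center_idx, dtype=np.int64)
    # Full distance-to-center matrix kept for cheap swap evaluation.
    D = cdist(X, X[center_idx])
    assign = D.argmin(axis=1)
    dist = D[np.arange(len(X)), assign]
    total = dist.sum()

    for _ in range(n_medoid_rounds):
        for c in range(len(center_idx)):
            members = np.flatnonzero(assign == c)
            if len(members) <= 1:
                continue
            cand = int(rng.choice(members))
            if cand == center_idx[c]:
                continue
            D_trial = D.copy()
            D_trial[:, c] = np.linalg.norm(X - X[cand], axis=1)
            trial_assign = D_trial.argmin(axis=1)
            trial_total = D_trial[np.arange(len(X)), trial_assign].sum()
            if trial_total < total:
                center_idx[c] = cand
                D = D_trial
                assign = trial_assign
                total = trial_total
    dist = D[np.arange(len(X)), assign]
    return Clustering(center_indices=center_idx, assignments=assign,
                      distances=dist, cluster_radius=float(cluster_radius),
                      n_states=len(center_idx))


def split_assignments(assignments: np.ndarray, lengths) -> list[np.ndarray]:
    """Split a pooled assignment vector back into per-trajectory sequences."""
    out = []
    start = 0
    for n in lengths:
        out.append(np.asarray(assignments[start:start + n]))
        start += n
    if start != len(assignments):
        raise ValueError("lengths do not sum to the number of assignments")
    return out


def ward_cluster(points: np.ndarray, n_clusters: int = 5) -> np.ndarray:
    """Ward-linkage agglomerative clustering (Euclidean metric).

    Points are recursively merged minimizing the within-cluster variance
    increase until ``n_clusters`` remain.  Labels are renumbered by order of
    first appearance so the result is deterministic for a given input order.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if n_clusters > len(points):
        raise ValueError(f"n_clusters={n_clusters} exceeds n_points={len(points)}")
    if n_clusters == len(points):
        return np.arange(len(points))
    Z = linkage(points, method="ward")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    relabel, labels = {}, np.empty(len(raw), dtype=np.int64)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel)
        labels[i] = relabel[r]
    return labels


def knn_assign(labeled_points: np.ndarray, labels: np.ndarray,
               queries: np.ndarray, k: int = 5) -> np.ndarray:
    """Assign each query the majority label among its k nearest labeled points.

    Ties are broken in favor of the tied label whose member is nearest to the
    query.  Exhaustive Euclidean search (the contract is the result, not the
    speed).
    """
    L = np.atleast_2d(np.asarray(labeled_points, dtype=float))
    Q = np.atleast_2d(np.asarray(queries, dtype=float))
    labels = np.asarray(labels)
    if len(L) == 0:
        raise ValueError("empty labeled set")
    if k > len(L):
        raise ValueError(f"k={k} exceeds number of labeled points {len(L)}")
    D = cdist(Q, L)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    out = np.empty(len(Q), dtype=labels.dtype)
    for qi in range(len(Q)):
        neigh = labels[order[qi]]
        uniq, counts = np.unique(neigh, return_counts=True)
        best = counts.max()
        tied = set(uniq[counts == best])
        if len(tied) == 1:
            out[qi] = next(iter(tied))
        else:
            for lab in neigh:  # neighbors in distance order; first tied wins
                if lab in tied:
                    out[qi] = lab
                    break
    return out
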