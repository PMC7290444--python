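"""k-means partitioning of the SOM codebook and cluster-count selection.

The 100 trained prototype vectors are clustered with Lloyd's algorithm
(k-means++ seeding, multiple restarts), the unit labels are painted onto
the 10x10 grid, and each limb inherits the label of its best matching unit.
The number of clusters is chosen by a sensitivity analysis over a k range:
for each k the codebook is re-clustered and the mean silhouette of the
codebook vectors is recorded; the chosen k maximizes the silhouette, with
the within-cluster inertia curve reported alongside as elbow diagnostics.

Cluster labels are arbitrary up to permutation; comparisons against ground
truth should use the adjusted Rand index.  For reporting, labels can be
canonicalized so that cluster 0 is the one richest in typically developing
limbs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import silhouette_score

from .scores import GVSVector, gvs_matrix
from .som import SOMModel, bmu_batch


@dataclass
class ClusterModel:
    k: int
    labels: np.ndarray  # cluster index per clustered point (codebook unit)
    centroids: np.ndarray  # (k, n_features)
    inertia: float
    seed: int
    n_init: int

    def __post_init__(self) -> None:
        if self.inertia < 0:
            raise ValueError("inertia must be non-negative")
        present = np.unique(self.labels)
        if present.min() < 0 or present.max() >= self.k or len(present) != self.k:
            raise ValueError("every cluster must be non-empty with labels in 0..k-1")


def _kmeans_pp_seeds(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = points.shape[0]
    centers = np.empty((k, points.shape[1]))
    centers[0] = points[rng.integers(n)]
    d2 = np.sum((points - centers[0]) ** 2, axis=1)
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[i] = points[rng.integers(n)]
            continue
        probs = d2 / total
        centers[i] = points[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((points - centers[i]) ** 2, axis=1))
    return centers


def _assign(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d2 = (
        np.sum(centers**2, axis=1)[None, :]
        - 2.0 * points @ centers.T
        + np.sum(points**2, axis=1)[:, None]
    )
    return np.argmin(d2, axis=1)


def _inertia(points: np.ndarray, centers: np.ndarray, labels: np.ndarray) -> float:
    return float(np.sum((points - centers[labels]) ** 2))


def _lloyd(points: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int = 300) -> tuple[np.ndarray, np.ndarray, float]:
    centers = _kmeans_pp_seeds(points, k, rng)
    labels = _assign(points, centers)
    prev_inertia = np.inf
    for _ in range(max_iter):
        for j in range(k):
            mask = labels == j
            if np.any(mask):
                centers[j] = points[mask].mean(axis=0)
            else:
                # empty-cluster repair: re-seed at the point farthest from
                # its current centroid
                far = np.argmax(np.sum((points - centers[labels]) ** 2, axis=1))
                centers[j] = points[far]
        new_labels = _assign(points, centers)
        inertia = _inertia(points, centers, new_labels)
        # Lloyd monotonicity: inertia never increases between iterations
        assert inertia <= prev_inertia + 1e-9, "inertia increased during Lloyd"
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
        prev_inertia = inertia
    return labels, centers, _inertia(points, centers, labels)


def kmeans(points: np.ndarray, k: int, seed: int = 0, n_init: int = 10) -> ClusterModel:
    """Lloyd's algorithm with k-means++ seeding and ``n_init`` restarts."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be 2-D")
    m = points.shape[0]
    if k < 1:
        raise ValueError("k must be positive")
    if k > m:
        raise ValueError(f"k={k} exceeds number of points m={m}")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_init):
        labels, centers, inertia = _lloyd(points, k, rng)
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia)
    labels, centers, inertia = best
    return ClusterModel(
        k=k, labels=labels, centroids=centers, inertia=inertia, seed=seed, n_init=n_init
    )


def cluster_som(model: SOMModel, k: int, seed: int = 0,
                n_init: int = 10) -> tuple[ClusterModel, np.ndarray]:
    """k-means over the (unweighted) codebook; labels arranged on the grid."""
    cm = kmeans(model.codebook, k, seed=seed, n_init=n_init)
    grid = cm.labels.reshape(model.config.grid_rows, model.config.grid_cols)
    return cm, grid


def assign_limbs(som: SOMModel, clusters: ClusterModel,
                 gvs: Iterable[GVSVector]) -> dict[str, tuple[int, int]]:
    """Each limb's (BMU unit index, cluster label) via its normalized GVS."""
    vectors = list(gvs)
    if not vectors:
        return {}
    z = som.normalize(gvs_matrix(vectors))
    units = bmu_batch(som, z)
    return {
        v.limb_id: (int(u), int(clusters.labels[u])) for v, u in zip(vectors, units)
    }


def select_k(som: SOMModel, k_range: Sequence[int] = range(2, 11), seed: int = 0,
             n_init: int = 10) -> tuple[int, list[dict]]:
    """Sensitivity analysis for the number of clusters.

    For each candidate k, the codebook is clustered and the mean silhouette
    of the codebook vectors plus the inertia (elbow diagnostic) is recorded.
    Returns (k maximizing the silhouette, per-k diagnostics); ties go to the
    smaller k.  A collapsed (constant) codebook has no defined silhouette
    and raises.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > som.n_units:
        raise ValueError("k_range must lie within [2, number of units]")
    if np.allclose(som.codebook, som.codebook[0]):
        raise ValueError("degenerate map: codebook collapsed to a single point")
    diagnostics = []
    for k in ks:
        cm, _ = cluster_som(som, k, seed=seed, n_init=n_init)
        sil = float(silhouette_score(som.codebook, cm.labels))
        diagnostics.append({"k": k, "inertia": cm.inertia, "silhouette": sil})
    best = max(diagnostics, key=lambda d: (d["silhouette"], -d["k"]))
    return int(best["k"]), diagnostics


def canonicalize_labels(limb_clusters: Mapping[str, int],
                        td_limb_ids: Iterable[str], k: int) -> dict[int, int]:
    """Relabeling that orders clusters by descending TD-limb fraction.

    Returns old-label -> new-label, so the TD-dominated cluster reports as
    group 0.  Ties break on cluster size then old label for determinism.
    """
    td = set(td_limb_ids)
    n_total = np.zeros(k, dtype=int)
    n_td = np.zeros(k, dtype=int)
    for limb, lab in limb_clusters.items():
        n_total[lab] += 1
        n_td[lab] += limb in td
    frac = np.where(n_total > 0, n_td / np.maximum(n_total, 1), 0.0)
    order = sorted(range(k), key=lambda j: (-frac[j], -n_total[j], j))
    return {old: new for new, old in enumerate(order)}
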