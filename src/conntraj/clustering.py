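"""Recovery-trajectory phenotyping: agglomerative clustering, silhouette K.

Patients are clustered per scale on their raw (unstandardized) 4-timepoint
score vectors — all four entries share that scale's units — using pairwise
Euclidean distances and agglomerative hierarchical linkage. The number of
clusters is chosen by the mean silhouette coefficient over tree cuts at
K = 2..min(10, n-1), with ties broken toward the smallest K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .cohort import TIMEPOINTS

LINKAGES = ("ward", "average", "complete")


class DegenerateDataError(ValueError):
    """All trajectories identical: clustering is undefined."""


@dataclass
class ClusterSolution:
    scale: str
    linkage_matrix: np.ndarray
    k_selected: int
    labels: pd.Series  # subject -> 1..K, contiguous
    silhouette_by_k: dict[int, float]
    linkage: str = "ward"

    @property
    def n_subjects(self) -> int:
        return len(self.labels)


def _as_feature_matrix(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        missing = [c for c in TIMEPOINTS if c not in features.columns]
        if missing:
            raise ValueError(f"feature table lacks timepoints {missing}")
        X = features[list(TIMEPOINTS)].to_numpy(dtype=float)
        subjects = [str(s) for s in features.index]
    else:
        X = np.asarray(features, dtype=float)
        subjects = [str(i) for i in range(len(X))]
    if X.ndim != 2:
        raise ValueError("features must be 2-D")
    if np.isnan(X).any():
        raise ValueError("features contain missing values")
    return X, subjects


def pairwise_distances(features) -> np.ndarray:
    """Euclidean distance matrix on raw trajectory vectors."""
    X, _ = _as_feature_matrix(features)
    if len(X) < 2:
        raise ValueError("need at least 2 subjects")
    return squareform(pdist(X, metric="euclidean"))


def agglomerate(distances: np.ndarray, linkage: str = "ward") -> np.ndarray:
    """Agglomerative merge history (scipy linkage matrix) from a distance
    matrix. Ward linkage assumes the distances are Euclidean, which holds
    for trajectory features by construction."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    distances = np.asarray(distances, dtype=float)
    if distances.ndim == 2:
        if distances.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        condensed = squareform(distances, checks=True)
    else:
        condensed = distances
    return hierarchy.linkage(condensed, method=linkage)


def cut_tree(linkage_matrix: np.ndarray, k: int) -> np.ndarray:
    """Partition into (at most) k clusters; labels relabeled 1..K by order
    of first appearance so output is deterministic and contiguous."""
    raw = hierarchy.fcluster(linkage_matrix, t=k, criterion="maxclust")
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for idx, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[idx] = mapping[lab]
    return out


def silhouette(labels, distances: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean and per-point silhouette values.

    s(i) = (b - a) / max(a, b) with a the mean within-cluster distance and b
    the smallest mean distance to another cluster; points in singleton
    clusters contribute 0 by convention. Requires at least two clusters.
    """
    labels = np.asarray(labels)
    distances = np.asarray(distances, dtype=float)
    n = len(labels)
    if distances.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    svals = np.zeros(n)
    for i in range(n):
        own = labels[i]
        same = (labels == own)
        m = same.sum()
        if m == 1:
            svals[i] = 0.0
            continue
        a = distances[i, same].sum() / (m - 1)
        b = min(distances[i, labels == other].mean() for other in uniq if other != own)
        denom = max(a, b)
        svals[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(svals.mean()), svals


def cluster_trajectories(
    features, scale: str = "", k_range: range | None = None,
    linkage: str = "ward",
) -> ClusterSolution:
    """Cluster one scale's trajectories and pick K by mean silhouette.

    ``k_range`` defaults to 2..min(10, n-1); cuts that collapse to fewer
    distinct clusters than requested are skipped. Ties in silhouette go to
    the smallest K. Fully deterministic.
    """
    X, subjects = _as_feature_matrix(features)
    n = len(X)
    if n < 3:
        raise ValueError("need at least 3 subjects to select K")
    dist = pairwise_distances(X)
    if np.allclose(dist, 0):
        raise DegenerateDataError("all trajectories identical")
    Z = agglomerate(dist, linkage)
    if k_range is None:
        k_range = range(2, min(10, n - 1) + 1)

    sil_by_k: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        if not 2 <= k <= n - 1:
            continue
        labs = cut_tree(Z, k)
        if len(np.unique(labs)) < 2:
            continue
        mean_s, _ = silhouette(labs, dist)
        sil_by_k[k] = mean_s
        labels_by_k[k] = labs
    if not sil_by_k:
        raise DegenerateDataError("no valid cut in the requested K range")

    best_k = min(
        (k for k in sil_by_k),
        key=lambda k: (-sil_by_k[k], k),
    )
    labels = pd.Series(labels_by_k[best_k], index=pd.Index(subjects, name="subject_id"),
                       name="cluster")
    return ClusterSolution(
        scale=scale, linkage_matrix=Z, k_selected=int(best_k),
        labels=labels, silhouette_by_k=sil_by_k, linkage=linkage,
    )
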