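"""Twice-clustering of pooled WQCP samples into connectome patterns.

K-means is sensitive to its random initialisation; the twice-clustering
scheme removes that randomness by fixing the initial centers with
agglomerative (Ward) hierarchical clustering and then refining them with
plain Lloyd iterations.  The number of patterns K is chosen by minimising
the Davies-Bouldin index over a candidate range, rerunning the full
twice-clustering at each K.  Each resulting cluster of WQCP samples is a
dynamic functional connectome pattern (DFCP); its centroid connectivity
matrix is the mean of every window-level dFC matrix whose parent segment
was assigned to the cluster.

The entire procedure is deterministic given its input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from sklearn.metrics import davies_bouldin_score

from .core import DfcTensor
from .segmentation import SegmentSet, WqcpSample

logger = logging.getLogger(__name__)

__all__ = [
    "TwiceClusteringResult",
    "DfcpCentroid",
    "RatioDistribution",
    "hierarchical_init",
    "kmeans_refine",
    "select_k_davies_bouldin",
    "twice_cluster",
    "compute_dfcp_centroids",
    "ratio_distributions",
]


@dataclass
class TwiceClusteringResult:
    """Fitted clustering of the pooled WQCP dataset.

    ``labels`` are 1-based cluster ids (1..K) per sample; ``db_curve`` maps
    each candidate K to its Davies-Bouldin index (populated by
    :func:`select_k_davies_bouldin`).
    """

    k: int
    labels: np.ndarray
    init_centers: np.ndarray
    final_centers: np.ndarray
    inertia: float
    n_iter: int
    db_curve: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = np.bincount(self.labels, minlength=self.k + 1)[1:]
        if (counts == 0).any():
            raise ValueError("every cluster must be non-empty")


@dataclass
class DfcpCentroid:
    """Mean dFC matrix of one pattern within one group scope.

    ``scope`` is a group label or ``"pooled"``; ``matrix`` is the average of
    the ``n_windows_averaged`` window-level dFC matrices belonging to the
    cluster within that scope, or None if the scope contributed no windows.
    """

    cluster: int
    scope: str
    matrix: np.ndarray | None
    n_windows_averaged: int

    @property
    def absent(self) -> bool:
        return self.matrix is None


@dataclass
class RatioDistribution:
    """Per-subject occupancy ratios over patterns.

    ``ratios`` has shape (n_subjects, K); row s gives the fraction of
    subject s's WQCP samples assigned to each cluster (rows sum to 1).
    """

    subject_ids: list[str]
    groups: list[str]
    ratios: np.ndarray

    @property
    def k(self) -> int:
        return self.ratios.shape[1]


# ---------------------------------------------------------------------------
# Clustering stages


def hierarchical_init(wqcp_matrix: np.ndarray, k: int) -> np.ndarray:
    """Initial cluster centers from Ward-linkage agglomerative clustering.

    The dendrogram is cut at ``k`` clusters and each cluster's mean is an
    initial center.  Deterministic.
    """
    x = np.asarray(wqcp_matrix, dtype=float)
    n = x.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} outside [1, n_samples={n}]")
    if k == n:
        return x.copy()
    z = linkage(x, method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    return np.vstack([x[labels == c].mean(axis=0) for c in range(1, k + 1)])


def _cut_tree_centers(x: np.ndarray, z: np.ndarray, k: int) -> np.ndarray:
    labels = fcluster(z, t=k, criterion="maxclust")
    return np.vstack([x[labels == c].mean(axis=0) for c in range(1, k + 1)])


def kmeans_refine(
    wqcp_matrix: np.ndarray,
    init_centers: np.ndarray,
    max_iter: int = 300,
) -> TwiceClusteringResult:
    """Lloyd iterations from fixed initial centers (no restarts).

    Runs until the assignment reaches a fixpoint or ``max_iter`` iterations;
    the within-cluster sum of squares (inertia) is asserted non-increasing
    across iterations.  A cluster that empties is reseeded with the sample
    farthest from its assigned center (logged).
    """
    x = np.asarray(wqcp_matrix, dtype=float)
    centers = np.asarray(init_centers, dtype=float).copy()
    if not np.isfinite(centers).all():
        raise ValueError("initial centers must be finite")
    k = centers.shape[0]
    prev_inertia = np.inf
    labels = None
    for it in range(1, max_iter + 1):
        d2 = cdist(x, centers, metric="sqeuclidean")
        new_labels = d2.argmin(axis=1)
        # repair empty clusters with the farthest sample
        for c in range(k):
            if not (new_labels == c).any():
                far = d2[np.arange(x.shape[0]), new_labels].argmax()
                logger.info("empty cluster %d reseeded with sample %d", c + 1, far)
                centers[c] = x[far]
                d2[:, c] = ((x - centers[c]) ** 2).sum(axis=1)
                new_labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(x.shape[0]), new_labels].sum())
        if inertia > prev_inertia + 1e-8 * max(1.0, prev_inertia):
            raise AssertionError("k-means inertia increased")
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        prev_inertia = inertia
        centers = np.vstack([x[labels == c].mean(axis=0) for c in range(k)])
    # final inertia with updated centers
    d2 = cdist(x, centers, metric="sqeuclidean")
    inertia = float(d2[np.arange(x.shape[0]), d2.argmin(axis=1)].sum())
    return TwiceClusteringResult(
        k=k,
        labels=labels + 1,
        init_centers=np.asarray(init_centers, dtype=float),
        final_centers=centers,
        inertia=inertia,
        n_iter=it,
    )


def twice_cluster(wqcp_matrix: np.ndarray, k: int) -> TwiceClusteringResult:
    """Hierarchical initialisation followed by K-means refinement at fixed K."""
    return kmeans_refine(wqcp_matrix, hierarchical_init(wqcp_matrix, k))


def select_k_davies_bouldin(
    wqcp_matrix: np.ndarray,
    k_range: tuple[int, int] = (2, 30),
) -> TwiceClusteringResult:
    """Choose K by minimising the Davies-Bouldin index.

    For each K in ``k_range`` (inclusive) the full twice-clustering is rerun
    and its Davies-Bouldin index computed (mean over clusters of the worst
    (s_i + s_j) / d_ij ratio, s = mean within-cluster centroid distance,
    d = centroid separation; lower is better).  Ties break toward the
    smallest K.  Returns the winning model with ``db_curve`` filled in.
    """
    x = np.asarray(wqcp_matrix, dtype=float)
    n = x.shape[0]
    k_lo, k_hi = int(k_range[0]), int(k_range[1])
    if k_lo < 2:
        raise ValueError("k_range must start at 2 or above")
    k_hi = min(k_hi, n - 1)
    if k_hi < k_lo:
        raise ValueError(f"k_range {k_range} infeasible for {n} samples")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate input: all WQCP samples identical")
    z = linkage(x, method="ward")  # one tree, cut per K
    db_curve: dict[int, float] = {}
    models: dict[int, TwiceClusteringResult] = {}
    for k in range(k_lo, k_hi + 1):
        model = kmeans_refine(x, _cut_tree_centers(x, z, k))
        db_curve[k] = float(davies_bouldin_score(x, model.labels))
        models[k] = model
    best_k = min(db_curve, key=lambda k: (db_curve[k], k))
    best = models[best_k]
    best.db_curve = db_curve
    return best


# ---------------------------------------------------------------------------
# Centroids and occupancy ratios


def compute_dfcp_centroids(
    result: TwiceClusteringResult,
    samples: list[WqcpSample],
    tensors: dict[str, DfcTensor],
) -> list[DfcpCentroid]:
    """Average the window-level dFC matrices behind each cluster.

    Every window whose parent segment's WQCP carries cluster label c
    contributes to cluster c's centroid, within each group scope and pooled.
    The pooled centroid equals the window-count-weighted combination of the
    group centroids.  A (cluster, scope) pair with zero windows is flagged
    absent rather than zero-filled.
    """
    if len(samples) != result.labels.size:
        raise ValueError("labels and samples misaligned")
    groups = sorted({s.group for s in samples})
    some_tensor = next(iter(tensors.values()))
    n_roi = some_tensor.n_roi
    sums: dict[tuple[int, str], np.ndarray] = {}
    counts: dict[tuple[int, str], int] = {}
    for samp, label in zip(samples, result.labels):
        if samp.subject_id not in tensors:
            raise KeyError(f"no dFC tensor for subject {samp.subject_id}")
        block = tensors[samp.subject_id].matrices[samp.start : samp.stop]
        key = (int(label), samp.group)
        if key not in sums:
            sums[key] = np.zeros((n_roi, n_roi))
            counts[key] = 0
        sums[key] += block.sum(axis=0)
        counts[key] += block.shape[0]
    out: list[DfcpCentroid] = []
    for c in range(1, result.k + 1):
        pooled_sum = np.zeros((n_roi, n_roi))
        pooled_n = 0
        for g in groups:
            key = (c, g)
            n = counts.get(key, 0)
            mat = sums[key] / n if n else None
            out.append(DfcpCentroid(cluster=c, scope=g, matrix=mat, n_windows_averaged=n))
            if n:
                pooled_sum += sums[key]
                pooled_n += n
        out.append(
            DfcpCentroid(
                cluster=c,
                scope="pooled",
                matrix=pooled_sum / pooled_n if pooled_n else None,
                n_windows_averaged=pooled_n,
            )
        )
    return out


def ratio_distributions(
    result: TwiceClusteringResult, samples: list[WqcpSample]
) -> RatioDistribution:
    """Per-subject occupancy ratio of each pattern.

    ratio(subject, c) = (# of the subject's WQCP samples labelled c) /
    (subject's total samples); samples are counted equally, not weighted by
    segment length.
    """
    if len(samples) != result.labels.size:
        raise ValueError("labels and samples misaligned")
    order: list[str] = []
    group_of: dict[str, str] = {}
    for s in samples:
        if s.subject_id not in group_of:
            order.append(s.subject_id)
            group_of[s.subject_id] = s.group
    idx = {sid: i for i, sid in enumerate(order)}
    counts = np.zeros((len(order), result.k))
    for samp, label in zip(samples, result.labels):
        counts[idx[samp.subject_id], int(label) - 1] += 1
    totals = counts.sum(axis=1, keepdims=True)
    return RatioDistribution(
        subject_ids=order,
        groups=[group_of[s] for s in order],
        ratios=counts / totals,
    )
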