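"""Hub detection on centroid connectivity matrices.

A weighted centroid matrix is binarised at a grid of proportional
thresholds (densities 10%..40% by default): at density d, the top
round(d * n_edges) edges by absolute weight are kept.  Two local metrics
are computed per node on each binary graph — degree k and participation
coefficient P = 1 - sum_s (k_is / k_i)^2 over community modules s — and
integrated over the density grid by the trapezoid rule (AUC), removing the
arbitrariness of any single threshold.  Critical ROIs are nodes whose
degree AUC *and* participation AUC both exceed the across-node mean by more
than one (sample) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "ThresholdedGraph",
    "MetricTable",
    "CriticalRoiSet",
    "DEFAULT_DENSITY_GRID",
    "proportional_threshold",
    "degree",
    "modularity_partition",
    "participation_coefficient",
    "metric_auc",
    "compute_metric_table",
    "select_critical_rois",
]

DEFAULT_DENSITY_GRID = np.round(np.arange(0.10, 0.401, 0.01), 2)


@dataclass
class ThresholdedGraph:
    """Binary graph retaining a fixed fraction of the strongest edges."""

    density: float
    adjacency: np.ndarray
    source: str = ""

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class MetricTable:
    """Per-node degree and participation across the density grid plus AUCs.

    ``degree`` and ``participation`` have shape (n_nodes, n_densities);
    ``auc_degree`` / ``auc_participation`` are per-node scalars.
    """

    densities: np.ndarray
    degree: np.ndarray
    participation: np.ndarray
    auc_degree: np.ndarray
    auc_participation: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        n = self.degree.shape[0]
        df = pd.DataFrame({"roi": np.arange(1, n + 1)})
        for j, d in enumerate(self.densities):
            df[f"k_{d:.2f}"] = self.degree[:, j]
            df[f"p_{d:.2f}"] = self.participation[:, j]
        df["auc_k"] = self.auc_degree
        df["auc_p"] = self.auc_participation
        return df


@dataclass
class CriticalRoiSet:
    """Hub selection: 1-based ROI indices whose AUC exceeds mean + 1 SD,
    per metric, and their intersection."""

    by_degree: list[int]
    by_participation: list[int]
    intersection: list[int]
    stats: dict[str, float]


# ---------------------------------------------------------------------------


def proportional_threshold(
    matrix: np.ndarray, density: float, source: str = ""
) -> ThresholdedGraph:
    """Binarise a symmetric zero-diagonal weight matrix at a target density.

    Keeps the top round(density * n_edges) edges ranked by |weight|
    descending; ties at the cutoff break by ascending (i, j) edge index so
    the result is deterministic.
    """
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if m.shape != (n, n):
        raise ValueError("matrix must be square")
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    iu = np.triu_indices(n, k=1)
    weights = np.abs(m[iu])
    n_edges_total = weights.size
    n_keep = int(round(density * n_edges_total))
    if n_keep == 0:
        raise ValueError(f"density {density} retains 0 of {n_edges_total} edges")
    # stable sort on -|w| keeps ascending lexicographic order among ties
    order = np.argsort(-weights, kind="stable")
    keep = order[:n_keep]
    adj = np.zeros((n, n), dtype=int)
    adj[iu[0][keep], iu[1][keep]] = 1
    adj |= adj.T
    return ThresholdedGraph(density=density, adjacency=adj, source=source)


def degree(graph: ThresholdedGraph | np.ndarray) -> np.ndarray:
    """Per-node degree: row sums of the binary adjacency."""
    adj = graph.adjacency if isinstance(graph, ThresholdedGraph) else np.asarray(graph)
    return adj.sum(axis=1)


def modularity_partition(graph: ThresholdedGraph | np.ndarray) -> np.ndarray:
    """Community module per node by greedy modularity maximisation.

    Isolated nodes each get their own module.  Returns 0-based module ids.
    """
    adj = graph.adjacency if isinstance(graph, ThresholdedGraph) else np.asarray(graph)
    g = nx.from_numpy_array(adj)
    communities = nx.algorithms.community.greedy_modularity_communities(g)
    modules = np.empty(adj.shape[0], dtype=int)
    for mid, nodes in enumerate(communities):
        for node in nodes:
            modules[node] = mid
    return modules


def participation_coefficient(
    graph: ThresholdedGraph | np.ndarray, modules: np.ndarray
) -> np.ndarray:
    """P_i = 1 - sum_s (k_is / k_i)^2; 0 for isolated nodes.

    ``modules`` assigns every node to a community; a node whose edges all
    stay in its own module scores 0, one spreading edges evenly over many
    modules approaches 1.
    """
    adj = graph.adjacency if isinstance(graph, ThresholdedGraph) else np.asarray(graph)
    modules = np.asarray(modules)
    n = adj.shape[0]
    if modules.shape != (n,):
        raise ValueError("module partition must cover all nodes")
    k = adj.sum(axis=1).astype(float)
    uniq = np.unique(modules)
    k_is = np.zeros((n, uniq.size))
    for s, mod in enumerate(uniq):
        k_is[:, s] = adj[:, modules == mod].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = k_is / k[:, None]
        p = 1.0 - (frac**2).sum(axis=1)
    p[k == 0] = 0.0
    return p


def metric_auc(values: np.ndarray, densities: np.ndarray) -> np.ndarray:
    """Trapezoidal integral of a per-node metric over the density grid."""
    densities = np.asarray(densities, dtype=float)
    values = np.asarray(values, dtype=float)
    if densities.size < 2 or np.any(np.diff(densities) <= 0):
        raise ValueError("density grid must be strictly increasing with >= 2 points")
    if not np.isfinite(values).all():
        idx = np.argwhere(~np.isfinite(values))
        node, dens = idx[0]
        raise ValueError(
            f"non-finite metric at node {node + 1}, density {densities[dens]:.2f}"
        )
    return np.trapezoid(values, densities, axis=-1)


def compute_metric_table(
    matrix: np.ndarray,
    densities: np.ndarray = DEFAULT_DENSITY_GRID,
    modules: np.ndarray | None = None,
    source: str = "",
) -> MetricTable:
    """Degree and participation across the density grid, with AUCs.

    Unless ``modules`` is supplied, the community partition is recomputed on
    each thresholded graph by greedy modularity maximisation.
    """
    densities = np.asarray(densities, dtype=float)
    n = matrix.shape[0]
    deg = np.empty((n, densities.size))
    part = np.empty((n, densities.size))
    for j, d in enumerate(densities):
        g = proportional_threshold(matrix, d, source=source)
        deg[:, j] = degree(g)
        mods = modules if modules is not None else modularity_partition(g)
        part[:, j] = participation_coefficient(g, mods)
    return MetricTable(
        densities=densities,
        degree=deg,
        participation=part,
        auc_degree=metric_auc(deg, densities),
        auc_participation=metric_auc(part, densities),
    )


def select_critical_rois(table: MetricTable) -> CriticalRoiSet:
    """Nodes whose degree AUC and participation AUC both exceed
    mean + 1 sample standard deviation (strict); the intersection is the
    critical-ROI set."""

    def _select(auc: np.ndarray) -> tuple[list[int], float, float]:
        mean = float(auc.mean())
        sd = float(auc.std(ddof=1))
        if sd == 0:
            return [], mean, sd
        return (np.flatnonzero(auc > mean + sd) + 1).tolist(), mean, sd

    by_k, mean_k, sd_k = _select(table.auc_degree)
    by_p, mean_p, sd_p = _select(table.auc_participation)
    inter = sorted(set(by_k) & set(by_p))
    return CriticalRoiSet(
        by_degree=by_k,
        by_participation=by_p,
        intersection=inter,
        stats={"mean_k": mean_k, "sd_k": sd_k, "mean_p": mean_p, "sd_p": sd_p},
    )
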