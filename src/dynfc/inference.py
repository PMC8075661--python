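"""Group-level inference on connectome patterns.

Two questions are answered here.  First, which patterns are *specific* to
one group: per pattern, the subjects' occupancy ratios are compared between
groups with an equal-variance two-sample t-test at the very conservative
Bonferroni-style threshold p < alpha / K (alpha defaults to 1e-4).  Second,
where do the groups differ *within* the shared (general) patterns: per
pattern, each subject's mean dFC matrix over its windows in that pattern is
computed, and every upper-triangle edge is tested across subjects at
p < alpha / n_edges with n_edges = n_roi (n_roi - 1) / 2; edges significant
in every general pattern form the intersection set.

A reproducibility harness reruns the whole pipeline on subject-level
resamples and on alternative window lengths, matching the resulting
patterns back to the reference ones by centroid correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import RatioDistribution, TwiceClusteringResult

logger = logging.getLogger(__name__)

__all__ = [
    "DfcpClassification",
    "EdgeDifferenceResult",
    "ReproducibilityReport",
    "classify_dfcps",
    "edgewise_group_difference",
    "intersect_significant_edges",
    "match_clusters_by_correlation",
]

RATIO_ALPHA_NUMERATOR = 1e-4
EDGE_ALPHA_NUMERATOR = 1e-4


@dataclass
class DfcpClassification:
    """Per-pattern specific/general verdicts.

    ``table`` has one row per cluster with columns cluster, t, p,
    is_specific; ``alpha_ratio`` is the threshold alpha / K actually used.
    """

    table: pd.DataFrame
    alpha_ratio: float

    @property
    def specific_clusters(self) -> list[int]:
        return self.table.loc[self.table["is_specific"], "cluster"].tolist()

    @property
    def general_clusters(self) -> list[int]:
        return self.table.loc[~self.table["is_specific"], "cluster"].tolist()


@dataclass
class EdgeDifferenceResult:
    """Edgewise two-sample test output for one pattern.

    ``mask`` is a symmetric boolean n_roi x n_roi matrix of significant
    edges; ``stats`` holds per-edge t and p (upper triangle, row-major).
    """

    cluster: int
    mask: np.ndarray
    t: np.ndarray
    p: np.ndarray
    alpha_edge: float
    n_subjects: tuple[int, int]

    def edge_list(self) -> list[tuple[int, int]]:
        """Significant edges as 1-based (i, j) ROI pairs, i < j."""
        iu = np.triu_indices_from(self.mask, k=1)
        sig = self.mask[iu]
        return [(int(i) + 1, int(j) + 1) for i, j, s in zip(*iu, sig) if s]


@dataclass
class ReproducibilityReport:
    """Rows describing each rerun: sampling rate (or window duration), seed,
    detected specific clusters, and the correlation of the rerun's best-
    matching cluster center to the reference specific pattern's center."""

    rows: pd.DataFrame


# ---------------------------------------------------------------------------


def _ttest_columns(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Equal-variance two-sample t-test per column; degenerate columns
    (zero variance in both groups, equal means) get t=0, p=1."""
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(t)
    if bad.any():
        eq = np.isclose(a.mean(axis=0), b.mean(axis=0))
        t[bad] = 0.0
        p[bad & eq] = 1.0
        p[bad & ~eq] = 0.0
    return t, p


def classify_dfcps(
    ratios: RatioDistribution,
    alpha_numerator: float = RATIO_ALPHA_NUMERATOR,
) -> DfcpClassification:
    """Flag patterns whose occupancy ratio differs between the two groups.

    Per cluster, a Student (equal-variance) two-sample t-test compares the
    subjects' occupancy ratios between groups; the pattern is specific iff
    p < alpha_numerator / K.
    """
    groups = sorted(set(ratios.groups))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    g = np.asarray(ratios.groups)
    a = ratios.ratios[g == groups[0]]
    b = ratios.ratios[g == groups[1]]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    t, p = _ttest_columns(a, b)
    alpha = alpha_numerator / ratios.k
    table = pd.DataFrame(
        {
            "cluster": np.arange(1, ratios.k + 1),
            "t": t,
            "p": p,
            "is_specific": p < alpha,
        }
    )
    return DfcpClassification(table=table, alpha_ratio=alpha)


def subject_mean_dfc(
    cluster: int,
    labels: np.ndarray,
    samples,
    tensors,
) -> tuple[list[str], list[str], np.ndarray]:
    """Per-subject mean dFC matrix over the subject's windows in ``cluster``.

    Subjects with no windows in the cluster are omitted.  Returns
    (subject_ids, groups, stack of matrices).
    """
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    group_of: dict[str, str] = {}
    for samp, label in zip(samples, labels):
        if int(label) != cluster:
            continue
        block = tensors[samp.subject_id].matrices[samp.start : samp.stop]
        if samp.subject_id not in sums:
            sums[samp.subject_id] = np.zeros(block.shape[1:])
            counts[samp.subject_id] = 0
            group_of[samp.subject_id] = samp.group
        sums[samp.subject_id] += block.sum(axis=0)
        counts[samp.subject_id] += block.shape[0]
    sids = list(sums)
    mats = np.stack([sums[s] / counts[s] for s in sids]) if sids else np.empty((0,))
    return sids, [group_of[s] for s in sids], mats


def edgewise_group_difference(
    subject_matrices: np.ndarray,
    groups: list[str],
    cluster: int = 0,
    alpha_numerator: float = EDGE_ALPHA_NUMERATOR,
) -> EdgeDifferenceResult | None:
    """Edgewise two-sample t-test between groups for one pattern.

    ``subject_matrices`` stacks one mean dFC matrix per subject (the subject
    is the unit of analysis; windows within a subject are not independent).
    Each of the n_roi(n_roi-1)/2 upper-triangle edges is tested at
    p < alpha_numerator / n_edges.  Returns None (with a warning) if either
    group has fewer than 2 contributing subjects.
    """
    groups_arr = np.asarray(groups)
    uniq = sorted(set(groups))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    n_a = int((groups_arr == uniq[0]).sum())
    n_b = int((groups_arr == uniq[1]).sum())
    if n_a < 2 or n_b < 2:
        logger.warning(
            "pattern %d skipped: groups have %d/%d subjects", cluster, n_a, n_b
        )
        return None
    n_roi = subject_matrices.shape[1]
    iu = np.triu_indices(n_roi, k=1)
    n_edges = iu[0].size
    edges = subject_matrices[:, iu[0], iu[1]]
    t, p = _ttest_columns(edges[groups_arr == uniq[0]], edges[groups_arr == uniq[1]])
    alpha = alpha_numerator / n_edges
    sig = p < alpha
    mask = np.zeros((n_roi, n_roi), dtype=bool)
    mask[iu] = sig
    mask |= mask.T
    return EdgeDifferenceResult(
        cluster=cluster,
        mask=mask,
        t=t,
        p=p,
        alpha_edge=alpha,
        n_subjects=(n_a, n_b),
    )


def intersect_significant_edges(
    results: list[EdgeDifferenceResult],
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Edges significant in *every* general pattern (logical AND of masks).

    Returns the intersection mask and its 1-based (i, j) edge list.
    """
    if not results:
        raise ValueError("need at least one edge mask")
    mask = results[0].mask.copy()
    for r in results[1:]:
        mask &= r.mask
    iu = np.triu_indices_from(mask, k=1)
    edges = [(int(i) + 1, int(j) + 1) for i, j in zip(*iu) if mask[i, j]]
    return mask, edges


def match_clusters_by_correlation(
    centers_a: np.ndarray, centers_b: np.ndarray
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Greedy cluster correspondence between two center sets.

    Pearson correlation is computed between every pair of centers (rows);
    pairs are matched highest-correlation first, without replacement.
    Centers that are constant (undefined correlation) are excluded with a
    warning.  Returns (matching as 0-based (a_idx, b_idx) pairs, the full
    correlation matrix with NaN for excluded rows/columns).
    """
    a = np.asarray(centers_a, dtype=float)
    b = np.asarray(centers_b, dtype=float)
    sa = a.std(axis=1)
    sb = b.std(axis=1)
    corr = np.full((a.shape[0], b.shape[0]), np.nan)
    ok_a = sa > 0
    ok_b = sb > 0
    if (~ok_a).any() or (~ok_b).any():
        logger.warning("constant center vectors excluded from matching")
    az = (a - a.mean(axis=1, keepdims=True))[ok_a]
    bz = (b - b.mean(axis=1, keepdims=True))[ok_b]
    c = (az @ bz.T) / np.outer(
        np.sqrt((az**2).sum(axis=1)), np.sqrt((bz**2).sum(axis=1))
    )
    corr[np.ix_(ok_a, ok_b)] = c
    matching: list[tuple[int, int]] = []
    work = corr.copy()
    while np.isfinite(work).any():
        i, j = np.unravel_index(np.nanargmax(work), work.shape)
        matching.append((int(i), int(j)))
        work[i, :] = np.nan
        work[:, j] = np.nan
    return matching, corr
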