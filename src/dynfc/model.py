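"""Model/Results interface tying the pipeline stages together.

:class:`ConnectomeDynamics` is built from a cohort of per-subject ROI time
series; :meth:`~ConnectomeDynamics.fit` runs windowed dFC, quasistable
segmentation, twice-clustering with Davies-Bouldin model selection, and
occupancy-ratio classification, returning a
:class:`ConnectomeDynamicsResults` that carries the estimates and exposes
the second-stage analyses (edgewise group differences, hub extraction,
resampling and window-length reproducibility) plus a ``summary()`` table.

Example
-------
>>> from dynfc import make_cohort_config, generate_cohort, ConnectomeDynamics
>>> cohort = generate_cohort(make_cohort_config(n_roi=40, n_subjects_per_group=10, seed=3))
>>> res = ConnectomeDynamics.from_cohort(cohort, k_range=(2, 8)).fit()
>>> res.k, res.classification.specific_clusters
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import (
    RatioDistribution,
    TwiceClusteringResult,
    compute_dfcp_centroids,
    ratio_distributions,
    select_k_davies_bouldin,
    twice_cluster,
)
from .core import (
    DfcTensor,
    DfcsMatrix,
    RoiTimeSeries,
    WindowConfig,
    dfcs_from_tensor,
    sliding_window_dfc,
    static_fc,
)
from .graph import (
    DEFAULT_DENSITY_GRID,
    CriticalRoiSet,
    MetricTable,
    compute_metric_table,
    select_critical_rois,
)
from .inference import (
    DfcpClassification,
    EdgeDifferenceResult,
    ReproducibilityReport,
    classify_dfcps,
    edgewise_group_difference,
    intersect_significant_edges,
    match_clusters_by_correlation,
    subject_mean_dfc,
)
from .segmentation import WqcpSample, segment_subject

logger = logging.getLogger(__name__)

__all__ = ["ConnectomeDynamics", "ConnectomeDynamicsResults"]


class ConnectomeDynamics:
    """Dynamic connectome pattern model for a two-group cohort.

    Parameters
    ----------
    subjects:
        Per-subject ROI x time series; all subjects must share n_roi.
    window:
        Sliding-window settings; the window length in time points is derived
        per subject from its TR (36 s duration by default).
    k_range:
        Inclusive candidate range for the Davies-Bouldin model selection.
    alpha_ratio_numerator, alpha_edge_numerator:
        Numerators of the Bonferroni-style thresholds alpha/K (occupancy
        tests) and alpha/n_edges (edgewise tests).
    """

    def __init__(
        self,
        subjects: list[RoiTimeSeries],
        window: WindowConfig | None = None,
        k_range: tuple[int, int] = (2, 30),
        alpha_ratio_numerator: float = 1e-4,
        alpha_edge_numerator: float = 1e-4,
    ):
        if not subjects:
            raise ValueError("no subjects")
        n_roi = {ts.n_roi for ts in subjects}
        if len(n_roi) != 1:
            raise ValueError(f"inconsistent n_roi across cohort: {sorted(n_roi)}")
        groups = sorted({ts.group for ts in subjects})
        if len(groups) != 2:
            raise ValueError(f"expected exactly 2 groups, got {groups}")
        self.subjects = list(subjects)
        self.window = window or WindowConfig()
        self.k_range = k_range
        self.alpha_ratio_numerator = alpha_ratio_numerator
        self.alpha_edge_numerator = alpha_edge_numerator
        self.n_roi = n_roi.pop()
        self.groups = groups

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "ConnectomeDynamics":
        """Build from a :class:`~dynfc.synthetic.SyntheticCohort` (or any
        object with a ``subjects`` attribute)."""
        return cls(cohort.subjects, **kwargs)

    def fit(self, k: int | None = None) -> "ConnectomeDynamicsResults":
        """Run the full first-stage pipeline.

        With ``k=None`` the number of patterns is selected by the
        Davies-Bouldin index over ``k_range``; otherwise the twice-clustering
        runs at the given K.
        """
        tensors: dict[str, DfcTensor] = {}
        dfcs: dict[str, DfcsMatrix] = {}
        samples: list[WqcpSample] = []
        for ts in self.subjects:
            w = self.window.window_length(ts.tr)
            tensor = sliding_window_dfc(ts, w, step=self.window.step)
            tensors[ts.subject_id] = tensor
            strength = dfcs_from_tensor(tensor)
            dfcs[ts.subject_id] = strength
            _, subj_samples = segment_subject(strength, group=ts.group)
            samples.extend(subj_samples)
        x = np.vstack([s.vector for s in samples])
        if k is None:
            clustering = select_k_davies_bouldin(x, self.k_range)
        else:
            clustering = twice_cluster(x, k)
        ratios = ratio_distributions(clustering, samples)
        classification = classify_dfcps(ratios, self.alpha_ratio_numerator)
        return ConnectomeDynamicsResults(
            model=self,
            clustering=clustering,
            samples=samples,
            tensors=tensors,
            dfcs=dfcs,
            ratios=ratios,
            classification=classification,
        )


@dataclass
class ConnectomeDynamicsResults:
    """Fitted dynamic connectome patterns and their group-level statistics."""

    model: ConnectomeDynamics
    clustering: TwiceClusteringResult
    samples: list[WqcpSample]
    tensors: dict[str, DfcTensor]
    dfcs: dict[str, DfcsMatrix]
    ratios: RatioDistribution
    classification: DfcpClassification
    _centroids: list | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return self.clustering.k

    @property
    def specific_clusters(self) -> list[int]:
        return self.classification.specific_clusters

    @property
    def general_clusters(self) -> list[int]:
        return self.classification.general_clusters

    # -- centroids ---------------------------------------------------------

    def centroids(self):
        """Per-cluster mean dFC matrices for each group scope and pooled."""
        if self._centroids is None:
            self._centroids = compute_dfcp_centroids(
                self.clustering, self.samples, self.tensors
            )
        return self._centroids

    def centroid_matrix(self, cluster: int, scope: str = "pooled") -> np.ndarray:
        for c in self.centroids():
            if c.cluster == cluster and c.scope == scope:
                if c.absent:
                    raise ValueError(
                        f"cluster {cluster} has no windows in scope {scope!r}"
                    )
                return c.matrix
        raise KeyError(f"no centroid for cluster {cluster}, scope {scope!r}")

    # -- edgewise inference ------------------------------------------------

    def edge_differences(
        self, clusters: list[int] | None = None
    ) -> dict[int, EdgeDifferenceResult]:
        """Edgewise group tests per (by default general) pattern, on
        subject-level within-pattern mean dFC matrices."""
        if clusters is None:
            clusters = self.general_clusters
        out: dict[int, EdgeDifferenceResult] = {}
        for c in clusters:
            sids, groups, mats = subject_mean_dfc(
                c, self.clustering.labels, self.samples, self.tensors
            )
            if not sids:
                logger.warning("pattern %d has no subjects; skipped", c)
                continue
            res = edgewise_group_difference(
                mats, groups, cluster=c,
                alpha_numerator=self.model.alpha_edge_numerator,
            )
            if res is not None:
                out[c] = res
        return out

    def intersection_edges(self) -> tuple[np.ndarray, list[tuple[int, int]]]:
        """Edges significantly different in every general pattern."""
        diffs = self.edge_differences()
        if not diffs:
            raise ValueError("no general pattern produced an edge mask")
        return intersect_significant_edges(list(diffs.values()))

    # -- graph metrics -----------------------------------------------------

    def metric_table(
        self,
        cluster: int,
        scope: str | None = None,
        densities: np.ndarray = DEFAULT_DENSITY_GRID,
    ) -> MetricTable:
        scope = scope or self.model.groups[0]
        return compute_metric_table(
            self.centroid_matrix(cluster, scope), densities,
            source=f"cluster{cluster}:{scope}",
        )

    def critical_rois(
        self,
        cluster: int | None = None,
        scope: str | None = None,
        densities: np.ndarray = DEFAULT_DENSITY_GRID,
    ) -> CriticalRoiSet:
        """Hub ROIs of a pattern centroid (default: the specific pattern's
        centroid in the first group)."""
        if cluster is None:
            spec = self.specific_clusters
            if not spec:
                raise ValueError("no specific pattern detected; pass cluster=")
            cluster = spec[0]
        return select_critical_rois(self.metric_table(cluster, scope, densities))

    def static_fc_critical_rois(
        self,
        scope: str | None = None,
        densities: np.ndarray = DEFAULT_DENSITY_GRID,
    ) -> CriticalRoiSet:
        """Same hub selection applied to the group-mean static FC matrix —
        the static counterpart the dynamic selection is compared against."""
        scope = scope or self.model.groups[0]
        mats = [static_fc(ts) for ts in self.model.subjects if ts.group == scope]
        return select_critical_rois(
            compute_metric_table(np.mean(mats, axis=0), densities, source="staticFC")
        )

    # -- reproducibility ---------------------------------------------------

    def resample_reproducibility(
        self,
        rates: tuple[float, ...] = (0.5, 0.9),
        n_runs: int = 4,
        seed: int = 0,
    ) -> ReproducibilityReport:
        """Refit on subject-level resamples and match patterns back.

        For each rate, ``n_runs`` subsets are drawn without replacement
        within each group (fraction ``rate`` of its subjects), the model is
        refit at the reference K, and the rerun's patterns are matched to
        the reference centers by correlation.  Each row reports the
        correlation of the rerun cluster matched to the reference specific
        pattern and whether that cluster was itself flagged specific.
        """
        rng = np.random.default_rng(seed)
        ref_specific = self.specific_clusters
        rows = []
        for rate in rates:
            for run in range(n_runs):
                run_seed = int(rng.integers(2**31))
                subset = self._draw_subset(rate, run_seed)
                if subset is None:
                    logger.warning("rate %.2f run %d: resample too small", rate, run)
                    continue
                rows.append(
                    self._refit_row(subset, ref_specific, rate=rate, run=run,
                                    seed=run_seed)
                )
        return ReproducibilityReport(rows=pd.DataFrame(rows))

    def window_reproducibility(
        self, durations_s: tuple[float, ...] = (12.0, 60.0)
    ) -> ReproducibilityReport:
        """Refit the full cohort at alternative window durations and match
        the resulting patterns to the reference ones."""
        rows = []
        for dur in durations_s:
            row = self._refit_row(
                self.model.subjects, self.specific_clusters,
                duration_s=float(dur),
            )
            rows.append(row)
        return ReproducibilityReport(rows=pd.DataFrame(rows))

    def _draw_subset(self, rate: float, seed: int):
        rng = np.random.default_rng(seed)
        chosen: list[RoiTimeSeries] = []
        for g in self.model.groups:
            members = [ts for ts in self.model.subjects if ts.group == g]
            n_take = int(round(rate * len(members)))
            if n_take < 2:
                return None
            idx = rng.choice(len(members), size=n_take, replace=False)
            chosen.extend(members[i] for i in sorted(idx))
        return chosen

    def _refit_row(
        self,
        subjects: list[RoiTimeSeries],
        ref_specific: list[int],
        rate: float | None = None,
        run: int | None = None,
        seed: int | None = None,
        duration_s: float | None = None,
    ) -> dict:
        window = self.model.window
        if duration_s is not None:
            window = WindowConfig(duration_s=duration_s, step=window.step)
        sub_model = ConnectomeDynamics(
            subjects,
            window=window,
            k_range=self.model.k_range,
            alpha_ratio_numerator=self.model.alpha_ratio_numerator,
            alpha_edge_numerator=self.model.alpha_edge_numerator,
        )
        sub_res = sub_model.fit(k=self.k)
        matching, corr = match_clusters_by_correlation(
            self.clustering.final_centers, sub_res.clustering.final_centers
        )
        row = {
            "rate": rate,
            "run": run,
            "seed": seed,
            "duration_s": duration_s,
            "k": sub_res.k,
            "n_subjects": len(subjects),
            "specific_clusters": tuple(sub_res.specific_clusters),
        }
        # match against the reference specific pattern, falling back to the
        # first reference cluster when none was specific
        ref = ref_specific[0] if ref_specific else 1
        partner = dict(matching).get(ref - 1)
        row["matched_cluster"] = None if partner is None else partner + 1
        row["matched_correlation"] = (
            np.nan if partner is None else float(corr[ref - 1, partner])
        )
        row["matched_is_specific"] = (
            partner is not None and (partner + 1) in sub_res.specific_clusters
        )
        return row

    # -- summary -----------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary in the spirit of statsmodels."""
        g0, g1 = self.model.groups
        garr = np.asarray(self.ratios.groups)
        lines = [
            "Dynamic Functional Connectome Patterns",
            "=" * 54,
            f"Subjects: {len(self.model.subjects)}  "
            f"({g0}: {int((garr == g0).sum())}, {g1}: {int((garr == g1).sum())})",
            f"ROIs: {self.model.n_roi}   WQCP samples: {len(self.samples)}",
            f"Patterns (K): {self.k}"
            + (
                f"   Davies-Bouldin at K: {self.clustering.db_curve[self.k]:.3f}"
                if self.clustering.db_curve
                else ""
            ),
            f"Occupancy-ratio threshold: p < {self.classification.alpha_ratio:.3g}",
            "-" * 54,
            f"{'pattern':>8} {'n_samples':>10} {'mean_' + g0:>10} "
            f"{'mean_' + g1:>10} {'t':>8} {'p':>10}  class",
        ]
        counts = np.bincount(self.clustering.labels, minlength=self.k + 1)[1:]
        for _, r in self.classification.table.iterrows():
            c = int(r["cluster"])
            m0 = self.ratios.ratios[garr == g0, c - 1].mean()
            m1 = self.ratios.ratios[garr == g1, c - 1].mean()
            tag = "specific" if r["is_specific"] else "general"
            lines.append(
                f"{c:>8} {counts[c - 1]:>10} {m0:>10.3f} {m1:>10.3f} "
                f"{r['t']:>8.2f} {r['p']:>10.3g}  {tag}"
            )
        lines.append("=" * 54)
        return "\n".join(lines)
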