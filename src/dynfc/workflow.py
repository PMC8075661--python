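"""Configuration, file formats and the end-to-end pipeline runner.

File conventions (all plain text):

* manifest: TSV with columns subject_id / group / tr / path; ``path`` is a
  per-subject series TSV (rows = ROIs, columns = time points) relative to
  the manifest's directory.
* truth (synthetic cohorts): TSV of subject_id + state id per time point.
* atlas: TSV as in :mod:`dynfc.atlas`.
* BrainNet Viewer export: ``.node`` (x y z color size label, whitespace-
  delimited) and ``.edge`` (full square matrix, sub-threshold entries
  zeroed).

``run_pipeline`` executes dFC -> segmentation -> twice-clustering ->
classification -> edgewise tests -> hub extraction and writes every
artifact plus a JSON run report; given the same inputs it is idempotent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .atlas import AtlasTable, default_atlas, load_atlas
from .core import RoiTimeSeries, WindowConfig
from .model import ConnectomeDynamics
from .synthetic import SyntheticCohort

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "load_manifest",
    "write_cohort",
    "run_pipeline",
    "export_brainnet_files",
]


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults reproduce the reference
    settings (36 s windows, step 1, DB-selected K, densities 10-40%,
    alpha numerators 1e-4, visualisation threshold 0.75)."""

    manifest: str = ""
    atlas: str | None = None
    out_dir: str = "dynfc_run"
    window_duration_s: float = 36.0
    window_step: int = 1
    window_length_override: int | None = None
    k: int | None = None
    k_range: tuple[int, int] = (2, 30)
    alpha_ratio_numerator: float = 1e-4
    alpha_edge_numerator: float = 1e-4
    density_min: float = 0.10
    density_max: float = 0.40
    density_step: float = 0.01
    viz_edge_threshold: float = 0.75
    seed: int = 0
    resample_rates: tuple[float, ...] = (0.5, 0.9)
    resample_runs: int = 0  # 0 = skip the resampling harness

    def density_grid(self) -> np.ndarray:
        n = int(round((self.density_max - self.density_min) / self.density_step)) + 1
        return np.round(self.density_min + self.density_step * np.arange(n), 10)

    def window(self) -> WindowConfig:
        return WindowConfig(
            duration_s=self.window_duration_s,
            step=self.window_step,
            window_length_override=self.window_length_override,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        d["resample_rates"] = list(self.resample_rates)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["k_range"] = tuple(d.get("k_range", (2, 30)))
        d["resample_rates"] = tuple(d.get("resample_rates", (0.5, 0.9)))
        return cls(**d)

    def content_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Cohort IO


def _write_series(ts: RoiTimeSeries, path: Path) -> None:
    np.savetxt(path, ts.series, delimiter="\t", fmt="%.10g")


def _read_series(path: Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write a synthetic cohort as manifest + per-subject TSVs + truth TSV.

    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ts in cohort.subjects:
        _write_series(ts, out / f"{ts.subject_id}.tsv")
    manifest_path = out / "manifest.tsv"
    cohort.manifest.to_csv(manifest_path, sep="\t", index=False)
    truth_rows = []
    for sid, seq in cohort.state_sequences.items():
        truth_rows.append("\t".join([sid] + [str(int(s)) for s in seq]))
    (out / "truth_states.tsv").write_text("\n".join(truth_rows) + "\n")
    cohort.occupancy_table().to_csv(out / "truth_occupancy.tsv", sep="\t", index=False)
    return manifest_path


def load_manifest(manifest_path: str | Path) -> list[RoiTimeSeries]:
    """Load every subject listed in a manifest TSV."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    required = {"subject_id", "group", "tr", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    subjects = []
    for _, row in df.iterrows():
        series = _read_series(manifest_path.parent / row["path"])
        subjects.append(
            RoiTimeSeries(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                tr=float(row["tr"]),
                series=series,
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(config: PipelineConfig, subjects: list[RoiTimeSeries] | None = None):
    """Execute the full pipeline and write all artifacts to ``out_dir``.

    ``subjects`` may be passed directly (e.g. an in-memory synthetic
    cohort); otherwise they are loaded from ``config.manifest``.  Returns
    the fitted :class:`~dynfc.model.ConnectomeDynamicsResults`.
    """
    from .segmentation import wqcp_dataframe

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if subjects is None:
        if not config.manifest:
            raise ValueError("config.manifest is required when no subjects are given")
        subjects = load_manifest(config.manifest)
    atlas = load_atlas(config.atlas) if config.atlas else default_atlas()
    if atlas.n_roi != subjects[0].n_roi:
        logger.warning(
            "atlas has %d ROIs but series have %d; label lookups disabled",
            atlas.n_roi, subjects[0].n_roi,
        )
        atlas = None

    model = ConnectomeDynamics(
        subjects,
        window=config.window(),
        k_range=config.k_range,
        alpha_ratio_numerator=config.alpha_ratio_numerator,
        alpha_edge_numerator=config.alpha_edge_numerator,
    )
    results = model.fit(k=config.k)

    # artifacts
    wqcp_dataframe(results.samples).to_csv(out / "wqcp.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"sample": np.arange(len(results.samples)), "cluster": results.clustering.labels}
    ).to_csv(out / "labels.tsv", sep="\t", index=False)
    if results.clustering.db_curve:
        pd.DataFrame(
            sorted(results.clustering.db_curve.items()), columns=["k", "davies_bouldin"]
        ).to_csv(out / "db_curve.csv", index=False)
    ratio_df = pd.DataFrame(
        results.ratios.ratios,
        columns=[f"dfcp_{c}" for c in range(1, results.k + 1)],
    )
    ratio_df.insert(0, "subject_id", results.ratios.subject_ids)
    ratio_df.insert(1, "group", results.ratios.groups)
    ratio_df.to_csv(out / "ratios.tsv", sep="\t", index=False)
    results.classification.table.to_csv(out / "classification.tsv", sep="\t", index=False)

    edge_rows = []
    diffs = results.edge_differences()
    for c, res in diffs.items():
        for i, j in res.edge_list():
            edge_rows.append(
                {
                    "cluster": c,
                    "roi_i": i,
                    "roi_j": j,
                    "label_i": atlas.abbreviation(i) if atlas else "",
                    "label_j": atlas.abbreviation(j) if atlas else "",
                }
            )
    pd.DataFrame(edge_rows, columns=["cluster", "roi_i", "roi_j", "label_i", "label_j"]).to_csv(
        out / "edges.tsv", sep="\t", index=False
    )
    intersection: list[tuple[int, int]] = []
    if diffs:
        _, intersection = results.intersection_edges()

    critical = None
    if results.specific_clusters:
        crit = results.critical_rois()
        critical = {
            "cluster": results.specific_clusters[0],
            "by_degree": crit.by_degree,
            "by_participation": crit.by_participation,
            "intersection": crit.intersection,
        }
        pd.DataFrame(
            {
                "roi": crit.intersection,
                "abbreviation": [
                    atlas.abbreviation(r) if atlas else "" for r in crit.intersection
                ],
            }
        ).to_csv(out / "critical_rois.tsv", sep="\t", index=False)

    report = {
        "k": results.k,
        "n_samples": len(results.samples),
        "specific_clusters": results.specific_clusters,
        "general_clusters": results.general_clusters,
        "intersection_edges": intersection,
        "critical_rois": critical,
        "provenance": {
            "config_hash": config.content_hash(),
            "config": config.to_dict(),
            "dynfc_version": _version,
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))

    if config.resample_runs > 0:
        rep = results.resample_reproducibility(
            rates=config.resample_rates,
            n_runs=config.resample_runs,
            seed=config.seed,
        )
        rep.rows.to_csv(out / "reproducibility.tsv", sep="\t", index=False)
    return results


# ---------------------------------------------------------------------------
# Visualisation export


def export_brainnet_files(
    matrix: np.ndarray,
    atlas: AtlasTable,
    out_prefix: str | Path,
    node_sizes: np.ndarray | None = None,
    node_colors: np.ndarray | None = None,
    edge_threshold: float = 0.75,
) -> tuple[Path, Path]:
    """Write BrainNet Viewer ``.node`` and ``.edge`` files.

    ``.node`` rows are ``x y z color size label``; ``.edge`` is the full
    square matrix with |value| < ``edge_threshold`` zeroed.  The atlas must
    carry MNI coordinates for every ROI.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if atlas.n_roi != n:
        raise ValueError(f"atlas has {atlas.n_roi} ROIs, matrix has {n}")
    coords = atlas.coordinates()
    sizes = np.ones(n) if node_sizes is None else np.asarray(node_sizes, float)
    colors = np.ones(n, dtype=int) if node_colors is None else np.asarray(node_colors)
    labels = [atlas.abbreviation(i) for i in range(1, n + 1)]
    out_prefix = Path(out_prefix)
    node_path = out_prefix.with_suffix(".node")
    edge_path = out_prefix.with_suffix(".edge")
    with open(node_path, "w") as fh:
        for i in range(n):
            x, y, z = coords[i]
            label = labels[i].replace(" ", "_")
            fh.write(f"{x:.2f}\t{y:.2f}\t{z:.2f}\t{int(colors[i])}\t{sizes[i]:.4f}\t{label}\n")
    thresholded = np.where(np.abs(matrix) >= edge_threshold, matrix, 0.0) \
        if edge_threshold > 0 else matrix
    np.savetxt(edge_path, thresholded, delimiter="\t", fmt="%.6g")
    return node_path, edge_path
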