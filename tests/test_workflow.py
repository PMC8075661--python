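"""Atlas handling, configuration, cohort IO, pipeline runner and exports."""

import json

import numpy as np
import pandas as pd
import pytest

from dynfc import (
    default_atlas,
    export_brainnet_files,
    generate_cohort,
    load_atlas,
    load_manifest,
    make_cohort_config,
    run_pipeline,
    write_cohort,
)
from dynfc.atlas import AtlasTable
from dynfc.workflow import PipelineConfig


class TestAtlas:
    def test_default_partition_counts(self):
        atlas = default_atlas()
        assert atlas.n_roi == 246
        assert atlas.n_cortical == 210
        assert atlas.n_subcortical == 36

    @pytest.mark.parametrize(
        "index,abbrev",
        [
            (1, "A8m"),
            (13, "A10m"),
            (66, "A1/2/3ll"),
            (181, "A23v"),
            (187, "A32sg"),
            (219, "vCa"),
            (221, "GP"),
            (231, "mPFtha"),
            (237, "rTtha"),
            (239, "PPtha"),
            (246, "lPFtha"),
        ],
    )
    def test_reference_lookups(self, index, abbrev):
        assert default_atlas().abbreviation(index) == abbrev

    def test_tsv_roundtrip(self, tmp_path):
        atlas = default_atlas()
        path = tmp_path / "atlas.tsv"
        atlas.table.to_csv(path, sep="\t", index=False)
        loaded = load_atlas(str(path))
        assert loaded.n_roi == 246
        assert loaded.abbreviation(221) == "GP"

    def test_duplicate_indices_rejected(self):
        df = default_atlas().table.copy()
        df.loc[1, "index"] = 1
        with pytest.raises(ValueError, match="unique|contiguous"):
            AtlasTable(df)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"index": [1], "abbreviation": ["X"]}).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(ValueError, match="missing columns"):
            load_atlas(str(path))


class TestPipelineConfig:
    def test_yaml_roundtrip_unchanged(self, tmp_path):
        cfg = PipelineConfig(manifest="m.tsv", k_range=(2, 9), seed=42)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert PipelineConfig.from_yaml(path) == cfg

    def test_default_density_grid(self):
        grid = PipelineConfig().density_grid()
        assert grid.size == 31
        assert grid[0] == pytest.approx(0.10)
        assert grid[-1] == pytest.approx(0.40)

    def test_defaults_reproduce_reference_settings(self):
        cfg = PipelineConfig()
        assert cfg.window_duration_s == 36.0
        assert cfg.window_step == 1
        assert cfg.alpha_ratio_numerator == cfg.alpha_edge_numerator == 1e-4
        assert cfg.viz_edge_threshold == 0.75
        assert cfg.k is None  # K chosen by the Davies-Bouldin index


class TestCohortIO:
    def test_write_then_load_roundtrip(self, tmp_path):
        cohort = generate_cohort(
            make_cohort_config(n_subjects_per_group=2, n_roi=8, seed=2)
        )
        manifest = write_cohort(cohort, tmp_path)
        loaded = load_manifest(manifest)
        assert len(loaded) == 4
        by_id = {ts.subject_id: ts for ts in loaded}
        for ts in cohort.subjects:
            np.testing.assert_allclose(by_id[ts.subject_id].series, ts.series, atol=1e-9)
            assert by_id[ts.subject_id].tr == ts.tr
            assert by_id[ts.subject_id].group == ts.group

    def test_manifest_missing_column_rejected(self, tmp_path):
        path = tmp_path / "manifest.tsv"
        pd.DataFrame({"subject_id": ["a"], "group": ["A"]}).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(ValueError, match="missing columns"):
            load_manifest(path)


@pytest.fixture(scope="module")
def run_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    cohort = generate_cohort(
        make_cohort_config(n_subjects_per_group=34, n_roi=40, seed=11)
    )
    cfg = PipelineConfig(out_dir=str(out), k_range=(2, 8), seed=11)
    results = run_pipeline(cfg, subjects=cohort.subjects)
    return out, results


class TestRunPipeline:

    def test_planted_difference_yields_one_specific_cluster(self, run_dir):
        out, results = run_dir
        report = json.loads((out / "report.json").read_text())
        assert len(report["specific_clusters"]) == 1
        assert report["k"] == results.k

    def test_artifacts_written(self, run_dir):
        out, _ = run_dir
        for name in (
            "wqcp.tsv", "labels.tsv", "db_curve.csv", "ratios.tsv",
            "classification.tsv", "edges.tsv", "report.json", "critical_rois.tsv",
        ):
            assert (out / name).exists(), name

    def test_report_carries_provenance(self, run_dir):
        out, _ = run_dir
        report = json.loads((out / "report.json").read_text())
        assert "config_hash" in report["provenance"]
        assert report["provenance"]["config"]["k_range"] == [2, 8]

    def test_rerun_is_idempotent(self, run_dir, tmp_path):
        out, results = run_dir
        cohort = generate_cohort(
            make_cohort_config(n_subjects_per_group=34, n_roi=40, seed=11)
        )
        cfg = PipelineConfig(out_dir=str(tmp_path / "rerun"), k_range=(2, 8), seed=11)
        res2 = run_pipeline(cfg, subjects=cohort.subjects)
        r1 = json.loads((out / "report.json").read_text())
        r2 = json.loads((tmp_path / "rerun" / "report.json").read_text())
        for key in ("k", "n_samples", "specific_clusters", "intersection_edges"):
            assert r1[key] == r2[key]


def toy_atlas_with_coords(n=3):
    df = pd.DataFrame(
        {
            "index": np.arange(1, n + 1),
            "abbreviation": [f"R{i}" for i in range(1, n + 1)],
            "description": [f"region {i}" for i in range(1, n + 1)],
            "x": np.linspace(-10, 10, n),
            "y": np.zeros(n),
            "z": np.ones(n),
        }
    )
    return AtlasTable(df)


class TestBrainNetExport:
    def test_node_and_edge_shapes(self, tmp_path):
        atlas = toy_atlas_with_coords()
        m = np.array([[0, 0.8, 0.2], [0.8, 0, 0.9], [0.2, 0.9, 0]])
        node, edge = export_brainnet_files(m, atlas, tmp_path / "viz")
        lines = node.read_text().strip().splitlines()
        assert len(lines) == 3
        assert len(lines[0].split()) == 6
        loaded = np.loadtxt(edge)
        assert loaded.shape == (3, 3)
        np.testing.assert_allclose(loaded, loaded.T)

    def test_subthreshold_edges_zeroed(self, tmp_path):
        atlas = toy_atlas_with_coords()
        m = np.full((3, 3), 0.6)
        np.fill_diagonal(m, 0)
        _, edge = export_brainnet_files(m, atlas, tmp_path / "v", edge_threshold=0.75)
        assert np.all(np.loadtxt(edge) == 0.0)

    def test_zero_threshold_preserves_matrix(self, tmp_path):
        atlas = toy_atlas_with_coords()
        rng = np.random.default_rng(0)
        m = rng.normal(size=(3, 3))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        _, edge = export_brainnet_files(m, atlas, tmp_path / "v", edge_threshold=0.0)
        np.testing.assert_allclose(np.loadtxt(edge), m, atol=1e-6)

    def test_missing_coordinates_listed(self, tmp_path):
        atlas = default_atlas()  # no coordinates bundled
        with pytest.raises(ValueError, match="coordinates"):
            export_brainnet_files(np.zeros((246, 246)), atlas, tmp_path / "v")


def test_cli_simulate_and_run(tmp_path):
    from click.testing import CliRunner

    from dynfc.cli import main

    runner = CliRunner()
    data_dir = tmp_path / "cohort"
    r = runner.invoke(
        main,
        ["simulate", "--out-dir", str(data_dir), "--n-subjects", "3",
         "--n-roi", "12", "--n-states", "2", "--occupancy-a", "0.5",
         "--occupancy-b", "0.5", "--seed", "1"],
    )
    assert r.exit_code == 0, r.output
    assert (data_dir / "manifest.tsv").exists()
    r = runner.invoke(
        main,
        ["run", "--manifest", str(data_dir / "manifest.tsv"),
         "--out-dir", str(tmp_path / "out"), "--k", "2"],
    )
    assert r.exit_code == 0, r.output
    assert (tmp_path / "out" / "report.json").exists()
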