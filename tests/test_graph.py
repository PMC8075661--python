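"""Proportional thresholding, degree, participation coefficient, AUC and
hub selection."""

import numpy as np
import pytest

from dynfc import (
    degree,
    metric_auc,
    modularity_partition,
    participation_coefficient,
    proportional_threshold,
    select_critical_rois,
)
from dynfc.graph import MetricTable, compute_metric_table


def random_weights(rng, n):
    m = rng.normal(size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


class TestProportionalThreshold:
    def test_full_density_is_complete_graph(self, rng):
        g = proportional_threshold(random_weights(rng, 5), 1.0)
        assert g.n_edges == 10
        assert np.all(np.diag(g.adjacency) == 0)

    def test_top_weights_kept(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 0.9
        m[2, 3] = m[3, 2] = 0.8
        m[0, 2] = m[2, 0] = 0.1
        g = proportional_threshold(m, 2 / 6)
        assert g.adjacency[0, 1] == 1 and g.adjacency[2, 3] == 1
        assert g.n_edges == 2

    def test_negative_weights_ranked_by_magnitude(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = -0.9
        m[1, 2] = m[2, 1] = 0.2
        g = proportional_threshold(m, 1 / 3)
        assert g.adjacency[0, 1] == 1

    def test_edge_count_exact_for_any_density(self, rng):
        m = random_weights(rng, 12)
        for density in (0.1, 0.25, 0.4, 0.73):
            g = proportional_threshold(m, density)
            assert g.n_edges == round(density * 66)

    def test_tie_break_deterministic_and_lexicographic(self):
        m = np.full((4, 4), 0.5)
        np.fill_diagonal(m, 0.0)
        g = proportional_threshold(m, 2 / 6)
        assert g.adjacency[0, 1] == 1 and g.adjacency[0, 2] == 1
        assert g.n_edges == 2

    def test_zero_edge_density_rejected(self):
        with pytest.raises(ValueError):
            proportional_threshold(np.zeros((3, 3)), 0.01)


class TestDegreeAndParticipation:
    def test_triangle_and_star_degrees(self):
        triangle = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        np.testing.assert_array_equal(degree(triangle), [2, 2, 2])
        star = np.zeros((5, 5), int)
        star[0, 1:] = star[1:, 0] = 1
        np.testing.assert_array_equal(degree(star), [4, 1, 1, 1, 1])

    def test_degree_matches_edge_list_count(self, rng):
        g = proportional_threshold(random_weights(rng, 10), 0.3)
        edges = [
            (i, j)
            for i in range(10)
            for j in range(i + 1, 10)
            if g.adjacency[i, j]
        ]
        counts = np.zeros(10, int)
        for i, j in edges:
            counts[i] += 1
            counts[j] += 1
        np.testing.assert_array_equal(degree(g), counts)

    def test_intra_module_edges_score_zero(self):
        triangle = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        np.testing.assert_allclose(
            participation_coefficient(triangle, np.zeros(3, int)), 0.0
        )

    def test_even_split_scores_half(self):
        # node 0 has degree 4, split 2/2 across two modules
        adj = np.zeros((5, 5), int)
        adj[0, 1:] = adj[1:, 0] = 1
        modules = np.array([0, 0, 0, 1, 1])
        p = participation_coefficient(adj, modules)
        assert p[0] == pytest.approx(0.5)

    def test_three_one_split(self):
        adj = np.zeros((5, 5), int)
        adj[0, 1:] = adj[1:, 0] = 1
        modules = np.array([0, 0, 0, 0, 1])
        p = participation_coefficient(adj, modules)
        assert p[0] == pytest.approx(1 - (9 / 16 + 1 / 16))

    def test_isolated_node_scores_zero(self):
        adj = np.zeros((3, 3), int)
        adj[0, 1] = adj[1, 0] = 1
        p = participation_coefficient(adj, np.array([0, 0, 1]))
        assert p[2] == 0.0

    def test_bounds_on_random_graphs(self, rng):
        for _ in range(10):
            g = proportional_threshold(random_weights(rng, 15), 0.3)
            mods = modularity_partition(g)
            p = participation_coefficient(g, mods)
            assert np.all(p >= 0.0) and np.all(p <= 1.0)

    def test_partial_partition_rejected(self):
        with pytest.raises(ValueError):
            participation_coefficient(np.zeros((4, 4), int), np.array([0, 1]))


class TestMetricAuc:
    def test_constant_curve(self):
        grid = np.round(np.arange(0.10, 0.401, 0.01), 2)
        assert metric_auc(np.full(grid.size, 5.0), grid) == pytest.approx(1.5)

    def test_linear_curve_triangle_area(self):
        grid = np.array([0.10, 0.40])
        assert metric_auc(np.array([0.0, 6.0]), grid) == pytest.approx(0.9)

    def test_matches_brute_force_trapezoid(self, rng):
        grid = np.sort(rng.uniform(0.1, 0.4, 8))
        grid[0], grid[-1] = 0.1, 0.4
        values = rng.normal(size=(3, 8))
        got = metric_auc(values, grid)
        for node in range(3):
            expected = sum(
                0.5 * (values[node, i] + values[node, i + 1]) * (grid[i + 1] - grid[i])
                for i in range(7)
            )
            assert got[node] == pytest.approx(expected, abs=1e-12)

    def test_nan_metric_names_node_and_density(self):
        grid = np.array([0.1, 0.2, 0.3])
        values = np.array([[1.0, np.nan, 2.0]])
        with pytest.raises(ValueError, match="node 1.*0.20"):
            metric_auc(values, grid)


class TestCriticalRois:
    def test_hand_computed_selection(self):
        table = MetricTable(
            densities=np.array([0.1, 0.4]),
            degree=np.zeros((5, 2)),
            participation=np.zeros((5, 2)),
            auc_degree=np.array([10.0, 1.0, 1.0, 1.0, 1.0]),
            auc_participation=np.array([10.0, 1.0, 1.0, 1.0, 1.0]),
        )
        out = select_critical_rois(table)
        # mean 2.8, sample sd 4.0249..., cutoff 6.8249: only node 1
        assert out.by_degree == [1]
        assert out.stats["mean_k"] == pytest.approx(2.8)
        assert out.stats["sd_k"] == pytest.approx(4.024922, abs=1e-6)
        assert out.intersection == [1]

    def test_all_equal_selects_nothing(self):
        table = MetricTable(
            densities=np.array([0.1, 0.4]),
            degree=np.zeros((4, 2)),
            participation=np.zeros((4, 2)),
            auc_degree=np.full(4, 3.0),
            auc_participation=np.full(4, 3.0),
        )
        out = select_critical_rois(table)
        assert out.by_degree == [] and out.intersection == []

    def test_intersection_is_set_and(self):
        table = MetricTable(
            densities=np.array([0.1, 0.4]),
            degree=np.zeros((4, 2)),
            participation=np.zeros((4, 2)),
            auc_degree=np.array([9.0, 8.0, 0.0, 0.0]),
            auc_participation=np.array([0.0, 8.0, 9.0, 0.0]),
        )
        out = select_critical_rois(table)
        assert out.intersection == sorted(
            set(out.by_degree) & set(out.by_participation)
        )


class TestMetricTablePipeline:
    def test_degree_monotone_in_density(self, rng):
        m = random_weights(rng, 14)
        grid = np.array([0.1, 0.2, 0.3, 0.4])
        table = compute_metric_table(m, grid)
        diffs = np.diff(table.degree, axis=1)
        assert np.all(diffs >= 0)  # denser graphs only add edges

    def test_table_frame_has_auc_columns(self, rng):
        table = compute_metric_table(random_weights(rng, 10), np.array([0.2, 0.3]))
        df = table.to_frame()
        assert {"roi", "auc_k", "auc_p"} <= set(df.columns)
        assert len(df) == 10
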