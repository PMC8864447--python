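"""Grid-graph construction, disjoint shortest paths, and path features."""

import numpy as np
import pytest

from psthcomp import (SyntheticUnitSpec, build_graph, build_psth,
                      component_paths, generate_unit,
                      k_disjoint_shortest_paths, path_features,
                      path_rate_correlation, timing_regression)

from _oracles import enumerate_min_path_cost


class TestBuildGraph:
    def test_edge_weight_is_max_over_rate(self, make_psth):
        rates = np.array([[10.0, 50.0], [20.0, 5.0]])
        g = build_graph(make_psth(rates))
        # every in-edge of a vertex carries that vertex's weight
        assert g[(1, 1)][(1, 2)]["weight"] == pytest.approx(1.0)    # max vertex
        assert g[(1, 2)][(1, 1)]["weight"] == pytest.approx(5.0)    # 50/10
        assert g[(1, 1)][(2, 2)]["weight"] == pytest.approx(10.0)   # 50/5

    def test_zero_rate_vertex_gets_floored_weight(self, make_psth):
        rates = np.array([[0.0, 50.0], [20.0, 5.0]])
        g = build_graph(make_psth(rates), epsilon=1e-3)
        assert g[(1, 2)][(1, 1)]["weight"] == pytest.approx(50.0 / 1e-3)

    def test_neighbourhood_structure(self, make_psth):
        g = build_graph(make_psth(np.ones((3, 4))))
        preds = set(g.predecessors((2, 2)))
        assert preds == {(1, 1), (1, 2), (1, 3), (2, 1), (2, 3),
                         (3, 1), (3, 2), (3, 3)}
        assert set(g.successors("start")) == {(1, t) for t in range(1, 5)}
        assert all(g.has_edge((3, t), "goal") for t in range(1, 5))
        assert g[(3, 1)]["goal"]["weight"] == 0.0

    def test_bright_column_attracts_path(self, make_psth):
        rates = np.ones((3, 3))
        rates[:, 1] = 100.0
        paths = k_disjoint_shortest_paths(build_graph(make_psth(rates)), k=1)
        assert [t for _, t in paths[0].vertices] == [2, 2, 2]

    def test_too_small_matrix_rejected(self, make_psth):
        with pytest.raises(ValueError):
            build_graph(make_psth(np.ones((1, 50))))


class TestDisjointPaths:
    def test_uniform_grid_cost_equals_row_count(self, make_psth):
        rates = np.full((3, 4), 20.0)
        g = build_graph(make_psth(rates))
        paths = k_disjoint_shortest_paths(g, k=1)
        # all weights 1: the cheapest path takes one vertex per row
        assert paths[0].total_weight == pytest.approx(3.0)
        weights = rates.max() / rates
        assert enumerate_min_path_cost(weights.tolist()) == pytest.approx(3.0)

    def test_two_bright_columns_give_disjoint_ranks(self, make_psth):
        rates = np.ones((4, 20))
        rates[:, 4] = 100.0
        rates[:, 14] = 90.0
        paths = k_disjoint_shortest_paths(build_graph(make_psth(rates)), k=2)
        assert len(paths) == 2
        assert {t for _, t in paths[0].vertices} == {5}
        assert {t for _, t in paths[1].vertices} == {15}
        assert not (set(paths[0].vertices) & set(paths[1].vertices))

    def test_small_grid_exhausts_before_k(self, make_psth):
        paths = k_disjoint_shortest_paths(
            build_graph(make_psth(np.ones((2, 2)))), k=3)
        assert 0 < len(paths) < 3

    def test_all_zero_unit_has_no_paths(self, make_psth):
        assert component_paths(make_psth(np.zeros((3, 10)))) == []

    def test_dijkstra_matches_bruteforce_on_random_grids(self, make_psth):
        rng = np.random.default_rng(101)
        for _ in range(25):
            z_n = rng.integers(2, 5)
            b_n = rng.integers(2, 7)
            rates = rng.uniform(0.5, 100.0, size=(z_n, b_n))
            psth = make_psth(rates)
            g = build_graph(psth)
            paths = k_disjoint_shortest_paths(g, k=3)
            weights = (rates.max() / rates).tolist()
            assert paths[0].total_weight == \
                pytest.approx(enumerate_min_path_cost(weights))
            for i in range(len(paths)):
                for j in range(i + 1, len(paths)):
                    assert not (set(paths[i].vertices)
                                & set(paths[j].vertices))

    def test_raising_nonpath_vertex_rate_never_raises_cost(self, make_psth):
        rng = np.random.default_rng(55)
        rates = rng.uniform(1.0, 50.0, size=(3, 8))
        base = k_disjoint_shortest_paths(build_graph(make_psth(rates)), k=1)
        on_path = set(base[0].vertices)
        r_max = rates.max()
        for z in range(3):
            for t in range(8):
                if (z + 1, t + 1) in on_path:
                    continue
                bumped = rates.copy()
                bumped[z, t] = min(bumped[z, t] * 1.5, r_max)  # keep R_max fixed
                new = k_disjoint_shortest_paths(
                    build_graph(make_psth(bumped)), k=1)
                assert new[0].total_weight <= base[0].total_weight + 1e-9


class TestPathFeatures:
    def test_stationary_ridge(self, make_psth):
        rates = np.ones((10, 30))
        rates[:, 13] = 80.0
        p, = component_paths(make_psth(rates), k=1)
        assert p.median_time_bin == 14
        assert p.nonstationarity_ms == 0.0

    def test_diagonal_path_nonstationarity(self, make_psth):
        rates = np.ones((10, 30))
        for z in range(10):
            rates[z, z + 9] = 80.0  # t = z + 10 (1-based)
        p, = component_paths(make_psth(rates), k=1)
        assert p.nonstationarity_ms == 9.0
        assert [t for _, t, _ in p.per_row] == list(range(10, 20))

    def test_lattice_shift_quarter_bin_per_row(self, make_psth):
        rates = np.ones((10, 30))
        for z in range(10):
            rates[z, 14 - int(np.floor(0.25 * z))] = 80.0
        p, = component_paths(make_psth(rates), k=1)
        assert p.nonstationarity_ms == 2.0

    def test_per_row_rates_recover_programmed_slope_sign(self):
        spec = SyntheticUnitSpec("u", "IV", "sham", "contact", 1, [15.0],
                                 [60.0], [8.0], [0.0], baseline_rate=0.0,
                                 n_intensities=10, n_trials=50, seed=8)
        raster, _ = generate_unit(spec)
        p = component_paths(build_psth(raster), k=1)[0]
        res = timing_regression([z for z, _, _ in p.per_row],
                                [r for _, _, r in p.per_row])
        assert res.slope > 0
        assert res.p_value < 0.05

    def test_empty_path_rejected(self, make_psth):
        from psthcomp import ComponentPath
        with pytest.raises(ValueError):
            path_features(ComponentPath([], 0.0, 1), make_psth(np.ones((2, 2))))


class TestPathRateCorrelation:
    def _path_with_rates(self, rates_by_row):
        from psthcomp import ComponentPath
        p = ComponentPath([(z, 1) for z in rates_by_row], 0.0, 1)
        p.per_row = [(z, 1, r) for z, r in rates_by_row.items()]
        return p

    def test_identical_paths_fully_correlated(self):
        a = self._path_with_rates({z: float(z * 2 + 1) for z in range(1, 11)})
        r, p, ok = path_rate_correlation(a, a)
        assert ok and r == pytest.approx(1.0)

    def test_opposing_profiles_anticorrelated(self):
        a = self._path_with_rates({z: float(z) for z in range(1, 11)})
        b = self._path_with_rates({z: float(11 - z) for z in range(1, 11)})
        r, p, ok = path_rate_correlation(a, b)
        assert ok and r == pytest.approx(-1.0)

    def test_too_few_shared_rows_not_computable(self):
        a = self._path_with_rates({1: 1.0, 2: 2.0})
        b = self._path_with_rates({1: 2.0, 2: 1.0})
        assert path_rate_correlation(a, b)[2] is False

    def test_opposing_programmed_slopes_detected(self):
        """Two components with opposite intensity dependence yield a
        negative rank-1/rank-2 rate correlation in most replicates.

        With only 10 intensity rows the Pearson test is underpowered
        (|r| > 0.63 is needed for significance), so the property checked
        is the sign, plus a bound on the mean correlation.
        """
        rs = []
        n_rep = 40
        for rep in range(n_rep):
            spec = SyntheticUnitSpec(
                "u", "IV", "sham", "contact", 2, [12.0, 26.0],
                [60.0, 105.0], [5.0, -5.0], [0.0, 0.0], baseline_rate=0.0,
                n_intensities=10, n_trials=200, seed=2000 + rep)
            raster, _ = generate_unit(spec)
            paths = component_paths(build_psth(raster), k=2)
            assert len(paths) == 2
            r, p, ok = path_rate_correlation(paths[0], paths[1])
            assert ok
            rs.append(r)
        assert np.mean([r < 0 for r in rs]) >= 0.8
        assert np.mean(rs) < -0.3
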