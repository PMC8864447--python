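"""Local-maxima detection, the 25% isolation filter, and iterative merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psthcomp import (CellSpec, PopulationSpec, build_psth, classify_count,
                      filter_maxima, generate_population, local_maxima,
                      merge_maxima, unit_components)

from _oracles import merge_oracle


def _row(length=50, **bins):
    r = np.zeros(length)
    for b, v in bins.items():
        r[int(b[1:]) - 1] = v
    return r


class TestLocalMaxima:
    def test_flat_input_has_none(self):
        assert local_maxima(np.zeros(50)) == []
        assert local_maxima(np.full(50, 7.0)) == []

    def test_single_spike_bin(self):
        assert local_maxima(_row(b3=5)) == [3]

    def test_plateau_median(self):
        r = np.zeros(50)
        r[1:4] = 4.0  # bins 2-4
        assert local_maxima(r) == [3]

    def test_even_plateau_lower_median(self):
        r = np.zeros(50)
        r[1:5] = 4.0  # bins 2-5 -> lower median bin 3
        assert local_maxima(r) == [3]

    def test_endpoints_never_maxima(self):
        r = np.zeros(50)
        r[0] = 9.0
        r[-1] = 9.0
        assert local_maxima(r) == []

    def test_plateau_touching_edge_not_maximum(self):
        r = np.zeros(50)
        r[:3] = 4.0
        assert local_maxima(r) == []


class TestFilterMaxima:
    def test_weak_isolated_maximum_removed(self):
        r = _row(b10=100, b30=20)
        assert filter_maxima([10, 30], r) == [10]

    def test_weak_maximum_with_active_neighbor_kept(self):
        r = _row(b10=100, b30=20, b31=5)
        assert filter_maxima([10, 30], r) == [10, 30]

    def test_maximum_at_row_max_always_kept(self):
        r = _row(b10=100)
        assert filter_maxima([10], r) == [10]

    def test_threshold_is_strict(self):
        # exactly 25% of max is not "< 25%" and survives
        r = _row(b10=100, b30=25)
        assert filter_maxima([10, 30], r) == [10, 30]


class TestMergeMaxima:
    def test_distant_maxima_untouched(self):
        assert merge_maxima([10, 30]) == [10, 30]

    def test_single_merge_lower_median(self):
        assert merge_maxima([10, 12, 30]) == [11, 30]

    def test_iterative_nearest_pair_first(self):
        # (13,15) -> 14, then (10,14) -> 12
        assert merge_maxima([10, 13, 15]) == [12]

    def test_gap_is_inclusive(self):
        assert merge_maxima([10, 15]) == [12]
        assert merge_maxima([10, 16]) == [10, 16]

    def test_idempotent_and_order_invariant(self):
        merged = merge_maxima([4, 9, 11, 30, 33, 41])
        assert merge_maxima(merged) == merged
        assert merge_maxima([41, 30, 9, 4, 33, 11]) == merged
        diffs = np.diff(merged)
        assert np.all(diffs > 5)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(1, 50), min_size=0, max_size=12),
           st.integers(1, 8))
    def test_matches_exhaustive_oracle(self, bins, gap):
        assert merge_maxima(bins, merge_gap=gap) == merge_oracle(bins, gap)


class TestUnitComponents:
    def test_all_zero_psth_is_nonresponder(self, make_psth):
        cs = unit_components(make_psth(np.zeros((5, 50))))
        assert cs.n_components == 0
        assert cs.category == "0"

    def test_pooled_merge_across_intensities(self, make_psth):
        rates = np.zeros((5, 50))
        for z, b in enumerate([10, 11, 12, 11, 10]):
            rates[z, b - 1] = 50.0
        cs = unit_components(make_psth(rates))
        assert cs.component_times == [11]
        assert cs.supports[0] == {1, 2, 3, 4, 5}

    def test_two_programmed_bumps_recovered_exactly(self, make_psth):
        rates = np.zeros((5, 50))
        rates[:, 14] = 80.0   # bin 15
        rates[:, 23] = 60.0   # bin 24, 9 ms apart
        cs = unit_components(make_psth(rates))
        assert cs.component_times == [15, 24]
        assert cs.category == "2"

    def test_min_support_drops_single_intensity_clusters(self, make_psth):
        rates = np.zeros((5, 50))
        rates[:, 14] = 80.0
        rates[0, 39] = 80.0  # maximum in one intensity only
        assert unit_components(make_psth(rates),
                               min_support=1).component_times == [15, 40]
        assert unit_components(make_psth(rates),
                               min_support=2).component_times == [15]

    def test_component_times_within_contributing_range(self, make_psth):
        rng = np.random.default_rng(13)
        for _ in range(20):
            rates = rng.poisson(1.0, size=(4, 50)) * 25.0
            cs = unit_components(make_psth(rates))
            pooled = [b for bins in cs.per_intensity_maxima.values()
                      for b in bins]
            if pooled:
                for t in cs.component_times:
                    assert min(pooled) <= t <= max(pooled)

    def test_pairwise_separation_exceeds_gap(self, make_psth):
        rng = np.random.default_rng(29)
        for _ in range(20):
            rates = rng.poisson(0.8, size=(6, 50)) * 40.0
            cs = unit_components(make_psth(rates))
            assert np.all(np.diff(cs.component_times) > 5)


class TestClassify:
    @pytest.mark.parametrize("n,expected", [(0, "0"), (1, "1"), (2, "2"),
                                            (3, "3plus"), (4, "3plus")])
    def test_categories(self, n, expected):
        assert classify_count(n) == expected


def test_noiseless_population_category_recovery_is_perfect():
    """Baseline 0, sigma 0, components >= 8 ms apart: every programmed
    category is recovered exactly."""
    cells = [CellSpec("II", "sham", n_units=20,
                      proportions=(0.25, 0.25, 0.25, 0.25),
                      timing_sigma=0.0),
             CellSpec("IV", "sham", n_units=20,
                      proportions=(0.25, 0.25, 0.25, 0.25),
                      timing_sigma=0.0)]
    pop = PopulationSpec(cells=cells, baseline_rate=0.0,
                         peak_rate_range=(100.0, 150.0),
                         nonstationarity_range=(0.0, 4.5),
                         master_seed=17)
    rasters, _, units = generate_population(pop)
    truth = units.set_index("unit_id")["category"]
    for raster in rasters:
        cs = unit_components(build_psth(raster))
        assert min(cs.n_components, 3) == int(truth[raster.unit_id]), \
            raster.unit_id
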