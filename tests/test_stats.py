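import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geoaccess import (
    ANY_FACILITY_SCHEME,
    HOSPITAL_SCHEME,
    CutoffScheme,
    GridSpec,
    Raster,
    categorize_map,
    distribution_table,
    proportion_above,
    summarize_access,
    weighted_quantile,
    weighted_quantile_stats,
    wilson_interval,
)
from geoaccess.stats import Z_95


def rasters(times, pops, cell=1000.0):
    times = np.atleast_2d(np.asarray(times, dtype=float))
    pops = np.atleast_2d(np.asarray(pops, dtype=float))
    grid = GridSpec(*times.shape, cell)
    return Raster(grid, times), Raster(grid, pops)


class TestWilsonInterval:
    def test_closed_form_at_zero(self):
        lo, hi = wilson_interval(0.0, 100)
        assert lo == 0.0
        assert hi == pytest.approx(Z_95**2 / (100 + Z_95**2), rel=1e-6)
        assert hi == pytest.approx(0.03700, abs=1e-5)

    def test_closed_form_at_one(self):
        lo, hi = wilson_interval(1.0, 10)
        assert hi == 1.0
        assert lo == pytest.approx(10 / (10 + Z_95**2), rel=1e-6)
        assert lo == pytest.approx(0.72246, abs=1e-5)

    def test_symmetric_at_half(self):
        for n in (5, 50, 500):
            lo, hi = wilson_interval(0.5, n)
            assert lo + hi == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_direct_formula_on_grid(self):
        for p in np.linspace(0, 1, 21):
            for n in (1, 7, 30, 1000, 1e6):
                lo, hi = wilson_interval(p, n)
                z2n = Z_95**2 / n
                center = (p + z2n / 2) / (1 + z2n)
                half = Z_95 * np.sqrt(p * (1 - p) / n + z2n / (4 * n)) / (1 + z2n)
                assert lo == pytest.approx(max(0.0, center - half), abs=1e-12)
                assert hi == pytest.approx(min(1.0, center + half), abs=1e-12)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for count, n in [(3, 10), (0, 25), (25, 25), (417, 1000)]:
            lo, hi = wilson_interval(count / n, n, z=1.959963985)
            ref_lo, ref_hi = proportion_confint(count, n, alpha=0.05, method="wilson")
            assert lo == pytest.approx(ref_lo, abs=1e-9)
            assert hi == pytest.approx(ref_hi, abs=1e-9)

    @given(p=st.floats(0, 1), n=st.integers(1, 10**6))
    @settings(max_examples=200, derandomize=True)
    def test_always_contains_p_hat(self, p, n):
        lo, hi = wilson_interval(p, n)
        assert lo <= p <= hi

    def test_converges_to_point_mass_as_n_grows(self):
        lo, hi = wilson_interval(0.37, 1e8)
        assert hi - lo < 1e-3

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(0.5, 0)
        with pytest.raises(ValueError):
            wilson_interval(1.5, 10)


class TestProportionAbove:
    def test_direct_weighted_count(self):
        tt, pop = rasters([30.0, 400.0, 100.0], [10.0, 20.0, 70.0])
        est = proportion_above(tt, pop, 360.0)
        assert est.p_hat == pytest.approx(0.20)

    def test_all_below_cutoff_gives_zero(self):
        tt, pop = rasters([30.0, 40.0], [5.0, 5.0])
        assert proportion_above(tt, pop, 360.0).p_hat == 0.0

    def test_unreachable_counts_above_any_cutoff(self):
        tt, pop = rasters([np.inf, 10.0, 10.0], [5.0, 25.0, 20.0])
        assert proportion_above(tt, pop, 720.0).p_hat == pytest.approx(0.10)

    def test_non_increasing_in_cutoff(self):
        rng = np.random.default_rng(1)
        tt, pop = rasters(rng.uniform(0, 800, (5, 5)), rng.uniform(0, 10, (5, 5)))
        props = [proportion_above(tt, pop, c).p_hat for c in (60, 120, 360, 720)]
        assert all(a >= b for a, b in zip(props, props[1:]))

    def test_explicit_effective_n_controls_the_interval(self):
        tt, pop = rasters([30.0, 400.0], [50.0, 50.0])
        wide = proportion_above(tt, pop, 360.0, ci_n=10)
        narrow = proportion_above(tt, pop, 360.0, ci_n=10_000)
        assert wide.ci_high - wide.ci_low > narrow.ci_high - narrow.ci_low
        assert wide.ci_low <= wide.p_hat <= wide.ci_high

    def test_zero_population_rejected(self):
        tt, pop = rasters([30.0], [0.0])
        with pytest.raises(ValueError):
            proportion_above(tt, pop, 60.0)


class TestWeightedQuantiles:
    def test_top_fifth_of_uniform_1_to_100(self):
        """Unit weights on 1..100: the worst fifth is 81..100, median 90.5.

        Expected values brute-forced from the enumerated list with the
        midpoint convention: median of 81..100 is (90+91)/2, quartiles
        interpolate to 85.5 and 95.5.
        """
        times = np.arange(1, 101, dtype=float).reshape(10, 10)
        tt, pop = rasters(times, np.ones((10, 10)))
        med, (q1, q3) = weighted_quantile_stats(tt, pop, (0.8, 1.0))
        assert med == pytest.approx(90.5)
        assert (q1, q3) == (pytest.approx(85.5), pytest.approx(95.5))

    def test_degenerate_distribution(self):
        tt, pop = rasters(np.full((3, 3), 42.0), np.ones((3, 3)))
        med, (q1, q3) = weighted_quantile_stats(tt, pop)
        assert med == q1 == q3 == 42.0

    def test_scale_invariance_in_weights(self):
        rng = np.random.default_rng(5)
        t = rng.uniform(0, 500, (6, 6))
        w = rng.uniform(0.1, 9, (6, 6))
        tt, pop = rasters(t, w)
        tt2, pop2 = rasters(t, 2 * w)
        assert weighted_quantile_stats(tt, pop) == weighted_quantile_stats(tt2, pop2)

    def test_weight_splitting_matches_fine_grained_enumeration(self):
        # one heavy cell straddles the 80% boundary; replicate it as many
        # unit-weight cells and compare
        t = np.array([[10.0, 20.0, 30.0, 40.0]])
        w = np.array([[4.0, 4.0, 4.0, 8.0]])
        tt, pop = rasters(t, w)
        t_fine = np.repeat(t.ravel(), (4, 4, 4, 8)).reshape(4, 5)
        tt_f, pop_f = rasters(t_fine, np.ones((4, 5)))
        med, (q1, q3) = weighted_quantile_stats(tt, pop)
        med_f, (q1_f, q3_f) = weighted_quantile_stats(tt_f, pop_f)
        assert (med, q1, q3) == pytest.approx((med_f, q1_f, q3_f))

    def test_unreachable_band_reported_as_unreachable(self):
        t = np.array([[10.0, 20.0, np.inf, np.inf, np.inf]])
        w = np.ones((1, 5))
        tt, pop = rasters(t, w)
        med, (q1, q3) = weighted_quantile_stats(tt, pop, (0.8, 1.0))
        assert np.isposinf(med)

    def test_exclude_unreachable_option(self):
        t = np.array([[10.0, 20.0, 30.0, 40.0, np.inf]])
        tt, pop = rasters(t, np.ones((1, 5)))
        med, _ = weighted_quantile_stats(tt, pop, (0.8, 1.0), include_unreachable=False)
        assert np.isfinite(med)

    def test_invalid_band_rejected(self):
        tt, pop = rasters([10.0], [1.0])
        for band in [(0.9, 0.2), (-0.1, 0.5), (0.5, 1.2)]:
            with pytest.raises(ValueError):
                weighted_quantile_stats(tt, pop, band)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, derandomize=True)
    def test_quantiles_are_monotone_and_within_range(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 100, 30)
        w = rng.uniform(0.01, 5, 30)
        qs = weighted_quantile(v, w, [0.1, 0.5, 0.9])
        assert qs[0] <= qs[1] <= qs[2]
        assert v.min() <= qs[0] and qs[2] <= v.max()


class TestCategorizeMap:
    def test_hospital_scheme_boundaries(self):
        tt, pop = rasters([90.0, 120.0, 360.0, 800.0], [2.0, 2.0, 2.0, 2.0])
        cat = categorize_map(tt, pop, HOSPITAL_SCHEME)
        # closed-left bins: exactly 120 min falls in the 2-6h category
        np.testing.assert_array_equal(cat.values, [[0, 1, 2, 3]])

    def test_any_facility_scheme_top_category(self):
        tt, pop = rasters([400.0], [3.0])
        cat = categorize_map(tt, pop, ANY_FACILITY_SCHEME)
        assert cat.values[0, 0] == 3  # >6h

    def test_sparsely_populated_cells_masked(self):
        tt, pop = rasters([50.0, 50.0], [0.5, 1.0])
        cat = categorize_map(tt, pop, HOSPITAL_SCHEME)
        assert np.isnan(cat.values[0, 0]) and cat.values[0, 1] == 0

    def test_unreachable_in_top_category(self):
        tt, pop = rasters([np.inf], [2.0])
        assert categorize_map(tt, pop, HOSPITAL_SCHEME).values[0, 0] == 3

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            CutoffScheme("bad", (120.0, 60.0))
        with pytest.raises(ValueError):
            CutoffScheme("bad", ())

    def test_scheme_labels(self):
        assert HOSPITAL_SCHEME.labels == ["<2h", "2h-6h", "6h-12h", ">12h"]
        assert ANY_FACILITY_SCHEME.labels == ["<1h", "1h-2h", "2h-6h", ">6h"]


class TestDistributionTable:
    def test_all_population_at_time_zero(self):
        tt, pop = rasters([0.0, 0.0], [30.0, 70.0])
        table = distribution_table(tt, pop, bin_width=30.0)
        assert table.population.iloc[0] == 100.0
        assert table.population.iloc[1:].sum() == 0.0

    def test_bin_masses_conserve_population(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(0, 900, (8, 8))
        t[0, :3] = np.inf
        w = rng.uniform(0, 20, (8, 8))
        tt, pop = rasters(t, w)
        table = distribution_table(tt, pop, bin_width=60.0)
        keep = np.isfinite(t) | (w > 0)
        assert table.population.sum() == pytest.approx(w[w > 0].sum())

    def test_unreachable_mass_in_final_open_bin(self):
        tt, pop = rasters([10.0, np.inf], [6.0, 4.0])
        table = distribution_table(tt, pop, bin_width=30.0)
        assert np.isposinf(table.bin_right_min.iloc[-1])
        assert table.population.iloc[-1] == 4.0

    def test_empty_region_yields_zero_total(self):
        tt, pop = rasters([10.0, 20.0], [0.0, 0.0])
        table = distribution_table(tt, pop, bin_width=30.0)
        assert table.population.sum() == 0.0


class TestSummarizeAccess:
    def test_category_shares_sum_to_one(self):
        rng = np.random.default_rng(8)
        tt, pop = rasters(rng.uniform(0, 900, (6, 6)), rng.uniform(0, 50, (6, 6)))
        s = summarize_access(tt, pop, HOSPITAL_SCHEME)[0]
        assert sum(s.category_shares) == pytest.approx(1.0, abs=1e-9)

    def test_per_region_summaries_partition_population(self):
        from shapely.geometry import box

        grid = GridSpec(4, 4, 1000.0)
        tt = Raster(grid, np.full((4, 4), 100.0))
        pop = Raster(grid, np.ones((4, 4)))
        regions = {"west": box(0, -4000, 2000, 0), "east": box(2000, -4000, 4000, 0)}
        out = summarize_access(tt, pop, HOSPITAL_SCHEME, regions=regions)
        assert {s.region for s in out} == {"west", "east"}
        assert sum(s.total_population for s in out) == pytest.approx(16.0)
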