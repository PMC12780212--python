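import math

import numpy as np
import pytest

from hfmap.accessibility import (
    DEFAULT_SPEED_MODEL,
    WATERWAY_SPEEDS,
    TilePlan,
    build_speed_surface,
    extract_sources,
    least_cost_time,
    pixel_crossing_time,
    score_indirect,
    speed_walk_agriculture,
    speed_walk_natural,
    speed_waterway,
    tiled_least_cost,
)
from hfmap.errors import GridMismatchError, HFError
from hfmap.grid import RasterLayer

from conftest import dijkstra_travel_time, make_grid


class TestWalkingSpeeds:
    @pytest.mark.parametrize("slope", [1.0, 4.0, 10.0])
    def test_agriculture_power_law(self, slope):
        expect = 10.560326 * slope ** -0.199553
        assert speed_walk_agriculture(slope) == pytest.approx(expect, rel=1e-12)

    def test_agriculture_at_unit_slope(self):
        assert speed_walk_agriculture(1.0) == pytest.approx(10.560326)

    def test_slope_clamped_below_one_percent(self):
        assert speed_walk_agriculture(0.2) == speed_walk_agriculture(1.0)
        assert speed_walk_natural(0.0) == speed_walk_natural(1.0)

    @pytest.mark.parametrize("slope", [1.0, 4.0, 10.0])
    def test_natural_log_formula(self, slope):
        expect = -0.975931 * math.log(slope) + 6.761258
        assert speed_walk_natural(slope) == pytest.approx(expect, rel=1e-12)

    def test_natural_at_unit_slope_and_flooded_half(self):
        assert speed_walk_natural(1.0) == pytest.approx(6.761258)
        assert speed_walk_natural(1.0, flooded=True) == pytest.approx(3.380629)
        assert speed_walk_natural(10.0) == pytest.approx(4.514, abs=1e-3)

    def test_natural_floored_at_minimum(self):
        # the log formula goes negative around slope 1000%
        assert speed_walk_natural(1e6) == DEFAULT_SPEED_MODEL.min_walk_speed


class TestWaterwaySpeeds:
    # representative slope / elevation inside each band
    SLOPES = [2.0, 7.0, 12.0, 20.0, 30.0]
    ELEVATIONS = [300.0, 500.0, 1000.0, 2000.0, 3000.0]

    @pytest.mark.parametrize("ei", range(5))
    @pytest.mark.parametrize("si", range(5))
    def test_matrix_lookup_matches_printed_speeds(self, ei, si):
        v = speed_waterway(self.SLOPES[si], self.ELEVATIONS[ei])
        assert v == WATERWAY_SPEEDS[ei, si]

    def test_representative_matrix_cells(self):
        assert speed_waterway(2.0, 300.0) == 15.0
        assert speed_waterway(30.0, 3000.0) == 1.2
        assert speed_waterway(12.0, 1000.0) == 2.0

    def test_band_edges_belong_to_upper_band(self):
        # slope exactly 5% falls in the 5-10 band; elevation 450 in 450-700
        assert speed_waterway(5.0, 300.0) == 7.5
        assert speed_waterway(2.0, 450.0) == 7.5


class TestSpeedSurface:
    def _layers(self, n=6):
        grid = make_grid(n, n)
        z = lambda: np.zeros((n, n))
        return grid, z

    def test_road_beats_waterway(self):
        grid, z = self._layers()
        roads = z(); roads[2, 2] = 1
        ww = z(); ww[2, 2] = 1
        speed = build_speed_surface(
            RasterLayer(grid, np.full((6, 6), 4), "categorical"),
            RasterLayer(grid, roads.astype(int), "categorical", 0),
            RasterLayer(grid, ww),
            None,
            RasterLayer(grid, np.full((6, 6), 2.0)),
            RasterLayer(grid, np.full((6, 6), 300.0)),
            agriculture_codes=(4,),
        )
        assert speed.values[2, 2] == 60.0

    def test_bare_agriculture_uses_walk_formula(self):
        grid, z = self._layers()
        speed = build_speed_surface(
            RasterLayer(grid, np.full((6, 6), 4), "categorical"),
            RasterLayer(grid, z().astype(int), "categorical", 0),
            RasterLayer(grid, z()), None,
            RasterLayer(grid, np.full((6, 6), 1.0)),
            RasterLayer(grid, np.full((6, 6), 300.0)),
            agriculture_codes=(4,),
        )
        assert speed.values[0, 0] == pytest.approx(10.560326)

    def test_off_line_water_is_barrier(self):
        grid, z = self._layers()
        lulc = np.full((6, 6), 8)
        ww = z(); ww[3, :] = 1
        speed = build_speed_surface(
            RasterLayer(grid, lulc, "categorical"),
            RasterLayer(grid, z().astype(int), "categorical", 0),
            RasterLayer(grid, ww), None,
            RasterLayer(grid, np.full((6, 6), 2.0)),
            RasterLayer(grid, np.full((6, 6), 300.0)),
            water_codes=(8,),
        )
        assert speed.values[3, 0] == 15.0   # navigable river
        assert speed.values[0, 0] == 0.0    # open water off the line

    def test_matches_rule_by_rule_oracle_on_random_stack(self):
        rng = np.random.default_rng(9)
        n = 15
        grid = make_grid(n, n)
        lulc = rng.choice([1, 2, 3, 4, 8], size=(n, n))
        roads = rng.choice([0, 0, 0, 1, 2, 3], size=(n, n))
        ww = (rng.random((n, n)) < 0.2).astype(float)
        coast = (rng.random((n, n)) < 0.1).astype(float)
        slope = rng.uniform(0, 40, (n, n))
        elev = rng.uniform(0, 4000, (n, n))
        speed = build_speed_surface(
            RasterLayer(grid, lulc, "categorical"),
            RasterLayer(grid, roads, "categorical", 0),
            RasterLayer(grid, ww), RasterLayer(grid, coast),
            RasterLayer(grid, slope), RasterLayer(grid, elev),
            agriculture_codes=(4,), natural_codes=(1, 3), flooded_codes=(2,),
            water_codes=(8,),
        )
        for r in range(n):
            for c in range(n):
                if roads[r, c] == 1:
                    expect = 60.0
                elif roads[r, c] == 2:
                    expect = 40.0
                elif roads[r, c] == 3:
                    expect = 30.0
                elif coast[r, c]:
                    expect = 20.0
                elif ww[r, c]:
                    expect = speed_waterway(slope[r, c], elev[r, c])
                elif lulc[r, c] == 8:
                    expect = 0.0
                elif lulc[r, c] == 4:
                    expect = speed_walk_agriculture(slope[r, c])
                elif lulc[r, c] == 2:
                    expect = speed_walk_natural(slope[r, c], flooded=True)
                else:
                    expect = speed_walk_natural(slope[r, c])
                assert speed.values[r, c] == pytest.approx(float(expect)), (r, c)

    def test_grid_mismatch_rejected(self):
        g1, g2 = make_grid(4, 4), make_grid(5, 5)
        with pytest.raises(GridMismatchError):
            build_speed_surface(
                RasterLayer.zeros(g1, "categorical"),
                RasterLayer.zeros(g2, "categorical"),
                RasterLayer.zeros(g1), None,
                RasterLayer.zeros(g1), RasterLayer.zeros(g1),
            )


class TestCrossingTime:
    def test_anchor_speeds(self):
        grid = make_grid(1, 3)
        speed = RasterLayer(grid, np.array([[60.0, 15.0, 1e9]]))
        t = pixel_crossing_time(speed)
        assert t.values[0, 0] == pytest.approx(0.0005)
        assert t.values[0, 1] == pytest.approx(0.002)
        assert t.values[0, 2] == pytest.approx(0.0, abs=1e-10)

    def test_zero_speed_is_infinite_cost(self):
        grid = make_grid(1, 1)
        t = pixel_crossing_time(RasterLayer(grid, np.array([[0.0]])))
        assert np.isinf(t.values[0, 0])

    def test_negative_speed_rejected(self):
        grid = make_grid(1, 1)
        with pytest.raises(HFError):
            pixel_crossing_time(RasterLayer(grid, np.array([[-5.0]])))


class TestExtractSources:
    def test_isolated_pixel_leaves_no_sources(self):
        grid = make_grid(5, 5)
        vals = np.zeros((5, 5), int); vals[2, 2] = 1
        with pytest.raises(HFError, match="no built-environment cluster"):
            extract_sources(RasterLayer(grid, vals, "categorical"))

    def test_two_pixel_cluster_retained_diagonally(self):
        grid = make_grid(5, 5)
        vals = np.zeros((5, 5), int); vals[1, 1] = vals[2, 2] = 1
        src = extract_sources(RasterLayer(grid, vals, "categorical"))
        assert src.values.sum() == 2

    def test_mixed_field_matches_cluster_size_rule(self):
        rng = np.random.default_rng(2)
        grid = make_grid(20, 20)
        vals = (rng.random((20, 20)) < 0.15).astype(int)
        vals[0, 0] = vals[0, 1] = 1  # guarantee one valid cluster
        src = extract_sources(RasterLayer(grid, vals, "categorical"))
        from scipy import ndimage
        labels, n = ndimage.label(vals, structure=np.ones((3, 3), int))
        keep = np.zeros_like(vals, bool)
        for k in range(1, n + 1):
            if (labels == k).sum() >= 2:
                keep |= labels == k
        np.testing.assert_array_equal(src.values.astype(bool), keep)


class TestLeastCostTime:
    def test_uniform_cost_rook_distance(self):
        grid = make_grid(7, 7)
        cost = RasterLayer(grid, np.full((7, 7), 0.01))
        src = np.zeros((7, 7), int); src[0, 0] = src[0, 1] = 1
        tt = least_cost_time(cost, RasterLayer(grid, src, "categorical"))
        assert tt.hours[0, 0] == 0.0
        # from source edge: half-cost first step (source pixel costs 0)
        assert tt.hours[0, 2] == pytest.approx(0.005)
        assert tt.hours[3, 1] == pytest.approx(0.005 + 2 * 0.01)

    def test_matches_dijkstra_oracle_on_random_grid(self):
        rng = np.random.default_rng(17)
        grid = make_grid(20, 20)
        cost = rng.uniform(0.001, 0.05, (20, 20))
        src = np.zeros((20, 20), int)
        src[3, 4] = src[3, 5] = src[15, 12] = src[16, 12] = 1
        tt = least_cost_time(
            RasterLayer(grid, cost), RasterLayer(grid, src, "categorical")
        )
        oracle = dijkstra_travel_time(cost, src.astype(bool))
        np.testing.assert_allclose(tt.hours, oracle, rtol=1e-10)

    def test_zero_cost_corridor_never_increases_times(self):
        rng = np.random.default_rng(8)
        grid = make_grid(15, 15)
        cost = rng.uniform(0.01, 0.1, (15, 15))
        src = np.zeros((15, 15), int); src[0, 0] = src[0, 1] = 1
        base = least_cost_time(
            RasterLayer(grid, cost), RasterLayer(grid, src, "categorical")
        ).hours
        road = cost.copy(); road[7, :] = 1e-6
        faster = least_cost_time(
            RasterLayer(grid, road), RasterLayer(grid, src, "categorical")
        ).hours
        assert (faster <= base + 1e-12).all()

    def test_relaxation_property(self):
        rng = np.random.default_rng(21)
        grid = make_grid(12, 12)
        cost = rng.uniform(0.001, 0.05, (12, 12))
        src = np.zeros((12, 12), int); src[5, 5] = src[5, 6] = 1
        tt = least_cost_time(
            RasterLayer(grid, cost), RasterLayer(grid, src, "categorical")
        )
        c = cost.copy(); c[src.astype(bool)] = 0.0
        h = tt.hours
        for dr, dc in ((0, 1), (1, 0)):
            a = h[max(dr, 0): h.shape[0] if dr == 0 else None, max(dc, 0):]
            step = (c[:-dr or None, :-dc or None] + c[dr:, dc:]) / 2
            assert (h[dr:, dc:] <= h[:-dr or None, :-dc or None] + step + 1e-12).all()
            assert (h[:-dr or None, :-dc or None] <= h[dr:, dc:] + step + 1e-12).all()

    def test_barriers_leave_unreachable_pixels_infinite(self):
        grid = make_grid(3, 3)
        cost = np.full((3, 3), 0.01)
        cost[:, 1] = np.inf
        src = np.zeros((3, 3), int); src[0, 0] = src[1, 0] = 1
        tt = least_cost_time(
            RasterLayer(grid, cost), RasterLayer(grid, src, "categorical")
        )
        assert np.isinf(tt.hours[:, 2]).all()

    def test_empty_sources_rejected(self):
        grid = make_grid(3, 3)
        with pytest.raises(HFError):
            least_cost_time(
                RasterLayer(grid, np.full((3, 3), 0.01)),
                RasterLayer.zeros(grid, "categorical"),
            )


class TestTiledLeastCost:
    def _random_problem(self, n, seed):
        rng = np.random.default_rng(seed)
        grid = make_grid(n, n)
        cost = RasterLayer(grid, rng.uniform(0.001, 0.05, (n, n)))
        src = np.zeros((n, n), int)
        src[2, 2] = src[2, 3] = 1
        src[n - 3, n - 4] = src[n - 3, n - 3] = 1
        return cost, RasterLayer(grid, src, "categorical")

    def test_single_tile_identical_to_untiled(self):
        cost, src = self._random_problem(20, 4)
        untiled = least_cost_time(cost, src).hours
        tiled = tiled_least_cost(cost, src, TilePlan(1, 1, 0)).hours
        np.testing.assert_array_equal(tiled, untiled)

    def test_full_overlap_equals_untiled(self):
        cost, src = self._random_problem(40, 5)
        untiled = least_cost_time(cost, src).hours
        tiled = tiled_least_cost(cost, src, TilePlan(2, 2, 40)).hours
        np.testing.assert_allclose(tiled, untiled, rtol=1e-12)

    def test_small_overlap_never_underestimates(self):
        cost, src = self._random_problem(40, 6)
        untiled = least_cost_time(cost, src).hours
        tiled = tiled_least_cost(cost, src, TilePlan(2, 2, 3)).hours
        assert (tiled >= untiled - 1e-12).all()

    def test_noncovering_plan_rejected(self):
        cost, src = self._random_problem(10, 7)
        plan = TilePlan(1, 1, 0)
        bad_tiles = lambda shape: iter([(slice(0, 5), slice(0, 5))])
        object.__setattr__(plan, "tiles", bad_tiles)
        with pytest.raises(HFError, match="cover"):
            tiled_least_cost(cost, src, plan)


class TestScoreIndirect:
    def _tt(self, hours):
        from hfmap.accessibility import TravelTimeSurface
        grid = make_grid(1, len(hours))
        arr = np.array([hours], dtype=float)
        return TravelTimeSurface(grid, arr, arr == 0)

    def test_source_scores_four_and_horizon_zero(self):
        tt = self._tt([0.0, 2.0, 4.0, 5.0, np.inf])
        out = score_indirect(tt)
        assert out.values[0, 0] == pytest.approx(4.0)
        assert out.values[0, 1] == pytest.approx(4 / math.sqrt(40))  # ~0.632
        assert out.values[0, 2] == pytest.approx(0.1)  # floor at the horizon
        assert out.values[0, 3] == 0.0
        assert out.values[0, 4] == 0.0  # unreachable scores zero

    def test_range_and_source_only_maximum(self, pipe):
        ind = pipe.pressures["IND"].raster.values
        assert ind.min() >= 0.0
        assert ind.max() <= 4.0 + 1e-12
        at_max = np.argwhere(ind >= 4.0 - 1e-9)
        hours = pipe.travel_hours
        for r, c in at_max:
            assert hours[r, c] == 0.0
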