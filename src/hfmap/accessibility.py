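"""Indirect human pressure from accessibility.

Routine human influence (hunting, selective logging, gathering) reaches far
beyond mapped infrastructure.  It is modelled here as travel time from
inhabited built-environment clusters over a friction surface:

1. a per-pixel speed surface is assembled from precedence-ordered rules —
   roads (primary 60, secondary 40, tertiary 30 km/h), coastal navigation
   (20 km/h), river/lake navigation (a slope × elevation matrix), walking on
   agricultural land and walking through natural vegetation (slope-dependent,
   halved when flooded);
2. speed becomes a pixel-crossing time (hours per 30 m step); water off any
   navigable line is an impassable barrier;
3. multi-source least-cost travel time is computed from built-environment
   clusters of at least two pixels (single pixels are treated as artifacts,
   not habitation), moving horizontally or vertically, each step costing the
   mean of the two pixels' crossing times; source pixels cost nothing;
4. travel time is scored with an exponential decay from 4 at the source to
   zero beyond the 4-hour routine-travel horizon.

For national extents that exceed memory the computation tiles the grid with
wide overlaps and mosaics tiles by pixelwise minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.graph import MCP_Geometric

from .errors import GridMismatchError, HFError
from .grid import GridSpec, RasterLayer, connected_clusters
from .scoring import decay_score

ROAD_PRIMARY, ROAD_SECONDARY, ROAD_TERTIARY = 1, 2, 3

#: navigable-waterway speeds (km/h), rows = elevation bands (m), cols = slope bands (%)
WATERWAY_SPEEDS = np.array(
    [
        # slope:  <5    5-10  10-15 15-25  >25
        [15.0, 7.5, 3.8, 1.9, 1.4],  # elevation < 450 m
        [7.5, 3.9, 2.7, 1.9, 1.4],  # 450–700 m
        [3.8, 2.7, 2.0, 1.7, 1.4],  # 700–1800 m
        [1.9, 1.9, 1.7, 1.4, 1.3],  # 1800–2800 m
        [1.4, 1.4, 1.4, 1.3, 1.2],  # > 2800 m
    ]
)
WATERWAY_SLOPE_BREAKS = (5.0, 10.0, 15.0, 25.0)
WATERWAY_ELEVATION_BREAKS = (450.0, 700.0, 1800.0, 2800.0)


@dataclass(frozen=True)
class SpeedModel:
    """Precedence-ordered speed rules (all speeds km/h).

    Precedence is fixed: roads > coastline > waterways > agriculture walking
    > natural-vegetation walking.  Walking speeds were fitted to tracking
    data; slope (percent rise) is clamped to ≥ ``slope_clamp`` before the
    formulas are evaluated and natural-walking speed is floored at
    ``min_walk_speed``.
    """

    road_speeds: tuple[float, float, float] = (60.0, 40.0, 30.0)
    coastline_speed: float = 20.0
    waterway_matrix: tuple = tuple(map(tuple, WATERWAY_SPEEDS))
    agri_coeff: float = 10.560326
    agri_exponent: float = -0.199553
    natural_log_coeff: float = -0.975931
    natural_intercept: float = 6.761258
    flooded_divisor: float = 2.0
    slope_clamp: float = 1.0
    min_walk_speed: float = 0.1

    def waterway_array(self) -> np.ndarray:
        return np.asarray(self.waterway_matrix, dtype=float)


DEFAULT_SPEED_MODEL = SpeedModel()


def speed_walk_agriculture(slope_pct, model: SpeedModel = DEFAULT_SPEED_MODEL):
    """Walking speed on agricultural land: ``a · slope^b`` (power law)."""
    s = np.maximum(np.asarray(slope_pct, dtype=float), model.slope_clamp)
    return model.agri_coeff * s ** model.agri_exponent


def speed_walk_natural(slope_pct, flooded=False, model: SpeedModel = DEFAULT_SPEED_MODEL):
    """Walking speed through natural vegetation: ``c · ln(slope) + d``,
    halved when the terrain is flooded, floored at ``min_walk_speed``."""
    s = np.maximum(np.asarray(slope_pct, dtype=float), model.slope_clamp)
    v = model.natural_log_coeff * np.log(s) + model.natural_intercept
    v = np.where(np.asarray(flooded, dtype=bool), v / model.flooded_divisor, v)
    return np.maximum(v, model.min_walk_speed)


def speed_waterway(slope_pct, elevation_m, model: SpeedModel = DEFAULT_SPEED_MODEL):
    """Navigation speed on rivers and lakes from the slope × elevation matrix."""
    si = np.digitize(np.asarray(slope_pct, dtype=float), WATERWAY_SLOPE_BREAKS)
    ei = np.digitize(np.asarray(elevation_m, dtype=float), WATERWAY_ELEVATION_BREAKS)
    return model.waterway_array()[ei, si]


def build_speed_surface(
    lulc: RasterLayer,
    roads: RasterLayer,
    waterways: RasterLayer,
    coastline: RasterLayer | None,
    slope: RasterLayer,
    elevation: RasterLayer,
    model: SpeedModel = DEFAULT_SPEED_MODEL,
    agriculture_codes: tuple[int, ...] = (),
    natural_codes: tuple[int, ...] = (),
    flooded_codes: tuple[int, ...] = (),
    water_codes: tuple[int, ...] = (),
) -> RasterLayer:
    """Per-pixel speed (km/h) by the first applicable rule in precedence order.

    ``roads`` carries class codes 1/2/3 (primary/secondary/tertiary);
    ``waterways`` and ``coastline`` are presence rasters of navigable lines.
    Water pixels not on a navigable line come out 0 km/h — impassable.
    Pixels matching none of the rules (e.g. bare or urban singletons) default
    to agricultural walking.
    """
    for layer in (roads, waterways, slope, elevation) + ((coastline,) if coastline else ()):
        if layer.grid != lulc.grid:
            raise GridMismatchError("all accessibility inputs must share one grid")

    shape = lulc.grid.shape
    speed = np.zeros(shape, dtype=float)
    assigned = np.zeros(shape, dtype=bool)

    def apply(mask: np.ndarray, value) -> None:
        sel = mask & ~assigned
        speed[sel] = np.broadcast_to(value, shape)[sel] if np.ndim(value) else value
        assigned[sel] = True

    for code, v in zip((ROAD_PRIMARY, ROAD_SECONDARY, ROAD_TERTIARY), model.road_speeds):
        apply(roads.values == code, v)
    if coastline is not None:
        apply((coastline.values > 0) & ~coastline.nodata_mask, model.coastline_speed)
    apply(
        (waterways.values > 0) & ~waterways.nodata_mask,
        speed_waterway(slope.values, elevation.values, model),
    )
    # off-line water is a barrier: claim it before the walking rules
    water = np.isin(lulc.values, water_codes)
    apply(water, 0.0)
    apply(
        np.isin(lulc.values, agriculture_codes),
        speed_walk_agriculture(slope.values, model),
    )
    flooded = np.isin(lulc.values, flooded_codes)
    apply(
        np.isin(lulc.values, natural_codes) | flooded,
        speed_walk_natural(slope.values, flooded, model),
    )
    # fallback for anything unclassified
    apply(~assigned, speed_walk_agriculture(slope.values, model))
    return RasterLayer(lulc.grid, speed, "continuous")


def pixel_crossing_time(speed: RasterLayer, pixel_size: float | None = None) -> RasterLayer:
    """Hours to traverse one pixel horizontally or vertically.

    Zero speed encodes a barrier and maps to infinite cost; negative speeds
    are rejected.
    """
    v = np.asarray(speed.values, dtype=float)
    if np.any(v[~speed.nodata_mask] < 0):
        raise HFError("speeds must be non-negative")
    ps_km = (pixel_size if pixel_size is not None else speed.grid.pixel_size) / 1000.0
    with np.errstate(divide="ignore"):
        t = np.where(v > 0, ps_km / np.where(v > 0, v, 1.0), np.inf)
    t[speed.nodata_mask] = np.inf
    return speed.with_values(t, nodata=-1.0)


def extract_sources(built_env: RasterLayer, min_cluster: int = 2) -> RasterLayer:
    """Keep 8-connected built-environment clusters of at least ``min_cluster``
    pixels as accessibility sources; drop singletons (likely artifacts)."""
    labels, sizes = connected_clusters(built_env, connectivity=8)
    keep = np.flatnonzero(sizes >= min_cluster) + 1
    mask = np.isin(labels.values, keep)
    if not mask.any():
        raise HFError(
            f"no built-environment cluster reaches {min_cluster} pixels; "
            "no accessibility sources"
        )
    return RasterLayer(built_env.grid, mask.astype(np.uint8), "categorical", nodata=255)


@dataclass
class TravelTimeSurface:
    """Hours of least-cost travel from the nearest source; inf = unreachable."""

    grid: GridSpec
    hours: np.ndarray
    sources: np.ndarray

    def __post_init__(self) -> None:
        self.hours = np.asarray(self.hours, dtype=float)
        self.sources = np.asarray(self.sources, dtype=bool)
        if self.hours.shape != self.grid.shape or self.sources.shape != self.grid.shape:
            raise HFError("travel-time arrays must match the grid shape")


def least_cost_time(cost: RasterLayer, sources: RasterLayer) -> TravelTimeSurface:
    """Multi-source least-cost travel time over 4-connected moves.

    ``cost`` holds per-pixel crossing times (hours); each step costs the mean
    of the two pixels' crossing times.  Source pixels traverse at no cost and
    start at time 0.
    """
    cost.require_same_grid(sources)
    src = (sources.values != 0) & ~sources.nodata_mask
    if not src.any():
        raise HFError("least_cost_time requires at least one source pixel")
    c = np.asarray(cost.values, dtype=float).copy()
    if np.any(c[~src] < 0):
        raise HFError("crossing times must be non-negative")
    c[src] = 0.0  # inhabited pixels cost nothing to traverse
    mcp = MCP_Geometric(c, fully_connected=False)
    hours, _ = mcp.find_costs(np.argwhere(src))
    return TravelTimeSurface(cost.grid, hours, src)


@dataclass(frozen=True)
class TilePlan:
    """Split the grid into ``n_tile_rows × n_tile_cols`` tiles whose cores
    partition the grid, each expanded by ``overlap_pixels`` on every side."""

    n_tile_rows: int
    n_tile_cols: int
    overlap_pixels: int

    def tiles(self, shape: tuple[int, int]):
        n_rows, n_cols = shape
        row_edges = np.linspace(0, n_rows, self.n_tile_rows + 1).astype(int)
        col_edges = np.linspace(0, n_cols, self.n_tile_cols + 1).astype(int)
        for i in range(self.n_tile_rows):
            for j in range(self.n_tile_cols):
                r0 = max(0, row_edges[i] - self.overlap_pixels)
                r1 = min(n_rows, row_edges[i + 1] + self.overlap_pixels)
                c0 = max(0, col_edges[j] - self.overlap_pixels)
                c1 = min(n_cols, col_edges[j + 1] + self.overlap_pixels)
                yield slice(r0, r1), slice(c0, c1)


def tiled_least_cost(
    cost: RasterLayer, sources: RasterLayer, plan: TilePlan
) -> TravelTimeSurface:
    """Least-cost travel time computed per overlapping tile, mosaicked by
    pixelwise minimum.  With overlaps at least as wide as any shortest path's
    excursion the result equals the untiled computation; it never
    underestimates it.
    """
    cost.require_same_grid(sources)
    if plan.overlap_pixels < 0:
        raise HFError("tile overlap must be non-negative")
    covered = np.zeros(cost.grid.shape, dtype=bool)
    hours = np.full(cost.grid.shape, np.inf)
    src_all = (sources.values != 0) & ~sources.nodata_mask
    for rs, cs in plan.tiles(cost.grid.shape):
        covered[rs, cs] = True
        sub_src = src_all[rs, cs]
        if not sub_src.any():
            continue
        sub_grid = GridSpec(
            cost.grid.crs_id,
            cost.grid.origin_x + cs.start * cost.grid.pixel_size,
            cost.grid.origin_y - rs.start * cost.grid.pixel_size,
            rs.stop - rs.start,
            cs.stop - cs.start,
            cost.grid.pixel_size,
        )
        sub_cost = RasterLayer(sub_grid, cost.values[rs, cs], "continuous", cost.nodata)
        sub_sources = RasterLayer(sub_grid, sub_src.astype(np.uint8), "categorical", 255)
        tt = least_cost_time(sub_cost, sub_sources)
        hours[rs, cs] = np.minimum(hours[rs, cs], tt.hours)
    if not covered.all():
        raise HFError("tile plan does not cover the grid")
    return TravelTimeSurface(cost.grid, hours, src_all)


def score_indirect(
    tt: TravelTimeSurface, s0: float = 4.0, t_max_hours: float = 4.0, floor: float = 0.1
) -> RasterLayer:
    """Score travel time: exponential decay from ``s0`` at the source to zero
    beyond the ``t_max_hours`` routine-travel horizon.  Unreachable pixels
    score 0 (influence absent, not unknown)."""
    finite = np.isfinite(tt.hours)
    scores = np.zeros(tt.grid.shape, dtype=float)
    scores[finite] = decay_score(tt.hours[finite], s0, t_max_hours, floor)
    return RasterLayer(tt.grid, scores, "continuous")
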