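"""Seeded synthetic landscapes for exercising the full HF pipeline.

The generator emulates the *shapes* of the national input stack — patchy
categorical land cover, a hierarchical road network linking settlements,
clustered point infrastructure, a log-normally clustered population raster,
a blurred radiance raster correlated with population (plus gas-flare
hotspots), and smooth terrain yielding slope in percent — on a desk-scale
grid (500 × 500 pixels of 30 m, i.e. 15 km × 15 km, by default).  It makes
no attempt at the real geography of Peru or Ecuador; its purpose is a
deterministic, fully known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
from scipy import ndimage
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist
from shapely.geometry import LineString, Point, box

from .errors import HFError
from .grid import FeatureSet, GridSpec, RasterLayer

# LULC category codes
FOREST, FLOODED_FOREST, SHRUB, AGRICULTURE, PASTURE, PLANTATION, URBAN, WATER = range(1, 9)
LULC_NAMES = {
    FOREST: "forest", FLOODED_FOREST: "flooded_forest", SHRUB: "shrub",
    AGRICULTURE: "agriculture", PASTURE: "pasture", PLANTATION: "plantation",
    URBAN: "urban", WATER: "water",
}

DEFAULT_GRID = GridSpec("EPSG:32718", 500000.0, 8500000.0, 500, 500, 30.0)


@dataclass(frozen=True)
class LandscapeParams:
    """Statistical targets of the synthetic country."""

    class_fractions: dict = field(default_factory=lambda: {
        FOREST: 0.53, FLOODED_FOREST: 0.05, SHRUB: 0.10, AGRICULTURE: 0.12,
        PASTURE: 0.08, PLANTATION: 0.03, WATER: 0.04, URBAN: 0.05,
    })
    lulc_smoothing: float = 10.0
    terrain_smoothing: float = 15.0
    elevation_range: tuple[float, float] = (50.0, 3500.0)
    max_settlements: int = 12
    n_wells: int = 8
    n_refineries: int = 2
    n_filling_stations: int = 3
    n_mines: int = 4
    n_power_points: int = 4
    n_trails: int = 6
    n_flares: int = 3
    urban_population_mean: float = 3.2   # log-space mean of persons/pixel
    urban_population_sigma: float = 1.0
    radiance_scale: float = 0.9
    radiance_blur_sigma: float = 2.0


@dataclass
class LandscapeBundle:
    """Everything the pipeline consumes, on one grid, from one seed."""

    grid: GridSpec
    elevation: RasterLayer
    slope: RasterLayer
    lulc: RasterLayer
    roads: FeatureSet
    trails: FeatureSet
    railways: FeatureSet
    waterways: FeatureSet
    coastline: FeatureSet
    settlements: FeatureSet
    wells: FeatureSet
    refineries: FeatureSet
    filling_stations: FeatureSet
    mines: FeatureSet
    power_points: FeatureSet
    population: RasterLayer
    radiance: RasterLayer
    seed: int = 0
    params: LandscapeParams = field(default_factory=LandscapeParams)

    def water_mask(self) -> RasterLayer:
        return RasterLayer(
            self.grid, (self.lulc.values == WATER).astype(np.uint8), "categorical", 255
        )


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return (f - f.min()) / (f.max() - f.min() + 1e-12)


def _slope_percent(elevation: np.ndarray, pixel_size: float) -> np.ndarray:
    gy, gx = np.gradient(elevation, pixel_size)
    return np.hypot(gx, gy) * 100.0


def _quantile_classes(field_values: np.ndarray, fractions: dict) -> np.ndarray:
    """Assign categories by rank quantiles of a smooth field → patchy classes
    whose pixel fractions match the targets exactly."""
    flat = field_values.ravel()
    order = np.argsort(flat, kind="stable")
    out = np.empty(flat.shape, dtype=np.int64)
    n = len(flat)
    start = 0
    # low field values become water, high values urban
    sequence = [WATER, FLOODED_FOREST, FOREST, SHRUB, PASTURE, AGRICULTURE, PLANTATION, URBAN]
    for code in sequence:
        frac = fractions.get(code, 0.0)
        stop = start + int(round(frac * n))
        if code == sequence[-1]:
            stop = n
        out[order[start:stop]] = code
        start = stop
    return out.reshape(field_values.shape)


def _cluster_centroids(mask: np.ndarray, grid: GridSpec, max_count: int):
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.argsort(-sizes)[:max_count] + 1
    centroids = ndimage.center_of_mass(mask, labels, keep)
    return [grid.pixel_center(int(round(r)), int(round(c))) for r, c in centroids]


def _river_polyline(elevation: np.ndarray, grid: GridSpec, axis: int) -> LineString:
    """A polyline following the elevation minimum across the grid."""
    idx = np.argmin(elevation, axis=axis)
    pts = []
    step = max(1, len(idx) // 80)
    for j in range(0, len(idx), step):
        r, c = (idx[j], j) if axis == 0 else (j, idx[j])
        pts.append(grid.pixel_center(int(r), int(c)))
    return LineString(pts)


def generate_landscape(
    seed: int,
    grid: GridSpec = DEFAULT_GRID,
    params: LandscapeParams | None = None,
) -> LandscapeBundle:
    """Generate a deterministic synthetic landscape bundle for ``seed``."""
    params = params or LandscapeParams()
    total = sum(params.class_fractions.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise HFError(f"class fractions must sum to 1, got {total}")
    rng = np.random.default_rng(seed)
    shape = grid.shape
    crs = grid.crs_id

    # terrain
    elev01 = _smooth_field(rng, shape, params.terrain_smoothing)
    lo, hi = params.elevation_range
    elevation = lo + elev01 * (hi - lo)
    slope = _slope_percent(elevation, grid.pixel_size)

    # land cover: quantiles of a second smooth field, nudged downhill for water
    lulc_field = 0.8 * _smooth_field(rng, shape, params.lulc_smoothing) + 0.2 * elev01
    lulc = _quantile_classes(lulc_field, params.class_fractions)

    # settlements at the cores of urban patches
    urban_mask = lulc == URBAN
    centers = _cluster_centroids(urban_mask, grid, params.max_settlements)
    settlements = FeatureSet(
        "point", [(Point(x, y), {"name": f"settlement_{i}"}) for i, (x, y) in enumerate(centers)], crs
    )

    # roads: minimum spanning tree over settlements, classed by edge length
    road_feats, trail_feats, rail_feats = [], [], []
    if len(centers) >= 2:
        coords = np.asarray(centers)
        mst = minimum_spanning_tree(squareform(pdist(coords))).tocoo()
        edges = sorted(zip(mst.row, mst.col, mst.data), key=lambda e: -e[2])
        n_edges = len(edges)
        for rank, (i, j, _d) in enumerate(edges):
            if rank < max(1, n_edges // 5):
                cls = 1
            elif rank < max(2, n_edges // 2):
                cls = 2
            else:
                cls = 3
            road_feats.append(
                (LineString([coords[i], coords[j]]), {"class": cls})
            )
        # one railway along the longest corridor
        i, j, _ = edges[0]
        rail_feats.append((LineString([coords[i], coords[j]]), {"class": "rail"}))
        for _ in range(params.n_trails):
            k = rng.integers(len(coords))
            angle = rng.uniform(0, 2 * np.pi)
            length = rng.uniform(500, 3000)
            end = coords[k] + length * np.array([np.cos(angle), np.sin(angle)])
            xmin, ymin, xmax, ymax = grid.bounds
            end = np.clip(end, [xmin, ymin], [xmax - 1, ymax - 1])
            trail_feats.append((LineString([coords[k], end]), {"class": "trail"}))
    roads = FeatureSet("line", road_feats, crs)
    trails = FeatureSet("line", trail_feats, crs)
    railways = FeatureSet("line", rail_feats, crs)

    # rivers along terrain minima; coastline on the western boundary
    waterways = FeatureSet(
        "line",
        [(_river_polyline(elevation, grid, 0), {"name": "river_ns"}),
         (_river_polyline(elevation, grid, 1), {"name": "river_ew"})],
        crs,
    )
    xmin, ymin, xmax, ymax = grid.bounds
    coastline = FeatureSet(
        "line",
        [(LineString([(xmin + grid.pixel_size / 2, ymin), (xmin + grid.pixel_size / 2, ymax)]),
          {"name": "coast"})],
        crs,
    )

    def random_points(n: int, label: str) -> FeatureSet:
        pts = []
        for i in range(n):
            x = rng.uniform(xmin + grid.pixel_size, xmax - grid.pixel_size)
            y = rng.uniform(ymin + grid.pixel_size, ymax - grid.pixel_size)
            pts.append((Point(x, y), {"name": f"{label}_{i}"}))
        return FeatureSet("point", pts, crs)

    wells = random_points(params.n_wells, "well")
    refineries = random_points(params.n_refineries, "refinery")
    filling_stations = random_points(params.n_filling_stations, "filling_station")
    mines = random_points(params.n_mines, "mine")
    power_points = random_points(params.n_power_points, "power")

    # population: log-normal on urban pixels, light rural tail, local smoothing
    population = np.zeros(shape)
    if urban_mask.any():
        population[urban_mask] = rng.lognormal(
            params.urban_population_mean, params.urban_population_sigma,
            int(urban_mask.sum()),
        )
    rural = np.isin(lulc, (AGRICULTURE, PASTURE)) & (rng.random(shape) < 0.05)
    population[rural] = rng.lognormal(0.0, 0.8, int(rural.sum()))
    population = ndimage.gaussian_filter(population, 1.0)

    # radiance: blurred population signal plus gas flares near wells
    radiance = ndimage.gaussian_filter(
        population * params.radiance_scale, params.radiance_blur_sigma
    )
    well_pixels = [grid.world_to_pixel(p.x, p.y) for p in wells.geometries()]
    for r, c in well_pixels[: params.n_flares]:
        radiance[r, c] += rng.uniform(80.0, 150.0)

    return LandscapeBundle(
        grid=grid,
        elevation=RasterLayer(grid, elevation, "continuous"),
        slope=RasterLayer(grid, slope, "continuous"),
        lulc=RasterLayer(grid, lulc, "categorical"),
        roads=roads, trails=trails, railways=railways,
        waterways=waterways, coastline=coastline, settlements=settlements,
        wells=wells, refineries=refineries, filling_stations=filling_stations,
        mines=mines, power_points=power_points,
        population=RasterLayer(grid, population, "continuous"),
        radiance=RasterLayer(grid, radiance, "continuous"),
        seed=seed, params=params,
    )


# ---------------------------------------------------------------------------
# synthetic visual truth

def table5_area_score(coverage_fraction: float) -> int:
    """Map plot coverage of an area pressure to the 0–3 visual score."""
    f = float(coverage_fraction)
    if f < 0 or f > 1:
        raise HFError(f"coverage fraction outside [0, 1]: {f}")
    if f < 0.005:
        return 0
    if f <= 0.125:
        return 1
    if f <= 0.50:
        return 2
    return 3


def table5_occurrence_score(count: int) -> int:
    """Map occurrences of line/point pressures within the plot to 0–3."""
    if count < 0:
        raise HFError("occurrence count cannot be negative")
    return min(int(count), 3)


def visual_truth_from_pipeline(
    pressures,
    plots,
    max_scores,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> None:
    """Synthetic "interpreter" that reads the pipeline's own pressure layers.

    For each plot the per-pressure scores at the center pixel are summed,
    rounded to the map's two-decimal precision and normalized by the sum of
    the pressure maxima — exactly inverting the standardization, so with
    ``noise_sd=0`` the visual index equals the normalized HF index and the
    validation metrics reach their ideal values.  Gaussian noise of standard
    deviation ``noise_sd`` (on the [0, 1] index scale) emulates interpreter
    disagreement.  Results are stored on the plots in place.
    """
    rng = np.random.default_rng(seed)
    denom = float(sum(max_scores.values()))
    for p in plots:
        total = 0.0
        for pid, layer in pressures.items():
            v = layer.raster.values[p.row, p.col]
            if v != layer.raster.nodata:
                total += float(v)
        index = round(total, 2) / denom
        if noise_sd > 0:
            index = float(np.clip(index + rng.normal(0.0, noise_sd), 0.0, 1.0))
        p.visual_index = index


def visual_truth_from_imagery(
    bundle: LandscapeBundle,
    plots,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> None:
    """Synthetic visual interpretation of the landscape itself.

    Per plot, area pressures are scored from true LULC coverage of the 300 m
    plot window, line/point pressures from true feature occurrences in the
    plot, and indirect pressure from presence of roads, waterways or
    settlements in the 5 km buffer — each mapped through the 0–3 visual
    bands.  ``noise_sd`` is the probability scale of one-band flips.
    Scores are stored on the plots in place.
    """
    rng = np.random.default_rng(seed)
    grid = bundle.grid
    half_px = max(1, int(round(plots[0].plot_size_m / 2 / grid.pixel_size))) if plots else 1

    def plot_box(p):
        h = p.plot_size_m / 2
        return box(p.x - h, p.y - h, p.x + h, p.y + h)

    def occurrences(featureset, geom):
        return sum(1 for g in featureset.geometries() if g.intersects(geom))

    def flip(score: int, top: int = 3) -> int:
        if noise_sd > 0 and rng.random() < min(1.0, noise_sd):
            return int(np.clip(score + rng.choice([-1, 1]), 0, top))
        return score

    for p in plots:
        r0, r1 = max(0, p.row - half_px), min(grid.n_rows, p.row + half_px)
        c0, c1 = max(0, p.col - half_px), min(grid.n_cols, p.col + half_px)
        window = bundle.lulc.values[r0:r1, c0:c1]
        n_px = max(1, window.size)

        def cover(code) -> float:
            return float(np.count_nonzero(np.isin(window, code)) / n_px)

        pb = plot_box(p)
        buffer = Point(p.x, p.y).buffer(p.buffer_radius_m)
        road_occ = occurrences(bundle.roads, pb)
        indirect_present = int(
            occurrences(bundle.roads, buffer) > 0
            or occurrences(bundle.waterways, buffer) > 0
            or occurrences(bundle.settlements, buffer) > 0
        )
        urban_area = table5_area_score(cover(URBAN))
        p.visual_scores = {
            "BE": [flip(urban_area),
                   flip(table5_occurrence_score(occurrences(bundle.settlements, pb)))],
            "LU": [flip(table5_area_score(cover(AGRICULTURE))),
                   flip(table5_area_score(cover(PASTURE))),
                   flip(table5_area_score(cover(PLANTATION)))],
            "RR": [flip(table5_occurrence_score(road_occ)),
                   flip(table5_occurrence_score(occurrences(bundle.railways, pb))),
                   flip(table5_occurrence_score(occurrences(bundle.trails, pb)))],
            "OG": [flip(table5_occurrence_score(
                occurrences(bundle.wells, pb) + occurrences(bundle.refineries, pb)
                + occurrences(bundle.filling_stations, pb)))],
            "M": [flip(table5_occurrence_score(occurrences(bundle.mines, pb)))],
            # urban areas and settlement surroundings proxy PD and EI
            "PD": [flip(urban_area)],
            "EI": [flip(urban_area)],
            "IND": [indirect_present],
        }
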