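"""End-to-end HF pipeline over an in-memory landscape bundle.

This is the programmatic twin of the file-driven run configuration: it
scores every dataset of a :class:`~hfmap.synthetic.LandscapeBundle` with the
default national scoring scheme, computes the accessibility-based indirect
pressure, combines and aggregates, and returns the HF map together with the
per-pressure layers.  Tests and the acceptance script run the method through
this entry point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import synthetic as syn
from .accessibility import (
    DEFAULT_SPEED_MODEL,
    SpeedModel,
    build_speed_surface,
    extract_sources,
    least_cost_time,
    pixel_crossing_time,
    score_indirect,
)
from .assembly import HFMap, PressureLayer, aggregate_hf, combine_pressure
from .grid import FeatureSet, RasterLayer, rasterize
from .scoring import DEFAULT_CATEGORY_SCORES as S
from .scoring import DEFAULT_POINT_RADII_M as R
from .scoring import score_linear, score_log_count, score_points

#: per-pressure score maxima of the default (Peru-flavoured) configuration
DEFAULT_PRESSURE_MAXIMA: dict[str, float] = {
    "BE": 10.0, "LU": 5.5, "PD": 10.0, "IND": 4.0,
    "RR": 8.75, "EI": 10.0, "OG": 10.0, "M": 7.25,
}

ROAD_CLASS_SCORES = {1: S["primary_roads"], 2: S["secondary_roads"], 3: S["country_roads"]}


def _subset_lines(fs: FeatureSet, cls: int) -> FeatureSet:
    return FeatureSet(
        "line", [(g, a) for g, a in fs.features if a.get("class") == cls], fs.crs_id
    )


@dataclass
class PipelineResult:
    hf: HFMap
    pressures: dict[str, PressureLayer]
    travel_hours: np.ndarray | None = None


def indirect_pressure(
    bundle: syn.LandscapeBundle,
    s0: float = 4.0,
    t_max_hours: float = 4.0,
    floor: float = 0.1,
    model: SpeedModel = DEFAULT_SPEED_MODEL,
    min_cluster: int = 2,
) -> tuple[PressureLayer, np.ndarray]:
    """Accessibility model over the bundle: speed surface → crossing cost →
    least-cost time from inhabited clusters → decay score over 4 hours."""
    grid = bundle.grid
    roads = RasterLayer(
        grid,
        np.maximum.reduce([
            np.where(rasterize(_subset_lines(bundle.roads, c), grid, 1.0).values > 0, c, 0)
            for c in (3, 2, 1)
        ] or [np.zeros(grid.shape)]).astype(np.int64),
        "categorical", 0,
    )
    waterway_presence = rasterize(bundle.waterways, grid, 1.0)
    coast_presence = rasterize(bundle.coastline, grid, 1.0)
    speed = build_speed_surface(
        bundle.lulc, roads, waterway_presence, coast_presence,
        bundle.slope, bundle.elevation, model,
        agriculture_codes=(syn.AGRICULTURE, syn.PASTURE, syn.PLANTATION),
        natural_codes=(syn.FOREST, syn.SHRUB),
        flooded_codes=(syn.FLOODED_FOREST,),
        water_codes=(syn.WATER,),
    )
    cost = pixel_crossing_time(speed)
    built = RasterLayer(
        grid, (bundle.lulc.values == syn.URBAN).astype(np.uint8), "categorical", 255
    )
    sources = extract_sources(built, min_cluster)
    tt = least_cost_time(cost, sources)
    layer = score_indirect(tt, s0, t_max_hours, floor)
    return PressureLayer("IND", layer), tt.hours


def score_bundle(
    bundle: syn.LandscapeBundle, include: set[str] | None = None
) -> dict[str, list[RasterLayer]]:
    """Score every dataset of the bundle with the default national scheme.

    ``include`` optionally restricts the dataset ids (useful for version
    subsets and for monotonicity checks); indirect pressure is handled
    separately by :func:`indirect_pressure`.
    """
    grid = bundle.grid

    def direct_lulc(mapping):
        out = np.zeros(grid.shape)
        for code, score in mapping.items():
            out[bundle.lulc.values == code] = score
        return RasterLayer(grid, out, "continuous")

    scorers = {
        "urban": ("BE", lambda: direct_lulc({syn.URBAN: S["urban"]})),
        "settlements": ("BE", lambda: score_points(
            bundle.settlements, grid, S["settlements"], "approx")),
        "lulc": ("LU", lambda: direct_lulc({
            syn.AGRICULTURE: S["agriculture_peru"],
            syn.PASTURE: S["pasture_peru"],
            syn.PLANTATION: S["tree_plantations"],
        })),
        "population": ("PD", lambda: score_log_count(bundle.population)),
        "radiance": ("EI", lambda: score_linear(bundle.radiance)),
        "power_points": ("EI", lambda: score_points(
            bundle.power_points, grid, S["electrical_points"], "actual",
            radius=R["electrical_points"])),
        "wells": ("OG", lambda: score_points(
            bundle.wells, grid, S["wells"], "actual", radius=R["wells"])),
        "refineries": ("OG", lambda: score_points(
            bundle.refineries, grid, S["refineries_deposits"], "actual",
            radius=R["refineries_deposits"])),
        "filling_stations": ("OG", lambda: score_points(
            bundle.filling_stations, grid, S["filling_stations"], "actual",
            radius=R["filling_stations"])),
        "mines": ("M", lambda: score_points(
            bundle.mines, grid, S["mining"], "actual", radius=R["mining"])),
        "roads_primary": ("RR", lambda: rasterize(
            _subset_lines(bundle.roads, 1), grid, ROAD_CLASS_SCORES[1])),
        "roads_secondary": ("RR", lambda: rasterize(
            _subset_lines(bundle.roads, 2), grid, ROAD_CLASS_SCORES[2])),
        "roads_country": ("RR", lambda: rasterize(
            _subset_lines(bundle.roads, 3), grid, ROAD_CLASS_SCORES[3])),
        "railways": ("RR", lambda: rasterize(bundle.railways, grid, S["railways"])),
        "trails": ("RR", lambda: rasterize(bundle.trails, grid, S["trails"])),
    }
    scored: dict[str, list[RasterLayer]] = {}
    for dataset_id, (pid, fn) in scorers.items():
        if include is not None and dataset_id not in include:
            continue
        scored.setdefault(pid, []).append(fn())
    return scored


def run_pipeline(
    bundle: syn.LandscapeBundle,
    include: set[str] | None = None,
    with_indirect: bool = True,
    year: int | None = None,
    version_tag: str = "sdg15",
) -> PipelineResult:
    """Score → combine by max → add indirect pressure → aggregate → mask."""
    scored = score_bundle(bundle, include)
    pressures = [
        combine_pressure(layers, pid, year) for pid, layers in sorted(scored.items())
    ]
    hours = None
    if with_indirect:
        ind, hours = indirect_pressure(bundle)
        pressures.append(ind)
    hf = aggregate_hf(pressures, bundle.water_mask(), year=year, version_tag=version_tag)
    return PipelineResult(hf, {p.pressure_id: p for p in pressures}, hours)
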