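"""Write a synthetic landscape bundle to disk with a ready-to-run config.

The bundle's rasters go out as ASCII grids and its feature sets as GeoJSON;
``run.yaml`` wires them into the default national scoring scheme so
``hfmap build-hf --config run.yaml`` reproduces the in-memory pipeline.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from . import synthetic as syn
from .grid import FeatureSet, RasterLayer
from .io import write_ascii_grid, write_geojson
from .scoring import DEFAULT_CATEGORY_SCORES as S
from .scoring import DEFAULT_POINT_RADII_M as R


def write_bundle(bundle: syn.LandscapeBundle, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_ascii_grid(bundle.elevation, out / "elevation.asc")
    write_ascii_grid(bundle.slope, out / "slope.asc")
    write_ascii_grid(bundle.lulc, out / "lulc.asc")
    write_ascii_grid(bundle.population, out / "population.asc")
    write_ascii_grid(bundle.radiance, out / "radiance.asc")
    write_ascii_grid(bundle.water_mask(), out / "water.asc")

    write_geojson(bundle.roads, out / "roads.geojson")
    for cls, name in ((1, "primary"), (2, "secondary"), (3, "country")):
        sub = FeatureSet(
            "line",
            [(g, a) for g, a in bundle.roads.features if a.get("class") == cls],
            bundle.roads.crs_id,
        )
        write_geojson(sub, out / f"roads_{name}.geojson")
    for name in ("trails", "railways", "waterways", "coastline", "settlements",
                 "wells", "refineries", "filling_stations", "mines", "power_points"):
        write_geojson(getattr(bundle, name), out / f"{name}.geojson")

    g = bundle.grid
    cfg = {
        "grid": {
            "crs_id": g.crs_id, "origin_x": g.origin_x, "origin_y": g.origin_y,
            "n_rows": g.n_rows, "n_cols": g.n_cols, "pixel_size": g.pixel_size,
        },
        "version": "sdg15",
        "years": [2018],
        "water_mask": "water.asc",
        "datasets": [
            {"id": "urban", "pressure": "BE", "case": "direct",
             "format": "raster_categorical", "path": "lulc.asc",
             "max_score": S["urban"],
             "params": {"mapping": {int(syn.URBAN): S["urban"]}}},
            {"id": "settlements", "pressure": "BE", "case": "point_approx",
             "format": "vector_point", "path": "settlements.geojson",
             "max_score": S["settlements"],
             "params": {"score": S["settlements"]}},
            {"id": "lulc", "pressure": "LU", "case": "direct",
             "format": "raster_categorical", "path": "lulc.asc",
             "max_score": S["pasture_peru"],
             "params": {"mapping": {
                 int(syn.AGRICULTURE): S["agriculture_peru"],
                 int(syn.PASTURE): S["pasture_peru"],
                 int(syn.PLANTATION): S["tree_plantations"],
             }}},
            {"id": "population", "pressure": "PD", "case": "log_count",
             "format": "raster_continuous", "path": "population.asc", "national": False},
            {"id": "radiance", "pressure": "EI", "case": "linear",
             "format": "raster_continuous", "path": "radiance.asc", "national": False},
            {"id": "power_points", "pressure": "EI", "case": "point_actual",
             "format": "vector_point", "path": "power_points.geojson",
             "max_score": S["electrical_points"],
             "params": {"score": S["electrical_points"], "radius": R["electrical_points"]}},
            {"id": "wells", "pressure": "OG", "case": "point_actual",
             "format": "vector_point", "path": "wells.geojson",
             "params": {"score": S["wells"], "radius": R["wells"]}},
            {"id": "refineries", "pressure": "OG", "case": "point_actual",
             "format": "vector_point", "path": "refineries.geojson",
             "params": {"score": S["refineries_deposits"], "radius": R["refineries_deposits"]}},
            {"id": "filling_stations", "pressure": "OG", "case": "point_actual",
             "format": "vector_point", "path": "filling_stations.geojson",
             "params": {"score": S["filling_stations"], "radius": R["filling_stations"]}},
            {"id": "mines", "pressure": "M", "case": "point_actual",
             "format": "vector_point", "path": "mines.geojson",
             "max_score": S["mining"],
             "params": {"score": S["mining"], "radius": R["mining"]}},
            {"id": "roads_primary", "pressure": "RR", "case": "direct",
             "format": "vector_line", "path": "roads_primary.geojson",
             "max_score": S["primary_roads"],
             "params": {"score": S["primary_roads"]}},
            {"id": "roads_secondary", "pressure": "RR", "case": "direct",
             "format": "vector_line", "path": "roads_secondary.geojson",
             "max_score": S["secondary_roads"],
             "params": {"score": S["secondary_roads"]}},
            {"id": "roads_country", "pressure": "RR", "case": "direct",
             "format": "vector_line", "path": "roads_country.geojson",
             "max_score": S["country_roads"],
             "params": {"score": S["country_roads"]}},
            {"id": "railways", "pressure": "RR", "case": "direct",
             "format": "vector_line", "path": "railways.geojson",
             "max_score": S["railways"],
             "params": {"score": S["railways"]}},
            {"id": "trails", "pressure": "RR", "case": "direct",
             "format": "vector_line", "path": "trails.geojson",
             "max_score": S["trails"],
             "params": {"score": S["trails"]}},
        ],
        "accessibility": {
            "enabled": True,
            "lulc": "lulc.asc", "slope": "slope.asc", "elevation": "elevation.asc",
            "roads": "roads.geojson", "waterways": "waterways.geojson",
            "coastline": "coastline.geojson",
            "built_env_datasets": ["urban"],
            "agriculture_codes": [int(syn.AGRICULTURE), int(syn.PASTURE), int(syn.PLANTATION)],
            "natural_codes": [int(syn.FOREST), int(syn.SHRUB)],
            "flooded_codes": [int(syn.FLOODED_FOREST)],
            "water_codes": [int(syn.WATER)],
        },
        "validation": {"seed": int(bundle.seed)},
    }
    run_path = out / "run.yaml"
    run_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return run_path
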