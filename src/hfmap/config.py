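"""Run-configuration schema, loading, and the file-driven pipeline inputs.

A run configuration is a YAML tree declaring the working grid, the HF
version (``sdg15`` — non-restrictive, ``official`` — nationally produced
datasets only, ``multitemporal`` — multitemporal datasets only), the years,
one entry per input dataset (path(s), pressure, scoring case, parameters,
static/multitemporal and national/global flags), the accessibility block and
the validation parameters.  Everything is validated at load; unknown keys,
missing files and case/parameter mismatches are rejected with the offending
field named.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pydantic
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .accessibility import (
    TilePlan,
    extract_sources,
    least_cost_time,
    pixel_crossing_time,
    build_speed_surface,
    score_indirect,
    tiled_least_cost,
)
from .assembly import PressureLayer, ProvenanceRecord
from .errors import ConfigError, HFError
from .grid import FeatureSet, GridSpec, RasterLayer, rasterize
from .io import read_ascii_grid, read_geojson
from .scoring import PRESSURE_IDS, DatasetScoreSpec

Version = Literal["sdg15", "official", "multitemporal"]
DataFormat = Literal[
    "raster_continuous", "raster_categorical", "vector_point", "vector_line", "vector_polygon"
]


class GridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    crs_id: str
    origin_x: float
    origin_y: float
    n_rows: int = Field(ge=1)
    n_cols: int = Field(ge=1)
    pixel_size: float = Field(default=30.0, gt=0)

    def to_grid(self) -> GridSpec:
        return GridSpec(self.crs_id, self.origin_x, self.origin_y,
                        self.n_rows, self.n_cols, self.pixel_size)


class DatasetEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")
    id: str
    pressure: str
    case: Literal["direct", "decay", "log_count", "log_density", "linear",
                  "point_actual", "point_approx"]
    format: DataFormat
    params: dict = Field(default_factory=dict)
    path: Optional[str] = None
    paths: dict[int, str] = Field(default_factory=dict)
    static: bool = True
    national: bool = True
    qualifications: Optional[tuple[float, float, float, float]] = None
    max_score: Optional[float] = None

    @pydantic.field_validator("pressure")
    @classmethod
    def _known_pressure(cls, v: str) -> str:
        if v not in PRESSURE_IDS:
            raise ValueError(f"unknown pressure id {v!r} (expected one of {PRESSURE_IDS})")
        return v

    @pydantic.model_validator(mode="after")
    def _has_source(self) -> "DatasetEntry":
        if self.static and self.path is None:
            raise ValueError(f"static dataset {self.id!r} needs 'path'")
        if not self.static and not self.paths:
            raise ValueError(f"multitemporal dataset {self.id!r} needs 'paths' per year")
        return self

    def path_for(self, year: int) -> str:
        if self.static:
            return self.path  # type: ignore[return-value]
        if year not in self.paths:
            raise ConfigError(f"dataset {self.id!r} has no path for year {year}")
        return self.paths[year]

    def score_spec(self) -> DatasetScoreSpec:
        return DatasetScoreSpec(
            self.id, self.pressure, self.case, dict(self.params),
            qualifications=self.qualifications, max_score=self.max_score,
        )


class TileConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_tile_rows: int = Field(default=1, ge=1)
    n_tile_cols: int = Field(default=1, ge=1)
    overlap_m: float = Field(default=100_000.0, ge=0)


class AccessibilityConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    lulc: str
    slope: str
    elevation: str
    roads: Optional[str] = None
    road_class_attr: str = "class"
    waterways: Optional[str] = None
    coastline: Optional[str] = None
    built_env_datasets: list[str] = Field(default_factory=list)
    agriculture_codes: list[int] = Field(default_factory=list)
    natural_codes: list[int] = Field(default_factory=list)
    flooded_codes: list[int] = Field(default_factory=list)
    water_codes: list[int] = Field(default_factory=list)
    s0: float = 4.0
    t_max_hours: float = 4.0
    floor: float = 0.1
    min_cluster: int = 2
    tile: Optional[TileConfig] = None


class ValidationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    total_n: int = 120
    min_per_stratum: int = 10
    tolerance: float = 0.20
    seed: int = 0
    strata_breaks: tuple[float, float, float] = (4.0, 8.0, 18.0)
    plot_size_m: float = 300.0
    buffer_radius_m: float = 5000.0


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    grid: GridConfig
    version: Version = "sdg15"
    years: list[int] = Field(default_factory=lambda: [2018])
    datasets: list[DatasetEntry]
    water_mask: Optional[str] = None
    accessibility: Optional[AccessibilityConfig] = None
    validation: ValidationConfig = Field(default_factory=ValidationConfig)
    base_dir: Path = Path(".")

    def resolve(self, path: str) -> Path:
        return (self.base_dir / path).resolve()

    def active_datasets(self, year: int) -> list[DatasetEntry]:
        out = []
        for d in self.datasets:
            if self.version == "official" and not d.national:
                continue
            if self.version == "multitemporal" and d.static:
                continue
            out.append(d)
        return out

    def load_water_mask(self) -> RasterLayer | None:
        if self.water_mask is None:
            return None
        return read_ascii_grid(self.resolve(self.water_mask), "categorical")

    def pressure_maxima(self) -> dict[str, float]:
        """Per-pressure score ceiling over the active datasets (IND from the
        accessibility origin score)."""
        maxima: dict[str, float] = {}
        for d in self.active_datasets(self.years[0]):
            ms = d.score_spec().max_score
            maxima[d.pressure] = max(maxima.get(d.pressure, 0.0), ms)
        if self.accessibility and self.accessibility.enabled:
            maxima["IND"] = self.accessibility.s0
        return maxima


def load_config(path: str | Path) -> RunConfig:
    """Load and fully validate a YAML run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: malformed YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    raw.setdefault("base_dir", str(path.parent))
    try:
        config = RunConfig.model_validate(raw)
    except pydantic.ValidationError as exc:
        detail = "; ".join(
            ".".join(str(loc) for loc in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"{path}: {detail}") from exc
    _check_files(config)
    return config


def _check_files(config: RunConfig) -> None:
    missing = []
    for d in config.datasets:
        for p in ([d.path] if d.static else list(d.paths.values())):
            if p and not config.resolve(p).exists():
                missing.append(f"datasets[{d.id}]: {p}")
    if config.water_mask and not config.resolve(config.water_mask).exists():
        missing.append(f"water_mask: {config.water_mask}")
    acc = config.accessibility
    if acc and acc.enabled:
        for name in ("lulc", "slope", "elevation", "roads", "waterways", "coastline"):
            p = getattr(acc, name)
            if p and not config.resolve(p).exists():
                missing.append(f"accessibility.{name}: {p}")
    if missing:
        raise ConfigError("missing input files: " + "; ".join(missing))


def serialize_config(config: RunConfig) -> dict:
    out = config.model_dump(mode="json", exclude={"base_dir"})
    return out


# ---------------------------------------------------------------------------
# file-driven inputs for one year

def _load_dataset(config: RunConfig, entry: DatasetEntry, year: int):
    path = config.resolve(entry.path_for(year))
    if entry.format == "raster_continuous":
        return read_ascii_grid(path, "continuous")
    if entry.format == "raster_categorical":
        return read_ascii_grid(path, "categorical")
    kind = entry.format.split("_", 1)[1]
    return read_geojson(path, kind)  # type: ignore[arg-type]


def _presence(data, grid: GridSpec, entry: DatasetEntry) -> np.ndarray:
    if isinstance(data, FeatureSet):
        return rasterize(data, grid, 1.0).values > 0
    if entry.format == "raster_categorical" and "mapping" in entry.params:
        codes = [int(k) for k in entry.params["mapping"]]
        return np.isin(data.values, codes)
    return (data.values > 0) & ~data.nodata_mask


def resolve_year_inputs(
    config: RunConfig, year: int
) -> tuple[dict[str, list[RasterLayer]], list[ProvenanceRecord]]:
    """Load, score and group all datasets for one year; compute the indirect
    pressure when the accessibility block is enabled."""
    grid = config.grid.to_grid()
    scored: dict[str, list[RasterLayer]] = {}
    records: list[ProvenanceRecord] = []
    loaded: dict[str, tuple] = {}
    for entry in config.active_datasets(year):
        data = _load_dataset(config, entry, year)
        loaded[entry.id] = (data, entry)
        spec = entry.score_spec()
        if "mapping" in spec.params:
            spec.params["mapping"] = {int(k): v for k, v in spec.params["mapping"].items()}
        layer = spec.apply(data, grid)
        scored.setdefault(entry.pressure, []).append(layer)
        records.append(ProvenanceRecord(
            year, entry.id, entry.pressure, entry.case, dict(entry.params),
            str(entry.path_for(year)), entry.static,
        ))

    acc = config.accessibility
    if acc and acc.enabled:
        layer, record = _indirect_from_config(config, grid, loaded, year)
        scored.setdefault("IND", []).append(layer)
        records.append(record)
    return scored, records


def _road_class_raster(config: RunConfig, acc: AccessibilityConfig, grid: GridSpec) -> RasterLayer:
    codes = np.zeros(grid.shape, dtype=np.int64)
    if acc.roads:
        roads = read_geojson(config.resolve(acc.roads), "line")
        for cls in (3, 2, 1):  # higher class wins
            sub = FeatureSet(
                "line",
                [(g, a) for g, a in roads.features if int(a.get(acc.road_class_attr, 3)) == cls],
                roads.crs_id,
            )
            mask = rasterize(sub, grid, 1.0).values > 0
            codes[mask] = cls
    return RasterLayer(grid, codes, "categorical", 0)


def _indirect_from_config(config, grid, loaded, year):
    acc = config.accessibility
    lulc = read_ascii_grid(config.resolve(acc.lulc), "categorical")
    slope = read_ascii_grid(config.resolve(acc.slope), "continuous")
    elevation = read_ascii_grid(config.resolve(acc.elevation), "continuous")
    roads = _road_class_raster(config, acc, grid)

    def presence_layer(path):
        if path is None:
            return RasterLayer.zeros(grid)
        return rasterize(read_geojson(config.resolve(path), "line"), grid, 1.0)

    waterways = presence_layer(acc.waterways)
    coastline = presence_layer(acc.coastline) if acc.coastline else None

    speed = build_speed_surface(
        lulc, roads, waterways, coastline, slope, elevation,
        agriculture_codes=tuple(acc.agriculture_codes),
        natural_codes=tuple(acc.natural_codes),
        flooded_codes=tuple(acc.flooded_codes),
        water_codes=tuple(acc.water_codes),
    )
    cost = pixel_crossing_time(speed)

    built = np.zeros(grid.shape, dtype=bool)
    for ds_id in acc.built_env_datasets:
        if ds_id not in loaded:
            raise ConfigError(
                f"accessibility.built_env_datasets names unknown dataset {ds_id!r}"
            )
        data, entry = loaded[ds_id]
        built |= _presence(data, grid, entry)
    sources = extract_sources(
        RasterLayer(grid, built.astype(np.uint8), "categorical", 255), acc.min_cluster
    )
    if acc.tile and (acc.tile.n_tile_rows > 1 or acc.tile.n_tile_cols > 1):
        plan = TilePlan(
            acc.tile.n_tile_rows, acc.tile.n_tile_cols,
            int(round(acc.tile.overlap_m / grid.pixel_size)),
        )
        tt = tiled_least_cost(cost, sources, plan)
    else:
        tt = least_cost_time(cost, sources)
    layer = score_indirect(tt, acc.s0, acc.t_max_hours, acc.floor)
    record = ProvenanceRecord(
        year, "indirect_accessibility", "IND", "decay",
        {"s0": acc.s0, "t_max_hours": acc.t_max_hours, "floor": acc.floor,
         "min_cluster": acc.min_cluster},
        "accessibility model", True,
    )
    return layer, record


def provenance_json(records: list[ProvenanceRecord]) -> str:
    return json.dumps([vars(r) for r in records], indent=2, default=str)
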