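"""Assembling scored datasets into pressure layers and the HF index.

Scored datasets belonging to one pressure (e.g. primary, secondary and
country roads within "roads and railways") are combined by pixelwise
*maximum*; the eight pressure layers — built environments (BE), land use
(LU), population density (PD), indirect pressures (IND), roads and railways
(RR), electrical infrastructure (EI), oil and gas (OG) and mining (M) — are
then *summed* into the HF index.  Water bodies are masked out, values are
rounded (half-even) to two decimals, and the index can be classified into
four landscape classes with breakpoints 1, 4 and 15.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import HFError
from .grid import NODATA_CONTINUOUS, RasterLayer, mask_water
from .scoring import PRESSURE_IDS

log = logging.getLogger(__name__)

#: HF classification breakpoints and labels (left-closed intervals).
CLASS_BREAKS = (1.0, 4.0, 15.0)
CLASS_LABELS = {
    1: "original ecosystem, no significant human influence",
    2: "original ecosystem with human influence",
    3: "rural landscape",
    4: "highly modified landscape",
}


@dataclass
class PressureLayer:
    """One scored pressure in [0, 10]."""

    pressure_id: str
    raster: RasterLayer
    year: int | None = None

    def __post_init__(self) -> None:
        if self.pressure_id not in PRESSURE_IDS:
            raise HFError(f"unknown pressure id {self.pressure_id!r}")
        valid = ~self.raster.nodata_mask
        vals = self.raster.values[valid]
        if vals.size and (vals.min() < 0 or vals.max() > 10):
            raise HFError(
                f"pressure {self.pressure_id}: values outside [0, 10] "
                f"(min {vals.min():.3f}, max {vals.max():.3f})"
            )


@dataclass
class HFMap:
    """The aggregated human-footprint index for one year."""

    raster: RasterLayer
    year: int | None = None
    version_tag: str = "sdg15"
    pressures: tuple[str, ...] = ()


def combine_pressure(
    scored: list[RasterLayer], pressure_id: str, year: int | None = None
) -> PressureLayer:
    """Pixelwise maximum over the scored datasets of one pressure.

    Nodata pixels are ignored unless every layer is nodata there.
    """
    if not scored:
        raise HFError(f"pressure {pressure_id}: no scored rasters to combine")
    grid = scored[0].grid
    stack = []
    for layer in scored:
        layer.require_same_grid(scored[0])
        vals = layer.values.astype(float).copy()
        vals[layer.nodata_mask] = -np.inf
        stack.append(vals)
    out = np.max(stack, axis=0)
    all_nodata = ~np.isfinite(out)
    out[all_nodata] = NODATA_CONTINUOUS
    return PressureLayer(
        pressure_id, RasterLayer(grid, out, "continuous", NODATA_CONTINUOUS), year
    )


def aggregate_hf(
    pressures: list[PressureLayer],
    water: RasterLayer | None = None,
    year: int | None = None,
    version_tag: str = "sdg15",
) -> HFMap:
    """Sum the pressure layers into the HF index.

    Each pressure may appear once.  Nodata pixels of a single pressure do not
    contribute; pixels nodata in every pressure stay nodata.  Water is masked
    afterwards and values are rounded half-even to two decimals.
    """
    ids = [p.pressure_id for p in pressures]
    if len(set(ids)) != len(ids):
        raise HFError(f"duplicate pressure ids in aggregation: {sorted(ids)}")
    if not pressures:
        raise HFError("aggregate_hf needs at least one pressure layer")
    grid = pressures[0].raster.grid
    total = np.zeros(grid.shape, dtype=float)
    any_valid = np.zeros(grid.shape, dtype=bool)
    for p in pressures:
        p.raster.require_same_grid(pressures[0].raster)
        valid = ~p.raster.nodata_mask
        total[valid] += p.raster.values[valid]
        any_valid |= valid
    total = np.round(total, 2)  # numpy rounds half-even
    total[~any_valid] = NODATA_CONTINUOUS
    hf = RasterLayer(grid, total, "continuous", NODATA_CONTINUOUS)
    if water is not None:
        hf = mask_water(hf, water)
    return HFMap(hf, year=year, version_tag=version_tag, pressures=tuple(sorted(ids)))


def classify_hf(hf: HFMap) -> RasterLayer:
    """Classify the HF index into the four landscape classes.

    Intervals are left-closed: [0, 1) original, [1, 4) influenced,
    [4, 15) rural, [15, ∞) highly modified.
    """
    raster = hf.raster
    valid = ~raster.nodata_mask
    if np.any(raster.values[valid] < 0):
        raise HFError("HF index cannot be negative")
    classes = np.digitize(raster.values, CLASS_BREAKS) + 1
    classes = classes.astype(np.int64)
    classes[~valid] = 255
    return RasterLayer(raster.grid, classes, "categorical", 255)


def rescale_for_display(hf: HFMap, top: float = 30.0) -> RasterLayer:
    """Optional presentation rescale of the HF index onto a 0–``top`` scale
    (values above ``top`` capped).  Display only — never feeds analysis."""
    raster = hf.raster
    out = np.clip(raster.values, 0.0, top)
    out[raster.nodata_mask] = raster.nodata
    return raster.with_values(out)


# ---------------------------------------------------------------------------
# multi-year series

@dataclass
class ProvenanceRecord:
    year: int
    dataset_id: str
    pressure_id: str
    case: str
    params: dict
    source: str
    static: bool


@dataclass
class SeriesResult:
    maps: list[HFMap]
    pressure_layers: dict[int, dict[str, PressureLayer]]
    provenance: list[ProvenanceRecord] = field(default_factory=list)


def build_series(config, years: list[int] | None = None) -> SeriesResult:
    """Produce one HF map per year from a run configuration.

    Static datasets are reused across years; multitemporal datasets must
    resolve a path for every requested year.  A provenance record (dataset →
    pressure → scoring case → parameters) is kept for every contribution.
    """
    from .config import resolve_year_inputs  # late import: config builds on assembly

    years = years if years is not None else config.years
    maps: list[HFMap] = []
    provenance: list[ProvenanceRecord] = []
    per_year_pressures: dict[int, dict[str, PressureLayer]] = {}
    for year in years:
        scored_by_pressure, records = resolve_year_inputs(config, year)
        pressures = [
            combine_pressure(layers, pid, year)
            for pid, layers in sorted(scored_by_pressure.items())
        ]
        water = config.load_water_mask()
        hf = aggregate_hf(pressures, water, year=year, version_tag=config.version)
        maps.append(hf)
        per_year_pressures[year] = {p.pressure_id: p for p in pressures}
        provenance.extend(records)
        log.info("built HF map for %s (%s pressures)", year, len(pressures))
    return SeriesResult(maps, per_year_pressures, provenance)
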