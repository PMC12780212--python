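"""Pressure-scoring template and scoring cases.

Every input dataset is converted into a raster of human-influence scores in
[0, 10].  A dataset's ceiling (its *maximum score*) comes from a four-criterion
template: loss of original ecosystem cover, imperviousness of surfaces,
habitat viability, and pollution risk, with criterion importances (CI)
4/3/2/1 summing to 10.  Each dataset receives a qualification in [0, 1] per
criterion and its maximum score is the CI-weighted sum, never above 10; a
score of 4 or more marks loss of the original ecosystem.

Six scoring cases turn prepared data into scores:

* direct        — category (or presence) lookup at the mapped location;
* decay         — exponential decay of the score with distance from sources;
* log_count     — ``5.41 * log10(count + 1)`` for per-pixel population
                  counts, saturating at 10 above 70 persons/pixel;
* log_density   — ``2.5 * log10(density + 1)`` for census population density;
* linear        — linear ramp, used for nighttime-light radiance between
                  0.5 and 60 nW·cm⁻²·sr⁻¹;
* point_actual / point_approx — point infrastructure burned over a known
  footprint radius, or at the point pixel with a decaying halo when the
  location is only approximate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .errors import HFError
from .grid import FeatureSet, GridSpec, RasterLayer, euclidean_distance, rasterize

PRESSURE_IDS = ("BE", "LU", "PD", "IND", "RR", "EI", "OG", "M")

#: score marking loss of the original ecosystem
NATURAL_LOSS_THRESHOLD = 4.0


@dataclass(frozen=True)
class ScoringTemplate:
    """Criterion importances (CI): cover loss, imperviousness, habitat
    viability, pollution risk.  They must sum to 10."""

    importances: tuple[float, float, float, float] = (4.0, 3.0, 2.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.importances) != 4 or any(ci <= 0 for ci in self.importances):
            raise HFError("template needs four positive criterion importances")
        if not math.isclose(sum(self.importances), 10.0):
            raise HFError(f"criterion importances must sum to 10, got {sum(self.importances)}")

    def max_score(self, qualifications: Sequence[float]) -> float:
        return dataset_max_score(qualifications, self)


DEFAULT_TEMPLATE = ScoringTemplate()


def dataset_max_score(
    qualifications: Sequence[float], template: ScoringTemplate = DEFAULT_TEMPLATE
) -> float:
    """CI-weighted sum of the four criterion qualifications (each in [0, 1])."""
    q = tuple(float(v) for v in qualifications)
    if len(q) != 4:
        raise HFError(f"expected four qualifications, got {len(q)}")
    if any(v < 0 or v > 1 for v in q):
        raise HFError(f"qualifications must lie in [0, 1], got {q}")
    return float(sum(ci * qc for ci, qc in zip(template.importances, q)))


#: The scoring template rows: dataset label -> (pressure ids, qualifications).
#: Maximum scores are *derived* from the qualifications via the template.
TEMPLATE_ROWS: dict[str, tuple[tuple[str, ...], tuple[float, float, float, float]]] = {
    "urban_areas": (("BE",), (1, 1, 1, 1)),
    "densely_populated_areas": (("PD",), (1, 1, 1, 1)),
    "densely_illuminated_areas": (("EI",), (1, 1, 1, 1)),
    "wells_depots_refineries_stations_filling_stations": (("OG",), (1, 1, 1, 1)),
    "power_plants_dams_substations_towers_turbines": (("EI",), (1, 1, 1, 0)),
    "primary_roads_railways_runways": (("RR", "BE"), (1, 1, 0.75, 0.25)),
    "solar_power_hydroelectric_plants": (("EI",), (1, 0.75, 1, 0)),
    "secondary_roads": (("RR",), (1, 1, 0.5, 0.25)),
    "settlements_ports_sparse_houses": (("BE",), (1, 0.75, 0.5, 0.25)),
    "mining_areas": (("M",), (1, 0.25, 0.75, 1)),
    "artificial_water_bodies": (("LU",), (1, 0, 1, 0)),
    "country_roads": (("RR",), (1, 0.5, 0.25, 0)),
    "pasture": (("LU",), (1, 0, 0.75, 0)),
    "agriculture": (("LU",), (1, 0, 0.5, 0.25)),
    "pipelines": (("OG",), (1, 0, 0.5, 0.25)),
    "transmission_power_lines": (("EI",), (1, 0, 0.5, 0)),
    "trails": (("RR",), (0, 0.25, 0.25, 0)),
}

#: Tree plantations share the LULC case with a qualification of (1, 0, 0.25, 0);
#: kept separate from TEMPLATE_ROWS to preserve the 17-row printed layout
#: (Peru and Ecuador share the value).
PLANTATION_QUALIFICATIONS = (1, 0, 0.25, 0)

#: Default category scores used by the national configurations.
DEFAULT_CATEGORY_SCORES: dict[str, float] = {
    "urban": 10.0,
    "runways": 8.75,
    "sparse_houses": 7.5,
    "settlements": 7.5,
    "ports": 7.5,
    "pasture_peru": 5.5,
    "agriculture_peru": 5.25,
    "lulc_ecuador": 5.25,
    "tree_plantations": 4.5,
    "artificial_water_bodies": 6.0,
    "primary_roads": 8.75,
    "railways": 8.75,
    "secondary_roads": 8.25,
    "country_roads": 6.0,
    "trails": 1.25,
    "pipelines": 5.25,
    "transmission_lines": 5.0,
    "electrical_points": 9.0,
    "solar_hydro_plants": 8.25,
    "wells": 10.0,
    "filling_stations": 10.0,
    "refineries_deposits": 10.0,
    "mining": 7.25,
}

#: Footprint radii (m) for point features at actual locations.
DEFAULT_POINT_RADII_M: dict[str, float] = {
    "electrical_points": 50.0,
    "solar_hydro_plants": 50.0,
    "wells": 50.0,
    "filling_stations": 150.0,
    "refineries_deposits": 500.0,
    "mining": 50.0,
}


# ---------------------------------------------------------------------------
# scoring cases

def score_direct(raster: RasterLayer, mapping: Mapping[int, float]) -> RasterLayer:
    """Category → score lookup; unmapped categories score 0, nodata stays."""
    for code, score in mapping.items():
        if score > 10 or score < 0:
            raise HFError(f"category {code}: score {score} outside [0, 10]")
    out = np.zeros(raster.grid.shape, dtype=float)
    for code, score in mapping.items():
        out[raster.values == code] = score
    from .grid import NODATA_CONTINUOUS

    out[raster.nodata_mask] = NODATA_CONTINUOUS
    return RasterLayer(raster.grid, out, "continuous", NODATA_CONTINUOUS)


def decay_score(
    distance: np.ndarray, s0: float, max_distance: float, floor: float = 0.1
) -> np.ndarray:
    """``s(d) = S0 · exp(−d · ln(S0/floor) / D)`` for d ≤ D, zero beyond.

    The rate is calibrated so the score equals ``floor`` exactly at the
    maximum distance D, preserving both the stated origin score and the
    stated extinction distance.
    """
    if max_distance <= 0:
        raise HFError(f"max distance must be positive, got {max_distance}")
    if not 0 < s0 <= 10:
        raise HFError(f"origin score must lie in (0, 10], got {s0}")
    if not 0 < floor < s0:
        raise HFError(f"decay floor must lie in (0, S0), got {floor}")
    rate = math.log(s0 / floor) / max_distance
    d = np.asarray(distance, dtype=float)
    return np.where(d <= max_distance, s0 * np.exp(-d * rate), 0.0)


def score_exponential_decay(
    distance: RasterLayer, s0: float, max_distance: float, floor: float = 0.1
) -> RasterLayer:
    out = decay_score(distance.values, s0, max_distance, floor)
    out[distance.nodata_mask] = distance.nodata
    return distance.with_values(out)


def score_log_count(
    count: RasterLayer, coeff: float = 5.41, cap_threshold: float = 70.0
) -> RasterLayer:
    """Population-count scoring: ``min(10, coeff · log10(count + 1))``,
    saturating at 10 above ``cap_threshold`` persons per pixel."""
    vals = count.values.astype(float)
    valid = ~count.nodata_mask
    if np.any(vals[valid] < 0):
        raise HFError("population counts must be non-negative")
    out = np.where(valid, np.minimum(10.0, coeff * np.log10(np.abs(vals) + 1)), vals)
    out[valid & (vals > cap_threshold)] = 10.0
    return count.with_values(out)


def score_log_density(density: RasterLayer, coeff: float = 2.5) -> RasterLayer:
    """Census population-density scoring: ``min(10, coeff · log10(density + 1))``."""
    vals = density.values.astype(float)
    valid = ~density.nodata_mask
    if np.any(vals[valid] < 0):
        raise HFError("population densities must be non-negative")
    out = np.where(valid, np.minimum(10.0, coeff * np.log10(np.abs(vals) + 1)), vals)
    return density.with_values(out)


def score_linear(
    values: RasterLayer, vmin: float = 0.5, vmax: float = 60.0, smax: float = 10.0
) -> RasterLayer:
    """Linear ramp: below ``vmin`` → 0, at/above ``vmax`` → ``smax``."""
    if vmax <= vmin:
        raise HFError(f"vmax ({vmax}) must exceed vmin ({vmin})")
    v = values.values.astype(float)
    out = np.clip(smax * (v - vmin) / (vmax - vmin), 0.0, smax)
    out[v < vmin] = 0.0
    out[values.nodata_mask] = values.nodata
    return values.with_values(out)


def score_points(
    points: FeatureSet,
    grid: GridSpec,
    score: float,
    mode: Literal["actual", "approx"],
    radius: float | None = None,
    s0: float = 4.0,
    max_distance: float = 100.0,
    floor: float = 0.1,
) -> RasterLayer:
    """Score point infrastructure.

    ``actual``: the feature footprint is known to exceed a pixel; the score is
    burned on every pixel whose center lies within ``radius`` of a point.
    ``approx``: the location is approximate; the point pixel receives the
    score and its surroundings a halo decaying exponentially from ``s0`` to
    zero at ``max_distance``.  Points outside the grid are skipped (with a
    warning reporting how many).
    """
    if points.geometry_kind != "point":
        raise HFError("score_points requires point features")
    inside, n_skipped = [], 0
    for geom, attrs in points.features:
        pts = geom.geoms if geom.geom_type == "MultiPoint" else [geom]
        for p in pts:
            if grid.contains(p.x, p.y):
                inside.append((p, attrs))
            else:
                n_skipped += 1
    if n_skipped:
        warnings.warn(f"score_points: skipped {n_skipped} point(s) outside the grid")
    if not inside:
        return RasterLayer.zeros(grid)
    kept = FeatureSet("point", inside, points.crs_id or grid.crs_id)
    presence = rasterize(kept, grid, 1.0)
    dist = euclidean_distance(presence)

    if mode == "actual":
        if radius is None or radius < grid.pixel_size:
            raise HFError("actual mode needs a radius of at least one pixel")
        out = np.where(dist.values <= radius, float(score), 0.0)
    elif mode == "approx":
        halo = decay_score(dist.values, s0, max_distance, floor)
        out = np.where(presence.values > 0, float(score), halo)
    else:
        raise HFError(f"unknown point-scoring mode {mode!r}")
    return RasterLayer(grid, out, "continuous")


# ---------------------------------------------------------------------------
# dataset scoring specification

Case = Literal[
    "direct", "decay", "log_count", "log_density", "linear", "point_actual", "point_approx"
]

_REQUIRED_PARAMS: dict[str, tuple[str, ...]] = {
    "direct": (),
    "decay": ("s0", "max_distance"),
    "log_count": (),
    "log_density": (),
    "linear": (),
    "point_actual": ("score", "radius"),
    "point_approx": ("score",),
}


@dataclass
class DatasetScoreSpec:
    """How one input dataset becomes a scored raster in [0, max_score]."""

    dataset_id: str
    pressure_id: str
    case: Case
    params: dict = field(default_factory=dict)
    qualifications: tuple[float, float, float, float] | None = None
    max_score: float | None = None
    template: ScoringTemplate = DEFAULT_TEMPLATE

    def __post_init__(self) -> None:
        if self.pressure_id not in PRESSURE_IDS:
            raise HFError(
                f"dataset {self.dataset_id!r}: unknown pressure {self.pressure_id!r}"
            )
        if self.case not in _REQUIRED_PARAMS:
            raise HFError(f"dataset {self.dataset_id!r}: unknown scoring case {self.case!r}")
        missing = [k for k in _REQUIRED_PARAMS[self.case] if k not in self.params]
        if missing:
            raise HFError(
                f"dataset {self.dataset_id!r}: case {self.case!r} missing params {missing}"
            )
        if self.max_score is None:
            if self.qualifications is None:
                self.max_score = 10.0
            else:
                self.max_score = self.template.max_score(self.qualifications)
        if not 0 <= self.max_score <= 10:
            raise HFError(
                f"dataset {self.dataset_id!r}: max score {self.max_score} outside [0, 10]"
            )

    def apply(self, data: RasterLayer | FeatureSet, grid: GridSpec) -> RasterLayer:
        """Run the declared scoring case and cap at the dataset maximum."""
        p = self.params
        if self.case == "direct":
            if isinstance(data, FeatureSet):
                scored = rasterize(data, grid, p.get("score", self.max_score))
            else:
                scored = score_direct(data, p.get("mapping", {1: self.max_score}))
        elif self.case == "decay":
            if isinstance(data, FeatureSet):
                data = rasterize(data, grid, 1.0)
            dist = euclidean_distance(data)
            scored = score_exponential_decay(
                dist, p["s0"], p["max_distance"], p.get("floor", 0.1)
            )
        elif self.case == "log_count":
            scored = score_log_count(
                data, p.get("coeff", 5.41), p.get("cap_threshold", 70.0)
            )
        elif self.case == "log_density":
            scored = score_log_density(data, p.get("coeff", 2.5))
        elif self.case == "linear":
            scored = score_linear(
                data, p.get("vmin", 0.5), p.get("vmax", 60.0), p.get("smax", 10.0)
            )
        elif self.case == "point_actual":
            scored = score_points(data, grid, p["score"], "actual", radius=p["radius"])
        else:  # point_approx
            scored = score_points(
                data, grid, p["score"], "approx",
                s0=p.get("s0", 4.0),
                max_distance=p.get("max_distance", 100.0),
                floor=p.get("floor", 0.1),
            )
        valid = ~scored.nodata_mask
        out = scored.values.copy()
        out[valid] = np.minimum(out[valid], self.max_score)
        return scored.with_values(out)
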