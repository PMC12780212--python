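"""Common projected grid, raster/vector containers and core raster operators.

Every layer in the pipeline lives on a shared :class:`GridSpec`: a projected,
meter-unit, north-up grid with square pixels (30 m by default), top-left
origin and row-major storage.  Pixel centers sit at
``origin + (index + 0.5) * pixel_size``; all distances are center-to-center.

Operations never reproject: layers must already share a CRS identifier, and a
mismatch is rejected (reprojection is an input-preparation step, outside this
package).  :func:`regrid` is the convenience wrapper that resamples a raster
onto another grid *within* the same CRS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry.base import BaseGeometry

from .errors import GeometryError, GridMismatchError, HFError

NODATA_CONTINUOUS = -9999.0
NODATA_CATEGORICAL = 255

Kind = Literal["continuous", "categorical"]
GeometryKind = Literal["point", "line", "polygon"]

_KIND_TO_GEOM_TYPES = {
    "point": ("Point", "MultiPoint"),
    "line": ("LineString", "MultiLineString"),
    "polygon": ("Polygon", "MultiPolygon"),
}


@dataclass(frozen=True)
class GridSpec:
    """Georeferencing contract for a projected, meter-unit raster grid."""

    crs_id: str
    origin_x: float
    origin_y: float
    n_rows: int
    n_cols: int
    pixel_size: float = 30.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise HFError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise HFError("grid must have at least one row and one column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.pixel_size,
            self.origin_x + self.n_cols * self.pixel_size,
            self.origin_y,
        )

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates as 1-D arrays (xs of columns, ys of rows)."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.pixel_size
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * self.pixel_size
        return xs, ys

    def world_to_pixel(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the pixel containing map point (x, y)."""
        col = int(math.floor((x - self.origin_x) / self.pixel_size))
        row = int(math.floor((self.origin_y - y) / self.pixel_size))
        return row, col

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.pixel_size,
            self.origin_y - (row + 0.5) * self.pixel_size,
        )

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return xmin <= x < xmax and ymin < y <= ymax


@dataclass
class RasterLayer:
    """A single-band raster bound to a :class:`GridSpec`."""

    grid: GridSpec
    values: np.ndarray
    kind: Kind = "continuous"
    nodata: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise HFError(
                f"raster shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.kind not in ("continuous", "categorical"):
            raise HFError(f"unknown raster kind {self.kind!r}")
        if self.nodata is None:
            self.nodata = (
                NODATA_CONTINUOUS if self.kind == "continuous" else NODATA_CATEGORICAL
            )

    @classmethod
    def full(
        cls, grid: GridSpec, fill: float, kind: Kind = "continuous", nodata=None
    ) -> "RasterLayer":
        dtype = float if kind == "continuous" else np.int64
        return cls(grid, np.full(grid.shape, fill, dtype=dtype), kind, nodata)

    @classmethod
    def zeros(cls, grid: GridSpec, kind: Kind = "continuous", nodata=None) -> "RasterLayer":
        return cls.full(grid, 0, kind, nodata)

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.values == self.nodata

    def with_values(self, values: np.ndarray, kind: Kind | None = None, nodata=None) -> "RasterLayer":
        return RasterLayer(self.grid, values, kind or self.kind,
                           self.nodata if nodata is None else nodata)

    def require_same_grid(self, other: "RasterLayer | GridSpec") -> None:
        grid = other.grid if isinstance(other, RasterLayer) else other
        if grid != self.grid:
            raise GridMismatchError(f"grids differ: {self.grid} vs {grid}")


@dataclass
class FeatureSet:
    """Homogeneous vector features (geometry + attributes) in one CRS."""

    geometry_kind: GeometryKind
    features: list[tuple[BaseGeometry, dict]] = field(default_factory=list)
    crs_id: str = ""

    def __post_init__(self) -> None:
        allowed = _KIND_TO_GEOM_TYPES.get(self.geometry_kind)
        if allowed is None:
            raise GeometryError(f"unknown geometry kind {self.geometry_kind!r}")
        for i, (geom, _attrs) in enumerate(self.features):
            if geom.geom_type not in allowed:
                raise GeometryError(
                    f"feature {i}: {geom.geom_type} is not a {self.geometry_kind}"
                )
            if not geom.is_valid:
                raise GeometryError(f"feature {i}: invalid geometry")

    def __len__(self) -> int:
        return len(self.features)

    def geometries(self) -> list[BaseGeometry]:
        return [g for g, _ in self.features]


# ---------------------------------------------------------------------------
# rasterization

def _segment_cells(c0: float, r0: float, c1: float, r1: float) -> Iterable[tuple[int, int]]:
    """Grid cells traversed by a segment, in continuous (col, row) pixel space.

    Amanatides–Woo voxel traversal: yields every cell the segment passes
    through ("all touched"), endpoints included.
    """
    ix, iy = int(math.floor(c0)), int(math.floor(r0))
    ix1, iy1 = int(math.floor(c1)), int(math.floor(r1))
    dx, dy = c1 - c0, r1 - r0
    step_x = 1 if dx > 0 else -1
    step_y = 1 if dy > 0 else -1
    if dx != 0:
        t_delta_x = abs(1.0 / dx)
        next_x = ix + (1 if dx > 0 else 0)
        t_max_x = (next_x - c0) / dx
    else:
        t_delta_x = math.inf
        t_max_x = math.inf
    if dy != 0:
        t_delta_y = abs(1.0 / dy)
        next_y = iy + (1 if dy > 0 else 0)
        t_max_y = (next_y - r0) / dy
    else:
        t_delta_y = math.inf
        t_max_y = math.inf

    yield ix, iy
    # bound on traversal length protects against degenerate float cases
    for _ in range(abs(ix1 - ix) + abs(iy1 - iy) + 4):
        if ix == ix1 and iy == iy1:
            return
        if t_max_x < t_max_y:
            t_max_x += t_delta_x
            ix += step_x
        else:
            t_max_y += t_delta_y
            iy += step_y
        yield ix, iy


def _line_cells(geom: BaseGeometry, grid: GridSpec) -> Iterable[tuple[int, int]]:
    parts = geom.geoms if geom.geom_type == "MultiLineString" else [geom]
    ps = grid.pixel_size
    for part in parts:
        coords = np.asarray(part.coords)
        cols = (coords[:, 0] - grid.origin_x) / ps
        rows = (grid.origin_y - coords[:, 1]) / ps
        for k in range(len(coords) - 1):
            yield from _segment_cells(cols[k], rows[k], cols[k + 1], rows[k + 1])


def _polygon_burn_mask(geom: BaseGeometry, grid: GridSpec) -> tuple[slice, slice, np.ndarray]:
    """Window slices and boolean mask of pixel centers covered by a polygon."""
    xmin, ymin, xmax, ymax = geom.bounds
    ps = grid.pixel_size
    c0 = max(0, int(math.floor((xmin - grid.origin_x) / ps)))
    c1 = min(grid.n_cols, int(math.ceil((xmax - grid.origin_x) / ps)))
    r0 = max(0, int(math.floor((grid.origin_y - ymax) / ps)))
    r1 = min(grid.n_rows, int(math.ceil((grid.origin_y - ymin) / ps)))
    if c0 >= c1 or r0 >= r1:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0), bool)
    xs = grid.origin_x + (np.arange(c0, c1) + 0.5) * ps
    ys = grid.origin_y - (np.arange(r0, r1) + 0.5) * ps
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(geom, xx.ravel(), yy.ravel()).reshape(xx.shape)
    return slice(r0, r1), slice(c0, c1), inside


def rasterize(
    features: FeatureSet,
    grid: GridSpec,
    burn: float | str,
    background: float = 0.0,
) -> RasterLayer:
    """Burn vector features onto the grid, resolving overlaps by maximum.

    ``burn`` is either a constant score or the name of a feature attribute.
    Polygons burn pixels whose *centers* they contain; lines and points burn
    every pixel they touch.  Pixels touched by no feature keep ``background``.
    """
    if features.crs_id and features.crs_id != grid.crs_id:
        raise GridMismatchError(
            f"feature CRS {features.crs_id!r} does not match grid CRS {grid.crs_id!r}"
        )
    out = np.full(grid.shape, background, dtype=float)

    for i, (geom, attrs) in enumerate(features.features):
        if isinstance(burn, str):
            if burn not in attrs:
                raise GeometryError(f"feature {i}: missing burn attribute {burn!r}")
            value = float(attrs[burn])
        else:
            value = float(burn)

        if features.geometry_kind == "polygon":
            rs, cs, inside = _polygon_burn_mask(geom, grid)
            window = out[rs, cs]
            window[inside] = np.maximum(window[inside], value)
        elif features.geometry_kind == "line":
            for col, row in _line_cells(geom, grid):
                if 0 <= row < grid.n_rows and 0 <= col < grid.n_cols:
                    out[row, col] = max(out[row, col], value)
        else:  # point
            pts = geom.geoms if geom.geom_type == "MultiPoint" else [geom]
            for p in pts:
                row, col = grid.world_to_pixel(p.x, p.y)
                if 0 <= row < grid.n_rows and 0 <= col < grid.n_cols:
                    out[row, col] = max(out[row, col], value)

    return RasterLayer(grid, out, "continuous")


# ---------------------------------------------------------------------------
# resampling

def resample(raster: RasterLayer, target: GridSpec) -> RasterLayer:
    """Resample onto ``target``: bilinear for continuous, mode for categorical.

    The categorical mode aggregates source pixels whose centers fall inside
    each target cell; target cells receiving no source center (upsampling)
    take the nearest source pixel.  Nodata propagates and never votes.
    """
    if raster.grid.crs_id != target.crs_id:
        raise GridMismatchError("resample requires matching CRS")
    if raster.kind == "continuous":
        return _resample_bilinear(raster, target)
    if raster.kind == "categorical":
        return _resample_mode(raster, target)
    raise HFError(f"unknown raster kind {raster.kind!r}")


def _target_center_source_indices(src: GridSpec, target: GridSpec):
    xs, ys = target.pixel_centers()
    cols = (xs - src.origin_x) / src.pixel_size - 0.5
    rows = (src.origin_y - ys) / src.pixel_size - 0.5
    return np.meshgrid(cols, rows)  # (col grid, row grid)


def _resample_bilinear(raster: RasterLayer, target: GridSpec) -> RasterLayer:
    cols, rows = _target_center_source_indices(raster.grid, target)
    vals = raster.values.astype(float)
    vals[raster.nodata_mask] = np.nan
    out = ndimage.map_coordinates(
        vals, [rows.ravel(), cols.ravel()], order=1, mode="constant", cval=np.nan
    ).reshape(target.shape)
    nodata = NODATA_CONTINUOUS
    out = np.where(np.isnan(out), nodata, out)
    return RasterLayer(target, out, "continuous", nodata)


def _resample_mode(raster: RasterLayer, target: GridSpec) -> RasterLayer:
    src = raster.grid
    xs, ys = src.pixel_centers()
    tcols = np.floor((xs - target.origin_x) / target.pixel_size).astype(int)
    trows = np.floor((target.origin_y - ys) / target.pixel_size).astype(int)
    cc, rr = np.meshgrid(tcols, trows)
    valid = (
        (cc >= 0) & (cc < target.n_cols) & (rr >= 0) & (rr < target.n_rows)
        & ~raster.nodata_mask
    )
    codes = np.unique(raster.values[~raster.nodata_mask])
    code_pos = {c: i for i, c in enumerate(codes)}
    n_cells = target.n_rows * target.n_cols
    counts = np.zeros((n_cells, len(codes)), dtype=np.int64)
    if valid.any():
        flat_cell = rr[valid] * target.n_cols + cc[valid]
        flat_code = np.vectorize(code_pos.get, otypes=[np.int64])(raster.values[valid])
        np.add.at(counts, (flat_cell, flat_code), 1)

    nodata = NODATA_CATEGORICAL
    out = np.full(n_cells, nodata, dtype=np.int64)
    has_votes = counts.sum(axis=1) > 0
    if len(codes):
        out[has_votes] = codes[np.argmax(counts[has_votes], axis=1)]

    if not has_votes.all():
        # upsampling: fall back to nearest source pixel (within the extent)
        cols, rows = _target_center_source_indices(src, target)
        nearest = ndimage.map_coordinates(
            raster.values.astype(float),
            [rows.ravel(), cols.ravel()],
            order=0, mode="nearest",
        )
        inside = (
            (cols.ravel() >= -0.5) & (cols.ravel() <= src.n_cols - 0.5)
            & (rows.ravel() >= -0.5) & (rows.ravel() <= src.n_rows - 0.5)
        )
        nearest[~inside] = nodata
        out[~has_votes] = nearest[~has_votes].astype(np.int64)
    return RasterLayer(target, out.reshape(target.shape), "categorical", nodata)


def regrid(raster: RasterLayer, target: GridSpec) -> RasterLayer:
    """Convenience re-gridder (same CRS); alias of :func:`resample`."""
    return resample(raster, target)


# ---------------------------------------------------------------------------
# distance, clusters, masking

def euclidean_distance(mask: RasterLayer) -> RasterLayer:
    """Meter distance from every pixel center to the nearest on-pixel center."""
    on = _binary(mask)
    if not on.any():
        raise HFError("euclidean_distance requires at least one on-pixel")
    dist = ndimage.distance_transform_edt(~on, sampling=mask.grid.pixel_size)
    return RasterLayer(mask.grid, dist, "continuous")


def connected_clusters(
    mask: RasterLayer, connectivity: Literal[4, 8] = 8
) -> tuple[RasterLayer, np.ndarray]:
    """Label connected components of a binary mask.

    Returns the label raster (0 = background) and an array of cluster sizes,
    ``sizes[k]`` being the pixel count of label ``k + 1``.
    """
    if connectivity not in (4, 8):
        raise HFError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labels, n = ndimage.label(_binary(mask), structure=structure)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return RasterLayer(mask.grid, labels, "categorical", nodata=0), sizes


def mask_water(raster: RasterLayer, water: RasterLayer) -> RasterLayer:
    """Set water pixels to nodata, leaving everything else untouched."""
    raster.require_same_grid(water)
    out = raster.values.copy()
    out[_binary(water)] = raster.nodata
    return raster.with_values(out)


def _binary(layer: RasterLayer) -> np.ndarray:
    return (layer.values != 0) & ~layer.nodata_mask
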