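"""Plain-text raster and vector I/O.

Rasters travel as ESRI ASCII grids (``.asc``) with a ``.prj``-style sidecar
carrying the CRS identifier; vectors as GeoJSON.  Both are text formats that
any GIS reads directly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import shapely.geometry

from .errors import HFError
from .grid import FeatureSet, GeometryKind, GridSpec, Kind, RasterLayer


def write_ascii_grid(layer: RasterLayer, path: str | Path) -> None:
    path = Path(path)
    g = layer.grid
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin_x!r}\n"
        f"yllcorner {g.origin_y - g.n_rows * g.pixel_size!r}\n"
        f"cellsize {g.pixel_size!r}\n"
        f"NODATA_value {layer.nodata!r}\n"
    )
    fmt = "%d" if np.issubdtype(layer.values.dtype, np.integer) else "%.8g"
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, layer.values, fmt=fmt)
    if g.crs_id:
        path.with_suffix(path.suffix + ".prj").write_text(g.crs_id + "\n")


def read_ascii_grid(path: str | Path, kind: Kind = "continuous") -> RasterLayer:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        values = np.loadtxt(fh)
    try:
        n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
        cellsize = header["cellsize"]
        origin_x = header["xllcorner"]
        origin_y = header["yllcorner"] + n_rows * cellsize
        nodata = header.get("nodata_value")
    except KeyError as exc:  # pragma: no cover - malformed input
        raise HFError(f"{path}: missing ASCII-grid header field {exc}") from exc
    prj = path.with_suffix(path.suffix + ".prj")
    crs_id = prj.read_text().strip() if prj.exists() else ""
    grid = GridSpec(crs_id, origin_x, origin_y, n_rows, n_cols, cellsize)
    values = values.reshape(grid.shape)
    if kind == "categorical":
        values = values.astype(np.int64)
    return RasterLayer(grid, values, kind, nodata)


def write_geojson(features: FeatureSet, path: str | Path) -> None:
    doc = {
        "type": "FeatureCollection",
        "hfmap:geometry_kind": features.geometry_kind,
        "hfmap:crs_id": features.crs_id,
        "features": [
            {
                "type": "Feature",
                "geometry": shapely.geometry.mapping(geom),
                "properties": attrs,
            }
            for geom, attrs in features.features
        ],
    }
    Path(path).write_text(json.dumps(doc))


_GEOJSON_KINDS: dict[str, GeometryKind] = {
    "Point": "point", "MultiPoint": "point",
    "LineString": "line", "MultiLineString": "line",
    "Polygon": "polygon", "MultiPolygon": "polygon",
}


def read_geojson(path: str | Path, geometry_kind: GeometryKind | None = None) -> FeatureSet:
    doc = json.loads(Path(path).read_text())
    feats = [
        (shapely.geometry.shape(f["geometry"]), dict(f.get("properties") or {}))
        for f in doc.get("features", [])
    ]
    kind = geometry_kind or doc.get("hfmap:geometry_kind")
    if kind is None:
        if not feats:
            raise HFError(f"{path}: empty collection with no declared geometry kind")
        kind = _GEOJSON_KINDS[feats[0][0].geom_type]
    return FeatureSet(kind, feats, doc.get("hfmap:crs_id", ""))
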