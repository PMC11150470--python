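"""Plain-text raster and vector I/O.

Rasters are stored as ESRI ASCII grids (one file per band), polygons as
GeoJSON, tables as CSV.  All coordinates are planar meters with the origin
at the raster's upper-left corner; the y axis runs *downward* with the row
index (row r, col c -> center x=(c+0.5)*cellsize, y=(r+0.5)*cellsize).
This is a self-consistent local frame, not a geographic CRS.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import shapely.geometry as sgeom

DEFAULT_NODATA = -9999


def write_ascii_grid(path, array, cellsize, nodata=DEFAULT_NODATA, fmt=None):
    """Write a 2-D array as an ESRI ASCII grid. NaN cells become *nodata*."""
    array = np.asarray(array)
    if array.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {array.shape}")
    nrows, ncols = array.shape
    if fmt is None:
        fmt = "%d" if np.issubdtype(array.dtype, np.integer) else "%.6g"
    out = array.astype(float, copy=True)
    out[~np.isfinite(out)] = nodata
    if np.issubdtype(array.dtype, np.integer):
        out = out.astype(np.int64)
    header = (
        f"ncols {ncols}\nnrows {nrows}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize {cellsize}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)


def read_ascii_grid(path, masked=False):
    """Read an ESRI ASCII grid.

    Returns ``(array, cellsize)``.  With ``masked=True`` nodata cells are
    returned as NaN (array is float); otherwise the raw values are kept.
    """
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    if masked:
        data = data.astype(float)
        data[data == nodata] = np.nan
    return data, header["cellsize"]


def write_units_geojson(units: pd.DataFrame, path) -> None:
    """Write analysis units (unit_id, country_id, forest_area_km2, geometry)."""
    feats = []
    for _, row in units.iterrows():
        feats.append(
            {
                "type": "Feature",
                "properties": {
                    "unit_id": int(row["unit_id"]),
                    "country_id": int(row["country_id"]),
                    "forest_area_km2": float(row["forest_area_km2"]),
                },
                "geometry": sgeom.mapping(row["geometry"]),
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_units_geojson(path) -> pd.DataFrame:
    raw = json.loads(Path(path).read_text())
    rows = []
    for feat in raw["features"]:
        props = dict(feat["properties"])
        props["geometry"] = sgeom.shape(feat["geometry"])
        rows.append(props)
    return pd.DataFrame(rows)


def unit_id_grid(units: pd.DataFrame, shape, pixel_size) -> np.ndarray:
    """Rasterize unit polygons by pixel-center containment.

    Returns an int32 grid of unit_ids, -1 where no unit contains the pixel
    center.  Pixels claimed by several (overlapping) units go to the unit
    listed first.
    """
    nrows, ncols = shape
    xs = (np.arange(ncols) + 0.5) * pixel_size
    ys = (np.arange(nrows) + 0.5) * pixel_size
    X, Y = np.meshgrid(xs, ys)
    grid = np.full(shape, -1, dtype=np.int32)
    for _, row in units.iterrows():
        geom = row["geometry"]
        if not geom.is_valid:
            raise ValueError(f"invalid polygon for unit_id={row['unit_id']}")
        inside = shapely.contains_xy(geom, X.ravel(), Y.ravel()).reshape(shape)
        grid[inside & (grid == -1)] = int(row["unit_id"])
    return grid
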