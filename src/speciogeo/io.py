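"""Text-format exports: Newick, CSV, GeoJSON and ESRI ASCII grid rasters.

All outputs are plain text.  Grid-cell geometries (ranges, bioregions) are
axis-aligned degree rectangles, written as GeoJSON polygons; rasters go to
the ESRI ASCII grid format (readable by any GIS and by numpy).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .simulate import GridSpec
from .trees import Phylogeny

__all__ = [
    "write_newick_set",
    "write_ascii_grid",
    "read_ascii_grid",
    "ranges_to_geojson",
    "bioregions_to_geojson",
]


def write_newick_set(trees: list[Phylogeny], path: str | Path) -> None:
    """One Newick string per line (posterior-sample layout)."""
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick().rstrip("\n") + "\n")


def write_ascii_grid(
    raster: np.ndarray,
    grid: GridSpec,
    path: str | Path,
    nodata: float = -9999.0,
) -> None:
    """ESRI ASCII grid export (row 0 = northernmost, as stored)."""
    a = np.asarray(raster, float)
    if a.shape != (grid.n_rows, grid.n_cols):
        raise ValueError("raster shape does not match grid")
    a = np.where(np.isnan(a), nodata, a)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.lon_min}\n"
        f"yllcorner {grid.lat_min}\n"
        f"cellsize {grid.resolution}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, a, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid back into (raster, GridSpec)."""
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            k, v = fh.readline().split()
            hdr[k.lower()] = float(v)
        a = np.loadtxt(fh)
    res = hdr["cellsize"]
    grid = GridSpec(
        lat_min=hdr["yllcorner"],
        lat_max=hdr["yllcorner"] + res * hdr["nrows"],
        lon_min=hdr["xllcorner"],
        lon_max=hdr["xllcorner"] + res * hdr["ncols"],
        resolution=res,
    )
    a = np.where(a == hdr["nodata_value"], np.nan, a)
    return a.reshape(grid.n_rows, grid.n_cols), grid


def _cell_polygon(grid: GridSpec, cell_id: int) -> list[list[list[float]]]:
    row, col = grid.rowcol(cell_id)
    n = grid.lat_max - row * grid.resolution
    s = n - grid.resolution
    w = grid.lon_min + col * grid.resolution
    e = w + grid.resolution
    return [[[w, s], [e, s], [e, n], [w, n], [w, s]]]


def ranges_to_geojson(
    ranges: dict[str, np.ndarray], grid: GridSpec, path: str | Path
) -> None:
    """Each species becomes a MultiPolygon of its occupied cells."""
    feats = []
    for sp in sorted(ranges):
        feats.append(
            {
                "type": "Feature",
                "properties": {"species": sp,
                               "n_cells": int(len(ranges[sp]))},
                "geometry": {
                    "type": "MultiPolygon",
                    "coordinates": [
                        _cell_polygon(grid, int(c)) for c in ranges[sp]
                    ],
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def bioregions_to_geojson(
    bioregions: np.ndarray, grid: GridSpec, path: str | Path
) -> None:
    """Each bioregion becomes a MultiPolygon of its member cells."""
    b = np.asarray(bioregions).ravel()
    feats = []
    for j in np.unique(b):
        cells = np.flatnonzero(b == j)
        feats.append(
            {
                "type": "Feature",
                "properties": {"region": int(j),
                               "n_cells": int(len(cells))},
                "geometry": {
                    "type": "MultiPolygon",
                    "coordinates": [
                        _cell_polygon(grid, int(c)) for c in cells
                    ],
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
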