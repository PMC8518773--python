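"""GeoTIFF and table I/O.

Rasters are stored as plain (Geo)TIFFs carrying the three tags every GIS
understands: ModelPixelScale (33550), ModelTiepoint (33922) and GDAL_NODATA
(42113).  Only square-cell, north-up rasters in a single planar CRS are
supported; there is no reprojection.
"""
from __future__ import annotations

import os

import numpy as np
import tifffile

from .grid import Grid, MultibandRaster, Raster, ClassRaster

__all__ = ["read_raster", "write_raster", "read_class_raster", "write_class_raster"]

_TAG_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_NODATA = 42113


def _geotags(grid: Grid, *, integer: bool = False) -> list:
    ox, oy = grid.origin
    nodata = repr(int(grid.nodata)) if integer else repr(grid.nodata)
    return [
        (_TAG_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0), True),
        (_TAG_NODATA, "s", 0, nodata, True),
    ]


def write_raster(path: str | os.PathLike,
                 raster: Raster | MultibandRaster | ClassRaster) -> None:
    """Write a raster to GeoTIFF, encoding invalid cells as the nodata sentinel."""
    grid = raster.grid
    integer = isinstance(raster, ClassRaster)
    if integer:
        data = raster.labels.astype(np.int16).copy()
        data[~raster.mask] = int(grid.nodata)
    elif isinstance(raster, MultibandRaster):
        data = raster.values.astype(np.float64).copy()
        data[:, ~raster.mask] = grid.nodata
    else:
        data = raster.values.astype(np.float64).copy()
        data[~raster.mask] = grid.nodata
    tifffile.imwrite(path, data, extratags=_geotags(grid, integer=integer),
                     photometric="minisblack")


def _read_grid(page: tifffile.TiffPage, shape: tuple[int, int]) -> Grid:
    tags = page.tags
    if _TAG_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise ValueError("file lacks GeoTIFF georeferencing tags")
    sx, sy = tags[_TAG_SCALE].value[:2]
    if abs(sx - sy) > 1e-9:
        raise ValueError(f"non-square cells: {sx} x {sy}")
    tie = tags[_TAG_TIEPOINT].value
    nodata = float(tags[_TAG_NODATA].value) if _TAG_NODATA in tags else -9999.0
    return Grid(nrows=shape[0], ncols=shape[1], cell_size=float(sx),
                origin=(float(tie[3]), float(tie[4])), nodata=nodata)


def read_raster(path: str | os.PathLike,
                expected_bands: int = 1) -> Raster | MultibandRaster:
    """Read a single- or 4-band GeoTIFF written by :func:`write_raster`.

    Raises on a missing file, a band-count mismatch, or non-square cells.
    Nodata cells come back masked (and compare equal to the grid sentinel
    in the raw value matrix).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(float)
        if data.ndim == 2:
            nbands, shape = 1, data.shape
        else:
            nbands, shape = data.shape[0], data.shape[1:]
        if nbands != expected_bands:
            raise ValueError(f"expected {expected_bands} band(s), file has {nbands}")
        grid = _read_grid(tf.pages[0], shape)
    if nbands == 1:
        mask = ~np.isclose(data, grid.nodata)
        return Raster(grid, data, mask)
    mask = ~np.isclose(data, grid.nodata).any(axis=0)
    return MultibandRaster(grid, data, mask)


def read_class_raster(path: str | os.PathLike) -> ClassRaster:
    """Read an integer cover map (nodata sentinel marks unlabelled cells)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if data.ndim != 2:
            raise ValueError("class raster must be single-band")
        grid = _read_grid(tf.pages[0], data.shape)
    labels = data.astype(np.int16).copy()
    mask = labels != int(grid.nodata)
    labels[~mask] = 0  # ClassRaster treats label 0 as unlabelled
    return ClassRaster(grid, labels, mask)


def write_class_raster(path: str | os.PathLike, classes: ClassRaster) -> None:
    write_raster(path, classes)
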