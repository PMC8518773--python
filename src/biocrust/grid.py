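"""Shared raster data model: grids, single- and multi-band rasters, class maps.

Conventions
-----------
* Row 0 is the northernmost row; a cell's value refers to the cell centre.
* All distances are metres in one planar CRS; cells are square.
* Nodata is carried as an explicit boolean mask (``True`` = valid), never as
  a magic value inside arithmetic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable

import numpy as np

__all__ = [
    "Grid",
    "Raster",
    "MultibandRaster",
    "ClassRaster",
    "CoverClass",
    "BAND_LABELS",
    "BAND_CENTRES_NM",
    "BIOCRUST_CLASSES",
    "VEGETATION_CLASSES",
    "AlignmentError",
    "assert_aligned",
]

#: Band order of the 4-band multispectral camera (band centres in nm).
BAND_LABELS = ("green", "red", "red_edge", "nir")
BAND_CENTRES_NM = {"green": 550.0, "red": 660.0, "red_edge": 735.0, "nir": 790.0}


class CoverClass(IntEnum):
    """The seven surface covers mapped in the study site."""

    SOIL = 1        # bare soil
    BL = 2          # bright lichens
    BLM = 3         # bright lichens with moss
    MOSS = 4        # moss-dominated biocrust
    FULG = 5        # Fulgensia spp. with moss
    GREENVEG = 6    # green vascular vegetation (tussocks)
    DRYVEG = 7      # dry vascular vegetation


BIOCRUST_CLASSES = (CoverClass.BL, CoverClass.BLM, CoverClass.MOSS, CoverClass.FULG)
VEGETATION_CLASSES = (CoverClass.GREENVEG, CoverClass.DRYVEG)


class AlignmentError(ValueError):
    """Two rasters do not share the same grid."""


@dataclass(frozen=True)
class Grid:
    """Georeferencing header shared by all rasters of one scene.

    ``origin`` is the (easting, northing) of the *upper-left corner* of the
    upper-left cell; ``nodata`` is the sentinel used on disk only.
    """

    nrows: int
    ncols: int
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) in metres."""
        return (self.ncols * self.cell_size, self.nrows * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate arrays of cell centres, shape (nrows, ncols)."""
        ox, oy = self.origin
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = ox + (cols + 0.5) * self.cell_size
        y = oy - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col) indices (no bounds check)."""
        ox, oy = self.origin
        col = np.floor((np.asarray(x) - ox) / self.cell_size).astype(int)
        row = np.floor((oy - np.asarray(y)) / self.cell_size).astype(int)
        return row, col


def _check_values(grid: Grid, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(
            f"value matrix shape {values.shape} does not match grid {grid.shape}"
        )
    return values


@dataclass
class Raster:
    """A single-band grid-registered surface with an explicit validity mask."""

    grid: Grid
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = _check_values(self.grid, self.values)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError("mask shape does not match grid")
            self.mask = self.mask & np.isfinite(self.values)

    def filled(self, fill: float = np.nan) -> np.ndarray:
        """Values with invalid cells replaced by ``fill``."""
        out = self.values.copy()
        out[~self.mask] = fill
        return out

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Raster":
        return Raster(self.grid, values, self.mask.copy() if mask is None else mask)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


@dataclass
class MultibandRaster:
    """Four co-registered reflectance (or DN) bands: green, red, red-edge, NIR."""

    grid: Grid
    values: np.ndarray  # shape (4, nrows, ncols)
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    bands: tuple[str, ...] = BAND_LABELS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if tuple(self.bands) != BAND_LABELS:
            raise ValueError(f"bands must be {BAND_LABELS} in order")
        if self.values.shape != (4, *self.grid.shape):
            raise ValueError(
                f"expected 4 bands of shape {self.grid.shape}, got {self.values.shape}"
            )
        if self.mask is None:
            self.mask = np.isfinite(self.values).all(axis=0)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError("mask shape does not match grid")

    def band(self, label: str) -> Raster:
        """Extract one band as a :class:`Raster`."""
        i = self.bands.index(label)
        return Raster(self.grid, self.values[i].copy(), self.mask.copy())

    def filled(self, fill: float = np.nan) -> np.ndarray:
        out = self.values.copy()
        out[:, ~self.mask] = fill
        return out


@dataclass
class ClassRaster:
    """Integer surface-cover map over the seven :class:`CoverClass` codes."""

    grid: Grid
    labels: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError("label matrix shape does not match grid")
        self.labels = self.labels.astype(np.int16)
        if self.mask is None:
            self.mask = self.labels > 0
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError("mask shape does not match grid")
        valid = self.labels[self.mask]
        codes = {int(c) for c in CoverClass}
        bad = set(np.unique(valid).tolist()) - codes
        if bad:
            raise ValueError(f"labels outside the seven cover codes: {sorted(bad)}")

    def fraction(self, cls: CoverClass | Iterable[CoverClass]) -> float:
        """Fraction of valid cells carrying the given class(es)."""
        if isinstance(cls, CoverClass):
            cls = (cls,)
        sel = np.isin(self.labels, [int(c) for c in cls]) & self.mask
        n = self.mask.sum()
        return float(sel.sum() / n) if n else float("nan")


def assert_aligned(*rasters: Raster | MultibandRaster | ClassRaster,
                   tol: float = 1e-6) -> None:
    """Verify that all rasters share one grid (origin, cell size, shape).

    Raises :class:`AlignmentError` naming the first differing field; no
    silent resampling anywhere in the pipeline.
    """
    if len(rasters) < 2:
        return
    a = rasters[0].grid
    for other in rasters[1:]:
        b = other.grid
        if (a.nrows, a.ncols) != (b.nrows, b.ncols):
            raise AlignmentError(
                f"shape mismatch: {(a.nrows, a.ncols)} vs {(b.nrows, b.ncols)}"
            )
        if abs(a.cell_size - b.cell_size) > tol:
            raise AlignmentError(
                f"cell_size mismatch: {a.cell_size} vs {b.cell_size}"
            )
        if (abs(a.origin[0] - b.origin[0]) > tol
                or abs(a.origin[1] - b.origin[1]) > tol):
            raise AlignmentError(f"origin mismatch: {a.origin} vs {b.origin}")
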