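"""Apparent thermal inertia as a soil-moisture proxy.

Thermal DN convert to surface temperature as ``T = 0.01·R − 100`` (°C);
albedo is approximated as the mean of the four band reflectances; and the
apparent thermal inertia is ``ATI = C·(1−α)/ΔT`` (K⁻¹) with ΔT the diurnal
amplitude (noon minus pre-dawn surface temperature) and C a solar
correction constant (1.19 for this site and date).  Vegetation is masked
out before plot aggregation, and plot-mean ATI is regressed against
plot-mean soil moisture.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
import shapely

from .grid import (ClassRaster, MultibandRaster, Raster, VEGETATION_CLASSES,
                   assert_aligned)

__all__ = [
    "ATIConfig",
    "ATIRegressionResult",
    "dn_to_temperature",
    "temperature_to_dn",
    "albedo",
    "ati",
    "mask_vegetation",
    "zonal_mean",
    "regress_ati_moisture",
]


@dataclass(frozen=True)
class ATIConfig:
    """ATI constants: solar correction factor and minimum usable ΔT."""

    c_solar: float = 1.19
    delta_t_min: float = 0.1  # K

    def __post_init__(self) -> None:
        if self.c_solar <= 0:
            raise ValueError("solar correction factor must be positive")


def dn_to_temperature(raw: Raster) -> Raster:
    """T (°C) = 0.01·R − 100 for thermal-camera digital numbers."""
    return Raster(raw.grid, 0.01 * raw.values - 100.0, raw.mask.copy())


def temperature_to_dn(temp: Raster, *, quantize: bool = True) -> Raster:
    """Inverse mapping R = 100·(T + 100), optionally rounded to integer DN."""
    dn = 100.0 * (temp.values + 100.0)
    if quantize:
        dn = np.floor(dn + 0.5)
    return Raster(temp.grid, dn, temp.mask.copy())


def albedo(image: MultibandRaster) -> Raster:
    """Broadband albedo approximated as the mean of the four band reflectances."""
    return Raster(image.grid, image.values.mean(axis=0), image.mask.copy())


def ati(albedo_r: Raster, t_predawn: Raster, t_noon: Raster,
        config: ATIConfig = ATIConfig()) -> Raster:
    """ATI = C·(1−α)/ΔT with ΔT = T_noon − T_predawn.

    Cells with ΔT below ``delta_t_min`` or α >= 1 become nodata rather than
    producing unstable or negative values.
    """
    assert_aligned(albedo_r, t_predawn, t_noon)
    dt = t_noon.values - t_predawn.values
    a = albedo_r.values
    valid = (albedo_r.mask & t_predawn.mask & t_noon.mask
             & (dt >= config.delta_t_min) & (a < 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = config.c_solar * (1.0 - a) / dt
    return Raster(albedo_r.grid, vals, valid)


def mask_vegetation(raster: Raster, classes: ClassRaster) -> Raster:
    """Set green- and dry-vegetation cells to nodata; leave the rest."""
    assert_aligned(raster, classes)
    veg = np.isin(classes.labels, [int(c) for c in VEGETATION_CLASSES]) & classes.mask
    return Raster(raster.grid, raster.values.copy(), raster.mask & ~veg)


def zonal_mean(raster: Raster, polygons) -> tuple[np.ndarray, np.ndarray]:
    """Mean of valid cells whose centres fall inside each polygon.

    Returns (means, n_valid) arrays; a polygon with zero valid cells gets
    NaN and count 0 (callers should exclude those).  A polygon entirely
    outside the raster extent raises.
    """
    xs, ys = raster.grid.cell_centers()
    means = np.full(len(polygons), np.nan)
    counts = np.zeros(len(polygons), dtype=int)
    width, height = raster.grid.extent
    ox, oy = raster.grid.origin
    for i, poly in enumerate(polygons):
        minx, miny, maxx, maxy = poly.bounds
        if maxx < ox or minx > ox + width or maxy < oy - height or miny > oy:
            raise ValueError(f"polygon {i} lies fully outside the raster")
        r0, c0 = raster.grid.rowcol(minx, maxy)
        r1, c1 = raster.grid.rowcol(maxx, miny)
        r0, c0 = max(int(r0), 0), max(int(c0), 0)
        r1 = min(int(r1) + 1, raster.grid.nrows)
        c1 = min(int(c1) + 1, raster.grid.ncols)
        sub_x = xs[r0:r1, c0:c1].ravel()
        sub_y = ys[r0:r1, c0:c1].ravel()
        inside = shapely.contains_xy(poly, sub_x, sub_y).reshape(r1 - r0, c1 - c0)
        sel = inside & raster.mask[r0:r1, c0:c1]
        counts[i] = int(sel.sum())
        if counts[i]:
            means[i] = float(raster.values[r0:r1, c0:c1][sel].mean())
    return means, counts


@dataclass(frozen=True)
class ATIRegressionResult:
    """OLS fit of plot soil moisture on plot-mean ATI."""

    slope: float
    intercept: float
    r_squared: float
    n_plots: int
    residual_sd: float
    slope_stderr: float

    def slope_conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Two-sided (1−alpha) confidence interval for the slope."""
        t = stats.t.ppf(1.0 - alpha / 2.0, self.n_plots - 2)
        return (self.slope - t * self.slope_stderr,
                self.slope + t * self.slope_stderr)


def regress_ati_moisture(ati_means, moisture) -> ATIRegressionResult:
    """Ordinary least squares of soil moisture (%) on plot-mean ATI (K⁻¹)."""
    x = np.asarray(ati_means, dtype=float)
    y = np.asarray(moisture, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 plots with valid ATI/moisture pairs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in ATI")
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    rsd = float(np.sqrt((resid ** 2).sum() / (len(x) - 2))) if len(x) > 2 else 0.0
    r2 = float(fit.rvalue ** 2) if np.isfinite(fit.rvalue) else 0.0
    return ATIRegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=r2, n_plots=int(len(x)),
        residual_sd=rsd, slope_stderr=float(fit.stderr),
    )
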