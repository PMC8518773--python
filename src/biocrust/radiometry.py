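"""Radiometric calibration of 4-band multispectral imagery.

Raw digital numbers P are converted to pseudo-radiance per band,
``R = f²·(P − B)/(A·γ·ε + C)``, scaled to reflectance through the
panel-derived coefficient ``K = ρ_ref/R_ref`` (so ``ρ = K·R``), and finally
corrected with a per-band empirical line fitted against ground reference
targets.  Field spectra are resampled to the sensor bands with the band
response functions.

The denominator grouping ``A·γ·ε + C`` follows the published calibration
model for this camera family; the alternative groupings occasionally seen
in print differ only by a band-constant factor that the ``K`` scaling
cancels anyway.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import BAND_LABELS, MultibandRaster, Raster

__all__ = [
    "CameraParams",
    "Spectrum",
    "SensorBand",
    "EmpiricalLineModel",
    "resample_spectrum",
    "calibrate_dn",
    "fit_empirical_line",
    "apply_empirical_line",
]


def _per_band(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full(4, float(arr))
    if arr.shape != (4,):
        raise ValueError(f"{name} must be scalar or length-4 (one per band)")
    return arr


@dataclass(frozen=True)
class CameraParams:
    """Sensor calibration coefficients and exposure settings.

    ``a_coef``, ``b_coef``, ``c_coef`` are the camera-specific coefficients
    of the non-linear sensor model (per band or scalar); ``iso`` (γ),
    ``exposure`` (ε, seconds) and ``f_number`` (f) are the capture settings;
    ``panel_reflectance`` the manufacturer reflectance of the reference
    panel per band.
    """

    a_coef: np.ndarray = 2500.0
    b_coef: np.ndarray = 200.0
    c_coef: np.ndarray = 10.0
    iso: float = 800.0
    exposure: float = 0.01
    f_number: float = 2.2
    panel_reflectance: np.ndarray = 0.5
    dn_max: int = 65535

    def __post_init__(self) -> None:
        for name in ("a_coef", "b_coef", "c_coef", "panel_reflectance"):
            object.__setattr__(self, name, _per_band(getattr(self, name), name))
        if self.exposure <= 0 or self.f_number <= 0:
            raise ValueError("exposure and f-number must be positive")
        if np.any(self.denominator <= 0):
            raise ValueError("A*iso*exposure + C must be positive")

    @property
    def denominator(self) -> np.ndarray:
        return self.a_coef * self.iso * self.exposure + self.c_coef

    def dn_to_pseudo_radiance(self, dn) -> np.ndarray:
        """R = f²·(P − B)/(A·γ·ε + C), broadcast over (4, ...) arrays."""
        dn = np.asarray(dn, dtype=float)
        shape = (4,) + (1,) * (dn.ndim - 1)
        return (self.f_number ** 2 * (dn - self.b_coef.reshape(shape))
                / self.denominator.reshape(shape))

    def reflectance_to_dn(self, rho, k: np.ndarray) -> np.ndarray:
        """Invert the chain: P = B + ρ·(A·γ·ε + C)/(K·f²), unrounded."""
        rho = np.asarray(rho, dtype=float)
        shape = (4,) + (1,) * (rho.ndim - 1)
        k = np.asarray(k, dtype=float).reshape(shape)
        return (self.b_coef.reshape(shape)
                + rho * self.denominator.reshape(shape) / (k * self.f_number ** 2))


@dataclass(frozen=True)
class Spectrum:
    """A field spectroradiometer reflectance spectrum."""

    wavelengths: np.ndarray  # nm, strictly increasing
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if w.size < 2 or w.size != r.size:
            raise ValueError("spectrum needs >= 2 matching samples")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(r < 0) or np.any(r > 1.2):
            raise ValueError("reflectance must lie in [0, 1.2]")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "reflectance", r)


@dataclass(frozen=True)
class SensorBand:
    """A band response sampled as (wavelength, weight >= 0) pairs."""

    label: str
    wavelengths: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        g = np.asarray(self.weights, dtype=float)
        if w.size != g.size or w.size == 0:
            raise ValueError("response needs matching wavelength/weight samples")
        if np.any(g < 0) or g.sum() <= 0:
            raise ValueError("weights must be >= 0 with positive total")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "weights", g)

    @classmethod
    def gaussian(cls, label: str, centre: float, fwhm: float,
                 n: int = 41) -> "SensorBand":
        """Convenience Gaussian response over centre ± FWHM."""
        w = np.linspace(centre - fwhm, centre + fwhm, n)
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return cls(label, w, np.exp(-0.5 * ((w - centre) / sigma) ** 2))


def resample_spectrum(spectrum: Spectrum, bands: list[SensorBand]) -> np.ndarray:
    """Response-weighted mean of the (interpolated) spectrum in each band."""
    out = np.empty(len(bands))
    wmin, wmax = spectrum.wavelengths[0], spectrum.wavelengths[-1]
    for i, band in enumerate(bands):
        if band.wavelengths.min() < wmin or band.wavelengths.max() > wmax:
            raise ValueError(
                f"band {band.label!r} support outside spectrum range "
                f"[{wmin}, {wmax}] nm"
            )
        vals = np.interp(band.wavelengths, spectrum.wavelengths,
                         spectrum.reflectance)
        out[i] = np.average(vals, weights=band.weights)
    return out


def calibrate_dn(raw: MultibandRaster, cam: CameraParams,
                 panel_dn) -> tuple[MultibandRaster, np.ndarray]:
    """Raw DN → reflectance via the pseudo-radiance chain.

    ``panel_dn`` is the per-band mean DN over the reference panel (or any
    bright surface of known reflectance) captured with the same settings.
    Returns the reflectance raster (negatives floored at 0) and the
    per-band count of floored pixels.
    """
    panel_dn = _per_band(panel_dn, "panel_dn")
    r_ref = cam.dn_to_pseudo_radiance(panel_dn.reshape(4, 1)).ravel()
    if np.any(r_ref <= 0):
        raise ValueError("panel pseudo-radiance <= 0: panel darker than bias")
    k = cam.panel_reflectance / r_ref
    rho = k.reshape(4, 1, 1) * cam.dn_to_pseudo_radiance(raw.values)
    negative = (rho < 0) & raw.mask
    flagged = negative.sum(axis=(1, 2))
    rho = np.clip(rho, 0.0, None)
    return MultibandRaster(raw.grid, rho, raw.mask.copy()), flagged


@dataclass(frozen=True)
class EmpiricalLineModel:
    """Per-band linear map from sensor reflectance to ground reflectance."""

    gain: np.ndarray
    offset: np.ndarray
    n_targets: int
    residual_sd: np.ndarray

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.gain)) and np.all(np.isfinite(self.offset))):
            raise ValueError("non-finite empirical-line coefficients")


def fit_empirical_line(uav_reflectance: np.ndarray,
                       ground_reflectance: np.ndarray) -> EmpiricalLineModel:
    """Least-squares line per band through (UAV, ground) target reflectances.

    Inputs are (n_targets, 4) arrays; with exactly two targets the fit is
    exact interpolation.
    """
    uav = np.atleast_2d(np.asarray(uav_reflectance, dtype=float))
    gnd = np.atleast_2d(np.asarray(ground_reflectance, dtype=float))
    if uav.shape != gnd.shape or uav.shape[1] != 4:
        raise ValueError("targets must be (n, 4) arrays for both UAV and ground")
    n = uav.shape[0]
    if n < 2:
        raise ValueError("need >= 2 targets per band")
    gain = np.empty(4)
    offset = np.empty(4)
    resid_sd = np.empty(4)
    for b in range(4):
        x = uav[:, b]
        if np.ptp(x) == 0:
            raise ValueError(
                f"identical UAV reflectances in band {BAND_LABELS[b]}: singular fit"
            )
        gain[b], offset[b] = np.polyfit(x, gnd[:, b], 1)
        resid = gnd[:, b] - (gain[b] * x + offset[b])
        resid_sd[b] = float(np.std(resid, ddof=min(2, n - 1)) if n > 2 else 0.0)
    return EmpiricalLineModel(gain, offset, n, resid_sd)


def apply_empirical_line(model: EmpiricalLineModel,
                         image: MultibandRaster) -> MultibandRaster:
    """Apply the per-band line pixel-wise (negatives floored at 0)."""
    vals = (model.gain.reshape(4, 1, 1) * image.values
            + model.offset.reshape(4, 1, 1))
    return MultibandRaster(image.grid, np.clip(vals, 0.0, None), image.mask.copy())
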