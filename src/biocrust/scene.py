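"""Synthetic dryland study site with known ground truth.

Generates everything the pipeline consumes — DTM, soil-moisture field,
surface-cover map, multispectral reflectance and raw DN, a pre-dawn/noon
thermal pair, and a table of 2×2 m field plots with soil properties — from
one seed, with the statistical structure the field study reports:

* moisture increases with northernness and decreases with insolation,
  clipped to the observed 4.44–22.6 % range;
* moss cover rises and lichen cover falls with moisture; vascular
  vegetation forms clumped patches;
* apparent thermal inertia is a known linear function of moisture
  (ATI_true = a + b·moisture), which fixes the diurnal temperature
  amplitude ΔT = C·(1−α)/ATI_true;
* plot soluble salts decrease, and organic carbon / total P / total N
  increase, with plot northernness.

Every stochastic draw is Gaussian and independent per cell unless a
smoothing radius is requested; one seed reproduces the scene bit-exactly.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box

from .grid import (ClassRaster, CoverClass, Grid, MultibandRaster, Raster,
                   VEGETATION_CLASSES, assert_aligned)
from .radiometry import CameraParams
from .terrain import PSIRConfig, TerrainStack, compute_terrain_stack
from .thermal import ATIConfig

__all__ = [
    "SceneConfig",
    "EndmemberTable",
    "DEFAULT_ENDMEMBERS",
    "Scene",
    "generate_dtm",
    "generate_moisture",
    "generate_class_map",
    "generate_multispectral",
    "generate_thermal_pair",
    "generate_plot_table",
    "generate_scene",
]

# Table-4 soil attribute ranges (min, max) used as clip bounds
MOISTURE_RANGE = (4.44, 22.6)
SOLSAL_RANGE = (19.0, 96.0)
ORGCARB_RANGE = (0.14, 3.96)
PTOT_RANGE = (0.0, 7.26)
NTOT_RANGE = (0.01, 0.37)


@dataclass(frozen=True)
class EndmemberTable:
    """Per-class mean reflectance (4 bands) and per-band s.d.

    The default table is hand-authored config data chosen to honour the
    observed qualitative ordering: bright lichens are the brightest class,
    mosses the darkest biocrust (only dry vegetation is darker), green
    vegetation has the deepest chlorophyll absorption (lowest CR_red) and
    bare soil shows none (CR_red = 1).
    """

    means: dict  # CoverClass -> (4,) reflectance
    sds: dict    # CoverClass -> (4,) s.d.

    def mean_array(self) -> np.ndarray:
        return np.stack([np.asarray(self.means[c], dtype=float)
                         for c in CoverClass])

    def brightness(self, cls: CoverClass) -> float:
        return float(np.mean(self.means[cls]))


def _soil_endmember() -> tuple[float, ...]:
    # red sits exactly on the green→red-edge chord: CR_red = 1
    g, re = 0.20, 0.28
    red = g + (re - g) * (110.0 / 185.0)
    return (g, red, re, 0.30)


DEFAULT_ENDMEMBERS = EndmemberTable(
    means={
        CoverClass.SOIL: _soil_endmember(),
        CoverClass.BL: (0.35, 0.33, 0.40, 0.45),
        CoverClass.BLM: (0.28, 0.24, 0.33, 0.38),
        CoverClass.MOSS: (0.12, 0.075, 0.22, 0.30),
        CoverClass.FULG: (0.26, 0.22, 0.31, 0.36),
        CoverClass.GREENVEG: (0.10, 0.045, 0.25, 0.40),
        # dry litter: darkest class, only a weak residual red dip (CR ~0.93,
        # comfortably above the 0.75 repair threshold as in the field data)
        CoverClass.DRYVEG: (0.13, 0.135, 0.155, 0.185),
    },
    sds={c: (0.01, 0.01, 0.01, 0.01) for c in CoverClass},
)


@dataclass(frozen=True)
class SceneConfig:
    """Ground-truth parameters of the synthetic site.

    Defaults emulate the study conditions at a desk-scale extent: a gently
    inclined, bumpy 60×60 m hillslope at 0.5 m cells, 23 field plots, the
    Table-4 moisture range, and a positive ATI–moisture link.
    """

    extent: tuple[float, float] = (60.0, 60.0)  # m
    cell_size: float = 0.5                      # m
    seed: int = 0
    # gentle regional tilt plus knolls/hollows tall enough that local aspect
    # spans the full compass (the site's zones face W/E/S/N)
    plane_gradient: tuple[float, float] = (0.02, 0.03)  # dz/dx, dz/dy
    base_elevation: float = 620.0               # m a.s.l.
    bump_amplitude: float = 2.5                 # m
    bump_count: int = 12
    bump_sigma: tuple[float, float] = (5.0, 15.0)  # m, min/max footprint
    moisture_link: tuple[float, float, float, float] = (12.0, 8.0, -6.0, 1.0)
    # (m0 %, coef on min-max northernness, coef on min-max PSIR, noise sd %)
    clip_moisture: tuple[float, float] = MOISTURE_RANGE
    ati_link: tuple[float, float] = (0.02, 0.005)  # ATI = a + b*moisture (K^-1)
    thermal_baseline: float = 8.0               # pre-dawn surface temp, °C
    thermal_noise_sd: float = 0.5               # K, per thermal raster
    class_priors: tuple[float, ...] = (0.08, 0.05, 0.10, 0.20, 0.08, 0.09, 0.40)
    # order: Soil, BL, BLM, Moss, Fulg, GreenVeg, DryVeg
    class_response: tuple[float, ...] = (0.0, -0.5, -0.4, 0.9, -0.3, 0.0, 0.0)
    # log-odds shift per s.d. of moisture, same order
    veg_clump_scale: float = 2.0                # m, tussock patch scale
    reflectance_noise_sd: float = 0.01
    noise_smoothing_radius: float = 0.0         # m, 0 = independent noise
    camera: CameraParams = field(default_factory=CameraParams)
    k_true: tuple[float, ...] = (0.080, 0.082, 0.078, 0.081)
    ati_config: ATIConfig = field(default_factory=ATIConfig)
    psir_config: PSIRConfig = field(default_factory=lambda: PSIRConfig(
        day_step=10, hour_step=0.5))
    n_plots: int = 23
    plot_size: float = 2.0                      # m

    def __post_init__(self) -> None:
        if self.extent[0] <= 0 or self.extent[1] <= 0 or self.cell_size <= 0:
            raise ValueError("extent and cell_size must be positive")
        if abs(sum(self.class_priors) - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")
        a, b = self.ati_link
        if a + b * self.clip_moisture[0] <= 0:
            raise ValueError("ATI link must be positive at minimum moisture "
                             "(guarantees ΔT > 0)")

    def grid(self) -> Grid:
        ncols = int(round(self.extent[0] / self.cell_size))
        nrows = int(round(self.extent[1] / self.cell_size))
        return Grid(nrows=nrows, ncols=ncols, cell_size=self.cell_size)


def _rng(config: SceneConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _noise(rng, shape, sd: float, smooth_radius_cells: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    eps = rng.normal(0.0, sd, shape)
    if smooth_radius_cells > 0:
        sm = ndimage.gaussian_filter(eps, smooth_radius_cells)
        # rescale so the marginal sd stays at the requested level
        s = sm.std()
        if s > 0:
            sm *= sd / s
        return sm
    return eps


def generate_dtm(config: SceneConfig) -> Raster:
    """Inclined plane plus seeded smooth Gaussian bumps (zero-mean amplitudes)."""
    grid = config.grid()
    rng = _rng(config, 1)
    x, y = grid.cell_centers()
    gx, gy = config.plane_gradient
    z = config.base_elevation + gx * x + gy * y
    for _ in range(config.bump_count):
        if config.bump_amplitude == 0:
            break
        amp = rng.uniform(-config.bump_amplitude, config.bump_amplitude)
        cx = rng.uniform(0, config.extent[0])
        cy = rng.uniform(-config.extent[1], 0) + grid.origin[1]
        sig = rng.uniform(*config.bump_sigma)
        z = z + amp * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sig ** 2))
    return Raster(grid, z)


def _minmax(raster: Raster, name: str, needed: bool) -> np.ndarray:
    v = raster.filled(np.nan)
    vmin, vmax = np.nanmin(v), np.nanmax(v)
    if vmax == vmin:
        if needed:
            raise ValueError(f"constant {name} field: normalization undefined")
        return np.zeros_like(v)
    return (v - vmin) / (vmax - vmin)


def generate_moisture(dtm: Raster, northernness: Raster, psir: Raster,
                      config: SceneConfig) -> Raster:
    """Moisture (%) = m0 + m_north·ĉ + m_psir·p̂ + noise, clipped to range.

    ĉ and p̂ are the min-max-normalized northernness and PSIR fields.
    """
    assert_aligned(dtm, northernness, psir)
    m0, m_north, m_psir, noise_sd = config.moisture_link
    chat = _minmax(northernness, "northernness", m_north != 0)
    phat = _minmax(psir, "PSIR", m_psir != 0)
    rng = _rng(config, 2)
    smooth_cells = config.noise_smoothing_radius / config.cell_size
    vals = (m0 + m_north * chat + m_psir * phat
            + _noise(rng, dtm.grid.shape, noise_sd, smooth_cells))
    vals = np.clip(vals, *config.clip_moisture)
    mask = dtm.mask & northernness.mask & psir.mask
    return Raster(dtm.grid, vals, mask)


def generate_class_map(moisture: Raster, config: SceneConfig) -> ClassRaster:
    """Draw the cover map: moisture-tilted multinomial plus clumped vegetation.

    Vegetation classes are placed first as thresholded Gaussian-smoothed
    white noise at prior-matching quantiles (tussock patchiness); the
    remaining cells draw from the five ground classes with log-odds shifted
    by standardized moisture (moss up, lichens down by default).
    """
    grid = moisture.grid
    rng = _rng(config, 3)
    priors = np.asarray(config.class_priors, dtype=float)
    resp = np.asarray(config.class_response, dtype=float)
    m = moisture.filled(np.nan)
    msd = np.nanstd(m)
    zm = (m - np.nanmean(m)) / msd if msd > 0 else np.zeros_like(m)
    labels = np.zeros(grid.shape, dtype=np.int16)
    # vegetation patches
    p_green = priors[int(CoverClass.GREENVEG) - 1]
    p_dry = priors[int(CoverClass.DRYVEG) - 1]
    u = ndimage.gaussian_filter(rng.standard_normal(grid.shape),
                                config.veg_clump_scale / grid.cell_size)
    q_hi = np.quantile(u, 1.0 - p_green)
    q_lo = np.quantile(u, 1.0 - p_green - p_dry)
    labels[u >= q_hi] = int(CoverClass.GREENVEG)
    labels[(u >= q_lo) & (u < q_hi)] = int(CoverClass.DRYVEG)
    # ground classes on the rest
    ground = [CoverClass.SOIL, CoverClass.BL, CoverClass.BLM,
              CoverClass.MOSS, CoverClass.FULG]
    g_idx = np.array([int(c) - 1 for c in ground])
    logits = (np.log(priors[g_idx])[:, None, None]
              + resp[g_idx][:, None, None] * zm[None, :, :])
    logits -= logits.max(axis=0, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=0, keepdims=True)
    open_cells = labels == 0
    r, c = np.nonzero(open_cells)
    cum = np.cumsum(probs[:, r, c], axis=0)
    draw = rng.random(r.size)
    pick = (draw[None, :] > cum).sum(axis=0)
    labels[r, c] = np.array([int(cls) for cls in ground])[pick]
    return ClassRaster(grid, labels, moisture.mask.copy())


def generate_multispectral(classes: ClassRaster, config: SceneConfig,
                           endmembers: EndmemberTable = DEFAULT_ENDMEMBERS,
                           ) -> tuple[MultibandRaster, MultibandRaster, np.ndarray]:
    """Reflectance (endmember + noise, floored at 0) and the raw DN image.

    The DN image inverts the radiometric chain — P = B + ρ·(Aγε+C)/(K·f²) —
    and rounds half-up to integers; the per-band panel mean DN needed to
    re-derive K is returned alongside.
    """
    grid = classes.grid
    rng = _rng(config, 4)
    cam = config.camera
    k_true = np.asarray(config.k_true, dtype=float)
    means = endmembers.mean_array()  # (7, 4)
    lab = classes.labels
    rho = np.zeros((4, *grid.shape))
    idx = np.clip(lab, 1, 7) - 1
    base = means[idx].transpose(2, 0, 1)
    smooth_cells = config.noise_smoothing_radius / grid.cell_size
    if config.reflectance_noise_sd > 0:
        noise = np.stack([
            _noise(rng, grid.shape, config.reflectance_noise_sd, smooth_cells)
            for _ in range(4)
        ])
    else:
        noise = 0.0
    rho = np.clip(base + noise, 0.0, None)
    rho[:, ~classes.mask] = 0.0
    reflectance = MultibandRaster(grid, rho, classes.mask.copy())
    dn = cam.reflectance_to_dn(rho, k_true)
    dn = np.clip(np.floor(dn + 0.5), 0, cam.dn_max)
    raw = MultibandRaster(grid, dn, classes.mask.copy())
    panel_dn = cam.reflectance_to_dn(
        cam.panel_reflectance.reshape(4, 1), k_true).ravel()
    return reflectance, raw, panel_dn


def generate_thermal_pair(moisture: Raster, albedo_r: Raster,
                          config: SceneConfig,
                          ) -> tuple[Raster, Raster, Raster, Raster]:
    """Pre-dawn and noon surface temperature (°C) plus their raw DN rasters.

    ΔT = C·(1−α)/ATI_true with ATI_true = a + b·moisture, so the thermal
    pair encodes the ground-truth ATI exactly (up to the optional noise).
    """
    assert_aligned(moisture, albedo_r)
    a, b = config.ati_link
    ati_true = a + b * moisture.values
    if np.any(ati_true[moisture.mask] <= 0):
        raise ValueError("non-positive true ATI: check ati_link")
    rng = _rng(config, 5)
    c = config.ati_config.c_solar
    dt = c * (1.0 - albedo_r.values) / ati_true
    smooth_cells = config.noise_smoothing_radius / moisture.grid.cell_size
    t_pre = (config.thermal_baseline
             + _noise(rng, moisture.grid.shape, config.thermal_noise_sd,
                      smooth_cells))
    t_noon = (t_pre + dt
              + _noise(rng, moisture.grid.shape, config.thermal_noise_sd,
                       smooth_cells))
    mask = moisture.mask & albedo_r.mask
    grid = moisture.grid
    from .thermal import temperature_to_dn

    pre = Raster(grid, t_pre, mask)
    noon = Raster(grid, t_noon, mask)
    return pre, noon, temperature_to_dn(pre), temperature_to_dn(noon)


def _plot_polygons(points: np.ndarray, size: float):
    half = size / 2.0
    return [box(x - half, y - half, x + half, y + half) for x, y in points]


def generate_plot_table(moisture: Raster, northernness: Raster,
                        classes: ClassRaster, config: SceneConfig,
                        n_plots: int | None = None) -> pd.DataFrame:
    """The field-plot table: polygons, soil properties, fractional covers.

    Plots are 2×2 m squares at seeded non-overlapping locations.  Moisture
    is the zonal mean of the field over non-vegetation cells (mirroring the
    vegetation-free plot means used downstream); soluble salts decrease and
    organic carbon / P / N increase with plot northernness, plus noise,
    clipped to the observed ranges.
    """
    from .thermal import mask_vegetation, zonal_mean

    assert_aligned(moisture, northernness, classes)
    n_plots = config.n_plots if n_plots is None else n_plots
    rng = _rng(config, 6)
    grid = moisture.grid
    ox, oy = grid.origin
    width, height = grid.extent
    half = config.plot_size / 2.0
    margin = half + grid.cell_size
    veg = (np.isin(classes.labels, [int(c) for c in VEGETATION_CLASSES])
           & classes.mask)
    pts: list[tuple[float, float]] = []
    attempts = 0
    min_sep = config.plot_size * np.sqrt(2.0)  # disjoint squares
    while len(pts) < n_plots:
        attempts += 1
        if attempts > 500 * n_plots:
            raise RuntimeError(
                f"placed only {len(pts)} of {n_plots} non-overlapping plots"
            )
        x = rng.uniform(ox + margin, ox + width - margin)
        y = rng.uniform(oy - height + margin, oy - margin)
        if any((x - px) ** 2 + (y - py) ** 2 < min_sep ** 2 for px, py in pts):
            continue
        # field plots were laid on biocrust/soil surfaces, not inside
        # tussocks: reject mostly-vegetated squares
        r0, c0 = grid.rowcol(x - half, y + half)
        r1, c1 = grid.rowcol(x + half, y - half)
        window = veg[max(r0, 0):r1 + 1, max(c0, 0):c1 + 1]
        if window.size == 0 or window.mean() > 0.5:
            continue
        pts.append((x, y))
    points = np.asarray(pts)
    polys = _plot_polygons(points, config.plot_size)
    moisture_nv = mask_vegetation(moisture, classes)
    north_nv = mask_vegetation(northernness, classes)
    moist_mean, _ = zonal_mean(moisture_nv, polys)
    north_mean, _ = zonal_mean(north_nv, polys)
    nhat = north_mean / 2.0  # northernness in [0,2] -> [0,1]
    soil = {
        "SolSal": np.clip(92.0 - 28.0 * nhat + rng.normal(0, 6.0, n_plots),
                          *SOLSAL_RANGE),
        "OrgCarb": np.clip(0.45 + 1.1 * nhat + rng.normal(0, 0.25, n_plots),
                           *ORGCARB_RANGE),
        "P_tot": np.clip(0.15 + 0.9 * nhat + rng.normal(0, 0.25, n_plots),
                         *PTOT_RANGE),
        "N_tot": np.clip(0.03 + 0.10 * nhat + rng.normal(0, 0.02, n_plots),
                         *NTOT_RANGE),
    }
    # fractional covers from the class map
    fracs = {c.name: np.zeros(n_plots) for c in CoverClass}
    for i, poly in enumerate(polys):
        minx, miny, maxx, maxy = poly.bounds
        r0, c0 = grid.rowcol(minx, maxy)
        r1, c1 = grid.rowcol(maxx, miny)
        sub = classes.labels[max(r0, 0):r1 + 1, max(c0, 0):c1 + 1]
        subm = classes.mask[max(r0, 0):r1 + 1, max(c0, 0):c1 + 1]
        n_valid = subm.sum()
        for c in CoverClass:
            fracs[c.name][i] = ((sub == int(c)) & subm).sum() / n_valid
    table = pd.DataFrame({
        "plot_id": np.arange(n_plots),
        "x": points[:, 0],
        "y": points[:, 1],
        "moisture": moist_mean,
        "northernness": north_mean,
        **soil,
        **fracs,
    })
    table.attrs["geometry"] = polys
    return table


@dataclass
class Scene:
    """A fully generated synthetic study site with its ground truth."""

    config: SceneConfig
    dtm: Raster
    terrain: TerrainStack
    moisture: Raster
    classes: ClassRaster
    reflectance: MultibandRaster
    raw_dn: MultibandRaster
    panel_dn: np.ndarray
    albedo: Raster
    t_predawn: Raster
    t_noon: Raster
    dn_predawn: Raster
    dn_noon: Raster
    plots: pd.DataFrame

    @property
    def ati_true(self) -> Raster:
        a, b = self.config.ati_link
        return Raster(self.moisture.grid, a + b * self.moisture.values,
                      self.moisture.mask.copy())

    def truth(self) -> dict:
        """Ground-truth parameters as a JSON-serializable dict."""
        cfg = asdict(self.config)
        cfg["camera"] = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                         for k, v in asdict(self.config.camera).items()}
        return cfg


def generate_scene(config: SceneConfig = SceneConfig(),
                   endmembers: EndmemberTable = DEFAULT_ENDMEMBERS) -> Scene:
    """Generate the full synthetic site (terrain → moisture → covers → imagery)."""
    from .thermal import albedo as albedo_op

    dtm = generate_dtm(config)
    stack = compute_terrain_stack(dtm, psir_config=config.psir_config,
                                  smooth_diameter=1.0)
    moisture = generate_moisture(stack.elevation, stack.northernness,
                                 stack.psir, config)
    classes = generate_class_map(moisture, config)
    reflectance, raw_dn, panel_dn = generate_multispectral(classes, config,
                                                           endmembers)
    alb = albedo_op(reflectance)
    t_pre, t_noon, dn_pre, dn_noon = generate_thermal_pair(moisture, alb, config)
    plots = generate_plot_table(moisture, stack.northernness, classes, config)
    return Scene(config, dtm, stack, moisture, classes, reflectance, raw_dn,
                 panel_dn, alb, t_pre, t_noon, dn_pre, dn_noon, plots)
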