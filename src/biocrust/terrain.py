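"""Terrain attributes from a vegetation-free DTM.

Implements the attribute set used to explain biocrust distribution:
slope and aspect by the Zevenbergen–Thorne second-order polynomial method,
northernness (cos(aspect)+1), priority-flood pit removal, Tarboton's
D-infinity flow routing and contributing area, the topographic wetness
index TWI = ln(A / tan β), the length–slope factor
LSF = (n+1)·(A/22.13)^n·(sin β/0.0896)^m, a clear-sky annual potential
solar incoming radiation (PSIR) model, and circular focal smoothing.

A is the *specific* catchment area (accumulated area / cell width, metres)
throughout, matching the D-infinity toolchain convention; the raw
accumulated area in m² is available via ``dinf_area(..., specific=False)``.
"""
from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import Grid, Raster, assert_aligned

__all__ = [
    "LSFParams",
    "PSIRConfig",
    "FlowField",
    "TerrainStack",
    "fill_pits",
    "slope_aspect",
    "northernness",
    "dinf_flow",
    "dinf_area",
    "boundary_outflow",
    "twi",
    "lsf",
    "psir_annual",
    "focal_mean_circular",
    "compute_terrain_stack",
]

#: Default clamp so TWI stays finite on flat cells (tan β >= 1e-3, i.e. ~0.057°).
TAN_BETA_MIN = 1e-3


@dataclass(frozen=True)
class LSFParams:
    """Constants of the length–slope factor."""

    n: float = 0.4
    m: float = 1.3
    area_ref: float = 22.13    # reference slope length (m)
    slope_ref: float = 0.0896  # reference sine of slope

    def __post_init__(self) -> None:
        if self.n <= 0 or self.m <= 0:
            raise ValueError("LSF exponents must be positive")


@dataclass(frozen=True)
class PSIRConfig:
    """Clear-sky annual insolation model parameters.

    Transmissivity and the diffuse proportion default to the uniform
    clear-sky values used for the study site (0.5 and 0.3); latitude
    defaults to the site's 40.03° N.
    """

    latitude: float = 40.03
    transmissivity: float = 0.5
    diffuse_proportion: float = 0.3
    solar_constant: float = 1367.0  # W/m²
    day_step: int = 5               # days between sampled days
    hour_step: float = 0.25         # hours between sampled instants
    horizon_shading: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.transmissivity <= 1:
            raise ValueError("transmissivity must be in (0, 1]")
        if not 0 <= self.diffuse_proportion <= 1:
            raise ValueError("diffuse_proportion must be in [0, 1]")
        if abs(self.latitude) >= 90:
            raise ValueError("|latitude| must be < 90 degrees")


@dataclass
class FlowField:
    """Per-cell D-infinity flow: receiving neighbours and proportions.

    ``rec`` holds up to two flattened receiver indices per cell (-1 = none);
    ``prop`` the matching proportions (sum to 1 for draining cells, 0 for
    outlet cells whose flow leaves the grid); ``angle`` the flow direction in
    radians counter-clockwise from east (NaN for outlets/nodata).
    """

    grid: Grid
    rec: np.ndarray    # (ncells, 2) int
    prop: np.ndarray   # (ncells, 2) float
    angle: np.ndarray  # (nrows, ncols) float
    is_outlet: np.ndarray  # (nrows, ncols) bool


@dataclass
class TerrainStack:
    """The attribute rasters fed to the statistical analyses."""

    elevation: Raster
    slope: Raster          # degrees
    aspect: Raster         # degrees clockwise from north, downslope
    northernness: Raster   # cos(aspect)+1, in [0, 2]
    cca: Raster            # specific catchment area (m)
    twi: Raster
    lsf: Raster
    psir: Raster           # Wh/m²/yr

    def as_dict(self) -> dict[str, Raster]:
        return {
            "Elevation": self.elevation,
            "Slope": self.slope,
            "Northernness": self.northernness,
            "TWI": self.twi,
            "LSF": self.lsf,
            "PSIR": self.psir,
        }


# ---------------------------------------------------------------------------
# pit removal


def fill_pits(dtm: Raster, epsilon: float = 1e-6) -> Raster:
    """Remove depressions by priority-flood, raising cells minimally.

    Every cell ends with a non-ascending path to the grid boundary; the
    output is >= the input everywhere.  ``epsilon`` imposes a tiny gradient
    across filled flats so the flow field stays resolvable; pass 0 for the
    exact minimal fill.
    """
    z = dtm.filled(np.nan)
    mask = dtm.mask
    if not mask.any():
        raise ValueError("all-nodata DTM")
    nr, nc = z.shape
    out = z.copy()
    closed = ~mask  # nodata cells never processed
    heap: list[tuple[float, int, int]] = []
    for r in range(nr):
        for c in range(nc):
            if mask[r, c] and (r in (0, nr - 1) or c in (0, nc - 1)
                               or _touches_nodata(mask, r, c)):
                heapq.heappush(heap, (z[r, c], r, c))
                closed[r, c] = True
    while heap:
        zc, r, c = heapq.heappop(heap)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc and not closed[rr, cc]:
                    closed[rr, cc] = True
                    spill = out[r, c]
                    new_z = z[rr, cc] if z[rr, cc] > spill else spill + epsilon
                    out[rr, cc] = new_z
                    heapq.heappush(heap, (new_z, rr, cc))
    return Raster(dtm.grid, out, mask)


def _touches_nodata(mask: np.ndarray, r: int, c: int) -> bool:
    nr, nc = mask.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and not mask[rr, cc]:
                return True
    return False


# ---------------------------------------------------------------------------
# slope / aspect / northernness


def slope_aspect(dtm: Raster) -> tuple[Raster, Raster]:
    """Slope (degrees) and aspect (degrees clockwise from north, downslope).

    Partial derivatives follow the Zevenbergen–Thorne second-order
    polynomial fit: central differences over the 3×3 window (one-sided at
    the grid edge).  Flat cells get nodata aspect.
    """
    if dtm.grid.nrows < 3 or dtm.grid.ncols < 3:
        raise ValueError("DTM must be at least 3x3")
    z = dtm.filled(np.nan)
    cs = dtm.grid.cell_size
    # row axis points south, so dz/dnorth = -d/drow
    dz_drow, dz_dcol = np.gradient(z, cs)
    p = dz_dcol          # dz/dx (east)
    q = -dz_drow         # dz/dy (north)
    slope = np.degrees(np.arctan(np.hypot(p, q)))
    flat = np.hypot(p, q) == 0
    # azimuth of the downslope vector (-p, -q), clockwise from north
    aspect = np.degrees(np.arctan2(-p, -q)) % 360.0
    aspect[flat] = np.nan
    valid = dtm.mask & np.isfinite(slope)
    return (Raster(dtm.grid, slope, valid),
            Raster(dtm.grid, aspect, valid & ~flat))


def northernness(aspect: Raster) -> Raster:
    """cos(aspect) + 1, in [0, 2]: 2 = facing due north, 0 = due south."""
    vals = np.cos(np.radians(aspect.filled(np.nan))) + 1.0
    return Raster(aspect.grid, vals, aspect.mask & np.isfinite(vals))


# ---------------------------------------------------------------------------
# D-infinity flow routing (Tarboton)

# neighbour directions indexed 0..7, angles counter-clockwise from east
_DIR_OFFSETS = {
    "E": (0, 1), "NE": (-1, 1), "N": (-1, 0), "NW": (-1, -1),
    "W": (0, -1), "SW": (1, -1), "S": (1, 0), "SE": (1, 1),
}
_DIR_ANGLE = {
    "E": 0.0, "NE": math.pi / 4, "N": math.pi / 2, "NW": 3 * math.pi / 4,
    "W": math.pi, "SW": 5 * math.pi / 4, "S": 3 * math.pi / 2, "SE": 7 * math.pi / 4,
}
# the eight triangular facets as (cardinal, diagonal, sign of rotation from
# the cardinal toward the diagonal in ccw angle)
_FACETS = [
    ("E", "NE", +1), ("N", "NE", -1), ("N", "NW", +1), ("W", "NW", -1),
    ("W", "SW", +1), ("S", "SW", -1), ("S", "SE", +1), ("E", "SE", -1),
]


def _facet_solution(z0, zc, zd, cs):
    """Slope magnitude, rotation r in [0, pi/4] and validity for one facet."""
    s1 = (z0 - zc) / cs
    s2 = (zc - zd) / cs
    r = math.atan2(s2, s1)
    if r < 0.0:
        r = 0.0
        mag = s1
    elif r > math.pi / 4:
        r = math.pi / 4
        mag = (z0 - zd) / (cs * math.sqrt(2.0))
    else:
        mag = math.hypot(s1, s2)
    return mag, r


def dinf_flow(dtm_filled: Raster) -> FlowField:
    """Tarboton's D-infinity flow direction over the eight triangular facets.

    Flow from each cell is split between the two neighbours bounding the
    steepest-descent facet, proportionally to angular distance.  Boundary
    cells without an interior downslope neighbour drain out of the grid;
    an interior cell without any downslope facet is a pit and raises.
    """
    z = dtm_filled.filled(np.nan)
    mask = dtm_filled.mask
    nr, nc = z.shape
    cs = dtm_filled.grid.cell_size
    ncells = nr * nc
    rec = np.full((ncells, 2), -1, dtype=np.int64)
    prop = np.zeros((ncells, 2), dtype=float)
    angle = np.full((nr, nc), np.nan)
    is_outlet = np.zeros((nr, nc), dtype=bool)

    for r in range(nr):
        on_edge_r = r == 0 or r == nr - 1
        for c in range(nc):
            if not mask[r, c]:
                continue
            z0 = z[r, c]
            best = (0.0, None)  # (magnitude, (facet, r_angle))
            for card, diag, sign in _FACETS:
                dr1, dc1 = _DIR_OFFSETS[card]
                dr2, dc2 = _DIR_OFFSETS[diag]
                r1, c1 = r + dr1, c + dc1
                r2, c2 = r + dr2, c + dc2
                if not (0 <= r1 < nr and 0 <= c1 < nc and mask[r1, c1]):
                    continue
                if not (0 <= r2 < nr and 0 <= c2 < nc and mask[r2, c2]):
                    # degenerate facet: cardinal descent only
                    s1 = (z0 - z[r1, c1]) / cs
                    if s1 > best[0]:
                        best = (s1, (card, diag, sign, 0.0, (r1, c1), None))
                    continue
                mag, rang = _facet_solution(z0, z[r1, c1], z[r2, c2], cs)
                if mag > best[0]:
                    best = (mag, (card, diag, sign, rang, (r1, c1), (r2, c2)))
            idx = r * nc + c
            if best[1] is None:
                on_edge = on_edge_r or c == 0 or c == nc - 1 \
                    or _touches_nodata(mask, r, c)
                if not on_edge:
                    raise ValueError(
                        f"pit at interior cell ({r}, {c}): run fill_pits first"
                    )
                is_outlet[r, c] = True
                continue
            _, (card, diag, sign, rang, n1, n2) = best
            angle[r, c] = (_DIR_ANGLE[card] + sign * rang) % (2 * math.pi)
            p_diag = rang / (math.pi / 4)
            if n2 is None or p_diag == 0.0:
                rec[idx, 0] = n1[0] * nc + n1[1]
                prop[idx, 0] = 1.0
            elif p_diag == 1.0:
                rec[idx, 0] = n2[0] * nc + n2[1]
                prop[idx, 0] = 1.0
            else:
                rec[idx, 0] = n1[0] * nc + n1[1]
                prop[idx, 0] = 1.0 - p_diag
                rec[idx, 1] = n2[0] * nc + n2[1]
                prop[idx, 1] = p_diag
    return FlowField(dtm_filled.grid, rec, prop, angle, is_outlet)


def dinf_area(flow: FlowField, grid: Grid | None = None, *,
              specific: bool = True,
              elevation: Raster | None = None) -> Raster:
    """Accumulate contributing area along the D-infinity flow field.

    Cells are processed from high to low elevation (topological order on the
    strictly-downhill flow graph).  Returns specific catchment area
    (m²/m = m) by default, or raw accumulated area in m².
    """
    grid = grid or flow.grid
    nr, nc = grid.shape
    cs = grid.cell_size
    acc = np.full(nr * nc, cs * cs)
    valid = np.zeros(nr * nc, dtype=bool)
    # order: topological sort via Kahn's algorithm on receiver in-degrees
    indeg = np.zeros(nr * nc, dtype=np.int64)
    for k in range(2):
        targets = flow.rec[:, k]
        ok = targets >= 0
        np.add.at(indeg, targets[ok], 1)
    from collections import deque

    queue = deque(np.nonzero(indeg == 0)[0].tolist())
    seen = 0
    rec, prop = flow.rec, flow.prop
    while queue:
        i = queue.popleft()
        seen += 1
        valid[i] = True
        for k in range(2):
            j = rec[i, k]
            if j >= 0:
                acc[j] += prop[i, k] * acc[i]
                indeg[j] -= 1
                if indeg[j] == 0:
                    queue.append(j)
    if seen < nr * nc:
        raise ValueError("cycle detected in flow field")
    out = acc.reshape(nr, nc)
    if specific:
        out = out / cs
    mask = flow.is_outlet | np.isfinite(flow.angle)
    return Raster(grid, out, mask)


def boundary_outflow(flow: FlowField, area: Raster, *, specific: bool = True) -> float:
    """Total accumulated area (m²) leaving the grid through outlet cells."""
    scale = flow.grid.cell_size if specific else 1.0
    return float(area.values[flow.is_outlet].sum() * scale)


# ---------------------------------------------------------------------------
# wetness / erosion indices


def twi(cca: Raster, slope: Raster, *, tan_beta_min: float = TAN_BETA_MIN) -> Raster:
    """Topographic wetness index ln(A / tan β), slope in degrees.

    tan β is clamped below by ``tan_beta_min`` so flat cells stay finite.
    """
    assert_aligned(cca, slope)
    a = cca.filled(np.nan)
    if np.any(a[cca.mask & slope.mask] <= 0):
        raise ValueError("catchment area must be positive")
    tb = np.maximum(np.tan(np.radians(slope.filled(np.nan))), tan_beta_min)
    vals = np.log(a / tb)
    return Raster(cca.grid, vals, cca.mask & slope.mask)


def lsf(cca: Raster, slope: Raster, params: LSFParams = LSFParams()) -> Raster:
    """Length–slope factor (n+1)·(A/22.13)^n·(sin β/0.0896)^m."""
    assert_aligned(cca, slope)
    a = cca.filled(np.nan)
    if np.any(a[cca.mask & slope.mask] < 0):
        raise ValueError("catchment area must be non-negative")
    sb = np.sin(np.radians(slope.filled(np.nan)))
    vals = ((params.n + 1.0)
            * (a / params.area_ref) ** params.n
            * (sb / params.slope_ref) ** params.m)
    return Raster(cca.grid, vals, cca.mask & slope.mask)


# ---------------------------------------------------------------------------
# potential solar incoming radiation


def _solar_position(lat_rad: float, day: int, hour: float) -> tuple[float, float]:
    """(cos zenith, azimuth from north, rad) for one instant, standard formulas."""
    decl = math.radians(23.45) * math.sin(2 * math.pi * (284 + day) / 365.0)
    h = math.radians(15.0 * (hour - 12.0))
    cosz = (math.sin(lat_rad) * math.sin(decl)
            + math.cos(lat_rad) * math.cos(decl) * math.cos(h))
    az = math.atan2(math.sin(h),
                    math.cos(h) * math.sin(lat_rad)
                    - math.tan(decl) * math.cos(lat_rad)) + math.pi
    return cosz, az % (2 * math.pi)


def _horizon_tangents(z: np.ndarray, cs: float, max_steps: int = 200) -> np.ndarray:
    """tan(horizon angle) per cell for the 8 compass directions (N first, cw)."""
    nr, nc = z.shape
    dirs = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
    out = np.full((8, nr, nc), -np.inf)
    zf = np.where(np.isfinite(z), z, -np.inf)
    for d, (dr, dc) in enumerate(dirs):
        dist = math.hypot(dr, dc) * cs
        best = np.full((nr, nc), -np.inf)
        for t in range(1, max_steps + 1):
            sr, sc = dr * t, dc * t
            if abs(sr) >= nr or abs(sc) >= nc:
                break
            shifted = np.full((nr, nc), -np.inf)
            rs = slice(max(0, -sr), min(nr, nr - sr))
            cs_ = slice(max(0, -sc), min(nc, nc - sc))
            rt = slice(max(0, sr), min(nr, nr + sr))
            ct = slice(max(0, sc), min(nc, nc + sc))
            shifted[rs, cs_] = zf[rt, ct]
            np.maximum(best, (shifted - zf) / (t * dist), out=best)
        out[d] = best
    return out


def psir_annual(dtm: Raster, slope: Raster, aspect: Raster,
                config: PSIRConfig = PSIRConfig()) -> Raster:
    """Annual potential solar incoming radiation (Wh/m²/yr), clear sky.

    For each sampled instant the direct component on the tilted cell is
    S0·τ^(1/cos z)·max(0, cos θi) (zeroed when the local horizon hides the
    sun, ray-marched over 8 directions), and the diffuse component is
    diffuse_proportion·S0·τ^(1/cos z)·(1+cos s)/2 under a uniform sky.
    Instants are integrated with day_step × hour_step weights.
    """
    assert_aligned(dtm, slope, aspect)
    lat = math.radians(config.latitude)
    s_rad = np.radians(slope.filled(np.nan))
    # flat cells have undefined aspect; sin(s)=0 there makes the value moot
    a_rad = np.radians(aspect.filled(0.0))
    cos_s, sin_s = np.cos(s_rad), np.sin(s_rad)
    sky = (1.0 + cos_s) / 2.0
    total = np.zeros(dtm.grid.shape)
    if config.horizon_shading:
        hor = _horizon_tangents(dtm.filled(np.nan), dtm.grid.cell_size)
    tau, s0, dp = config.transmissivity, config.solar_constant, config.diffuse_proportion
    for day in range(1, 366, config.day_step):
        for hour in np.arange(0.0, 24.0, config.hour_step):
            cosz, az = _solar_position(lat, day, float(hour))
            if cosz <= 1e-6:
                continue
            sinz = math.sqrt(1.0 - cosz * cosz)
            beam = s0 * tau ** (1.0 / cosz)
            cosi = cosz * cos_s + sinz * sin_s * np.cos(az - a_rad)
            direct = beam * np.clip(cosi, 0.0, None)
            if config.horizon_shading:
                d8 = int(round(az / (math.pi / 4))) % 8
                tan_elev = cosz / sinz if sinz > 1e-12 else np.inf
                direct = np.where(hor[d8] > tan_elev, 0.0, direct)
            total += (direct + dp * beam * sky) * config.hour_step
    total *= config.day_step
    mask = dtm.mask & slope.mask
    return Raster(dtm.grid, total, mask)


# ---------------------------------------------------------------------------
# focal smoothing


def focal_mean_circular(raster: Raster, diameter: float) -> Raster:
    """Mean over cells whose centres lie within diameter/2, ignoring nodata."""
    if diameter < 0:
        raise ValueError("diameter must be >= 0")
    cs = raster.grid.cell_size
    radius = diameter / 2.0
    half = int(radius // cs)
    if half < 1:
        return Raster(raster.grid, raster.values.copy(), raster.mask.copy())
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    footprint = (np.hypot(xx, yy) * cs) <= radius + 1e-12
    vals = np.where(raster.mask, raster.values, 0.0)
    num = ndimage.convolve(vals, footprint.astype(float), mode="constant")
    den = ndimage.convolve(raster.mask.astype(float), footprint.astype(float),
                           mode="constant")
    with np.errstate(invalid="ignore"):
        out = num / den
    return Raster(raster.grid, out, raster.mask & (den > 0))


# ---------------------------------------------------------------------------
# convenience


def compute_terrain_stack(dtm: Raster,
                          psir_config: PSIRConfig = PSIRConfig(),
                          lsf_params: LSFParams = LSFParams(),
                          smooth_diameter: float = 1.0) -> TerrainStack:
    """Full attribute stack from a raw DTM (smooth → derive → route → index)."""
    smoothed = focal_mean_circular(dtm, smooth_diameter)
    slo, asp = slope_aspect(smoothed)
    north = northernness(asp)
    filled = fill_pits(smoothed)
    flow = dinf_flow(filled)
    area = dinf_area(flow)
    return TerrainStack(
        elevation=smoothed,
        slope=slo,
        aspect=asp,
        northernness=north,
        cca=area,
        twi=twi(area, slo),
        lsf=lsf(area, slo, lsf_params),
        psir=psir_annual(smoothed, slo, asp, psir_config),
    )
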