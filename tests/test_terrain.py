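import math

import numpy as np
import pytest

import biocrust as bc
from biocrust import terrain
from conftest import make_plane


# ---------------------------------------------------------------------------
# brute-force oracle for D-infinity accumulation


def recursive_accumulation(flow: bc.FlowField) -> np.ndarray:
    """Independent oracle: memoized recursion over the inflow graph."""
    nr, nc = flow.grid.shape
    cs = flow.grid.cell_size
    inflows = [[] for _ in range(nr * nc)]
    for i in range(nr * nc):
        for k in range(2):
            j = flow.rec[i, k]
            if j >= 0:
                inflows[j].append((i, flow.prop[i, k]))
    memo: dict[int, float] = {}

    def acc(i: int) -> float:
        if i not in memo:
            memo[i] = cs * cs + sum(p * acc(j) for j, p in inflows[i])
        return memo[i]

    import sys
    sys.setrecursionlimit(10000)
    return np.array([acc(i) for i in range(nr * nc)]).reshape(nr, nc)


def random_pitfree_dtm(seed: int, n: int = 6) -> bc.Raster:
    rng = np.random.default_rng(seed)
    g = bc.Grid(nrows=n, ncols=n, cell_size=1.0)
    x, y = g.cell_centers()
    z = 0.3 * x + 0.2 * y + rng.random((n, n))
    return terrain.fill_pits(bc.Raster(g, z), epsilon=1e-6)


# ---------------------------------------------------------------------------
# pit filling


def test_fill_pits_leaves_drained_plane_unchanged():
    dtm = make_plane(gx=0.1, gy=0.05)
    out = terrain.fill_pits(dtm, epsilon=0.0)
    np.testing.assert_array_equal(out.values, dtm.values)


def test_fill_pits_raises_single_pit_to_spill_elevation():
    # tilted plane with one cell dug 1 m deep: water escapes east through
    # the next cell, so the pit fills exactly to that cell's elevation
    dtm = make_plane(nrows=5, ncols=5, gx=-0.2)
    z = dtm.values.copy()
    spill = z[2, 3]
    z[2, 2] -= 1.0
    out = terrain.fill_pits(bc.Raster(dtm.grid, z), epsilon=0.0)
    assert out.values[2, 2] == pytest.approx(spill, abs=1e-12)


def test_fill_pits_bowl_fills_to_rim_notch():
    # rim at 10 with one notch at 9.2: the whole inner bowl fills to 9.2
    z = np.full((5, 5), 10.0)
    z[1:4, 1:4] = 9.0
    z[2, 2] = 8.0
    z[0, 2] = 9.2
    g = bc.Grid(nrows=5, ncols=5, cell_size=1.0)
    out = terrain.fill_pits(bc.Raster(g, z), epsilon=0.0)
    np.testing.assert_allclose(out.values[1:4, 1:4], 9.2)


def test_fill_pits_never_lowers_cells(default_scene):
    dtm = default_scene.dtm
    out = terrain.fill_pits(dtm)
    assert np.all(out.values[out.mask] >= dtm.values[dtm.mask] - 1e-12)


def test_fill_pits_all_nodata_raises():
    g = bc.Grid(nrows=3, ncols=3, cell_size=1.0)
    r = bc.Raster(g, np.zeros((3, 3)), np.zeros((3, 3), bool))
    with pytest.raises(ValueError):
        terrain.fill_pits(r)


# ---------------------------------------------------------------------------
# slope / aspect / northernness


def test_plane_slope_and_aspect_closed_form():
    # z falls eastwards at 0.5 m/m: slope atan(0.5), downslope azimuth 90
    dtm = make_plane(gx=-0.5)
    slo, asp = terrain.slope_aspect(dtm)
    assert slo.values[4, 4] == pytest.approx(math.degrees(math.atan(0.5)))
    assert asp.values[4, 4] == pytest.approx(90.0)


def test_aspect_rotates_with_the_plane():
    for (gx, gy), expected in [((-0.3, 0.0), 90.0), ((0.0, -0.3), 0.0),
                               ((0.3, 0.0), 270.0), ((0.0, 0.3), 180.0)]:
        _, asp = terrain.slope_aspect(make_plane(gx=gx, gy=gy))
        assert asp.values[4, 4] == pytest.approx(expected)


def test_flat_raster_slope_zero_aspect_nodata():
    slo, asp = terrain.slope_aspect(make_plane())
    assert np.all(slo.values == 0.0)
    assert not asp.mask.any()


def test_slope_aspect_requires_3x3():
    g = bc.Grid(nrows=2, ncols=5, cell_size=1.0)
    with pytest.raises(ValueError):
        terrain.slope_aspect(bc.Raster(g, np.zeros((2, 5))))


@pytest.mark.parametrize("aspect_deg,expected", [(0.0, 2.0), (90.0, 1.0),
                                                 (180.0, 0.0), (270.0, 1.0)])
def test_northernness_spot_values(aspect_deg, expected):
    g = bc.Grid(nrows=1, ncols=1, cell_size=1.0)
    n = terrain.northernness(bc.Raster(g, np.array([[aspect_deg]])))
    assert n.values[0, 0] == pytest.approx(expected, abs=1e-12)


def test_northernness_plus_southness_is_two(default_scene):
    asp = default_scene.terrain.aspect
    north = terrain.northernness(asp)
    south = bc.Raster(asp.grid,
                      np.cos(np.radians(asp.filled(np.nan) - 180.0)) + 1.0,
                      asp.mask)
    s = north.values[north.mask & south.mask] + south.values[north.mask & south.mask]
    np.testing.assert_allclose(s, 2.0, atol=1e-12)


# ---------------------------------------------------------------------------
# D-infinity


def test_dinf_plane_east_cardinal_case():
    dtm = make_plane(gx=-0.2)
    flow = terrain.dinf_flow(dtm)
    # interior cells flow due east (angle 0), 100% to the east neighbour
    assert flow.angle[4, 4] == pytest.approx(0.0)
    idx = 4 * 9 + 4
    assert flow.rec[idx, 0] == 4 * 9 + 5
    assert flow.prop[idx, 0] == pytest.approx(1.0)


def test_dinf_halfway_between_east_and_southeast_splits_evenly():
    # dip azimuth exactly 22.5 deg below east: facet angle pi/8
    ang = math.pi / 8
    dtm = make_plane(gx=-math.cos(ang), gy=math.sin(ang))
    flow = terrain.dinf_flow(dtm)
    idx = 4 * 9 + 4
    props = dict(zip(flow.rec[idx], flow.prop[idx]))
    east = 4 * 9 + 5
    southeast = 5 * 9 + 5
    assert props[east] == pytest.approx(0.5, abs=1e-10)
    assert props[southeast] == pytest.approx(0.5, abs=1e-10)


def test_dinf_cone_flow_is_radial():
    g = bc.Grid(nrows=11, ncols=11, cell_size=1.0)
    x, y = g.cell_centers()
    cx, cy = x[5, 5], y[5, 5]
    z = 20.0 - np.hypot(x - cx, y - cy)  # peak at the centre: radial outflow
    flow = terrain.dinf_flow(bc.Raster(g, z))
    # near-radial everywhere (the triangular-facet fit of a curved surface
    # tilts flow toward the diagonal by up to ~7 degrees)...
    for r, c in [(5, 8), (2, 5), (8, 5), (5, 2), (3, 3), (7, 7)]:
        expected = math.atan2(y[r, c] - cy, x[r, c] - cx) % (2 * math.pi)
        diff = (flow.angle[r, c] - expected + math.pi) % (2 * math.pi) - math.pi
        assert abs(diff) < 0.15
    # ...and the size of the deviation is 4-fold rotationally symmetric
    # (its sign can flip on exact facet ties)
    def radial_dev(r, c):
        d = (flow.angle[r, c] - math.atan2(y[r, c] - cy, x[r, c] - cx)
             ) % (2 * math.pi)
        return min(d, 2 * math.pi - d)

    for r, c in [(5, 8), (3, 3), (4, 7)]:
        assert radial_dev(r, c) == pytest.approx(radial_dev(10 - c, r), abs=1e-9)


def test_dinf_interior_pit_raises():
    z = np.full((5, 5), 10.0)
    z[2, 2] = 5.0
    g = bc.Grid(nrows=5, ncols=5, cell_size=1.0)
    with pytest.raises(ValueError, match="pit"):
        terrain.dinf_flow(bc.Raster(g, z))


def test_ridge_cell_has_own_area_only():
    dtm = make_plane(gx=-0.2)  # west edge is the ridge line
    flow = terrain.dinf_flow(dtm)
    area = terrain.dinf_area(flow)
    np.testing.assert_allclose(area.values[:, 0], 1.0)  # sca = cs = 1 m


def test_single_file_column_accumulates_k_cells():
    dtm = make_plane(gx=-0.2)
    flow = terrain.dinf_flow(dtm)
    area = terrain.dinf_area(flow)
    np.testing.assert_allclose(area.values[4, :], np.arange(1, 10))


@pytest.mark.parametrize("seed", range(100))
def test_dinf_area_matches_recursive_oracle(seed):
    dtm = random_pitfree_dtm(seed)
    flow = terrain.dinf_flow(dtm)
    got = terrain.dinf_area(flow, specific=False)
    want = recursive_accumulation(flow)
    assert np.max(np.abs(got.values - want)) < 1e-9


@pytest.mark.parametrize("seed", range(0, 100, 7))
def test_mass_conservation_boundary_outflow(seed):
    dtm = random_pitfree_dtm(seed, n=8)
    flow = terrain.dinf_flow(dtm)
    area = terrain.dinf_area(flow, specific=False)
    out = terrain.boundary_outflow(flow, area, specific=False)
    assert out == pytest.approx(64.0, rel=1e-6)


# ---------------------------------------------------------------------------
# TWI / LSF


def test_twi_direct_arithmetic():
    g = bc.Grid(nrows=1, ncols=1, cell_size=1.0)
    a = bc.Raster(g, np.array([[10.0]]))
    s = bc.Raster(g, np.array([[45.0]]))
    assert terrain.twi(a, s).values[0, 0] == pytest.approx(math.log(10.0))


def test_twi_flat_cell_uses_clamp():
    g = bc.Grid(nrows=1, ncols=1, cell_size=1.0)
    a = bc.Raster(g, np.array([[5.0]]))
    s = bc.Raster(g, np.array([[0.0]]))
    assert terrain.twi(a, s).values[0, 0] == pytest.approx(math.log(5.0 / 1e-3))


def test_twi_monotone_in_area():
    g = bc.Grid(nrows=1, ncols=3, cell_size=1.0)
    a = bc.Raster(g, np.array([[1.0, 5.0, 50.0]]))
    s = bc.Raster(g, np.full((1, 3), 20.0))
    v = terrain.twi(a, s).values[0]
    assert v[0] < v[1] < v[2]


def test_twi_nonpositive_area_raises():
    g = bc.Grid(nrows=1, ncols=1, cell_size=1.0)
    with pytest.raises(ValueError):
        terrain.twi(bc.Raster(g, np.array([[0.0]])),
                    bc.Raster(g, np.array([[10.0]])))


def test_lsf_unit_case_and_scaling():
    g = bc.Grid(nrows=1, ncols=1, cell_size=1.0)
    s = bc.Raster(g, np.array([[math.degrees(math.asin(0.0896))]]))
    a1 = bc.Raster(g, np.array([[22.13]]))
    assert terrain.lsf(a1, s).values[0, 0] == pytest.approx(1.4)
    a2 = bc.Raster(g, np.array([[44.26]]))
    ratio = terrain.lsf(a2, s).values[0, 0] / 1.4
    assert ratio == pytest.approx(2.0 ** 0.4, rel=1e-12)


def test_lsf_zero_area_is_zero():
    g = bc.Grid(nrows=1, ncols=1, cell_size=1.0)
    a = bc.Raster(g, np.array([[0.0]]))
    s = bc.Raster(g, np.array([[10.0]]))
    assert terrain.lsf(a, s).values[0, 0] == 0.0


# ---------------------------------------------------------------------------
# PSIR


def test_psir_flat_dtm_uniform():
    dtm = make_plane(nrows=7, ncols=7)
    slo, asp = terrain.slope_aspect(dtm)
    cfg = terrain.PSIRConfig(day_step=30, hour_step=1.0, horizon_shading=False)
    p = terrain.psir_annual(dtm, slo, asp, cfg)
    v = p.values[p.mask]
    assert np.ptp(v) <= 1e-9 * v.mean()
    assert np.all(v > 0)


def test_psir_south_facing_exceeds_north_facing():
    # ridge running east-west: north half faces north, south half faces south
    g = bc.Grid(nrows=21, ncols=9, cell_size=1.0)
    x, y = g.cell_centers()
    crest = y[10, 0]
    z = 100.0 - 0.36 * np.abs(y - crest)  # ~20 degree slopes
    dtm = bc.Raster(g, z)
    slo, asp = terrain.slope_aspect(dtm)
    cfg = terrain.PSIRConfig(day_step=15, hour_step=0.5, horizon_shading=False)
    p = terrain.psir_annual(dtm, slo, asp, cfg)
    north_mean = p.values[3:8].mean()   # rows above crest face north
    south_mean = p.values[13:18].mean()
    assert south_mean > north_mean


def test_psir_zero_transmissivity_leaves_diffuse_only():
    dtm = make_plane(nrows=5, ncols=5)
    slo, asp = terrain.slope_aspect(dtm)
    lo = terrain.psir_annual(dtm, slo, asp, terrain.PSIRConfig(
        transmissivity=1e-9, day_step=60, hour_step=2.0, horizon_shading=False))
    # both direct and diffuse carry tau**(1/cos z): annual total collapses
    # from ~1e6 Wh/m2/yr to (numerically) nothing
    assert np.all(lo.values[lo.mask] < 1.0)


def test_psir_invariant_to_elevation_offset(default_scene):
    dtm = default_scene.terrain.elevation
    slo, asp = terrain.slope_aspect(dtm)
    cfg = terrain.PSIRConfig(day_step=90, hour_step=2.0)
    a = terrain.psir_annual(dtm, slo, asp, cfg)
    shifted = bc.Raster(dtm.grid, dtm.values + 57.0, dtm.mask)
    b = terrain.psir_annual(shifted, slo, asp, cfg)
    np.testing.assert_allclose(a.values[a.mask], b.values[b.mask], rtol=1e-12)


def test_psir_latitude_bound():
    with pytest.raises(ValueError):
        terrain.PSIRConfig(latitude=90.0)


# ---------------------------------------------------------------------------
# focal smoothing


def test_focal_mean_constant_unchanged():
    g = bc.Grid(nrows=6, ncols=6, cell_size=0.5)
    r = bc.Raster(g, np.full((6, 6), 4.0))
    out = terrain.focal_mean_circular(r, 1.0)
    np.testing.assert_allclose(out.values, 4.0)


def test_focal_mean_small_diameter_is_identity():
    g = bc.Grid(nrows=4, ncols=4, cell_size=0.5)
    vals = np.random.default_rng(1).random((4, 4))
    out = terrain.focal_mean_circular(bc.Raster(g, vals), 0.4)
    np.testing.assert_array_equal(out.values, vals)


def test_focal_mean_plus_shaped_window_hand_case():
    # 0.5 m cells, 1 m diameter: the window is the centre plus 4 cardinals
    g = bc.Grid(nrows=3, ncols=3, cell_size=0.5)
    vals = np.arange(9, dtype=float).reshape(3, 3)
    out = terrain.focal_mean_circular(bc.Raster(g, vals), 1.0)
    assert out.values[1, 1] == pytest.approx((4 + 1 + 3 + 5 + 7) / 5)


def test_focal_mean_ignores_nodata():
    g = bc.Grid(nrows=3, ncols=3, cell_size=0.5)
    vals = np.arange(9, dtype=float).reshape(3, 3)
    mask = np.ones((3, 3), bool)
    mask[0, 1] = False  # value 1 excluded
    out = terrain.focal_mean_circular(bc.Raster(g, vals, mask), 1.0)
    assert out.values[1, 1] == pytest.approx((4 + 3 + 5 + 7) / 4)
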