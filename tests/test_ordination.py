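import numpy as np
import pandas as pd
import pytest

import biocrust as bc
from biocrust import ordination
from biocrust.grid import CoverClass


# ---------------------------------------------------------------------------
# semivariogram


def test_semivariogram_constant_field_is_zero():
    rng = np.random.default_rng(0)
    xy = rng.uniform(0, 50, (100, 2))
    lags, gamma, _ = ordination.empirical_semivariogram(
        xy, np.full(100, 3.0), max_lag=30.0)
    np.testing.assert_allclose(gamma[np.isfinite(gamma)], 0.0)


def test_semivariogram_white_noise_flat_at_variance():
    rng = np.random.default_rng(1)
    n, sigma = 1200, 2.0
    xy = rng.uniform(0, 100, (n, 2))
    vals = rng.normal(0, sigma, n)
    lags, gamma, _ = ordination.empirical_semivariogram(xy, vals, max_lag=60.0,
                                                        n_bins=10)
    # each binned gamma estimates sigma^2; allow 3 s.e. with huge pair counts
    ok = np.isfinite(gamma)
    assert np.all(np.abs(gamma[ok] - sigma ** 2) < 0.5)


def test_semivariogram_smoothed_field_rises_then_sills():
    from scipy import ndimage
    rng = np.random.default_rng(2)
    field = ndimage.gaussian_filter(rng.standard_normal((80, 80)), 6.0)
    rows, cols = np.mgrid[0:80, 0:80]
    sel = rng.choice(80 * 80, 1500, replace=False)
    xy = np.column_stack([cols.ravel()[sel], rows.ravel()[sel]]).astype(float)
    vals = field.ravel()[sel]
    lags, gamma, rng_est = ordination.empirical_semivariogram(
        xy, vals, max_lag=40.0, n_bins=10)
    first = gamma[np.isfinite(gamma)][:4]
    assert np.all(np.diff(first) > -1e-12)  # monotone over the first bins
    assert rng_est > lags[0]


def test_semivariogram_needs_enough_points():
    with pytest.raises(ValueError):
        ordination.empirical_semivariogram(np.zeros((10, 2)), np.zeros(10), 5.0)


# ---------------------------------------------------------------------------
# minimum-distance sampling


def _valid_raster(n=80, cell=0.5):
    g = bc.Grid(nrows=n, ncols=n, cell_size=cell)
    return bc.Raster(g, np.zeros((n, n)))


def test_sample_respects_minimum_distance_and_seed():
    cfg = bc.OrdinationConfig(n_points=60, min_distance=3.0, seed=5)
    r = _valid_raster()
    pts = ordination.sample_min_distance(r, cfg)
    assert len(pts) == 60
    from scipy.spatial.distance import pdist
    assert pdist(pts).min() >= 3.0
    again = ordination.sample_min_distance(r, cfg)
    np.testing.assert_array_equal(pts, again)


def test_sample_overpacking_reports_achieved_count():
    cfg = bc.OrdinationConfig(n_points=500, min_distance=3.0, seed=1)
    with pytest.raises(ordination.SamplingError, match="placed only"):
        ordination.sample_min_distance(_valid_raster(40), cfg)


def test_sample_stays_on_valid_cells():
    g = bc.Grid(nrows=40, ncols=40, cell_size=1.0)
    mask = np.zeros((40, 40), bool)
    mask[:, :20] = True  # west half valid
    r = bc.Raster(g, np.zeros((40, 40)), mask)
    cfg = bc.OrdinationConfig(n_points=30, min_distance=2.0, seed=2)
    pts = ordination.sample_min_distance(r, cfg)
    assert np.all(pts[:, 0] < 20.0)


# ---------------------------------------------------------------------------
# buffer extraction


def test_extract_cover_uniform_map():
    g = bc.Grid(nrows=30, ncols=30, cell_size=0.5)
    classes = bc.ClassRaster(g, np.full((30, 30), int(CoverClass.MOSS),
                                        dtype=np.int16))
    pts = np.array([[7.5, -7.5]])
    cover, veg, soil = ordination.extract_cover(classes, pts, 3.0)
    assert cover.loc[0, "MOSS"] == pytest.approx(1.0)
    assert veg[0] == 0.0 and soil[0] == 0.0


def test_extract_cover_half_split_through_centre():
    g = bc.Grid(nrows=40, ncols=40, cell_size=0.5)
    labels = np.full((40, 40), int(CoverClass.SOIL), dtype=np.int16)
    labels[:, 20:] = int(CoverClass.MOSS)  # east half moss
    classes = bc.ClassRaster(g, labels)
    pts = np.array([[10.0, -10.0]])  # on the split line
    cover, veg, soil = ordination.extract_cover(classes, pts, 3.0)
    # one cell-row of the discrete disk (13 of ~113 cells) is ~0.06
    assert abs(cover.loc[0, "MOSS"] - 0.5) < 0.06
    assert abs(soil[0] - 0.5) < 0.06
    assert cover.loc[0, "MOSS"] + soil[0] == pytest.approx(1.0)


def test_extract_cover_fractions_sum_to_one(default_scene):
    sc = default_scene
    cfg = bc.OrdinationConfig(n_points=40, min_distance=3.0, seed=4)
    pts = ordination.sample_min_distance(sc.moisture, cfg)
    cover, veg, soil = ordination.extract_cover(sc.classes, pts, 3.0)
    total = cover.sum(axis=1).to_numpy() + veg + soil
    np.testing.assert_allclose(total, 1.0, atol=1e-12)
    assert np.all(cover.to_numpy() >= 0) and np.all(cover.to_numpy() <= 1)


# ---------------------------------------------------------------------------
# RDA


def brute_force_rda_eigenvalues(Y, X):
    """Oracle: explicit projection then full PCA of the fitted values."""
    Yc = Y - Y.mean(axis=0)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    P = Xs @ np.linalg.inv(Xs.T @ Xs) @ Xs.T
    Yhat = P @ Yc
    cov = Yhat.T @ Yhat / (len(Y) - 1)
    vals = np.linalg.eigvalsh(cov)[::-1]
    return vals[vals > 1e-12]


def test_rda_span_case_explains_everything():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((25, 3))
    B = rng.standard_normal((3, 4))
    Y = X @ B
    fit = ordination.rda_fit(Y, X)
    assert fit.proportion_explained == pytest.approx(1.0, abs=1e-10)


def test_rda_orthogonal_case_explains_nothing():
    n = 24
    X = np.column_stack([np.sin(2 * np.pi * np.arange(n) / n),
                         np.cos(2 * np.pi * np.arange(n) / n)])
    # Y constant in the X directions: use a response orthogonal to X columns
    Y = np.ones((n, 2))
    Y[:, 0] = np.sin(4 * np.pi * np.arange(n) / n)
    Y[:, 1] = np.cos(4 * np.pi * np.arange(n) / n)
    fit = ordination.rda_fit(Y, X)
    assert fit.proportion_explained == pytest.approx(0.0, abs=1e-10)


@pytest.mark.parametrize("seed", range(20))
def test_rda_eigenvalues_match_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    Y = rng.standard_normal((20, 3))
    X = rng.standard_normal((20, 2))
    fit = ordination.rda_fit(Y, X)
    want = brute_force_rda_eigenvalues(Y, X)
    got = fit.constrained_eigenvalues[:len(want)]
    np.testing.assert_allclose(got, want, atol=1e-8)


def test_rda_inertia_partition_and_affine_invariance():
    rng = np.random.default_rng(3)
    Y = rng.standard_normal((30, 4))
    X = rng.standard_normal((30, 3))
    fit = ordination.rda_fit(Y, X)
    total = fit.constrained_eigenvalues.sum() + fit.unconstrained_eigenvalues.sum()
    assert total == pytest.approx(fit.total_inertia, abs=1e-9)
    X2 = X * np.array([3.0, 0.2, 50.0]) + np.array([1.0, -7.0, 100.0])
    fit2 = ordination.rda_fit(Y, X2)
    assert fit2.proportion_explained == pytest.approx(
        fit.proportion_explained, abs=1e-10)


def test_rda_rank_deficient_raises():
    rng = np.random.default_rng(4)
    X = rng.standard_normal((15, 2))
    X = np.column_stack([X, X[:, 0]])
    with pytest.raises(ValueError, match="rank"):
        ordination.rda_fit(rng.standard_normal((15, 2)), X)


# ---------------------------------------------------------------------------
# permutation tests


def test_permutation_p_floor_is_one_over_n_plus_one():
    rng = np.random.default_rng(5)
    n = 40
    X = rng.standard_normal((n, 2))
    Y = X[:, [0]] * 5.0 + rng.standard_normal((n, 3)) * 0.01
    cfg = bc.OrdinationConfig(n_permutations=199, seed=5)
    tab = ordination.permutation_anova_marginal(Y, X, cfg)
    assert tab["p_value"].min() == pytest.approx(1.0 / 200.0)


def test_permutation_f_matches_partial_r2_ratio():
    rng = np.random.default_rng(6)
    n, p = 30, 3
    X = rng.standard_normal((n, p))
    Y = rng.standard_normal((n, 2))
    cfg = bc.OrdinationConfig(n_permutations=9, seed=6)
    tab = ordination.permutation_anova_marginal(Y, X, cfg)

    def explained(Xs_cols):
        Yc = Y - Y.mean(axis=0)
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        Xs = Xs[:, Xs_cols]
        beta, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)
        return np.trace((Xs @ beta).T @ (Xs @ beta)) / (n - 1)

    total = np.trace((Y - Y.mean(0)).T @ (Y - Y.mean(0))) / (n - 1)
    full = explained(list(range(p)))
    for t in range(p):
        red = explained([j for j in range(p) if j != t])
        f_ref = (full - red) / ((total - full) / (n - p - 1))
        assert tab.loc[t, "F"] == pytest.approx(f_ref, abs=1e-10)


def test_permutation_detects_strong_signal():
    rng = np.random.default_rng(7)
    n = 60
    X = rng.standard_normal((n, 2))
    Y = np.column_stack([X[:, 0] * 3, -X[:, 0] * 2, rng.standard_normal(n)])
    Y += rng.standard_normal(Y.shape) * 0.1
    cfg = bc.OrdinationConfig(n_permutations=199, seed=7)
    tab = ordination.permutation_anova_marginal(Y, X, cfg)
    assert tab.loc[0, "p_value"] <= 0.01
    assert tab.loc[1, "p_value"] > 0.05


# ---------------------------------------------------------------------------
# VIF screening


def test_orthonormal_predictors_have_unit_vif():
    n = 32
    t = np.arange(n)
    X = np.column_stack([np.sin(2 * np.pi * t / n), np.cos(2 * np.pi * t / n),
                         np.sin(4 * np.pi * t / n)])
    vifs = ordination.vif_table(X)["vif"].to_numpy()
    np.testing.assert_allclose(vifs, 1.0, atol=1e-10)


def test_duplicated_column_reports_infinite_vif_and_is_never_selected():
    rng = np.random.default_rng(8)
    x = rng.standard_normal(40)
    X = np.column_stack([x, x, rng.standard_normal(40)])
    vifs = ordination.vif_table(X)["vif"].to_numpy()
    assert np.isinf(vifs[0]) and np.isinf(vifs[1])
    Y = rng.standard_normal((40, 2))
    cfg = bc.OrdinationConfig(vif_threshold=10.0, seed=8)
    selected, table, fit = ordination.vif_select(Y, X, cfg,
                                                 predictor_names=["a", "b", "c"])
    assert not ({"a", "b"} <= set(selected))


def test_near_collinear_pair_never_jointly_selected():
    rng = np.random.default_rng(9)
    x = rng.standard_normal(60)
    x2 = x + rng.standard_normal(60) * 0.01  # corr ~0.99995
    X = np.column_stack([x, x2, rng.standard_normal(60)])
    pair_vif = ordination.vif_table(X[:, :2])["vif"].to_numpy()
    assert np.all(pair_vif > 10.0)
    Y = rng.standard_normal((60, 2))
    cfg = bc.OrdinationConfig(vif_threshold=10.0, seed=9)
    selected, _, _ = ordination.vif_select(
        Y, X, cfg, predictor_names=["x", "x2", "z"])
    assert not ({"x", "x2"} <= set(selected))
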