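"""Landscape-level constrained ordination of biocrust cover.

A semivariogram-guided random sample of points (pairwise distance >= 3 m)
is drawn over the valid area; fractional covers and terrain-attribute means
are extracted in a 3 m circle around each point; biocrust covers are then
related to the terrain predictors by redundancy analysis (RDA), with
marginal permutation tests per term, VIF screening (threshold 10) and
exhaustive adjusted-r² model selection.

RDA here is PCA of the fitted values of the multivariate regression of the
centred cover matrix Y on the standardized predictor matrix X; "inertia"
is total variance (trace of cov Y).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from .grid import (BIOCRUST_CLASSES, ClassRaster, CoverClass, Raster,
                   VEGETATION_CLASSES, assert_aligned)

__all__ = [
    "OrdinationConfig",
    "RDAResult",
    "empirical_semivariogram",
    "sample_min_distance",
    "extract_cover",
    "extract_circle_means",
    "rda_fit",
    "permutation_anova_marginal",
    "vif_table",
    "vif_select",
]


@dataclass(frozen=True)
class OrdinationConfig:
    """Sampling and testing parameters of the landscape analysis."""

    n_points: int = 1147
    min_distance: float = 3.0   # m
    buffer_radius: float = 3.0  # m
    n_permutations: int = 999
    vif_threshold: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_distance <= 0:
            raise ValueError("min_distance must be positive")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


# ---------------------------------------------------------------------------
# semivariogram and sampling


def empirical_semivariogram(xy: np.ndarray, values: np.ndarray,
                            max_lag: float, n_bins: int = 15,
                            ) -> tuple[np.ndarray, np.ndarray, float]:
    """Binned empirical semivariogram γ(h) and a pragmatic range estimate.

    γ(h) is half the mean squared difference within each lag bin; the range
    is the smallest lag centre where γ reaches 95% of the sill (mean of the
    last three bins).
    """
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(xy) < 30:
        raise ValueError("need >= 30 points for a semivariogram")
    from scipy.spatial.distance import pdist

    d = pdist(xy)
    dv2 = pdist(values.reshape(-1, 1), metric="sqeuclidean")
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    gamma = np.full(n_bins, np.nan)
    for i in range(n_bins):
        sel = (d > edges[i]) & (d <= edges[i + 1])
        if sel.sum() >= 2:
            gamma[i] = 0.5 * dv2[sel].mean()
    if np.all(np.isnan(gamma)):
        raise ValueError("fewer than 2 point pairs in every lag bin")
    finite = np.isfinite(gamma)
    sill = np.nanmean(gamma[finite][-3:])
    reached = finite & (gamma >= 0.95 * sill)
    rng_est = float(centres[reached][0]) if reached.any() else float(centres[-1])
    return centres, gamma, rng_est


class SamplingError(RuntimeError):
    def __init__(self, achieved: int, requested: int):
        super().__init__(
            f"placed only {achieved} of {requested} points at the requested "
            f"minimum distance"
        )
        self.achieved = achieved
        self.requested = requested


def sample_min_distance(valid_mask: Raster,
                        config: OrdinationConfig) -> np.ndarray:
    """Seeded dart-throwing sample with all pairwise distances >= min_distance.

    Points are uniform over valid cells; proposals are bounded (200 per
    requested point) and failure to reach ``n_points`` raises
    :class:`SamplingError` reporting the achieved count.
    """
    rng = np.random.default_rng(config.seed)
    grid = valid_mask.grid
    rows, cols = np.nonzero(valid_mask.mask)
    if rows.size == 0:
        raise ValueError("no valid area to sample")
    ox, oy = grid.origin
    cs = grid.cell_size
    d2 = config.min_distance ** 2
    cell = config.min_distance / np.sqrt(2.0)  # hash cell: at most 1 point each
    buckets: dict[tuple[int, int], int] = {}
    pts: list[tuple[float, float]] = []
    max_proposals = 200 * config.n_points
    proposals = 0
    while len(pts) < config.n_points and proposals < max_proposals:
        proposals += 1
        i = rng.integers(rows.size)
        u, v = rng.random(2)
        x = ox + (cols[i] + u) * cs
        y = oy - (rows[i] + v) * cs
        bx, by = int(x // cell), int(y // cell)
        ok = True
        for dx in (-2, -1, 0, 1, 2):
            for dy in (-2, -1, 0, 1, 2):
                j = buckets.get((bx + dx, by + dy))
                if j is not None:
                    px, py = pts[j]
                    if (px - x) ** 2 + (py - y) ** 2 < d2:
                        ok = False
                        break
            if not ok:
                break
        if ok:
            buckets[(bx, by)] = len(pts)
            pts.append((x, y))
    if len(pts) < config.n_points:
        raise SamplingError(len(pts), config.n_points)
    return np.asarray(pts)


# ---------------------------------------------------------------------------
# circular buffer extraction


def _disk_offsets(radius: float, cs: float) -> tuple[np.ndarray, np.ndarray]:
    half = int(np.ceil(radius / cs))
    dr, dc = np.mgrid[-half:half + 1, -half:half + 1]
    keep = (np.hypot(dr, dc) * cs) <= radius + 1e-12
    return dr[keep], dc[keep]


def extract_cover(classes: ClassRaster, points: np.ndarray, radius: float,
                  ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Fractional covers in a circle of ``radius`` around each point.

    Returns the biocrust cover matrix (columns BL, BLM, Moss, Fulg), plus
    the vegetation (GreenVeg+DryVeg) and bare-soil fraction vectors used as
    predictors.  Fractions are per valid cell inside the circle; a circle
    with zero valid cells raises.
    """
    grid = classes.grid
    dr, dc = _disk_offsets(radius, grid.cell_size)
    rows, cols = grid.rowcol(points[:, 0], points[:, 1])
    n = len(points)
    counts = np.zeros((n, 7), dtype=float)
    valid_n = np.zeros(n)
    for i in range(n):
        rr = rows[i] + dr
        cc = cols[i] + dc
        keep = (rr >= 0) & (rr < grid.nrows) & (cc >= 0) & (cc < grid.ncols)
        rr, cc = rr[keep], cc[keep]
        m = classes.mask[rr, cc]
        labs = classes.labels[rr, cc][m]
        if labs.size == 0:
            raise ValueError(f"sample circle {i} contains no valid cells")
        valid_n[i] = labs.size
        counts[i] = np.bincount(labs, minlength=8)[1:8]
    frac = counts / valid_n[:, None]
    cover = pd.DataFrame(
        {c.name: frac[:, int(c) - 1] for c in BIOCRUST_CLASSES})
    veg = frac[:, [int(c) - 1 for c in VEGETATION_CLASSES]].sum(axis=1)
    soil = frac[:, int(CoverClass.SOIL) - 1]
    return cover, veg, soil


def extract_circle_means(raster: Raster, points: np.ndarray,
                         radius: float) -> np.ndarray:
    """Mean of valid cells in a circle of ``radius`` around each point."""
    grid = raster.grid
    dr, dc = _disk_offsets(radius, grid.cell_size)
    rows, cols = grid.rowcol(points[:, 0], points[:, 1])
    out = np.full(len(points), np.nan)
    for i in range(len(points)):
        rr = rows[i] + dr
        cc = cols[i] + dc
        keep = (rr >= 0) & (rr < grid.nrows) & (cc >= 0) & (cc < grid.ncols)
        rr, cc = rr[keep], cc[keep]
        m = raster.mask[rr, cc]
        if m.any():
            out[i] = raster.values[rr, cc][m].mean()
    return out


# ---------------------------------------------------------------------------
# redundancy analysis


@dataclass
class RDAResult:
    """Constrained ordination of Y on X."""

    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    total_inertia: float
    proportion_explained: float
    adjusted_r_squared: float
    site_scores: np.ndarray       # fitted-value (lc) scores, n × k
    response_scores: np.ndarray   # cover loadings, m × k
    biplot_scores: np.ndarray     # predictor–axis correlations, p × k
    response_names: list = field(default_factory=list)
    predictor_names: list = field(default_factory=list)


def _prepare(Y, X):
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("Y and X must have the same number of rows")
    if n <= p + 1:
        raise ValueError("need more rows than predictors + 1")
    Yc = Y - Y.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant predictor column")
    Xs = (X - X.mean(axis=0)) / sd
    return Yc, Xs


def _fitted(Yc: np.ndarray, Xs: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)
    return Xs @ beta


def rda_fit(Y, X, response_names=None, predictor_names=None) -> RDAResult:
    """Redundancy analysis: PCA of the fitted values of Y ~ X.

    Y is centred, X standardized to unit variance.  Constrained eigenvalues
    come from the spectral decomposition of ŶᵀŶ/(n−1); the proportion
    explained is their sum over the total inertia (trace of cov Y), and the
    adjusted r² applies the usual (n−1)/(n−p−1) small-sample correction.
    """
    Yc, Xs = _prepare(Y, X)
    n, p = Xs.shape
    if np.linalg.matrix_rank(Xs) < p:
        raise ValueError("rank-deficient predictor matrix")
    Yhat = _fitted(Yc, Xs)
    resid = Yc - Yhat
    total = float(np.trace(Yc.T @ Yc) / (n - 1))
    # constrained axes
    u, s, vt = np.linalg.svd(Yhat / np.sqrt(n - 1), full_matrices=False)
    eig_c = s ** 2
    k = min(p, Yc.shape[1])
    eig_c = eig_c[:k]
    V = vt[:k].T
    site = Yhat @ V
    # unconstrained (residual) axes
    s_r = np.linalg.svd(resid / np.sqrt(n - 1), compute_uv=False)
    eig_u = s_r ** 2
    eig_u = eig_u[eig_u > 1e-12 * max(total, 1.0)]
    r2 = float(eig_c.sum() / total) if total > 0 else np.nan
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        site_sd = site.std(axis=0, ddof=1)
        biplot = np.array([
            [np.corrcoef(Xs[:, j], site[:, a])[0, 1] if site_sd[a] > 0 else 0.0
             for a in range(k)]
            for j in range(p)
        ])
    biplot = np.nan_to_num(biplot)
    return RDAResult(
        constrained_eigenvalues=eig_c,
        unconstrained_eigenvalues=eig_u,
        total_inertia=total,
        proportion_explained=r2,
        adjusted_r_squared=float(adj),
        site_scores=site,
        response_scores=V,
        biplot_scores=biplot,
        response_names=list(response_names) if response_names is not None else [],
        predictor_names=list(predictor_names) if predictor_names is not None else [],
    )


def _explained_inertia(Yc: np.ndarray, Xs: np.ndarray | None, n: int) -> float:
    if Xs is None or Xs.shape[1] == 0:
        return 0.0
    Yhat = _fitted(Yc, Xs)
    return float(np.trace(Yhat.T @ Yhat) / (n - 1))


def permutation_anova_marginal(Y, X, config: OrdinationConfig,
                               predictor_names=None) -> pd.DataFrame:
    """Marginal (type-III-like) permutation F tests per predictor term.

    For each term t, F = (I(X) − I(X₋ₜ)) / (I_resid(X)/(n−p−1)); the null
    distribution permutes the rows of the residuals of the reduced model
    (reduced fitted values + permuted residuals), n_permutations times;
    p = (#{F* >= F} + 1)/(N + 1).
    """
    Yc, Xs = _prepare(Y, X)
    n, p = Xs.shape
    rng = np.random.default_rng(config.seed)
    names = (list(predictor_names) if predictor_names is not None
             else [f"x{j}" for j in range(p)])
    total = float(np.trace(Yc.T @ Yc) / (n - 1))
    full = _explained_inertia(Yc, Xs, n)
    df_res = n - p - 1
    resid_full = (total - full) / df_res
    rows = []
    for t in range(p):
        keep = [j for j in range(p) if j != t]
        X_red = Xs[:, keep]
        red = _explained_inertia(Yc, X_red, n)
        f_obs = (full - red) / resid_full
        fitted_red = _fitted(Yc, X_red) if keep else np.zeros_like(Yc)
        resid_red = Yc - fitted_red
        count = 0
        for _ in range(config.n_permutations):
            perm = rng.permutation(n)
            Y_star = fitted_red + resid_red[perm]
            Y_star = Y_star - Y_star.mean(axis=0)
            full_s = _explained_inertia(Y_star, Xs, n)
            red_s = _explained_inertia(Y_star, X_red, n)
            total_s = float(np.trace(Y_star.T @ Y_star) / (n - 1))
            resid_s = (total_s - full_s) / df_res
            f_star = (full_s - red_s) / resid_s
            if f_star >= f_obs:
                count += 1
        rows.append({
            "term": names[t],
            "F": f_obs,
            "p_value": (count + 1) / (config.n_permutations + 1),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VIF screening and model selection


def vif_table(X, predictor_names=None) -> pd.DataFrame:
    """VIF_j = 1/(1 − R²_j) from regressing predictor j on the others.

    Perfect collinearity reports VIF = inf rather than raising.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = (list(predictor_names) if predictor_names is not None
             else [f"x{j}" for j in range(p)])
    Xs = (X - X.mean(axis=0))
    sd = Xs.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = Xs / sd
    vifs = []
    for j in range(p):
        if p == 1:
            vifs.append(1.0)
            continue
        others = np.delete(Xs, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, Xs[:, j], rcond=None)
        resid = Xs[:, j] - others @ beta
        sst = float((Xs[:, j] ** 2).sum())
        r2 = 1.0 - float((resid ** 2).sum()) / sst if sst > 0 else 1.0
        vifs.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    return pd.DataFrame({"term": names, "vif": vifs})


def vif_select(Y, X, config: OrdinationConfig,
               predictor_names=None) -> tuple[list, pd.DataFrame, RDAResult]:
    """Exhaustive subset search for the best RDA under the VIF screen.

    Every non-empty subset of candidate predictors is considered; subsets
    containing a member whose within-subset VIF exceeds the threshold are
    discarded; among the rest the subset maximizing the RDA adjusted r²
    wins.  Returns (selected names, full-candidate VIF table, best fit).
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if p < 2:
        raise ValueError("need >= 2 candidate predictors")
    names = (list(predictor_names) if predictor_names is not None
             else [f"x{j}" for j in range(p)])
    full_vif = vif_table(X, names)
    best: tuple[float, list, RDAResult] | None = None
    for size in range(1, p + 1):
        for subset in itertools.combinations(range(p), size):
            Xsub = X[:, list(subset)]
            vifs = vif_table(Xsub)["vif"].to_numpy()
            if np.any(vifs > config.vif_threshold):
                continue
            try:
                fit = rda_fit(Y, Xsub,
                              predictor_names=[names[j] for j in subset])
            except ValueError:
                continue
            if best is None or fit.adjusted_r_squared > best[0]:
                best = (fit.adjusted_r_squared, [names[j] for j in subset], fit)
    if best is None:
        raise ValueError("no admissible predictor subset under the VIF screen")
    return best[1], full_vif, best[2]
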