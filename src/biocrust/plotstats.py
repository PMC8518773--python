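"""Plot-level statistics: correlation ratio with min–max tercile binning,
tercile summary tables, and Kruskal–Wallis with Dunn's post hoc test.

The correlation ratio η² is the count-weighted between-category variance of
a soil property over its total variance, with categories formed by cutting
each terrain attribute — min–max standardized — at 1/3 and 2/3 into low,
medium and high terciles.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TercileBinning",
    "GroupTestResult",
    "tercile_bins",
    "correlation_ratio",
    "tercile_table",
    "kruskal_dunn",
]

TERCILE_LABELS = ("L", "M", "H")


@dataclass(frozen=True)
class TercileBinning:
    """Min–max standardized tercile labels of one attribute."""

    attribute: str
    vmin: float
    vmax: float
    labels: np.ndarray  # per-observation "L"/"M"/"H"


def tercile_bins(values, attribute: str = "") -> TercileBinning:
    """Cut (v−min)/(max−min) at 1/3 and 2/3 into L / M / H.

    Bins are left-closed; the maximum maps to H.  Constant input raises
    (the standardization is undefined).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need >= 3 values to form terciles")
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        raise ValueError("constant attribute: tercile standardization undefined")
    vhat = (v - vmin) / (vmax - vmin)
    labels = np.where(vhat < 1.0 / 3.0, "L", np.where(vhat < 2.0 / 3.0, "M", "H"))
    return TercileBinning(attribute, vmin, vmax, labels)


def correlation_ratio(y, labels) -> float:
    """η² = Σ nₓ(ȳₓ − ȳ)² / Σ(yᵢ − ȳ)² — in [0, 1]."""
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    if y.size != labels.size:
        raise ValueError("y and labels must have equal length")
    cats = np.unique(labels)
    if len(cats) < 2:
        raise ValueError("need >= 2 non-empty categories")
    grand = y.mean()
    total = float(((y - grand) ** 2).sum())
    if total == 0:
        raise ValueError("zero total variance")
    between = sum(
        (labels == c).sum() * (y[labels == c].mean() - grand) ** 2 for c in cats
    )
    return float(between / total)


def tercile_table(plots: pd.DataFrame, attributes: list[str],
                  properties: list[str], *, eta2_min: float = 0.3) -> pd.DataFrame:
    """Per-tercile mean ± s.d. of each soil property with its η².

    One row per (attribute, property); rows with η² below ``eta2_min`` are
    flagged ``represented = False`` (mirroring the reporting convention of
    showing only η² > 0.3).
    """
    rows = []
    for attr in attributes:
        binning = tercile_bins(plots[attr].to_numpy(), attr)
        for prop in properties:
            y = plots[prop].to_numpy(dtype=float)
            eta2 = correlation_ratio(y, binning.labels)
            row: dict = {"attribute": attr, "property": prop, "eta2": eta2,
                         "represented": eta2 >= eta2_min}
            for lab in TERCILE_LABELS:
                sel = binning.labels == lab
                row[f"{lab}_mean"] = float(y[sel].mean()) if sel.any() else np.nan
                row[f"{lab}_sd"] = (float(y[sel].std(ddof=1))
                                    if sel.sum() > 1 else np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GroupTestResult:
    """Kruskal–Wallis H test with Dunn's pairwise post hoc comparisons."""

    h_statistic: float
    p_value: float
    pairs: list[tuple[str, str]]
    z_statistics: np.ndarray
    p_adjusted: np.ndarray
    letters: dict[str, str]


def _dunn_z(values: np.ndarray, groups: np.ndarray,
            names: list) -> tuple[list, np.ndarray]:
    """Dunn z statistics on mean ranks with tie-corrected variance."""
    n = len(values)
    ranks = stats.rankdata(values)  # average ranks for ties
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (n - 1)))
    mean_rank = {g: ranks[groups == g].mean() for g in names}
    sizes = {g: int((groups == g).sum()) for g in names}
    pairs, zs = [], []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        pairs.append((a, b))
        zs.append(z)
    return pairs, np.asarray(zs)


def _letter_display(names: list, pairs: list, significant: np.ndarray) -> dict:
    """Compact letter display: groups not significantly different share a letter."""
    sig = {frozenset(p) for p, s in zip(pairs, significant) if s}

    def compatible(g, group_set):
        return all(frozenset((g, other)) not in sig for other in group_set)

    # insert-and-absorb: place each group in every compatible letter set;
    # when none fits, open a new set and absorb earlier compatible groups
    letter_sets: list[set] = []
    for i, g in enumerate(names):
        placed = False
        for s in letter_sets:
            if compatible(g, s):
                s.add(g)
                placed = True
        if not placed:
            new = {g}
            for h in names[:i]:
                if compatible(h, new):
                    new.add(h)
            letter_sets.append(new)
    # drop sets fully contained in another
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(s < t for j, t in enumerate(letter_sets) if i != j)]
    letters: dict[str, str] = {g: "" for g in names}
    for i, s in enumerate(letter_sets):
        ch = chr(ord("a") + i)
        for g in names:
            if g in s:
                letters[g] += ch
    return letters


def kruskal_dunn(groups: dict, adjust: str = "holm") -> GroupTestResult:
    """Kruskal–Wallis H (tie-corrected) plus Dunn's pairwise z tests.

    ``groups`` maps group name → 1-D values.  Pairwise two-sided normal
    p-values are adjusted with the chosen method (Holm by default) and
    summarized as a compact letter display.
    """
    names = list(groups)
    if len(names) < 2 or any(len(np.asarray(groups[g])) == 0 for g in names):
        raise ValueError("need >= 2 groups, each with >= 1 value")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical: no ranking information")
    h, p = stats.kruskal(*arrays)
    labels = np.concatenate([np.full(len(a), g) for g, a in zip(names, arrays)])
    pairs, zs = _dunn_z(pooled, labels, names)
    p_raw = 2.0 * stats.norm.sf(np.abs(zs))
    reject, p_adj, _, _ = multipletests(p_raw, alpha=0.05, method=adjust)
    letters = _letter_display(names, pairs, reject)
    return GroupTestResult(float(h), float(p), pairs, zs, p_adj, letters)
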