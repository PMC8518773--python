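"""Continuum removal, SVM cover classification, CR-threshold refinement
and accuracy assessment.

The continuum baseline is the straight line between the green (550 nm) and
red-edge (735 nm) band reflectances; the continuum-removed red value
``CR_red = min(1, ρ660/c)`` captures the chlorophyll-a absorption depth.
Two deterministic rules then repair the spectrally confusable pairs: dry
vegetation with strong chlorophyll absorption (CR_red < 0.75) becomes
moss, and bright-lichen pixels with no absorption at all (CR_red = 1)
become bare soil.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .grid import (BAND_CENTRES_NM, ClassRaster, CoverClass, MultibandRaster,
                   Raster, assert_aligned)

__all__ = [
    "RefinementRules",
    "TrainingSet",
    "ClassifierModel",
    "AccuracyReport",
    "cr_red",
    "build_training_set",
    "train_classifier",
    "classify",
    "refine",
    "assess_accuracy",
]

# interpolation weight of the red band centre on the green→red-edge chord
_W_RED = ((BAND_CENTRES_NM["red"] - BAND_CENTRES_NM["green"])
          / (BAND_CENTRES_NM["red_edge"] - BAND_CENTRES_NM["green"]))  # 110/185


@dataclass(frozen=True)
class RefinementRules:
    """Thresholds of the CR_red classification-repair rules."""

    dryveg_to_moss_threshold: float = 0.75
    bl_to_soil_value: float = 1.0
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not (0 < self.dryveg_to_moss_threshold <= 1
                and 0 < self.bl_to_soil_value <= 1):
            raise ValueError("CR thresholds must lie in (0, 1]")


def cr_red(image: MultibandRaster) -> Raster:
    """Continuum-removed reflectance at the red band (chlorophyll-a depth).

    The continuum at 660 nm is the linear interpolation between the green
    and red-edge reflectances; values above 1 (local maxima) are clipped
    to 1.  Cells with a non-positive continuum become nodata.
    """
    g = image.values[0]
    red = image.values[1]
    re = image.values[2]
    c = g + (re - g) * _W_RED
    valid = image.mask & (c > 0)
    if image.mask.any() and not valid.any():
        raise ValueError("continuum non-positive everywhere")
    with np.errstate(divide="ignore", invalid="ignore"):
        cr = np.clip(red / c, 0.0, 1.0)
    return Raster(image.grid, cr, valid)


@dataclass
class TrainingSet:
    """Labelled training pixels grouped by polygon."""

    features: np.ndarray    # (n_pixels, 4) reflectance
    labels: np.ndarray      # (n_pixels,) CoverClass codes
    polygon_ids: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.polygon_ids = np.asarray(self.polygon_ids)
        if self.features.ndim != 2 or self.features.shape[1] != 4:
            raise ValueError("features must be (n, 4)")
        if len(self.labels) != len(self.features):
            raise ValueError("labels and features must match")

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.labels))


def build_training_set(image: MultibandRaster, reference: ClassRaster,
                       seed: int, *, n_polygons: int = 15,
                       polygon_size: int = 3) -> TrainingSet:
    """Sample square labelled polygons per class from a reference map.

    Mimics field practice: at least ``n_polygons`` groups of
    ``polygon_size``² pixels (~100 pixels) per class present in the map.
    Homogeneous square windows are preferred; where a class is too
    fine-grained to fill its quota with pure windows, the remaining groups
    are scattered same-class pixels (as field operators digitize dispersed
    patches of a patchy cover).
    """
    assert_aligned(image, reference)
    rng = np.random.default_rng(seed)
    nr, nc = reference.grid.shape
    half = polygon_size // 2
    per_polygon = polygon_size ** 2
    feats, labs, pids = [], [], []
    pid = 0
    for cls in CoverClass:
        rows, cols = np.nonzero((reference.labels == int(cls)) & reference.mask
                                & image.mask)
        if rows.size == 0:
            continue
        got = 0
        used = np.zeros(rows.size, dtype=bool)
        order = rng.permutation(rows.size)
        for i in order:
            r, c = int(rows[i]), int(cols[i])
            if not (half <= r < nr - half and half <= c < nc - half):
                continue
            win = reference.labels[r - half:r + half + 1, c - half:c + half + 1]
            wmask = reference.mask[r - half:r + half + 1, c - half:c + half + 1]
            if not (wmask.all() and (win == int(cls)).all()):
                continue
            block = image.values[:, r - half:r + half + 1, c - half:c + half + 1]
            feats.append(block.reshape(4, -1).T)
            labs.append(np.full(per_polygon, int(cls)))
            pids.append(np.full(per_polygon, pid))
            used[i] = True
            pid += 1
            got += 1
            if got >= n_polygons:
                break
        while got < n_polygons and (~used).sum() >= per_polygon:
            free = np.nonzero(~used)[0]
            take = rng.choice(free, size=min(per_polygon, free.size),
                              replace=False)
            used[take] = True
            feats.append(image.values[:, rows[take], cols[take]].T)
            labs.append(np.full(len(take), int(cls)))
            pids.append(np.full(len(take), pid))
            pid += 1
            got += 1
    if not feats:
        raise ValueError("no trainable polygons found")
    return TrainingSet(np.vstack(feats), np.concatenate(labs),
                       np.concatenate(pids))


@dataclass
class ClassifierModel:
    """A trained RBF-kernel max-margin classifier over the 4 bands."""

    svc: SVC
    classes: np.ndarray


def train_classifier(training: TrainingSet, seed: int = 0, *,
                     c: float = 1.0, gamma: str | float = "scale") -> ClassifierModel:
    """Fit the RBF-kernel SVM (C=1, γ=1/(4·var) by default).

    The fit is deterministic given the data; ``seed`` only controls the
    tie-breaking RNG inside the solver.
    """
    if training.n_classes < 2:
        raise ValueError("need at least 2 classes to train")
    counts = np.bincount(training.labels)
    if np.any((counts > 0) & (counts < 2)):
        raise ValueError("need >= 2 samples per class")
    svc = SVC(C=c, kernel="rbf", gamma=gamma, random_state=int(seed))
    svc.fit(training.features, training.labels)
    return ClassifierModel(svc, svc.classes_)


def classify(model: ClassifierModel, image: MultibandRaster,
             chunk: int = 200_000) -> ClassRaster:
    """Per-pixel prediction; nodata pixels propagate as unlabelled."""
    if model.svc.n_features_in_ != 4:
        raise ValueError("model feature count does not match the 4 bands")
    labels = np.zeros(image.grid.shape, dtype=np.int16)
    rows, cols = np.nonzero(image.mask)
    feats = image.values[:, rows, cols].T
    preds = np.empty(len(feats), dtype=np.int16)
    for start in range(0, len(feats), chunk):
        preds[start:start + chunk] = model.svc.predict(feats[start:start + chunk])
    labels[rows, cols] = preds
    return ClassRaster(image.grid, labels, image.mask.copy())


def refine(classes: ClassRaster, cr: Raster,
           rules: RefinementRules = RefinementRules()
           ) -> tuple[ClassRaster, dict[str, int]]:
    """Apply the two CR_red repair rules; returns the new map and counts.

    DryVeg with CR_red < 0.75 → Moss; BL with CR_red = 1 (within ε) → Soil.
    No other pixel is touched; applying the rules twice is a no-op.
    """
    assert_aligned(classes, cr)
    labels = classes.labels.copy()
    crv = cr.filled(np.nan)
    dry_to_moss = (classes.mask & cr.mask
                   & (labels == int(CoverClass.DRYVEG))
                   & (crv < rules.dryveg_to_moss_threshold))
    bl_to_soil = (classes.mask & cr.mask
                  & (labels == int(CoverClass.BL))
                  & (crv >= rules.bl_to_soil_value - rules.epsilon))
    labels[dry_to_moss] = int(CoverClass.MOSS)
    labels[bl_to_soil] = int(CoverClass.SOIL)
    counts = {
        "dryveg_to_moss": int(dry_to_moss.sum()),
        "bl_to_soil": int(bl_to_soil.sum()),
    }
    return ClassRaster(classes.grid, labels, classes.mask.copy()), counts


@dataclass
class AccuracyReport:
    """Confusion matrix (rows = classified, columns = ground truth) and scores."""

    classes: np.ndarray
    matrix: np.ndarray
    overall_accuracy: float
    kappa: float
    producers_accuracy: dict[int, float]
    users_accuracy: dict[int, float]


def assess_accuracy(predicted: np.ndarray, reference: np.ndarray,
                    classes: np.ndarray | None = None) -> AccuracyReport:
    """Confusion matrix, overall accuracy and Cohen's kappa.

    OA = trace/total; κ = (p₀ − p_e)/(1 − p_e) with
    p_e = Σ row_total·col_total / total².
    """
    predicted = np.asarray(predicted).ravel()
    reference = np.asarray(reference).ravel()
    if predicted.size == 0 or predicted.size != reference.size:
        raise ValueError("need matching, non-empty prediction/reference labels")
    if classes is None:
        classes = np.unique(np.concatenate([predicted, reference]))
    classes = np.asarray(classes)
    k = len(classes)
    index = {int(c): i for i, c in enumerate(classes)}
    matrix = np.zeros((k, k), dtype=np.int64)
    for p, t in zip(predicted, reference):
        matrix[index[int(p)], index[int(t)]] += 1
    total = matrix.sum()
    p0 = matrix.trace() / total
    pe = float((matrix.sum(axis=1) * matrix.sum(axis=0)).sum()) / total ** 2
    if pe >= 1.0 - 1e-15:
        raise ValueError("degenerate confusion matrix: chance agreement is 1")
    kappa = (p0 - pe) / (1.0 - pe)
    col = matrix.sum(axis=0)
    row = matrix.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        producers = {int(c): float(matrix[i, i] / col[i]) if col[i] else np.nan
                     for i, c in enumerate(classes)}
        users = {int(c): float(matrix[i, i] / row[i]) if row[i] else np.nan
                 for i, c in enumerate(classes)}
    return AccuracyReport(classes, matrix, float(p0), float(kappa),
                          producers, users)
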