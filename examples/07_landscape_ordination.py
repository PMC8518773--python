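"""Landscape-scale redundancy analysis of biocrust covers on terrain.

Points are sampled at >= 3 m spacing, fractional covers and attribute
means extracted in 3 m circles, predictors screened by VIF, and the best
RDA (by adjusted r2) fitted; marginal permutation tests give per-term
significance.
"""
import numpy as np
import pandas as pd

import biocrust as bc
from biocrust import ordination
from biocrust.classify import (build_training_set, classify, cr_red, refine,
                               train_classifier)

seed = 6
scene = bc.generate_scene(bc.SceneConfig(seed=seed))
training = build_training_set(scene.reflectance, scene.classes, seed=seed)
cover_map, _ = refine(classify(train_classifier(training, seed=seed),
                               scene.reflectance),
                      cr_red(scene.reflectance))
ati_map = bc.mask_vegetation(bc.ati(scene.albedo, scene.t_predawn,
                                    scene.t_noon), cover_map)

cfg = bc.OrdinationConfig(n_points=150, n_permutations=199, seed=seed)
points = ordination.sample_min_distance(ati_map, cfg)
cover, veg, soil = ordination.extract_cover(cover_map, points,
                                            cfg.buffer_radius)
st = scene.terrain
X = pd.DataFrame({
    "Elevation": ordination.extract_circle_means(st.elevation, points, 3.0),
    "Slope": ordination.extract_circle_means(st.slope, points, 3.0),
    "Northernness": ordination.extract_circle_means(st.northernness, points, 3.0),
    "TWI": ordination.extract_circle_means(st.twi, points, 3.0),
    "LSF": ordination.extract_circle_means(st.lsf, points, 3.0),
    "PSIR": ordination.extract_circle_means(st.psir, points, 3.0),
    "ATI": ordination.extract_circle_means(ati_map, points, 3.0),
})
ok = X.notna().all(axis=1).to_numpy()
Y = cover[ok]
X = X[ok]

selected, vifs, fit = ordination.vif_select(Y.to_numpy(), X.to_numpy(), cfg,
                                            predictor_names=list(X.columns))
print("VIFs:", dict(zip(vifs.term, vifs.vif.round(1))))
print(f"selected predictors: {selected}")
print(f"explained {100 * fit.proportion_explained:.1f} % of total inertia "
      f"(adjusted r2 {fit.adjusted_r_squared:.3f})")
anova = ordination.permutation_anova_marginal(
    Y.to_numpy(), X[selected].to_numpy(), cfg, predictor_names=selected)
print(anova.to_string(index=False))
idx = {n: i for i, n in enumerate(Y.columns)}
print("axis-1 cover loadings:",
      {n: round(float(fit.response_scores[i, 0]), 2) for n, i in idx.items()})
# Moss loads opposite to the lichen covers on axis 1 and tracks ATI
# (moisture) - the moisture-driven niche separation the method was built
# to detect. Note the VIF screen discards the collinear aspect-derived
# predictors (Northernness, and often Slope/PSIR), as in field practice.
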