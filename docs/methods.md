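# Methods

This note documents the models implemented in `biocrust`, the defaults and
why they were chosen, what the synthetic scene generator does and does not
emulate, and the numerical conventions that matter when comparing output
against other toolchains.

## Raster model and conventions

All rasters are square-cell, north-up grids in one planar metric CRS
(row 0 = northernmost row; values refer to cell centres; distances in
metres). Validity is carried as an explicit boolean mask — the nodata
sentinel exists only on disk (GeoTIFF tags ModelPixelScale, ModelTiepoint,
GDAL_NODATA, written and read through `tifffile`). Every multi-input
operation checks grid identity to 1e-6 m and raises instead of resampling:
inputs on different grids must be resampled explicitly by the user.

## Terrain attributes

**Slope/aspect.** Partial derivatives are the central differences of the
3×3 window (the Zevenbergen–Thorne second-order polynomial fit), one-sided
at grid edges so an inclined plane is exact everywhere. Slope is stored in
degrees; aspect is the azimuth of the downslope direction, clockwise from
north, nodata on flat cells. Northernness is `cos(aspect)+1 ∈ [0,2]`
(2 = due north), so `northernness + southness = 2` identically.

**Pit removal** is priority-flood: cells are raised minimally so that every
cell has a non-ascending path to the boundary. An `epsilon` (default
1e-6 m) is added when raising so filled flats retain a resolvable gradient
toward their spill point; `epsilon=0` gives the exact minimal fill.

**D-infinity.** Flow direction is the steepest descent over the eight
triangular facets of the 3×3 window; flow splits between the two
neighbours bounding the chosen facet in proportion to angular distance.
Boundary cells without an interior downslope neighbour discharge out of
the grid; an unresolvable interior cell is reported as a pit.
Accumulation runs in topological order (Kahn's algorithm on the flow
graph) and is exact: it matches a memoized recursive oracle to < 1e-9 m²
on random surfaces, and total boundary outflow equals the grid area to
1e-6 relative. *A* is reported as **specific catchment area**
(accumulated area / cell width, metres), the convention of the standard
D-infinity tools; raw m² is available via `specific=False`. On smooth
curved surfaces (e.g. a perfect cone) facet angles deviate from the
analytic radial direction by up to ~7°, a known discretization property of
the facet fit, not an error.

**TWI and LSF.** `TWI = ln(A/tan β)` with `tan β` clamped at 1e-3
(≈ 0.057°) so flat cells stay finite; the clamp is a configurable
constant. `LSF = (n+1)(A/22.13)^n (sin β/0.0896)^m` with n = 0.4, m = 1.3.
Both accept specific catchment area by default (see above; the alternative
raw-area convention is exposed but not default).

**PSIR.** Annual clear-sky insolation (Wh/m²/yr) from standard solar
geometry: declination `23.45° sin(2π(284+d)/365)`, hour angle, zenith and
azimuth per instant; direct component `S₀ τ^(1/cos z) max(0, cos θᵢ)` on
the tilted cell, zeroed when the sun sits below the local horizon
(precomputed by ray-marching in 8 azimuth directions, on by default);
diffuse component `d·S₀ τ^(1/cos z) (1+cos s)/2` under a uniform sky.
Defaults: latitude 40.03° N, transmissivity τ = 0.5, diffuse proportion
d = 0.3, S₀ = 1367 W/m², every 5 days × 0.25 h. The model is invariant to
adding a constant to the DTM and uniform on a flat, unshaded surface. A
uniform (not standard-overcast) diffuse sky is an explicit design choice;
so is the τ^airmass clear-sky form — richer atmospheric models are out of
scope.

**Focal smoothing.** Mean over cells whose centres lie within the circular
window (default diameter 1 m), ignoring nodata; a diameter below one cell
is the identity.

## Radiometry

DN → reflectance follows `R = f²(P−B)/(A·γ·ε + C)`, `K = ρ_ref/R_ref`
from the panel's mean DN, `ρ = K·R`; negative reflectances are floored at
0 and counted. The denominator grouping `A·γ·ε + C` is adopted explicitly
(the published calibration model for this camera family); any re-grouping
that differs by a band-constant factor is absorbed by `K` and therefore
unobservable in `ρ`. Calibration is affine in DN per band (before the
floor). The empirical line is an independent per-band OLS fit of ground on
sensor reflectance — exact interpolation with two targets — and any
measured surface can serve as a target (the bright-target fallback when a
panel saturates). Spectral resampling is the response-weighted mean of the
linearly interpolated spectrum.

## Classification

The continuum at 660 nm is the chord between the 550 and 735 nm band
reflectances (band centres, not FWHM centroids); `CR_red = ρ₆₆₀/c`,
clipped into [0, 1] — the clip makes "equals 1" well-defined for the
bare-soil rule, tested with ε = 1e-6. The classifier is a scikit-learn
RBF-kernel SVC with C = 1 and γ = 1/(4·var) ("scale"), fixed for
determinism rather than tuned. Training polygons are sampled from a
labelled reference map: at least 15 groups of ~9 pixels per class,
preferring homogeneous 3×3 windows and falling back to scattered
same-class pixels for finely interspersed covers. The repair rules move
*only* DryVeg (CR_red < 0.75 → Moss) and BL (CR_red ≥ 1−ε → Soil) pixels
and are idempotent. Accuracy reports the confusion matrix with
**rows = classified, columns = ground truth**, OA = trace/total and
Cohen's κ = (p₀−p_e)/(1−p_e).

## Apparent thermal inertia

`T(°C) = 0.01·DN − 100`; `α` = mean of the four band reflectances;
`ATI = C(1−α)/ΔT` with `ΔT = T_noon − T_predawn`. C is an input constant
(default 1.19, the solar-correction value for the site and date; no
internal formula is computed because none is specified for it). Cells with
`ΔT < 0.1 K` or `α ≥ 1` become nodata rather than exploding. Emissivity is
taken as 1. Vegetation (GreenVeg, DryVeg) is masked before plot
aggregation; plot means average the valid cells whose centres fall inside
each polygon; the moisture link is quantified by OLS of moisture (%) on
plot-mean ATI with a t-based slope CI.

## Plot and landscape statistics

η² uses the count-weighted between-category variance over total variance
(it equals the R² of a regression on category indicators, which the tests
verify to 1e-12). Terciles cut the min–max standardized attribute at 1/3
and 2/3, left-closed, maximum → H. Tercile tables flag rows with η² < 0.3
as "not represented", mirroring the reporting convention for this system.
Dunn's test uses mean ranks with tie-corrected variance and Holm-adjusted
two-sided normal p-values (the adjustment method is configurable; Holm is
the default because the upstream tool's default is unstated), summarized
as a compact letter display (insert-and-absorb).

RDA centres Y (cover fractions share units) and standardizes X, then takes
the PCA of the fitted values of Y ~ X; "inertia" is total variance.
Reported: constrained/unconstrained eigenvalues (their sums partition
total inertia to 1e-9), proportion explained, adjusted
r² = 1−(1−R²)(n−1)/(n−p−1), fitted-value site scores, response loadings,
and predictor–axis correlations as biplot scores. Marginal permutation
tests permute the residuals of the reduced model (the standard scheme for
partial terms): `F_t = (I(X)−I(X₋ₜ)) / (I_resid(X)/(n−p−1))`,
`p = (#{F* ≥ F}+1)/(N+1)`, seeded; type-I error is calibrated (within
[0.03, 0.07] at α = 0.05 in the test suite, N = 199 over 500 null
replicates — N scaled down from the analysis default 999 to keep the
calibration loop cheap). VIFs are computed within each candidate subset;
subsets containing a member with VIF > 10 are discarded and the remainder
searched exhaustively (≤ 2⁹ models) for maximum adjusted r² — no stepwise
heuristics. Point sampling is seeded dart-throwing with a spatial hash
(all pairwise distances ≥ 3 m by construction; failure reports the
achieved count), and the empirical semivariogram (γ = half the mean
squared difference per lag bin; range = first lag at 95% of the sill,
sill = mean of the last three bins) is advisory for choosing that
distance.

## The synthetic scene generator

The generator produces the study conditions the pipeline is validated
under, at a desk scale: a 60 × 60 m site at 0.5 m cells (the field areas
are hectares at 0.10–0.15 m; all structure, not size, is what the tests
need) with 23 2×2 m plots. Its components:

- **DTM**: inclined plane (gradient 0.02/0.03) plus 12 Gaussian
  knolls/hollows with amplitudes uniform in ±2.5 m and footprints 5–15 m.
  The bumps are tall relative to the tilt deliberately, so local aspect
  spans the full compass — the field site's four zones face W/E/S/N, and
  without that diversity the northernness-driven structure below would be
  unrecoverable.
- **Moisture** (%): `m0 + 8·ĉ − 6·p̂ + N(0,1)`, with ĉ, p̂ the min–max
  normalized northernness and PSIR, clipped to the observed 4.44–22.6 %
  range (m0 = 12 centres the field near the observed mean ≈ 14 %).
  North-facing, low-insolation ground is wetter.
- **Cover map**: GreenVeg/DryVeg are clumped patches (Gaussian-smoothed
  white noise thresholded at prior-matching quantiles, 2 m patch scale);
  the five ground covers draw from a multinomial whose log-odds shift with
  standardized moisture (+0.9 for Moss; −0.5/−0.4/−0.3 for BL/BLM/Fulg),
  so mosses occupy wet ground and lichens dry ground. Default priors
  (Soil .08, BL .05, BLM .10, Moss .20, Fulg .08, GreenVeg .09,
  DryVeg .40) follow the cover ranking mapped in the field (dry vegetation
  dominant; mixed lichen classes rarest).
- **Reflectance**: per-class endmember + independent Gaussian noise
  (sd 0.01), floored at 0. The hand-authored endmember table is config
  data, not code, and satisfies the reported qualitative ordering: BL
  brightest; Moss darkest biocrust with strong chlorophyll absorption
  (CR_red ≈ 0.42); GreenVeg deepest absorption (≈ 0.24); Soil exactly on
  the continuum (CR_red = 1); DryVeg darkest overall with only a weak
  residual red dip (CR_red ≈ 0.93) — the repair threshold 0.75 was
  derived in the field from class CR statistics precisely so that true
  DryVeg sits well above it, and the endmember honours that construction.
  Raw DN invert the radiometric chain (`P = B + ρ(Aγε+C)/(K f²)`) with
  half-up rounding and clamping to the sensor range, so calibration
  recovers reflectance to within one DN step; the panel DN is emitted
  unrounded (it is a mean over panel pixels).
- **Thermal pair**: `ATI_true = 0.02 + 0.005·moisture` (K⁻¹) defines
  `ΔT = 1.19(1−α)/ATI_true`; pre-dawn temperature is a 8 °C baseline,
  noon adds ΔT, both with optional Gaussian noise (default sd 0.5 K, a
  typical uncooled-microbolometer pixel noise) and DN counterparts via
  `R = 100(T+100)`. At zero noise the pipeline recovers ATI_true to 1e-10
  and the plot regression is exact (r² = 1).
- **Plots**: 23 non-overlapping squares placed on ≤ 50 % vegetated ground
  (field plots target biocrust/soil surfaces). Moisture and northernness
  are vegetation-excluded zonal means; soil properties follow the
  reported trend directions in normalized plot northernness n̂ —
  SolSal = 92 − 28 n̂ + N(0,6), OrgCarb = 0.45 + 1.1 n̂ + N(0,0.25),
  P_tot = 0.15 + 0.9 n̂ + N(0,0.25), N_tot = 0.03 + 0.10 n̂ + N(0,0.02) —
  all clipped to the observed field ranges.

One seed reproduces the whole scene bit-exactly (independent substreams
per stage). Spatially correlated noise is available through a single
smoothing-radius parameter (default 0: independent per cell).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: photogrammetric (SfM) surface error and
vegetation-removal artefacts in the DTM; BRDF, shadowing and vignetting in
the optical bands; diurnal soil-heat-flux physics beyond the ATI identity;
spatial autocorrelation of measurement noise (unless enabled); soil
heterogeneity that would scatter the ATI–moisture link (the link is exact
by construction, so recovery tests probe numerics, not ecology); and
mixed pixels, since each cell carries one cover.

## Problem sizes and known limitations

End-to-end checks run on 60 × 60 m scenes with 150 ordination points and
199 permutations (the file-based analysis default remains 1147 points /
999 permutations; a 60 m site physically holds only ~250 points at 3 m
spacing). These sizes are the package's validation choice: they leave all
method parameters — thresholds, exponents, constants — at their
operational values.

Because the generated ATI–moisture link carries noise only on the thermal
(ATI) side, the plot regression of moisture on ATI is an
errors-in-variables fit: its OLS slope CI is slightly anticonservative,
and the measured coverage of the implied slope is ≈ 85–91 % across seed
sets rather than the nominal 95 %. With a moisture-side error source
(e.g. probe measurement error, which the generator deliberately omits to
keep plot moisture an exact zonal mean) coverage would be nominal; this is
documented rather than "fixed" by inflating the interval.

The SVM decision boundary, not the CR_red rules, does most of the work on
synthetic scenes (the endmember clusters are separable), so the repair
rules move few pixels here; their tests therefore verify the rule
contract exactly rather than a large accuracy gain. On real imagery with
overlapping class spectra the rules matter more.
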