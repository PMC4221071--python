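# Methods

This package re-creates, end to end on a synthetic study system, a
bioclimatic-envelope analysis for a cold-limited subalpine conifer
(whitebark pine, *Pinus albicaulis*, in a Greater-Yellowstone-like
mountain domain): derive water-balance covariates from monthly climate,
fit a presence/absence classifier, select an operating threshold,
project suitable habitat under a multi-member climate ensemble, and
quantify area loss, elevational shift, ensemble variability, and patch
fragmentation. This note documents the models, their assumptions, the
defaults that matter, and what the synthetic system can and cannot show.

## The synthetic study system

Real analyses of this kind consume proprietary or heavyweight gridded
products (interpolated station climatologies, statistically down-scaled
GCM archives, national forest-inventory plots, soil surveys). The
`synthetic_data` module replaces them with generators whose statistical
structure matches what the downstream method assumes, and whose ground
truth is known, so every stage is testable without a download.

**Terrain.** A sum of 2-D Gaussian mountain bumps on a gently sloping
plane, affinely rescaled to span 522–4206 m (the elevational gradient of
the emulated region) on a 64×64 local metric grid with 800 m cells. The
grid is deliberately not georeferenced: the science here needs elevation
structure, not projection handling; latitude enters only as a scalar
(default 44.5° N) for day length.

**Climate.** Monthly mean temperature is a sinusoidal seasonal cycle
(sea-level mean 16 °C, amplitude 11 °C, peak in July) plus an elevation
lapse and spatial heterogeneity fields; tmax/tmin are tmean ± a 6 °C
diurnal half-range; dewpoint is tmean minus a spatially varying
depression (mean 5 °C); precipitation combines a 40 mm/month base, an
orographic increase of 0.015 mm per metre of elevation, a May-peaked
seasonal shape, and multiplicative spatial patterns. Interannual
variability is a spatially constant per-year anomaly (additive
N(0, 0.6 °C) for temperature, multiplicative CV 0.12 for
precipitation) — a regional anomaly is all that survives 30-year
averaging, which is how the covariates are consumed.

Two structural choices deserve emphasis because the analysis would be
degenerate without them:

* *Winter inversions.* The lapse rate weakens in winter
  (`winter_lapse_factor` 0.4 of the −6.5 °C/km summer value, interpolated
  sinusoidally through the year) and winter temperature anomalies are
  larger than summer ones (cold-air pooling; sd 3.75 °C vs 1.5 °C). This
  is what decorrelates January minima from July maxima in real mountain
  climates; without it every temperature covariate is the same affine
  function of elevation and no selection or importance analysis can
  distinguish them.
* *Elevation-orthogonal anomaly fields.* All heterogeneity fields (winter
  and summer temperature offsets, winter and summer precipitation
  patterns, dewpoint depression) are smooth random surfaces explicitly
  residualized against the DEM and normalized to unit sd, so the lapse
  component and the anomaly component of every covariate are separately
  controlled and the realized covariate correlation structure is stable
  across seeds rather than at the mercy of chance field–terrain
  alignment.

**Soils.** Available water capacity declines linearly from 220 mm at the
valley floor to 40 mm on the peaks (thin alpine soils) with ±5%
multiplicative texture noise.

**Virtual species.** Presence probability is
`logistic(β₀ + β_t · z(tmax7) + β_p · z(log1p(pack4)))` with β₀ = −1,
β_t = −3.5, β_p = +3.0, where `tmax7` is the July maximum-temperature
normal and `pack4` the April snow-water-equivalent normal, standardized
over the domain. The log on snowpack makes the response saturating — an
adequate pack is as good as a deep one — and keeps the handful of
never-melting summit cells (where the monthly model accumulates
perennial ice) from dominating the scale; tree ensembles are invariant
to monotone covariate transforms, so recovery tests are unaffected.
These coefficients give a survey prevalence of ~0.30–0.36 (the emulated
study reports 938 presences in 2,571 plots, 0.36) and an out-of-bag AUC
near 0.95, i.e. the strong but imperfect separation the original
analysis reports. Surveys sample 2,500 random cells with within-cell
jitter; recorded elevation carries N(0, 25 m) noise plus a 2% rate of
gross errors (350–900 m) to exercise the elevation cull; presences draw
DBH so that 85% are adults (≥ 20 cm); 10% of adult presences are
falsified into primary-source absences with a collocated second-source
presence added in the same pixel, so the false-absence correction has a
measurable effect.

**Pseudo-GCM ensemble.** Each member starts from the historical monthly
climatology and adds a member-specific linear warming trend drawn around
the scenario mean (0.30 °C/decade, sd 0.08 for the moderate scenario;
0.55 °C/decade, sd 0.10 for the strong one — bracketing the down-scaled
CMIP5 spread for the region), an additive monthly precipitation drift
(0.5 mm/decade, member sd 1.0), and spatially constant AR(1) interannual
noise (ρ = 0.5). Trends are anchored at 2010 and run to 2099. The
ensemble reproduces the structure that matters for the variability
analysis — divergent member magnitudes around a common direction — not
the spatial covariance of real down-scaled archives.

## Water balance

A monthly Thornthwaite-type model with two stores per cell, snowpack and
a soil bucket of capacity AWC. Per month: precipitation splits into rain
and snow by a linear ramp in monthly mean temperature (all snow at or
below −2 °C, all rain at or above +4 °C); snowfall joins the pack and a
degree-month melt (40 mm per °C-month above 0 °C) draws it down; rain
plus melt meets the Thornthwaite PET demand in a Thornthwaite–Mather
bucket — surplus recharge above AWC leaves as runoff/seepage, and in
deficit months the soil dries along `soil · exp(−deficit/AWC)`. PET uses
the classical heat-index form (zero for freezing months) with a
solar-declination day-length correction and true month lengths. VPD is
the Tetens saturation curve evaluated at air and dewpoint temperature.
All four process parameterizations are configurable; the defaults are
the standard textbook formulation of this model family.

State is initialized with full soil and no snow, and the first year is
run once more than reported (spin-up, discarded). Mass closure
(`ppt = Δswe + Δsoil + aet + surplus`) holds to machine precision
(~1e-11 mm observed; 1e-6 mm asserted) at every cell-month, and is
enforced as a property test on random forcing, not just on the
generator's climate.

Monthly normals of water-balance outputs are computed by averaging the
per-year monthly outputs over the window (not by running the model on
averaged climate); a config switch (`normals_on_per_year_runs`) selects
the alternative. The difference matters because melt and drying are
nonlinear in temperature.

A note on high summits: cells whose warmest month stays below 0 °C
accumulate SWE without bound (the model has no glacier dynamics). This
is confined to the top ~1% of cells, far above the species boundary, and
is neutralized in the species definition by the saturating snowpack
response.

## Occurrence assembly

Three quality filters, in order: (1) presences count only with
DBH ≥ 20 cm (adults; sub-adults are hard to distinguish from congeners
in the emulated surveys, and the envelope should reflect established
individuals); absences are unaffected. (2) Records whose field-recorded
elevation differs from the DEM at their pixel by strictly more than
300 m are dropped (guard against coordinate error; the boundary value
300 m is kept). (3) All records in one predictor pixel collapse to a
single sample, presence overriding absence — the false-absence
correction — using half-open cell membership with row 0 at the north
edge, the same rule the plot sampler uses, so pixel assignment is
bit-stable across modules.

## Covariates and selection

Covariates are 30-year monthly normals named `<var><month>` (`tmax7`,
`pack4`, …) over the 1950–1980 fitting window. The candidate list is the
eight physiologically motivated variable-months of the emulated study
(tmin1, vpd3, ppt4, pack4, tmax7, aet7, pet8, ppt9), which is also the
default precedence order. Selection is two-pass: PCA on the correlation
matrix retains components to 95% cumulative variance and keeps the
variable with the largest absolute loading per retained component
(first-pass proxies); then a greedy filter in precedence order keeps a
variable iff its absolute Pearson correlation with everything already
kept is ≤ 0.75. Both thresholds are configurable. The proxy rule's
choice among near-equivalent loaders of one correlated block is
intrinsically data-sensitive; where a test needs a stable candidate set
(envelope recovery), it uses the correlation filter over all eight
candidates, which is the `variance_target = 1.0` configuration.

## Envelope model and diagnostics

The classifier is a random forest built as an explicit bagging loop over
scikit-learn decision trees: each tree fits an n-out-of-n bootstrap with
a random covariate subset per split (default ⌈√p⌉), grown to pure leaves
(`min_node_size` 1), 1000 trees by default, no class weighting. Bagging
is implemented in-package (rather than using the library forest) because
the diagnostics are defined on per-tree bootstrap membership: the OOB
probability of a sample is the presence-vote fraction among trees whose
bootstrap excluded it, and permutation importance permutes one covariate
and re-evaluates each tree only on its out-of-bag rows, reporting the
mean drop in OOB accuracy at the majority threshold. The library forest
is retained as an independent cross-check in the test suite.

Threshold selection: TPR and TNR curves are evaluated on the midpoints
of sorted unique OOB scores (padded beyond the extremes so the TPR−TNR
difference always brackets zero) and the operating point where
sensitivity equals specificity is found by linear interpolation, ties
resolving to the smallest threshold; the interpolated rates agree to
1e-6 by construction. Cohen's kappa and TSS (= TPR + TNR − 1) are
reported along the same grid, and AUC is the Mann–Whitney rank
statistic (ties counted one half).

The published out-of-bag confusion table of the emulated study
(763/169/176/1437) is used as a fixed arithmetic anchor: row
normalization reproduces its printed 81.9% / 89.1% / 10.9% cells
exactly, and its kappa is 0.708. (The table's fourth printed percentage
is inconsistent with its own counts; the counts are treated as
authoritative.)

## Projection and ensemble statistics

For each scenario, member, and target year (decadal 2010–2090 plus
2099), covariate normals are computed over the trailing 30-year window
ending at the target year — 2010 means 1981–2010 — with the historical
cube spliced in front of the future cube where the window predates it.
The water balance runs once per member over the full spliced record so
store state carries across the splice. The fitted ensemble votes a
probability surface; cells at or above the selected threshold are
suitable; area is cell count × 0.64 km²; percent-of-reference uses the
historical-window 2010 surface (never an ensemble member) as
denominator; elevation statistics are the mean and interpolated
2.5/97.5 percentiles of the DEM over suitable cells.

Ensemble statistics (mean and n−1 standard deviation of percent
reference area per scenario-year) are computed across members *after*
each member is projected. Member climates are never averaged before
projection — averaging first would launder interannual variability
through the classifier's nonlinearity — and a test pins the summary to
the by-hand statistics of the per-member rows.

## Patch dynamics

Suitable-habitat patches are 8-connected components (diagonals adjacent,
non-wrapping edges), labeled via `scipy.ndimage` with an explicit
renumbering to row-major first-seen order, and verified against a
hand-written flood fill on random rasters up to 64×64. Summaries are
patch count and median patch area (linear-interpolated median); no
minimum patch size is imposed by default (`min_patch_cells` 1). On the
64×64 toy domain the median is dominated by single-cell fringe patches,
so its trajectory is noisier than the real landscape's; the
fragmentation signature itself (count rises while median falls as a
large patch splits, then count falls as fragments are lost) is asserted
on constructed sequences where it is unambiguous.

## Problem sizes and numerical choices

The shipped analysis and the acceptance script use the 64×64 domain, 61
historical years, 2,500 plots, 9 members × 2 scenarios, decadal windows
to 2099, 300 trees, and 3–5 permutation repeats; the full run takes
about a minute on one core. Model defaults remain 1000 trees. Floating
point: closure is asserted at 1e-6 mm (observed ~1e-11); threshold
equalization at 1e-6; raster I/O (plain-text ESRI ASCII grids, the
package's only on-disk raster format) writes 17 significant digits so
float64 values round-trip bit-exactly. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; every
generator and the fit are pure functions of (inputs, seed).

## Limitations

The synthetic system has no spatial covariance in its interannual
anomalies, no real down-scaling artifacts, no survey design bias beyond
the injected false absences, and no glacier dynamics; the species is in
exact equilibrium with two covariates by construction. Passing tests
therefore demonstrate that the *method* recovers a known envelope and
propagates a known warming signal correctly — not that the emulated
study's specific habitat numbers are right, which would require its
proprietary inputs. Dispersal, disturbance, competition, and demography
are outside the bioclimatic approach altogether.
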