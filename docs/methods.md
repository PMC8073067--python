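# Methods

`satgai` implements a two-platform pipeline for monitoring the green area
index (GAI, m² of green plant area per m² of ground) of winter wheat and for
relating the canopy's seasonal radiation uptake to grain yield.  A
centimetre-resolution UAV sensor provides the reference; a 10 m satellite
sensor with a 20 m red-edge band is the system under assessment.  Because
real multispectral surveys of this kind are rarely redistributable, the
package ships a seeded synthetic-study generator that reproduces the
statistical structure of such a trial, so every stage is testable end to
end.

## Grid model and aggregation

All analysis happens on a lattice of square cells (10 m or 20 m) snapped to
integer multiples of the cell size in a planar metric CRS, mirroring the
satellite's pixel grid.  Cells are half-open boxes; a raster pixel belongs
to the cell containing its centre, which partitions the pixels exactly.  A
cell's value is the arithmetic mean of its non-NoData pixels; cells whose
valid-pixel area fraction falls below `min_coverage` (default 0.5) are
invalid, and arbitrary cells can be excluded explicitly by mask (field
margins, shadows, weeds).  Coarsening a layer averages valid children;
refining broadcasts the parent value.  No reprojection is supported: inputs
are assumed to share one projected CRS.

UAV and satellite acquisitions are treated as simultaneous when their dates
differ by at most five days (crop development over such a gap is
negligible).  Matching is one-to-one and greedy by increasing gap, with
ties broken toward the earlier UAV date.

## VI → GAI models

Seven empirical model families map band reflectance to GAI:

| family | form |
|---|---|
| simple ratio (NIR/Green, NIR/Red, NIR/RE) | GAI = a + b·SR |
| NDVI, EVI2, RENDVI | GAI = a·e^(b·VI) |
| VIQUO | GAI = a + b·NIR/Green + c·NIR/Red + d·NIR/RE |

The exponential family is canonically multiplicative (all published fitted
models of this family have that shape); an additive variant
`GAI = a + e^(b·VI)` is available behind `exponential_additive`.  Linear
forms are fitted by ordinary least squares; the exponential form by OLS on
log GAI (positive values only) refined with nonlinear least squares on the
original scale.  Negative predictions are clipped to zero **only** in the
crop-monitoring stage (`clip_negative`); calibration and evaluation use raw
predictions.

Two goodness measures are reported.  `standard` R² is 1 − SSres/SStot.  The
`as_printed` variant is Σ(yᵢ−ȳ)² / Σ(xᵢ−ȳ)² with yᵢ the predictions, xᵢ the
observations and ȳ the *prediction* mean — an unusual form that coincides
with the standard one exactly when the predictions come from an OLS fit
with intercept, but not in general.  Both are computed so results remain
comparable either way.

### Date-effect testing

Satellite scenes can carry per-acquisition artefacts (residual atmospheric
effects, geolocation error).  `date_effect_test` fits an additive model
(date-specific intercepts, common VI slope) and an interaction model
(date-specific slopes), reports the slope-heterogeneity F-test at α = 0.05,
Tukey-adjusted pairwise slope contrasts (studentized-range distribution on
the interaction-model covariance), and a compact-letter display produced by
the insert-and-absorb algorithm.  The implementation is plain linear
algebra; the test suite cross-checks it against an independent ANOVA
implementation.

## Crop monitoring: GAI courses and absorbed radiation

Per cell, dated GAI estimates are complemented with boundary points: 0.3
m²/m² on 1 February (or the first observed value if that is lower — winter
wheat canopies at the end of winter are small but not absent) and 0 m²/m²
at harvest.  GAI is interpolated linearly in calendar days.  Thermal time
(base 0 °C) is computed and exported but the interpolation axis is calendar
days.

Hourly weather is aggregated to daily mean temperature and daily incoming
photosynthetically active radiation (PAR, MJ m⁻²).  Daily PAR is weighted
by a trapezoidal temperature response — 0 at or below 2.5 °C, rising
linearly to 1 at 9.5 °C, flat to 20 °C, falling to 0 at 35 °C — applied to
the **daily mean** temperature; an hourly-weighting mode is deliberately
out of scope.  Daily absorbed radiation follows Lambert–Beer with
extinction coefficient k = 0.7,

    absorbed = weighted_PAR · (1 − e^(−k·GAI)),

cumulated in daily steps until harvest.  k and the trapezoid transitions
are configurable; the defaults above are the standard winter-wheat values.

## Yield maps

Plot-trial yields are known per plot.  Cell yields are the exact
area-weighted mixture of plot yields, with bare soil contributing zero;
fractions come from exact polygon clipping (shapely), not pixel counting,
so they are deterministic.  A fine-rasterisation oracle (0.1 m pixel
counting) exists only in the test suite.  Cells extending beyond the trial
boundary keep their value but are flagged invalid and excluded from
regressions by default.

## Scenario matrix

Scenarios cross three axes: temporal (all of a platform's acquisitions vs
only dates with a counterpart on the other platform within 5 days), spatial
(all bands on the 10 m grid; red edge at 20 m broadcast to 10 m; everything
at 20 m), and spectral (NIR/RE simple-ratio model vs the multi-ratio VIQUO
model).  The satellite has no native 10 m red edge, so its spatial options
are the latter two: the full crossing yields 12 UAV and 8 satellite
scenarios.  Each scenario predicts per-cell GAI (clipped at zero),
assembles courses, cumulates absorbed radiation to harvest and regresses
the cell yields on it, reporting slope, intercept and both R² variants.

## The synthetic study

The generator emulates a managed plot trial: rectangular plots (default
10 m × 6 m) separated by 2 m bare tramlines inside a 120 m × 80 m field;
per-plot phenology (logistic green-up anchored at 0.3 m²/m² on 1 February,
maximum GAI ~N(6, 0.9²), senescence linear to 0 at harvest on 25 July);
hourly weather from seasonal and diurnal sinusoids with noise; 12 irregular
UAV flights and 8 satellite passes (one satellite date has no UAV
counterpart within 5 days, so the temporal options differ).

Reflectance is generated by **inverting** the configured simple-ratio
closures — the red-edge reflectance of vegetated ground is held at 0.30 and
the NIR, green and red bands follow from the GAI-implied ratios; bare soil
gets fixed per-band reflectances whose NIR/RE ratio reads as GAI ≈ 0 —
rather than by a radiative-transfer model.  The object under test is the
monitoring pipeline, not canopy physics; this closure makes noise-free
recovery exact and every deviation attributable.  Satellite bands are
rendered at a 0.5 m sub-lattice and block-averaged into sensor pixels, so
mixed pixels mix reflectance (linearly), not GAI.

Satellite acquisitions carry three per-date artefacts on the NIR/RE simple
ratio: an additive shift δ_d ~ N(0, 0.08), a multiplicative rotation γ_d ~
N(1, 0.15²) (clipped to [0.5, 1.5]), and spatially varying scatter at the
20 m red-edge block scale (sd 0.08 SR units).  Together they reproduce the
structure seen when satellite GAI estimates are validated against a
high-resolution reference: single-date agreement anywhere between R² ≈ 0
and ≈ 0.7, systematic per-date slope changes, and a season-level agreement
far better than any single date.  Plot yields are linear in the plot's
cumulative absorbed PAR — computed with the pipeline's own course-assembly
rules on the UAV calendar, so that noise-free runs close exactly — with
α = −200 g/m², β = 1.15 g/MJ and Gaussian noise (σ = 25 g/m²), floored at
zero; defaults give plot yields of roughly 520–800 g/m², the range typical
of intensively managed winter wheat.

All randomness derives from `numpy` generators keyed on
(seed, stream, date, band), so outputs are identical across platforms and
independent of the order in which rasters are requested.

`SyntheticConfig.loop_closure()` is the special noise-free configuration
used for exactness checks: 20 m plots with no tramlines tiling the grid
exactly, all sensor noise, satellite artefacts and yield noise off.  Under
it the scenario regression must return R² = 1 and slope β to floating-point
accuracy; with bare strips present this exactness is unattainable in
principle, because cell yields mix plot yields linearly while reflectance
mixes through the nonlinear Lambert–Beer response.

### What the generator does not emulate

Clouds and atmospheric correction, geolocation error, soil-moisture
dynamics, row structure and view-angle effects, lodging, within-plot
heterogeneity, and any physiological yield determination beyond the linear
APAR response.  Passing tests therefore demonstrate the correctness and
statistical calibration of the *pipeline*, not the field-scale accuracy of
satellite GAI retrieval.

## Numerical choices

* Grid snapping uses a 1e−9 relative epsilon; pixel membership is exact
  half-open arithmetic (ceil/floor), so boundary pixels are never counted
  twice.
* The exponential fit excludes non-positive GAI from the log initialisation
  and falls back to the initial estimate if the nonlinear refinement fails
  to converge.
* Degenerate inputs raise: constant predictors, constant observations in
  R², empty observation lists, queries outside the course span, weather
  gaps beyond tolerance.
* Rendered reflectance is clipped to [1e−4, 1.4] (the raster contract
  tolerates slight super-unity values); strongly negative biased
  GAI-equivalents saturate the green/red closures at a GAI floor of 0.05
  while the NIR/RE ratio continues to carry the signal.
* Problem sizes in the test suite: the full-scale study is 120 m × 80 m
  (96 10-m cells, 81 plots) with a 0.08 m UAV pixel; unit tests use a
  40 m × 40 m trial with a 0.5 m UAV pixel, which preserves every code
  path at a fraction of the cost.

## Known limitations

* The pipeline assumes one projected metric CRS; no reprojection or
  geolocation-error correction.
* Yield regression is retrospective (radiation uptake is integrated to
  harvest); it is not a forecasting model.
* The `as_printed` R² can exceed 1 for badly biased predictions; it is
  reported for comparability, not recommended for model selection.
* Satellite artefact magnitudes are plausible defaults, not estimates
  fitted to any particular sensor.
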