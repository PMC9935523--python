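# Methods

This note documents the models, conventions and design choices behind
`soilrisk`, in the order of the assessment chain.

## Guideline screening

Screening compares each sample's concentration (mg/kg dry soil) to a
threshold from a named guideline set. Three sets are built in: the
Mongolian permissible values (MNS 5850:2019), and the Dutch Soil
Guidelines target and intervention values. Conventions:

- **Exceedance is strict** (ratio > 1): a concentration exactly at the
  threshold is compliant, matching the "permissible value" semantics.
  Boundary ties are measure-zero in continuous data, so the choice has no
  practical effect; it is fixed for determinism.
- **Missing data** — a metal without a measured concentration or without
  a threshold in the chosen set is reported as `not_evaluable` and
  excluded from counts, never silently dropped. Real surveys of this
  design measure As/Cr/Hg/Ni only in a subset of samples.
- Values below a detection limit are taken as reported; no substitution
  (e.g. DL/2) is applied by default because the reference workflow states
  none. A user can pre-process the table if a policy is needed.
- The registry is data-driven: custom sets merge over the immutable
  built-ins (`GuidelineSet.merged_with`), since standards are revised
  (the Mongolian standard itself was revised in 2019).

## Pollution indices

Per metal, PI = C/T against the permissible value. The integrated index
IPI_N = sqrt((PI_avg² + PI_max²)/2) weights the mean and the worst single
pollutant equally; it is homogeneous of degree 1 in the concentrations
and non-decreasing in each one, and satisfies
PI_max/√2 ≤ IPI_N ≤ PI_max.

Class closure: the printed scale fixes both ends ("≤ 0.7 safe", "≥ 3
heavy"); the interior boundaries are assigned left-closed
(precaution = (0.7, 1), slight = [1, 2), moderate = [2, 3)) so the
partition is total and disjoint.

The default metal set is {Cd, Cu, Pb, Zn} — the metals measured in every
sample of the reference design; any subset with thresholds is selectable.

Per-town aggregation reports **both** the mean of per-sample IPI_N and
the IPI_N of the town's mean concentrations, labelled separately. The
index is nonlinear, so the two differ in general (the mean of per-sample
values is the larger whenever single samples spike); conflating them
would make town summaries ambiguous.

## Exposure and risk model

Two pathways are modelled — incidental soil ingestion and dermal contact
— because they dominate soil exposure; inhalation is deliberately not
implemented. Doses:

    ADD_ing  = C_soil · IngR · EF · ED / (BW · AT) · 1e-6
    ADD_derm = C_soil · SA · AF · ABS · EF · ED / (BW · AT) · 1e-6

Built-in receptor parameters (overridable):

| parameter | unit | adult | child |
|---|---|---|---|
| IngR, soil ingestion rate | mg/day | 100 | 200 |
| EF, exposure frequency | days/yr | 350 | 350 |
| ED, exposure duration | yr | 24 | 6 |
| BW, body weight | kg | 65.0 | 15.9 |
| AT (non-carcinogenic) | days | 8760 | 2190 |
| SA, exposed skin area | cm² | 4350 | 1600 |
| AF, adherence factor | mg/cm² | 0.07 | 0.20 |

Averaging-time convention: AT_nc = ED × 365 per receptor; for
carcinogenic effects AT_ca = LT × 365 = 25 550 days (lifetime LT = 70
years) for both receptors. The body weights reflect Mongolian adult and
Chinese child reference values used in the source workflow rather than
the US defaults.

Toxicity values (mg/(kg·day) for RfD; (mg/(kg·day))⁻¹ for SF):
Cd (RfD_ing 1.00e-3, RfD_derm 1.00e-5, ABS 0.001, SF_ing 15),
Cu (4.00e-2, 1.20e-2, 0.001, —), Pb (3.50e-3, 5.25e-4, 0.001, 8.50e-3),
Zn (3.00e-1, 6.00e-2, 0.001, —).

- HQ = ADD(nc)/RfD per pathway; HI sums the two pathways per metal.
- **CR uses the ingestion pathway only** (CR = ADD_ing(ca) · SF_ing):
  only ingestion slope factors exist in the profile, and dermal slope
  factors are generally not published for these metals. Requesting CR for
  a metal without a slope factor raises an error rather than returning 0,
  so "no slope factor" can never be misread as "no risk".
- All quantities are **linear in C_soil**, so the average risk of a town
  equals the risk of its mean concentration — exactly, not approximately.
  `risk_table` therefore accepts either per-sample tables or
  pre-aggregated town means; the property is asserted in the test suite.
- Printed means of the reference survey carry three significant figures;
  recomputing the published risk grid from them reproduces every cell
  within 1% relative (observed maximum deviation 0.6%), the residual
  being the rounding of the means themselves. The last digits are not
  chased.

## Synthetic survey generator

The generator emulates the reference three-town design so that every
stage of the chain is testable without the (undeposited) field data.

- **Sampling network**: a triangular/hexagonal lattice anchored at the
  region centroid, pitch found by bisection so the clipped count equals
  the requested n exactly; surplus points nearest the boundary are
  dropped deterministically (ties by (y, x)). Town footprints default to
  rectangles of a few km², matching small-town scales, with 48/50/44
  samples (142 total).
- **Concentration model**: i.i.d. lognormal per metal. Given target
  arithmetic mean m and coefficient of variation cv (default 0.5),
  σ² = ln(1+cv²) and μ = ln m − σ²/2, so E[X] = m exactly. Lognormality
  is the standard model for right-skewed trace-metal data; the reference
  survey reports only town means and box distributions, so cv = 0.5 is a
  single realistic choice, configurable per metal.
- **Hotspots**: multiplicative enrichment with linear distance decay
  inside a radius (factor 1 at the rim, the configured maximum at the
  centre). Defaults mimic the narrative geography: town-centre clusters
  for Baganuur and Sharyn Gol, a ger-area cluster for Nalaikh, and an
  eastern mining-waste gradient for Sharyn Gol.
- **Mean-exact fixture** (`fixture_towns`): after simulation, each
  town × metal series is conditioned so its arithmetic mean equals the
  reference mean to floating precision and its guideline exceedances are
  exactly the documented ones — one Cu sample in Baganuur and three Pb
  samples in Sharyn Gol above the permissible values (the worst Pb also
  above the Dutch intervention value of 530 mg/kg). Mechanism: the
  injected exceedances replace the largest draws; all other values are
  scaled by a common factor and capped at 0.95 × threshold, the factor
  solved by bisection so the mean is exact. The cap is what makes the
  exceedance count a construction guarantee — an unconditioned lognormal
  draw would occasionally produce extra exceedances (e.g. ≈ 0.2% per
  sample for Cd at cv 0.5 in Baganuur).

**What the generator does not emulate**: spatially autocorrelated random
fields beyond the deterministic hotspots, measurement error, censoring at
detection limits, or the true per-sample distributions (only means are
matched). Tests passing on synthetic surveys therefore validate the
computational chain, not distributional claims about real soils.

## Spatial interpolation

The mapped variable defaults to per-sample IPI_N (compute-then-
interpolate, as pollution maps are usually presented); interpolating
concentrations first and computing indices on the rasters is equally
possible through the same API.

Ordinary kriging with a classical variogram (spherical, exponential or
gaussian) is used as the geostatistical interpolator. The empirical
semivariogram is binned into ≥ 8 lags up to half the maximum pair
distance and the model fitted by weighted least squares with pair-count
weights; if the fit does not converge, a moment fallback (nugget 0,
sill = sample variance, range = half max lag) is used with a warning.
Prediction solves the standard OK system with a Lagrange multiplier per
target point over the neighbours inside the search radius (default
500 m, max 32 nearest); the weights sum to 1 by construction and the
kriging variance is reported. With zero nugget OK interpolates exactly
at sample locations. IDW (power 2) is available as the deterministic
alternative; its predictions are convex combinations of neighbour
values. Cells with no sample inside the search radius are nodata,
mirroring the circular-neighbourhood convention of the reference maps.

Degenerate inputs: duplicate coordinates are averaged (logged); an
all-constant field short-circuits to a constant surface with a warning;
prediction at a sample location (distance < 1 nm) returns the sample
value directly, avoiding a singular system.

Rasters (default 10 m resolution) are written as ESRI ASCII grids — a
plain-text format every GIS reads — with the standard
ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value header.

## Between-town comparison

Per metal, each town's series is tested for normality with Shapiro–Wilk
at α = 0.01 (the gate of the reference workflow); one-way ANOVA is used
iff every town passes, Kruskal–Wallis otherwise. The gate is applied per
metal per town, never pooled; no post-hoc tests or multiplicity
correction across metals are applied (none are in the reference
workflow). The gated procedure's type-I error under a normal null stays
at the nominal level because the ANOVA branch is taken ≈ 97% of the time
and both branches are level-α tests; the suite verifies 5% ± 1% over
2,000 simulations.

## Problem sizes and determinism

The test suite and the acceptance script use the study-scale problem
sizes throughout: the 142-sample fixture, n = 10,000 for generator
calibration, n = 4,800 for mean-convergence checks, 1,000 random vectors
for algebraic properties and 2,000 simulations for the type-I error, all
driven by explicit integer seeds (no time-based entropy); reruns are
byte-identical. Report CSVs use scientific notation with three
significant figures for risk quantities, matching how such tables are
conventionally printed.

## Known limitations

- The proprietary interpolation of the reference maps (ESRI Empirical
  Bayesian Kriging with a thin-plate-spline semivariogram and smoothing
  factor) has no published closed form; ordinary kriging preserves the
  scientific contract (exact interpolation, uncertainty surface) but not
  cell-level agreement with those maps.
- Risk estimates are deterministic point estimates; probabilistic
  (Monte-Carlo) exposure uncertainty, dermal slope factors and
  bioaccessibility adjustment are out of scope.
- Background-value-based indices (I_geo, enrichment factors, PI against
  local backgrounds) are not implemented; all indices here are
  standard-referenced.
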