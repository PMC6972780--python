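# Methods

This note documents the models, conventions and design choices behind
`moosehab`: a pipeline that relates regional moose density from winter
track counts (WTC) to satellite-derived vegetation-productivity summaries
(Dynamic Habitat Indices), climate, terrain and human-influence covariates,
and that ships with a synthetic-scenario generator so every stage can be
verified against known ground truth.

## Dynamic Habitat Indices

Input is a stack of periodic FPAR observations (fraction of absorbed
photosynthetically active radiation, 0–1), 46 eight-day periods per year
over 12 years by default. Values missing because of winter darkness or
snow are NaN.

1. **Composite series.** For each within-year period, the composite value
   is the median over all years. When the target period (default 16 days)
   is a multiple of the native one, consecutive periods are pooled with
   the years before taking the median, i.e. the 16-day composite of
   periods {2p, 2p+1} is the median over `2 × n_years` values. A
   cell-period missing in every year stays missing.
2. **Cumulative DHI** is the sum of available composite values (total
   annual productivity, unitless sum of fractions). Missing periods are
   omitted without rescaling; rescaling by `n_periods/n_available` is a
   defensible alternative but changes the index's meaning in the darkness
   zone, so the gap-omitted sum is the default and only behaviour.
3. **Minimum DHI** is the lowest available composite value. With
   `darkness_fill` (default on), any pixel missing a *winter* period —
   winter being the first and last eighth of the year's periods, the
   insolation minimum for a mid-year growing peak — is set to 0: a gap
   caused by polar darkness or snow means the productivity floor is zero.
4. **Variation DHI** is the coefficient of variation, sample standard
   deviation (n−1 denominator) over available periods divided by the
   mean. Pixels with non-positive mean or fewer than two available
   periods are undefined (NaN). The CV is scale-free, so pixels identical
   up to a factor share it exactly.

Because `min ≤ mean` always, `minimum ≤ cumulative / n_periods` wherever
no values are missing; this and year-order invariance are asserted by
property tests, and a nested-loop recomputation on small random stacks is
the exactness oracle.

## Stable land cover and suitable habitat

A pixel's cover is *stable* when one class is observed in strictly more
than half of the years (all years count in the denominator, nodata years
included); strict majority makes ties impossible by construction, and
pixels without a strict majority are excluded. Suitable habitat is a
stable class in {1, 2, 3, 4, 5, 7, 8, 11} — the evergreen/deciduous/mixed
forest classes, open shrubland, woody savanna and permanent wetland —
intersected with the species range mask. Habitat area per region is the
true-cell count times the cell area (1 km² on the synthetic equal-area
grid). A majority-rule block resampler is provided for mismatched input
resolutions (e.g. 500 m cover on a 1 km grid).

## Densities from winter track counts

Counts are one total per region per year. Missing cells are filled by
linear interpolation over years within a region; boundary gaps take the
nearest observed value (a series cannot be extrapolated, and the filled
value is exact whenever the underlying series is locally linear). Each
region needs at least two observed years.

Density is count divided by suitable-habitat area; period densities are
the *mean of yearly densities* (not pooled counts over pooled area-years),
and the regression response is the natural log. Decades are the three
contiguous ten-year blocks 1981–1990, 1991–2000, 2001–2010. Zero-density
regions would be excluded from log-space modelling with a warning rather
than offset-adjusted; none arise under the default scenario.

Survey-quality diagnostics: the coefficient of variation of density among
regions per year, summarised per decade by the median of the annual CVs.
The peak-to-trough decline of the national total (maximum, then minimum
after the peak) recovers the reported 42% national collapse (900,000
animals in 1991 down to 520,000 in 2002).

## Zonal covariates

Raster covariates — the three DHI bands, BIO1–BIO19 bioclimatic variables,
elevation and the human footprint index — are averaged over *suitable
habitat* within each region; road density is road length over whole-region
area (km/km²), following the respective definitions. Assembly inner-joins
all sources on region id and fails loudly, naming any region absent from
any source: a silently dropped region would bias every later fit. Rural
population exists only for the second and third decades and is attached
to those decade tables only.

## Model selection

* **Screening.** Pearson correlations among all candidates are reported;
  the bioclimatic variables are clustered by average linkage on distance
  1 − ρ²_Spearman and the tree is cut at similarity ρ² ≥ 0.5 (the
  threshold is a configuration knob; the value is a conventional "half
  the rank variance shared" default). Within each multi-member cluster
  only the first variable in candidate order is retained (BIO1 before
  BIO4, etc.), a deterministic stand-in for expert nomination.
* **Best subsets.** All predictor subsets up to `max_model_size`
  (default 4) are enumerated and ranked by BIC with the convention
  `BIC = n·ln(RSS/n) + (p+1)·ln(n)` (intercept counted, error variance
  not). Absolute BIC therefore carries an arbitrary additive constant;
  only ΔBIC between models on the same data is meaningful, and all
  reported comparisons use ΔBIC. Below RSS = 1e−20 a model interpolates
  the data to numerical precision, its BIC is flagged −∞, and ranking
  falls back to parsimony: fewer predictors first, then lexicographic
  names. This makes the noiseless limit well-posed — with σ = 0 every
  superset of the true support fits exactly, and the parsimony tie-break
  returns exactly the generating support.
* **RMSE** uses the √(RSS/n) convention (a predictive-accuracy summary,
  not an unbiased σ̂).
* **VIF.** For the BIC-best model, VIF_j = 1/(1 − R²_j) from regressing
  predictor j on the others; predictors are dropped greedily (highest
  VIF first, ties resolved toward the later-listed predictor) until all
  VIF < 10.
* **Diagnostics.** Training residuals of the final model are mapped per
  region and summarised by an empirical semivariogram γ(h) = mean of
  (zᵢ − zⱼ)²/2 per distance bin over region centroids, with Euclidean or
  great-circle (haversine, km) distance.

## Decade comparison

The parsimonious model is refit independently per decade. Equality of a
pair of decades is tested by the extra-sum-of-squares F test on the pooled
pair: reduced = one regression for both decades, full = decade indicator
plus indicator × predictor interactions,
`F = [(RSS_red − RSS_full)/Δdf] / [RSS_full/(n − p_full − 1)]`.
The default (`scope="joint"`) tests intercept and slopes together — one
P value per decade pair; `scope="slopes"` keeps separate intercepts in
the reduced model and tests slope equality alone. Both are always
reported. The test is exact under normal errors; its null rejection rate
at α = 0.05 is verified at the nominal level over 2000 simulated pairs.

## Synthetic scenario generator

The generator emulates the study's data at desk scale with known truth.
Defaults follow the real design wherever it is stated: 62 regions,
12 FPAR years × 46 eight-day periods, 10 land-cover years, 30 abundance
years (1981–2010), 0.3% missing abundance cells. The grid is 80 × 80 cells
of 1 km² — large enough that every region (~100 cells) supports stable
zonal means, small enough that a full scenario generates in well under a
second; study-scale rasters are out of scope.

* **Regions**: Voronoi cells of a jittered rectangular lattice —
  contiguous, oblast-like regions of similar but varying size. Centroids
  map linearly to a 30–100°E × 50–70°N box.
* **FPAR**: per-pixel sinusoid with mean and amplitude driven by a
  latitudinal gradient plus a smooth vegetation field, i.i.d. Gaussian
  noise (SD 0.03), clipped to [0, 1]. The northern quarter of rows loses
  all winter periods to darkness (NaN), reproducing the zero-filled
  minimum-DHI zone.
* **Land cover**: classes occupy quantile bands of the vegetation field
  (patchy at the edges via pre-ranking jitter), with unsuitable classes
  interleaved mid-gradient so the vegetation extremes stay suitable and
  every region retains habitat; 8% of cells flip to a random class in any
  year, leaving a strict majority almost everywhere.
* **Climate**: temperature variables share the latitudinal gradient (and
  are therefore realistically inter-correlated, exercising the screening
  step); precipitation variables are independent smooth fields;
  human footprint increases southward. Units are plain °C / mm / index
  points (the ×10 integer convention of packaged climate files is a
  storage detail, not emulated).
* **Abundance**: per-region log baseline density is β₀ + Σβⱼzⱼ + ε with
  zⱼ the across-region z-scores of habitat-masked zonal means of the
  chosen covariates (default cumulative DHI and BIO1; β = (2.0, 0.5,
  −0.3), σ = 0.1), ε ~ N(0, σ²). A fixed national trajectory multiplier
  (growth to a 1991-style peak, collapse to ~2002, partial recovery),
  normalised to mean exactly 1, scales density by year, so the 30-year
  mean recovers the baseline and the peak-to-trough decline is ~42%.
  Counts are density × habitat area, deterministically rounded; a
  Poisson count model is available (`count_model="poisson"`) for
  mean–variance-linked count noise, but rounding is the default so that
  σ is the *single* noise dial — the noiseless limit σ = 0 then emits
  exact real-valued expected counts and supports exact identifiability
  checks (R²_adj = 1, exact support selection). Missing cells are drawn
  uniformly (exactly `round(fraction × cells)` of them, never leaving a
  region below two observed years).

What the generator does **not** emulate: sensor compositing artifacts and
quality flags; decade-specific dynamics beyond the shared national
multiplier (all decades share slopes and differ only in level, so decade
refits are deliberately homogeneous and the joint decade tests reject on
intercept alone); observation error in the counts themselves under the
default rounding model; real road networks (road length is tabulated).
Passing tests therefore demonstrate correctness of the *computational
pipeline* and calibration of its statistics under a known generative
model — not that the real survey data satisfy these assumptions.

## Problem sizes and numerical choices

Monte-Carlo checks use 200 scenario seeds for coefficient recovery
(±3 SE coverage ≥ 95%), 50 seeds for noiseless support selection, and
2000 simulated decade pairs for F-test calibration — sizes at which the
binomial error of each estimate is comfortably below the margin being
asserted, while the whole suite runs in a few minutes on one CPU. All
randomness flows from explicit integer seeds; identical configuration
gives bit-identical bundles and pipeline artifacts (the run manifest
records SHA-256 checksums of every table to make this checkable).
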