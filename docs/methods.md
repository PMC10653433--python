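# Methods

This note records the models the package implements, the choices made
where the design was genuinely open, and what the synthetic experiments
do and do not demonstrate.

## Grid model and I/O

All rasters live on an axis-aligned, north-up grid of square cells
(nominally 1 km). Cell ownership is half-open — a cell owns its left and
top edges — so point extraction is deterministic on boundaries. Stages
hard-fail on grid misalignment; nothing is resampled silently. Coarse
fields are brought to the analysis grid by nearest-neighbor resampling of
cell centers, which conserves the source value set. GeoTIFF files carry
the standard georeferencing tags plus a JSON description with the CRS
identifier (an opaque string: the package performs no reprojection),
units and categorical legends.

## Station preprocessing

The 8-h moving ozone average at hour *t* is the mean of hours *t−7…t*
provided at least 6 of those 8 are present, computed on a continuous
hourly index so windows may span midnight. A daily value is valid only if
strictly more than 75% of the day's 24 hourly slots are valid, i.e. at
least 19; 18/24 = 75% exactly does not qualify. Whether the daily
response is the mean of the 8-h series (default) or of raw hourly values
is a switch (`response="o3_8h" | "hourly"`): the 8-h reading smooths the
diel cycle but lets each day's value borrow up to 7 early-morning hours
from the previous day, which slightly attenuates day-to-day contrast;
recovery studies that need an exactly unbiased response use the raw
hourly reading.

## Concentration GLM

The retrieval model is a Gaussian-family GLM with a log link — the link
is dictated by the multiplicative structure of concentration data, and
the Gaussian family matches an additive measurement-noise model for a
continuous response; predictions `exp(x'β)` are positive by
construction. Fitting is IRLS with starting values from an OLS on
log(Y); rows with Y ≤ 0 are dropped (and counted) as degenerate under
the link. IRLS's convergence flag is unreliable when the fit is
numerically perfect (its deviance criterion oscillates at machine
precision), so a non-converged result is accepted only if a two-step
refit from the solution does not move the coefficients (relative 1e-8);
otherwise the fit errors out with diagnostics. Exactly collinear columns
are detected by incremental rank and dropped with a warning.

Variable selection is bidirectional stepwise on AIC starting from the
full model (each step takes the single add or drop that most reduces
AIC), followed by iterative removal of coefficients with p > 0.05,
refitting after each removal. Cross-validation partitions *records* (not
stations) into k = 10 seeded folds and repeats the entire selection per
training fold; R² is the squared Pearson correlation of pooled
out-of-fold predictions and RMSE is expressed as a percent of the
observed mean. Annual surfaces average the daily predictions over each
year's days, propagating missing covariates to nodata. The rise
indicator uses `≤`, so exact ties count as a rise.

## Change map and window metrics

Only 11 of the 25 possible from–to categories are retained: the five
identities and the six transitions among artificial, cultivated and
forest classes. Other transitions (any change involving grassland or
water) are treated as implausible artefacts: they become nodata rather
than errors, with a logged count, since a hard failure would make the
encoder unusable on real interpretation noise. Codes 1–5 are the
identities in class order A, C, F, G, W; codes 6–11 the transitions in
the order AC, AF, CA, CF, FA, FC.

The four per-pixel indices are computed over 3×3, 5×5 and 7×7 windows
sliding one pixel at a time, the value assigned to the central pixel:

* **HET** — number of distinct classes among valid window cells.
* **HOM** — number of valid cells sharing the center's class.
* **DMG** — `ln K − H`, with `H` the Shannon entropy of class
  proportions over valid cells. `K` is fixed globally at the number of
  categories present in the whole change map, so the dominance ceiling is
  identical for every pixel and values are comparable across the map; the
  per-window class count would make the index jump discontinuously with
  local richness. Clamped at 0 against floating-point undershoot.
* **CON** — `2 ln N − ent`, where `N` is the number of classes present in
  the window and `ent` the entropy of the rook-adjacency distribution,
  adjacencies counted in both orders and only between cell pairs fully
  inside the window. A single-class window yields 0 by literal
  application of the formula (the classical convention would call such a
  window maximally aggregated; the literal form is kept and documented).

Border pixels whose full window falls outside the raster are nodata
rather than computed on shrunken windows, avoiding scale mixing; nodata
cells inside a window are dropped from both the proportion and adjacency
tallies. The implementation is vectorised (per-class integral sums and
per-pair edge sums); tests compare every interior pixel against a naive
per-window recomputation.

## Sampling, screening and the logistic trend model

Training size follows the Cochran formula `N = ceil(Z²p(100−p)/E²)` with
percent-scale p and E (369 at p = 60, E = 5, Z = 1.96); the test set is a
fixed 300 drawn by the same principle, disjoint from training.
Stratified allocation is proportional to category share with
largest-remainder rounding, at least one pixel per present category, and
simple random sampling without replacement within categories. Only
pixels with complete metrics at all three window sizes are eligible, so
every sample has every candidate feature.

The Pearson screen correlates each index with the concentration trend
(annual mean difference between the two years) and stars significance at
p < 0.01 / 0.05 / 0.1.

The logistic model enters the change category as dummy indicators
against the most frequent category. Forward stepwise selection starts
from the intercept-only model; at each step every absent candidate is
refit, its deviance drop (−2 log-likelihood ratio, with 0·ln(0/0) ≡ 0)
recorded in a ledger, and the largest drop that passes a chi-square test
at α = 0.05 enters. The CLA dummy block moves atomically with
df = (number of categories − 1); a scalar-coded alternative
(`cla_encoding="scalar"`, df = 1) is provided for comparability with
ledgers that treat the category as one column. Fitting is binomial IRLS:
quasi-separated dummy levels (a rare category observed with one label
only) inflate their own coefficient but leave the deviance well-defined,
which is all the chi-square ledger needs; a fully separated fit (zero
deviance) raises an error naming the worst offender. PCP thresholds
predictions at 0.5 with ties classified as a rise, mirroring the rise
indicator's tie rule; AUC uses the Mann–Whitney rank form with midrank
tie correction.

## The synthetic study area

The generator is a pure function of its configuration (seed included)
and emulates, at desk scale, the statistical structure the analysis
assumes:

* **Land cover.** A Gaussian-smoothed noise field is
  quantile-thresholded into five classes (defaults: A 34%, C 8%, F 38%,
  G 8%, W 12%, smoothing 2.5 px). Change (default 15% of cells) is drawn
  patchily via a second smooth field, split across source classes
  (F 55%, A 35%, C 10%) and routed only along the six whitelisted
  transitions, making forest→artificial the most frequent — the
  urbanisation signature.
* **Covariates.** Ten reanalysis-style variables are standardized
  anomaly fields generated on a 6× coarser grid and passed through the
  package's own nearest-neighbor resampler, reproducing the blocky
  support of coarse products; LST is generated at the fine scale
  (28 ± 3 °C); LON/LAT/DNS are deterministic. Days are independent.
* **Stations.** Hourly concentration = `exp(x'β)` × a sinusoidal diel
  factor peaking at 15:00 with daily mean exactly 1, plus Gaussian noise
  (default sd 8 µg/m³), truncated at zero, with 8% of hours deleted at
  random so the validity rules genuinely bite. The true β puts modest
  loads (|β| 0.03–0.12) on the ten coarse variables and 0.045/°C on LST;
  LON/LAT/DNS are carried as pure-noise candidates.
* **Landscape-driven trend.** A latent score is built from the true
  logistic weights on the standardized "changed" indicator and the
  window-7 indices, re-standardized, and scaled by `signal_gain` (the sd
  of the latent logit; default 8, so the Bayes accuracy of the labels is
  ≈ 0.92). Labels are Bernoulli draws; the second year's LST is raised
  (lowered) by `lst_rise_amp` (default 6 °C) where the label says rise
  (no rise), so the concentration chain genuinely produces the labelled
  trend: the LST effect (≈ 0.27 on the log scale) dominates the
  inter-year covariate noise (sd ≈ 0.11 with 12 days per year), keeping
  accidental flips below ~1%. `signal_gain = 0` (the null preset) breaks
  the landscape–trend link entirely. The truth record persists β, the
  logistic weights, the latent labels and the realized rise of the true
  annual surfaces.
* **Scale defaults.** 72×72 cells, 15 stations, 12 days per analysis
  year (a season sample standing in for full years), 10 Voronoi
  districts. These sizes keep a full pipeline run at a few seconds while
  leaving ~350 station-day rows for the GLM and ~4300 eligible pixels
  for sampling.

A separate generator, `gen_stepwise_study`, produces feature tables for
model-selection studies with known truth: CLA (through a shared
"changed" effect), HET7, HOM7 and CON7 carry signal; DMG7 is a noisy
copy of CON7 (r = 0.8) with no signal of its own; and the window-3/5
columns are low-rank proxies of their window-7 counterparts (loadings
0.45/0.5 plus one shared fine-scale factor and a 0.05-sd idiosyncratic
term). The low-rank structure mirrors how nested windows of the same map
co-vary and is what makes "exactly the informative set" a recoverable
target: with α = 0.05 and nine residual-null candidates, forward
selection stops cleanly only ~85% of the time even in this favourable
design — an irreducible property of repeated chi-square testing, not of
the implementation.

## What the synthetic experiments show — and what they do not

Passing tests demonstrate that every formula is implemented as written
(against hand arithmetic and naive oracles), that the estimation chain
recovers known parameters at realistic noise, and that the end-to-end
pipeline turns a landscape-driven trend into a skilful probability map.
They do not demonstrate that real ozone trends are this predictable:
the generator's days are temporally independent, its covariates carry no
shared meteorological regimes, station placement is uniform, land-cover
interpretation error is absent, and the landscape→trend link is injected
through a single covariate (LST). Real-data performance (e.g. the
typical R² ≈ 0.5 and AUC ≈ 0.7 of station-sparse retrievals) will be far
below the synthetic ceiling, and the package makes no claim otherwise.

## Numerical conventions

Ties: rise indicator and classification threshold both resolve ties
upward (a rise). Cochran's N is rounded up after damping float error at
the ninth decimal. Largest-remainder ties go to the larger category,
then lower code. Deviance uses the convention 0·ln(0/0) ≡ 0 and reports
infinity when a hard 0/1 prediction contradicts its label. Sampling,
cross-validation folds and all generators are seeded; derived seeds stay
below 2³¹.
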