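# ozotrend

Per-pixel prediction of whether annual ground-level ozone concentrations
(GOCs) rose between two dates, from landscape pattern change.

Urbanising regions convert forest and cropland into artificial surfaces,
and the resulting landscape configuration measurably shapes where
ground-level ozone accumulates. `ozotrend` implements a two-stage hybrid
analysis for this question, aimed at air-quality and landscape-planning
researchers who have land-cover maps for two dates, hourly station ozone
records, and daily gridded covariates on a common ~1 km grid:

1. **Concentration retrieval (GLM).** Hourly station records are turned
   into valid daily values (8-h moving averages under the 6-of-8 rule,
   daily means only when strictly more than 75% of the 24 hourly slots are
   valid) and regressed on up to 14 gridded covariates with a
   log-link GLM, `η(E[Y]) = Xβ` with `η = log`. Variables are chosen by
   bidirectional AIC stepwise selection, then any coefficient with
   p > 0.05 is removed; 10-fold cross-validation reports R² and RMSE (as a
   percent of the observed mean). Daily surfaces `exp(x'β)` are averaged
   into annual means, and the rise indicator is
   `I(c) = 1` iff `AGOC_2015(c) ≤ AGOC_2020(c)`.
2. **Rise-probability model (LRM).** The two land-cover maps are encoded
   into an 11-category from–to change map (5 no-change classes A, C, F, G,
   W plus the six plausible transitions AC, AF, CA, CF, FA, FC). Four
   moving-window pattern indices — heterogeneity (HET), homogeneity (HOM),
   dominance (DMG = ln K − Shannon entropy) and contagion
   (CON = 2 ln N − adjacency entropy) — are computed at 3×3, 5×5 and 7×7
   windows. A Cochran-sized (`N = Z²p(100−p)/E²`), stratified, disjoint
   train/test sample is drawn; indices are screened by Pearson correlation
   against the concentration trend; and a logistic regression
   `P = 1/(1+e^(−ε−Σb_i V_i))` is built by forward deviance-stepwise
   selection with chi-square tests, every tested step recorded in a
   ledger. The model is scored by PCP (percent correctly predicted at the
   0.5 threshold) and rank-based AUC, then mapped into a per-pixel
   rise-probability surface with district means.

Because such data are rarely shareable, the package ships a first-class
synthetic generator (`ozotrend.synthgen`) that emulates the whole study —
patchy land-cover pairs with urbanisation-style change, coarse reanalysis
covariates passed through nearest-neighbor resampling, hourly station
series from a known log-linear model with a diel cycle, noise and
missingness, and a landscape-driven trend with persisted ground truth — so
every stage is testable end to end.

## Worked example

```python
from ozotrend import SynthConfig, run_pipeline

res = run_pipeline(SynthConfig(seed=7))
print("GLM variables :", res.glm.variables_)
print("CV            : R2 = %.3f, RMSE = %.2f%%" % (res.cv.r2, res.cv.rmse_pct))
print("LRM variables :", res.lrm.variables_)
print("Held-out      : PCP = %.2f%%, AUC = %.3f" % (res.report.pcp, res.report.auc))
```

prints

```
GLM variables : ['RH', 'BCTP', 'BCCMASS', 'OCSMASS', 'DUSMASS25', 'SO2SMASS',
                 'SO4SMASS', 'SSSMASS25', 'PGENTOT', 'QV2M', 'LST', 'LAT']
CV            : R2 = 0.978, RMSE = 4.34%
LRM variables : ['HOM7', 'DMG7', 'CON7', 'CLA', 'HET7']
Held-out      : PCP = 90.67%, AUC = 0.976
```

The retrieval stage kept the eleven covariates that truly drive the
synthetic concentrations (plus LAT) and predicts daily values within ~4%
of the observed mean; the trend stage recovered a model dominated by the
window-7 indices and the change category, classifying ~91% of held-out
sample pixels correctly. `res.surface` is the rise-probability raster,
`res.districts_mean` its per-district means, and `res.screen` the Pearson
screen (in this run HET7 correlates positively, DMG7 and CON7 negatively
with the concentration trend, all at p < 0.01 — the signature of
fragmented landscapes carrying a higher rise risk).

The same analysis is available from the shell, stage by stage:

```bash
ozotrend simulate --seed 7 --outdir run/   # synthetic study area (GeoTIFF/CSV)
ozotrend change   --seed 7 --outdir run/   # 11-category change map + areas
ozotrend metrics  --seed 7 --outdir run/   # HET/HOM/DMG/CON layers
ozotrend retrieve --seed 7 --outdir run/   # GLM, annual + rise surfaces
ozotrend trend    --seed 7 --outdir run/   # sampling, LRM, probability map
ozotrend report   --config cfg.yaml --seed 7 --outdir run/  # all in memory
```

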