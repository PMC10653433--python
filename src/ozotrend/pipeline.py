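"""End-to-end orchestration of the two-stage trend analysis.

Given a (synthetic or file-backed) study area, the pipeline:

1. aggregates hourly station ozone into valid daily values and fits the
   log-link GLM with AIC-stepwise selection, with 10-fold CV diagnostics;
2. predicts annual mean concentration surfaces for the two analysis years
   and derives the binary rise indicator and the concentration trend;
3. draws Cochran-sized, stratified, disjoint training and testing samples
   from the change map (restricted to pixels with complete 7x7 metric
   windows), screens the pattern indices against the trend, fits the
   deviance-stepwise logistic rise model, and evaluates PCP/AUC;
4. maps the fitted model into a per-pixel rise-probability surface with
   district means.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .changemap import area_proportions
from .geodata import CategoricalRaster, ContinuousRaster
from .ozone_glm import (
    CvReport,
    OzoneGLM,
    build_design,
    cross_validate,
    fit_glm,
    predict_annual,
    rise_indicator,
    station_daily,
)
from .risemodel import (
    EvalReport,
    RiseLogit,
    SampleSpec,
    build_feature_table,
    cochran_n,
    district_means,
    evaluate,
    pearson_screen,
    predict_surface,
    stepwise_deviance,
    stratified_sample,
)
from .synthgen import Scene, SynthConfig, generate_scene

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything a pipeline run produces, for reporting and testing."""

    scene: Scene
    design: pd.DataFrame
    glm: OzoneGLM
    cv: CvReport
    annual: dict
    rise: CategoricalRaster
    dgoc: ContinuousRaster
    train_features: pd.DataFrame
    test_features: pd.DataFrame
    screen: pd.DataFrame
    lrm: RiseLogit
    report: EvalReport
    surface: ContinuousRaster
    districts_mean: pd.DataFrame
    area_table: pd.DataFrame


def run_pipeline(
    cfg: SynthConfig,
    seed: int | None = None,
    glm_selection: str = "aic",
    response: str = "o3_8h",
    sample_spec: SampleSpec = SampleSpec(),
    n_test: int = 300,
    cv_folds: int = 10,
    alpha: float = 0.05,
) -> PipelineResult:
    """Run the full hybrid analysis on a synthetic study area.

    ``seed`` (if given) overrides the configuration seed; sampling and CV
    seeds are derived from it deterministically.  ``n_test`` follows the
    study design of a fixed-size test sample drawn by the same stratified
    principle, disjoint from training.
    """
    if seed is not None:
        cfg = replace(cfg, seed=int(seed))
    scene = generate_scene(cfg)
    base_seed = int(cfg.seed) % (2**31 - 1)

    # --- concentration retrieval stage
    daily = station_daily(scene.hourly, response=response)
    design = build_design(daily, scene.covariates, scene.stations)
    glm = fit_glm(design, selection=glm_selection)
    cv = cross_validate(design, k=cv_folds, seed=base_seed, selection=glm_selection)
    y1, y2 = min(cfg.years), max(cfg.years)
    annual = {y: predict_annual(glm, scene.covariates, y) for y in (y1, y2)}
    rise = rise_indicator(annual[y1], annual[y2])
    dgoc = ContinuousRaster(
        cfg.grid, annual[y2].values - annual[y1].values, units="ug/m3"
    )

    # --- landscape stage
    change = scene.change.raster
    eligible = rise.valid_mask.copy()
    for name in scene.metrics.names:
        eligible &= scene.metrics.layer(name).valid_mask
    n_train = cochran_n(sample_spec)
    train = stratified_sample(change, n_train, base_seed + 1, eligible_mask=eligible)
    taken = np.zeros(change.codes.shape, dtype=bool)
    taken[train["row"], train["col"]] = True
    test = stratified_sample(
        change, n_test, base_seed + 2, eligible_mask=eligible, exclude=taken
    )
    train_f = build_feature_table(train, scene.metrics, rise=rise, dgoc=dgoc)
    test_f = build_feature_table(test, scene.metrics, rise=rise, dgoc=dgoc)
    screen = pearson_screen(train_f)
    lrm = stepwise_deviance(train_f, alpha=alpha)
    report = evaluate(lrm, test_f)
    surface = predict_surface(lrm, scene.metrics, change)
    dmeans = district_means(surface, scene.districts)
    area = area_proportions(change, scene.districts)

    return PipelineResult(
        scene=scene,
        design=design,
        glm=glm,
        cv=cv,
        annual=annual,
        rise=rise,
        dgoc=dgoc,
        train_features=train_f,
        test_features=test_f,
        screen=screen,
        lrm=lrm,
        report=report,
        surface=surface,
        districts_mean=dmeans,
        area_table=area,
    )
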