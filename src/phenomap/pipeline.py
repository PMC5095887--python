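"""End-to-end plumbing: raster feature extraction and cross-year experiments.

This module strings the stages together in the order the method runs:
truncate to the season window, fit phenology per pixel, derive metrics,
anchor spectral metrics, assemble features; then train on the selected
training year's coverage truth, optionally adjust the mapping year's
phenological features into the training year's frame, predict coverage
and validate at county level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adjustment import adjust_feature_matrix, fit_adjustment
from .classification import predict_coverage, train_classifier
from .io_formats import FULL_WINDOW, SeasonWindow, truncate_to_window
from .phenology import derive_pheno_metrics, fit_double_sigmoid
from .progress import select_training_year, stage_dates_from_table
from .spectral import (EARLY_FEATURE_NAMES, FULL_FEATURE_NAMES, build_features,
                       spectral_metric_set)
from .synthetic import SimulatedScene, SimulationConfig, simulate_progress_table, simulate_scene
from .validation import ValidationReport, compare_counties, county_aggregate

__all__ = ["extract_scene_features", "CrossYearResult", "run_cross_year"]


def extract_pixel_features(series, window: SeasonWindow = FULL_WINDOW):
    """Feature vector for one pixel-year, or None when the pixel is unfit."""
    series = truncate_to_window(series, window)
    evi, valid = series.evi()
    curve = fit_double_sigmoid(series.dates, evi, window.mode, valid)
    if not curve.success:
        return None
    metrics = derive_pheno_metrics(curve, series.dates, evi, valid)
    spec = spectral_metric_set(series, metrics, window)
    return build_features(metrics, spec)


def extract_scene_features(scene: SimulatedScene,
                           window: SeasonWindow = FULL_WINDOW) -> np.ndarray:
    """Feature matrix ``(Hc*Wc, n_features)``; unfit pixels are NaN rows."""
    names = FULL_FEATURE_NAMES if window.mode == "full" else EARLY_FEATURE_NAMES
    hc, wc = scene.coverage.shape[1:]
    X = np.full((hc * wc, len(names)), np.nan)
    k = 0
    for i in range(hc):
        for j in range(wc):
            fv = extract_pixel_features(scene.pixel_series(i, j), window)
            if fv is not None:
                X[k] = fv.values
            k += 1
    return X


@dataclass
class CrossYearResult:
    mapping_year: int
    training_year: int
    strategy: str
    adjust: str
    report: ValidationReport
    coverage_pred: np.ndarray


def run_cross_year(
    config: SimulationConfig,
    mapping_year: int,
    strategy: str = "similar_progress",
    adjust: str = "A0",
    window: SeasonWindow = FULL_WINDOW,
    seed: int = 0,
    _feature_cache: dict | None = None,
    _scene_cache: dict | None = None,
) -> CrossYearResult:
    """Simulate, select a training year, train fuzzy models, map, validate.

    The two optional caches let callers that run several strategies on the
    same configuration reuse simulated scenes and extracted features.
    """
    scenes = _scene_cache if _scene_cache is not None else {}
    feats = _feature_cache if _feature_cache is not None else {}

    def scene(year):
        if year not in scenes:
            scenes[year] = simulate_scene(config, year)
        return scenes[year]

    def features(year):
        key = (year, window.mode)
        if key not in feats:
            feats[key] = extract_scene_features(scene(year), window)
        return feats[key]

    table = simulate_progress_table(config)
    all_years = sorted(config.year_shifts)
    stage_dates = {y: stage_dates_from_table(table, config.state, y)
                   for y in all_years}
    candidates = {y: sd for y, sd in stage_dates.items() if y != mapping_year}
    if strategy == "similar_progress":
        sel = select_training_year(mapping_year, candidates, strategy,
                                   stage_dates[mapping_year])
    else:
        sel = select_training_year(mapping_year, sorted(candidates), strategy)
    train_year = sel.selected

    names = FULL_FEATURE_NAMES if window.mode == "full" else EARLY_FEATURE_NAMES
    train_scene = scene(train_year)
    X_train = features(train_year)
    cov_train = train_scene.coverage.reshape(3, -1).T
    model = train_classifier(X_train, cov_train, mode="fuzzy",
                             feature_names=names, seed=seed,
                             state=config.state, year=train_year,
                             season=window.mode, adjustment=adjust,
                             strategy=strategy)

    map_scene = scene(mapping_year)
    X_map = features(mapping_year)
    if adjust != "A0":
        adj = fit_adjustment(stage_dates[mapping_year], stage_dates[train_year], adjust)
        X_map = adjust_feature_matrix(X_map, names, adj)
    cov_flat = predict_coverage(model, X_map)
    hc, wc = map_scene.coverage.shape[1:]
    cov_pred = cov_flat.reshape(3, hc, wc)

    mapped = county_aggregate(cov_pred, map_scene.zones, config.pixel_area_ha)
    reference = county_aggregate(map_scene.coverage, map_scene.zones,
                                 config.pixel_area_ha)
    report = compare_counties(mapped, reference)
    return CrossYearResult(mapping_year, train_year, strategy, adjust,
                           report, cov_pred)
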