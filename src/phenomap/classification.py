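"""Random-forest crop classification: hard labels and fuzzy coverage.

Models are trained state-by-state and year-by-year: a forest is fitted to
all usable pixels of one state in the training year and applied to the
mapping year of the same state.  Two pixel definitions are supported:

hard
    a single 3-class forest classifier trained on pure pixels;
fuzzy
    one regression forest per crop predicting the pixel's percent cover
    of that crop (sub-pixel fraction), trained on all pixels.

Defaults follow the protocol of k=100 trees with m=1 candidate variable
per node split.  Per-crop fuzzy predictions are clipped to [0, 100]; when
corn% + soybean% exceeds 100 the pair is rescaled proportionally and
other% takes the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .coverage import CLASS_CODES, UNLABELED

__all__ = ["TrainedModel", "train_classifier", "predict_coverage"]

DEFAULT_K = 100  # trees
DEFAULT_M = 1    # variables tried per node


@dataclass
class TrainedModel:
    """A fitted hard classifier or pair of fuzzy per-crop regressors."""

    mode: str                       # "hard" | "fuzzy"
    estimators: dict                # hard: {"hard": clf}; fuzzy: {"corn":…, "soybean":…}
    feature_names: tuple[str, ...]
    k: int = DEFAULT_K
    m: int = DEFAULT_M
    training_medians: np.ndarray | None = None
    meta: dict = field(default_factory=dict)   # state, year, season, adjustment…


def _clean_training(X: np.ndarray, y: np.ndarray):
    """Drop training rows with any missing feature."""
    keep = np.all(np.isfinite(X), axis=1)
    return X[keep], y[keep]


def train_classifier(
    X: np.ndarray,
    targets: np.ndarray,
    mode: str = "fuzzy",
    feature_names: tuple[str, ...] = (),
    k: int = DEFAULT_K,
    m: int = DEFAULT_M,
    seed: int | None = 0,
    **meta,
) -> TrainedModel:
    """Fit the forest(s).

    Parameters
    ----------
    X
        Feature matrix ``(n_pixels, n_features)``; rows with missing
        values are dropped from training.
    targets
        Hard mode: integer class codes per pixel (pure pixels only,
        ``UNLABELED`` rows are ignored).  Fuzzy mode: coverage array
        ``(3, n_pixels)`` or ``(n_pixels, 3)`` of (corn%, soybean%,
        other%) in [0, 100].
    """
    X = np.asarray(X, dtype=float)
    if feature_names and X.shape[1] != len(feature_names):
        raise ValueError("feature matrix width does not match feature names")
    medians = np.nanmedian(X, axis=0)

    if mode == "hard":
        y = np.asarray(targets)
        if y.shape[0] != X.shape[0]:
            raise ValueError("targets length must match feature rows")
        usable = y != UNLABELED
        Xc, yc = _clean_training(X[usable], y[usable])
        for cls, code in CLASS_CODES.items():
            if not np.any(yc == code):
                raise ValueError(f"no training samples for class {cls!r}")
        clf = RandomForestClassifier(n_estimators=k, max_features=m,
                                     random_state=seed, n_jobs=1)
        clf.fit(Xc, yc)
        ests = {"hard": clf}
    elif mode == "fuzzy":
        cov = np.asarray(targets, dtype=float)
        if cov.ndim != 2:
            raise ValueError("fuzzy targets must be a 2-D coverage array")
        if cov.shape[0] != X.shape[0]:
            cov = cov.T
        if cov.shape[0] != X.shape[0] or cov.shape[1] < 2:
            raise ValueError("coverage shape incompatible with features")
        if np.nanmin(cov) < 0 or np.nanmax(cov) > 100:
            raise ValueError("coverage targets must lie in [0, 100]")
        ests = {}
        for j, crop in enumerate(("corn", "soybean")):
            Xc, yc = _clean_training(X, cov[:, j])
            ok = np.isfinite(yc)
            if ok.sum() < 2:
                raise ValueError(f"too few training samples for class {crop!r}")
            reg = RandomForestRegressor(n_estimators=k, max_features=m,
                                        random_state=seed, n_jobs=1)
            reg.fit(Xc[ok], yc[ok])
            ests[crop] = reg
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return TrainedModel(mode=mode, estimators=ests,
                        feature_names=tuple(feature_names), k=k, m=m,
                        training_medians=medians, meta=meta)


def predict_coverage(model: TrainedModel, X: np.ndarray,
                     feature_names: tuple[str, ...] | None = None) -> np.ndarray:
    """Apply a trained model to a feature matrix.

    Pixels with every feature missing propagate as no-data (NaN rows /
    ``UNLABELED``); partially missing features are imputed with the
    training medians.

    Returns coverage ``(3, n_pixels)`` of (corn%, soybean%, other%) in
    fuzzy mode, or an integer class-code vector in hard mode.
    """
    X = np.asarray(X, dtype=float)
    if feature_names is not None and model.feature_names and \
            tuple(feature_names) != model.feature_names:
        raise ValueError("feature names do not match the trained model")
    n = X.shape[0]
    nodata = np.all(~np.isfinite(X), axis=1)
    Xi = X.copy()
    if model.training_medians is not None:
        bad = ~np.isfinite(Xi)
        Xi[bad] = np.broadcast_to(model.training_medians, Xi.shape)[bad]
    usable = ~nodata & np.all(np.isfinite(Xi), axis=1)

    if model.mode == "hard":
        out = np.full(n, UNLABELED, dtype=np.uint8)
        if usable.any():
            out[usable] = model.estimators["hard"].predict(Xi[usable])
        return out

    cov = np.full((3, n), np.nan)
    if usable.any():
        corn = np.clip(model.estimators["corn"].predict(Xi[usable]), 0.0, 100.0)
        soy = np.clip(model.estimators["soybean"].predict(Xi[usable]), 0.0, 100.0)
        total = corn + soy
        over = total > 100.0
        scale = np.where(over, 100.0 / np.where(over, total, 1.0), 1.0)
        corn, soy = corn * scale, soy * scale
        cov[0, usable] = corn
        cov[1, usable] = soy
        cov[2, usable] = 100.0 - corn - soy
    return cov
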