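"""Cross-year phenological adjustment of feature vectors.

Dates in the mapping year v are moved into the training year's frame t by
an affine map X_t = a + b * X_v whose coefficients come from the two
years' 50%-progress dates:

* A0 — no adjustment (a=0, b=1);
* A1 — ordinary least squares of training-year dates on mapping-year
  dates over the shared progress items;
* A2 — pure shift, b=1 and a = mean(X_t) - mean(X_v).

Date-type metrics (D_i, D_d, D_1..D_4, D_peak) transform as a + b*x;
date-difference (length) metrics L_id and L_14 are multiplied by b; growth
rates p and q are divided by b.  All other features, including every
spectral metric, are left untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .progress import StageDates
from .spectral import FeatureVector

__all__ = ["AdjustmentModel", "fit_adjustment", "apply_adjustment",
           "DATE_METRICS", "LENGTH_METRICS", "RATE_METRICS"]

DATE_METRICS = frozenset({"D_i", "D_d", "D_1", "D_2", "D_3", "D_4", "D_peak"})
LENGTH_METRICS = frozenset({"L_id", "L_14"})
RATE_METRICS = frozenset({"p", "q"})


@dataclass
class AdjustmentModel:
    kind: str  # A0 | A1 | A2
    a: float = 0.0
    b: float = 1.0
    stages: list[str] = field(default_factory=list)
    correlation: float = float("nan")

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "a": self.a, "b": self.b,
                           "stages": self.stages, "correlation": self.correlation})

    @classmethod
    def from_json(cls, s: str) -> "AdjustmentModel":
        return cls(**json.loads(s))


def fit_adjustment(map_dates: StageDates | None, train_dates: StageDates | None,
                   kind: str = "A0") -> AdjustmentModel:
    """Fit the mapping-year -> training-year date transform."""
    if kind == "A0":
        return AdjustmentModel("A0")
    if map_dates is None or train_dates is None:
        raise ValueError(f"{kind} requires stage dates for both years")
    shared = map_dates.shared_items(train_dates)
    xv = np.array([map_dates.dates[k] for k in shared])
    xt = np.array([train_dates.dates[k] for k in shared])
    if kind == "A2":
        if len(shared) < 1:
            raise ValueError("A2 needs at least one shared stage")
        return AdjustmentModel("A2", a=float(np.mean(xt) - np.mean(xv)), b=1.0,
                               stages=shared, correlation=float("nan"))
    if kind == "A1":
        if len(shared) < 2:
            raise ValueError("A1 needs at least two shared stages")
        b, a = np.polyfit(xv, xt, 1)
        if b <= 0:
            raise ValueError(f"degenerate A1 regression: slope {b:.4f} <= 0")
        with np.errstate(invalid="ignore"):
            r = float(np.corrcoef(xv, xt)[0, 1]) if len(shared) > 1 else float("nan")
        return AdjustmentModel("A1", a=float(a), b=float(b), stages=shared,
                               correlation=r)
    raise ValueError(f"unknown adjustment kind {kind!r}")


def apply_adjustment(features: FeatureVector, model: AdjustmentModel) -> FeatureVector:
    """Return a new feature vector with phenological metrics adjusted."""
    out = features.values.copy()
    for i, name in enumerate(features.names):
        if name in DATE_METRICS:
            out[i] = model.a + model.b * out[i]
        elif name in LENGTH_METRICS:
            out[i] = model.b * out[i]
        elif name in RATE_METRICS:
            out[i] = out[i] / model.b
        # spectral metrics and V_b/V_a are never adjusted
    return FeatureVector(mode=features.mode, values=out)


def adjust_feature_matrix(X: np.ndarray, names: tuple[str, ...],
                          model: AdjustmentModel) -> np.ndarray:
    """Vectorized :func:`apply_adjustment` over a (n_pixels, n_features) matrix."""
    X = X.copy()
    for i, name in enumerate(names):
        if name in DATE_METRICS:
            X[:, i] = model.a + model.b * X[:, i]
        elif name in LENGTH_METRICS:
            X[:, i] = model.b * X[:, i]
        elif name in RATE_METRICS:
            X[:, i] = X[:, i] / model.b
    return X
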