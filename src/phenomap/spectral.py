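"""Phenology-anchored spectral metrics and feature-vector assembly.

Seven spectral quantities — SWIR1 (band 6), SWIR2 (band 7), EVI,
NDTI = (b6-b7)/(b6+b7), VI64 = (b6-b4)/(b6+b4), DIF64 = b6-b4 and
DIF67 = b6-b7 — are each evaluated at two phenological anchors:

* ``avg`` — averaged over the high-growth period from D_i to D_d (or from
  D_i to the early-season window end when D_d is not yet observable);
* ``peak`` — interpolated to the date of maximum EVI, D_peak.

Reflectances are interpolated/averaged first and indices computed from the
interpolated reflectances, keeping a single consistent convention.

Together with the 13 (full-season) or 7 (early-season) phenological
metrics this yields feature vectors of exactly 27 or 21 named variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io_formats import EARLY_WINDOW, SeasonWindow
from .phenology import PhenoMetrics, ReflectanceSeries, compute_evi

__all__ = [
    "SPECTRAL_NAMES", "FULL_FEATURE_NAMES", "EARLY_FEATURE_NAMES",
    "FeatureVector", "interpolate_at", "average_between",
    "spectral_metric_set", "build_features",
]

SPECTRAL_NAMES = ("SWIR1", "SWIR2", "EVI", "NDTI", "VI64", "DIF64", "DIF67")

#: 0-based band columns used by the spectral metrics (red, NIR, blue for
#: EVI; green b4 and shortwave b6/b7 for the tillage/contrast indices)
_SPECTRAL_BANDS = [0, 1, 2, 3, 5, 6]

_SPECTRAL_SUFFIXED = tuple(f"{n}_{s}" for n in SPECTRAL_NAMES for s in ("avg", "peak"))
FULL_FEATURE_NAMES: tuple[str, ...] = PhenoMetrics.FULL_NAMES + _SPECTRAL_SUFFIXED
EARLY_FEATURE_NAMES: tuple[str, ...] = PhenoMetrics.EARLY_NAMES + _SPECTRAL_SUFFIXED

assert len(FULL_FEATURE_NAMES) == 27 and len(EARLY_FEATURE_NAMES) == 21


@dataclass
class FeatureVector:
    """Named classification inputs for one pixel."""

    mode: Literal["full", "early"]
    values: np.ndarray

    @property
    def names(self) -> tuple[str, ...]:
        return FULL_FEATURE_NAMES if self.mode == "full" else EARLY_FEATURE_NAMES

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def _valid_mask(series: ReflectanceSeries) -> np.ndarray:
    return series.valid_for(_SPECTRAL_BANDS)


def interpolate_at(series: ReflectanceSeries, target_doy: float) -> np.ndarray:
    """Per-band linear interpolation to ``target_doy`` between the nearest
    valid composites; NaN vector when the target lies outside the valid span."""
    ok = _valid_mask(series)
    t = series.dates[ok]
    out = np.full(series.bands.shape[1], np.nan)
    if len(t) == 0 or target_doy < t[0] or target_doy > t[-1]:
        return out
    for b in range(series.bands.shape[1]):
        out[b] = np.interp(target_doy, t, series.bands[ok, b])
    return out


def average_between(series: ReflectanceSeries, start: float, end: float) -> np.ndarray:
    """Per-band mean over valid composites with date in [start, end];
    NaN vector when the range holds no valid composite."""
    if not start < end:
        raise ValueError("start must precede end")
    ok = _valid_mask(series) & (series.dates >= start) & (series.dates <= end)
    if not ok.any():
        return np.full(series.bands.shape[1], np.nan)
    return series.bands[ok].mean(axis=0)


def _indices_from_bands(b: np.ndarray) -> dict[str, float]:
    red, nir, blue, green, swir1, swir2 = b[0], b[1], b[2], b[3], b[5], b[6]
    evi, _ = compute_evi(red, nir, blue)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndti = (swir1 - swir2) / (swir1 + swir2)
        vi64 = (swir1 - green) / (swir1 + green)
    return {
        "SWIR1": float(swir1), "SWIR2": float(swir2), "EVI": float(evi),
        "NDTI": float(ndti), "VI64": float(vi64),
        "DIF64": float(swir1 - green), "DIF67": float(swir1 - swir2),
    }


def spectral_metric_set(
    series: ReflectanceSeries,
    metrics: PhenoMetrics,
    window: SeasonWindow | None = None,
) -> dict[str, float]:
    """The 7 spectral metrics at both anchors (14 ``name_{avg,peak}`` values).

    ``avg`` averages reflectance over [D_i, D_d]; in early mode D_d is not
    available and the period runs from D_i to the window end DOY.
    Unobtainable anchors yield NaN entries (missing flags).
    """
    d_i = metrics.values["D_i"]
    if metrics.mode == "full":
        end = metrics.values["D_d"]
    else:
        end = float((window or EARLY_WINDOW).end_doy)
    out: dict[str, float] = {}
    if np.isfinite(d_i) and d_i < end:
        avg = _indices_from_bands(average_between(series, d_i, end))
    else:
        avg = {n: np.nan for n in SPECTRAL_NAMES}
    peak = _indices_from_bands(interpolate_at(series, metrics.values["D_peak"]))
    for n in SPECTRAL_NAMES:
        out[f"{n}_avg"] = avg[n]
        out[f"{n}_peak"] = peak[n]
    return out


def build_features(metrics: PhenoMetrics, spectral: dict[str, float],
                   mode: Literal["full", "early"] | None = None) -> FeatureVector:
    """Assemble the ordered 27- (full) or 21-element (early) feature vector."""
    if mode is not None and mode != metrics.mode:
        raise ValueError(f"mode mismatch: metrics are {metrics.mode!r}, requested {mode!r}")
    names = FULL_FEATURE_NAMES if metrics.mode == "full" else EARLY_FEATURE_NAMES
    missing = [n for n in _SPECTRAL_SUFFIXED if n not in spectral]
    if missing:
        raise ValueError(f"spectral metrics missing entries: {missing}")
    vals = np.array(
        [metrics.values[n] if n in metrics.values else spectral[n] for n in names],
        dtype=float,
    )
    return FeatureVector(mode=metrics.mode, values=vals)
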