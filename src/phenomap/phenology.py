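"""Phenology retrieval from EVI time series.

The seasonal EVI trajectory of an annual crop is modelled with an
asymmetric double sigmoid — the difference of two logistic ramps sharing a
background level and an amplitude::

    f(t) = V_b + V_a * [ sigma(p (t - D_i)) - sigma(q (t - D_d)) ]

where ``sigma`` is the standard logistic, ``V_b`` is the background
(non-growing-season) EVI, ``V_a`` the seasonal amplitude, ``p``/``q`` the
green-up and senescence slope parameters (day^-1) and ``D_i``/``D_d`` the
mid-dates (DOY) of the rising and falling segments.  In early-season mode
only the rising term is fitted, ``f(t) = V_b + V_a * sigma(p (t - D_i))``.

From a fitted curve a set of transition-date metrics is derived in closed
form: the second derivative of a logistic ramp has extrema where
``sigma = (1 +- 1/sqrt(3))/2``, i.e. at ``D_i +- ln(2 + sqrt(3))/p``, which
mark the start/end of green-up (D_1, D_2) and, for the falling segment,
the start/end of senescence (D_3, D_4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ReflectanceSeries",
    "PhenoCurve",
    "PhenoMetrics",
    "compute_evi",
    "double_sigmoid",
    "rising_sigmoid",
    "fit_double_sigmoid",
    "derive_pheno_metrics",
    "COMPOSITE_DOYS",
    "HALF_WIDTH_CONST",
]

# Nominal 8-day composite start DOYs: 1, 9, ..., 361 (46 per year).
COMPOSITE_DOYS = np.arange(1, 362, 8)

#: ln(2 + sqrt(3)) — half-width factor between a logistic mid-date and its
#: second-derivative extrema.
HALF_WIDTH_CONST = math.log(2.0 + math.sqrt(3.0))

# Fitting bounds.
VB_BOUNDS = (-0.2, 0.6)
VA_BOUNDS = (0.0, 1.2)
SLOPE_BOUNDS = (0.01, 1.0)
DATE_BOUNDS = (1.0, 366.0)
MIN_SEASON_GAP = 8.0  # D_d - D_i >= 8 days

MIN_OBS_FULL = 10
MIN_OBS_EARLY = 6


@dataclass
class ReflectanceSeries:
    """One pixel-year of multi-band 8-day composites.

    Parameters
    ----------
    dates
        Composite start day-of-year, strictly increasing, 1-based.
    bands
        Reflectance array of shape ``(n_composites, 7)`` for MODIS-like
        bands 1–7 (band 1 = red, 2 = NIR, 3 = blue, 4 = green,
        6/7 = shortwave infrared).
    quality
        Boolean good-observation flags, same shape as ``bands``.
    """

    dates: np.ndarray
    bands: np.ndarray
    quality: np.ndarray

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype=float)
        self.bands = np.asarray(self.bands, dtype=float)
        self.quality = np.asarray(self.quality, dtype=bool)
        if self.bands.ndim != 2 or self.bands.shape[1] != 7:
            raise ValueError("bands must have shape (n_composites, 7)")
        if self.bands.shape != self.quality.shape:
            raise ValueError("quality must match bands shape")
        if len(self.dates) != len(self.bands):
            raise ValueError("dates length must match composites")
        if np.any(np.diff(self.dates) <= 0):
            raise ValueError("dates must be strictly increasing")
        if len(self.dates) > 46:
            raise ValueError("at most 46 composites per year")

    # band index helpers (0-based columns for 1-based MODIS band numbers)
    @property
    def red(self) -> np.ndarray:
        return self.bands[:, 0]

    @property
    def nir(self) -> np.ndarray:
        return self.bands[:, 1]

    @property
    def blue(self) -> np.ndarray:
        return self.bands[:, 2]

    def valid_for(self, band_idx: list[int]) -> np.ndarray:
        """Good-quality mask requiring all listed 0-based band columns."""
        return np.all(self.quality[:, band_idx], axis=1)

    def evi(self) -> tuple[np.ndarray, np.ndarray]:
        """EVI per composite plus validity mask (quality and formula domain)."""
        evi, ok = compute_evi(self.red, self.nir, self.blue)
        return evi, ok & self.valid_for([0, 1, 2])


@dataclass
class PhenoCurve:
    """Fitted double-sigmoid parameters for one pixel."""

    v_b: float
    v_a: float
    p: float
    d_i: float
    q: float | None
    d_d: float | None
    mode: Literal["full", "early"]
    fit_rmse: float
    n_obs: int
    success: bool = True

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        if self.mode == "full":
            return double_sigmoid(t, self.v_b, self.v_a, self.p, self.d_i, self.q, self.d_d)
        return rising_sigmoid(t, self.v_b, self.v_a, self.p, self.d_i)


@dataclass
class PhenoMetrics:
    """The 13 (full) or 7 (early) phenological metrics of a fitted curve."""

    mode: Literal["full", "early"]
    values: dict = field(default_factory=dict)

    #: metric names in canonical order
    FULL_NAMES = (
        "V_b", "V_a", "p", "D_i", "q", "D_d",
        "D_1", "D_2", "D_3", "D_4", "L_id", "L_14", "D_peak",
    )
    EARLY_NAMES = ("V_b", "V_a", "p", "D_i", "D_1", "D_2", "D_peak")
    #: metrics only defined once the senescence segment is observed
    LATE_NAMES = ("q", "D_d", "D_3", "D_4", "L_id", "L_14")

    @property
    def names(self) -> tuple[str, ...]:
        return self.FULL_NAMES if self.mode == "full" else self.EARLY_NAMES

    def available(self, name: str) -> bool:
        return name in self.values and np.isfinite(self.values[name])

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in self.names], dtype=float)


def compute_evi(red, nir, blue):
    """Enhanced Vegetation Index, 2.5 (NIR - red)/(NIR + 6 red - 7.5 blue + 1).

    Returns ``(evi, valid)``; invalid where the denominator is <= 0 or the
    result falls outside [-1, 1.5].  Scalar inputs give scalar outputs.
    """
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    blue = np.asarray(blue, dtype=float)
    denom = nir + 6.0 * red - 7.5 * blue + 1.0
    valid = denom > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        evi = np.where(valid, 2.5 * (nir - red) / np.where(valid, denom, 1.0), np.nan)
    valid = valid & (evi >= -1.0) & (evi <= 1.5)
    evi = np.where(valid, evi, np.nan)
    if evi.ndim == 0:
        return float(evi), bool(valid)
    return evi, valid


def _sigma(x):
    # logistic, clipped to avoid overflow in exp
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def double_sigmoid(t, v_b, v_a, p, d_i, q, d_d):
    t = np.asarray(t, dtype=float)
    return v_b + v_a * (_sigma(p * (t - d_i)) - _sigma(q * (t - d_d)))


def rising_sigmoid(t, v_b, v_a, p, d_i):
    t = np.asarray(t, dtype=float)
    return v_b + v_a * _sigma(p * (t - d_i))


def _unfit(mode: str, n_obs: int) -> PhenoCurve:
    return PhenoCurve(np.nan, np.nan, np.nan, np.nan, None, None, mode,
                      np.nan, n_obs, success=False)


def _initial_guess(t: np.ndarray, y: np.ndarray, mode: str):
    lo, hi = np.percentile(y, [5, 95])
    v_b0 = float(np.clip(lo, *VB_BOUNDS))
    v_a0 = float(np.clip(hi - lo, 1e-3, VA_BOUNDS[1]))
    half = lo + 0.5 * (hi - lo)
    above = y >= half
    if above.any():
        d_i0 = float(t[np.argmax(above)])
        d_d0 = float(t[len(t) - 1 - np.argmax(above[::-1])])
    else:  # flat signal
        d_i0, d_d0 = float(t[len(t) // 3]), float(t[2 * len(t) // 3])
    d_i0 = float(np.clip(d_i0, *DATE_BOUNDS))
    if mode == "early":
        return np.array([v_b0, v_a0, 0.1, d_i0])
    gap0 = max(d_d0 - d_i0, MIN_SEASON_GAP + 1.0)
    return np.array([v_b0, v_a0, 0.1, d_i0, 0.1, gap0])


def fit_double_sigmoid(
    dates: np.ndarray,
    evi: np.ndarray,
    mode: Literal["full", "early"] = "full",
    valid: np.ndarray | None = None,
) -> PhenoCurve:
    """Bounded least-squares fit of the (double) sigmoid to an EVI series.

    ``valid`` masks usable observations (defaults to finite EVI).  Pixels
    with fewer than 10 (full) / 6 (early) valid observations, or where the
    optimizer fails, are returned with ``success=False`` and NaN parameters.

    The falling mid-date is internally parameterized as
    ``D_d = D_i + gap`` with ``gap >= 8`` days so the fitted season always
    has positive length.
    """
    dates = np.asarray(dates, dtype=float)
    evi = np.asarray(evi, dtype=float)
    if valid is None:
        valid = np.isfinite(evi)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(evi)
    t, y = dates[valid], evi[valid]
    min_obs = MIN_OBS_FULL if mode == "full" else MIN_OBS_EARLY
    if len(t) < min_obs:
        return _unfit(mode, len(t))

    if mode == "early":
        def resid(th):
            return rising_sigmoid(t, *th) - y
        lb = [VB_BOUNDS[0], VA_BOUNDS[0], SLOPE_BOUNDS[0], DATE_BOUNDS[0]]
        ub = [VB_BOUNDS[1], VA_BOUNDS[1], SLOPE_BOUNDS[1], DATE_BOUNDS[1]]
    else:
        def resid(th):
            v_b, v_a, p, d_i, q, gap = th
            return double_sigmoid(t, v_b, v_a, p, d_i, q, d_i + gap) - y
        lb = [VB_BOUNDS[0], VA_BOUNDS[0], SLOPE_BOUNDS[0], DATE_BOUNDS[0],
              SLOPE_BOUNDS[0], MIN_SEASON_GAP]
        ub = [VB_BOUNDS[1], VA_BOUNDS[1], SLOPE_BOUNDS[1], DATE_BOUNDS[1],
              SLOPE_BOUNDS[1], 365.0]

    x0 = np.clip(_initial_guess(t, y, mode), lb, ub)
    best = None
    # a couple of restarts with shifted mid-date guard against local minima
    for di_shift in (0.0, -24.0, 24.0):
        x = x0.copy()
        x[3] = np.clip(x[3] + di_shift, lb[3], ub[3])
        try:
            sol = least_squares(resid, x, bounds=(lb, ub), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
        if best is not None and best.cost < 1e-10 * max(len(t), 1):
            break
    if best is None:
        return _unfit(mode, len(t))

    rmse = float(np.sqrt(2.0 * best.cost / len(t)))
    if mode == "early":
        v_b, v_a, p, d_i = best.x
        return PhenoCurve(float(v_b), float(v_a), float(p), float(d_i),
                          None, None, "early", rmse, len(t))
    v_b, v_a, p, d_i, q, gap = best.x
    return PhenoCurve(float(v_b), float(v_a), float(p), float(d_i),
                      float(q), float(d_i + gap), "full", rmse, len(t))


def derive_pheno_metrics(
    curve: PhenoCurve,
    obs_dates: np.ndarray | None = None,
    obs_evi: np.ndarray | None = None,
    obs_valid: np.ndarray | None = None,
) -> PhenoMetrics:
    """Derive transition-date metrics from a fitted curve.

    D_1/D_2 (and D_3/D_4 in full mode) come from the closed form
    ``D_i -+ ln(2+sqrt(3))/p``.  D_peak is the argmax of the fitted curve
    over the observation window in full mode; in early mode the rising
    sigmoid is monotone, so D_peak falls back to the DOY of the maximum
    valid observed EVI (ties broken toward the earlier DOY), for which the
    observed series must be supplied.
    """
    if not curve.success:
        raise ValueError("cannot derive metrics from an unsuccessful fit")
    m = PhenoMetrics(mode=curve.mode)
    w = HALF_WIDTH_CONST
    vals = m.values
    vals["V_b"] = curve.v_b
    vals["V_a"] = curve.v_a
    vals["p"] = curve.p
    vals["D_i"] = curve.d_i
    vals["D_1"] = curve.d_i - w / curve.p
    vals["D_2"] = curve.d_i + w / curve.p

    if curve.mode == "full":
        vals["q"] = curve.q
        vals["D_d"] = curve.d_d
        vals["D_3"] = curve.d_d - w / curve.q
        vals["D_4"] = curve.d_d + w / curve.q
        vals["L_id"] = curve.d_d - curve.d_i
        vals["L_14"] = vals["D_4"] - vals["D_1"]
        if obs_dates is not None and len(obs_dates):
            t_lo, t_hi = float(np.min(obs_dates)), float(np.max(obs_dates))
        else:
            t_lo, t_hi = float(COMPOSITE_DOYS[0]), float(COMPOSITE_DOYS[-1])
        vals["D_peak"] = _curve_argmax(curve, t_lo, t_hi)
    else:
        if obs_dates is None or obs_evi is None:
            raise ValueError("early mode needs observed EVI for D_peak")
        obs_dates = np.asarray(obs_dates, dtype=float)
        obs_evi = np.asarray(obs_evi, dtype=float)
        ok = np.isfinite(obs_evi)
        if obs_valid is not None:
            ok &= np.asarray(obs_valid, dtype=bool)
        if not ok.any():
            raise ValueError("no valid observations for early-mode D_peak")
        t, y = obs_dates[ok], obs_evi[ok]
        vals["D_peak"] = float(t[np.argmax(y)])  # argmax -> first (earlier) tie
    return m


def _curve_argmax(curve: PhenoCurve, t_lo: float, t_hi: float) -> float:
    """Argmax of the fitted curve over [t_lo, t_hi], coarse grid + golden refine."""
    grid = np.linspace(t_lo, t_hi, 1024)
    i = int(np.argmax(curve(grid)))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(lambda t: -curve(t), bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)
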