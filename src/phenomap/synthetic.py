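"""Synthetic landscapes, reflectance time series and progress tables.

Everything the mapping pipeline consumes can be generated here with known
ground truth: a fine-resolution field-patch label raster (corn / soybean /
other), per-coarse-pixel 7-band 8-day composite stacks whose EVI follows a
double-sigmoid seasonal trajectory, weekly cumulative crop-progress tables
and a county-zone raster.  Per-year uniform phenology shifts emulate
interannual variability in crop development, the lever the cross-year
method is designed to handle.

The simulator works at the coarse (composite) grid: each coarse pixel's
reflectance is the coverage-weighted mixture of per-class band
trajectories, where each class trajectory is constructed so that the EVI
computed from its bands equals the class's double-sigmoid greenness curve
(plus observation noise).  Corn and soybean archetypes differ mainly in
green-up timing and in SWIR-green contrast at peak growth.

Stage-date conventions (simulator, not survey, definitions): planting and
emergence anchor on the green-up onset D_1, silking/blooming on the EVI
peak, dented/dropping-leaves on the senescence onset D_3, maturity on its
end D_4.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm

from .coverage import CLASS_CODES, aggregate_coverage
from .phenology import COMPOSITE_DOYS, HALF_WIDTH_CONST, ReflectanceSeries, double_sigmoid
from .progress import PROGRESS_COLUMNS, ProgressTable

__all__ = ["SimulationConfig", "SimulatedScene", "simulate_landscape",
           "simulate_pixel_series", "simulate_scene", "simulate_progress_table"]

CLASSES = ("corn", "soybean", "other")

#: per-class double-sigmoid parameter distributions, (mean, sd);
#: dates in DOY, slopes in day^-1, EVI dimensionless
DEFAULT_PHENO = {
    "corn":    {"v_b": (0.12, 0.015), "v_a": (0.55, 0.04), "p": (0.11, 0.010),
                "d_i": (158.0, 6.0), "q": (0.09, 0.010), "d_d": (245.0, 6.0)},
    "soybean": {"v_b": (0.12, 0.015), "v_a": (0.50, 0.04), "p": (0.10, 0.010),
                "d_i": (172.0, 6.0), "q": (0.10, 0.010), "d_d": (258.0, 6.0)},
    "other":   {"v_b": (0.18, 0.020), "v_a": (0.22, 0.040), "p": (0.050, 0.006),
                "d_i": (125.0, 8.0), "q": (0.040, 0.006), "d_d": (290.0, 8.0)},
}

#: band archetypes: reflectance = base + greenness * slope, per
#: (red, NIR*, blue, green, b5, SWIR1, SWIR2); NIR (band 2) is solved from
#: the EVI target instead of using the archetype
BAND_ARCHETYPES = {
    "corn":    {"base": (0.12, 0.0, 0.060, 0.090, 0.30, 0.28, 0.18),
                "slope": (-0.07, 0.0, -0.020, -0.020, 0.0, -0.14, -0.12)},
    "soybean": {"base": (0.12, 0.0, 0.060, 0.095, 0.30, 0.30, 0.19),
                "slope": (-0.07, 0.0, -0.020, -0.032, 0.0, -0.19, -0.135)},
    "other":   {"base": (0.11, 0.0, 0.055, 0.100, 0.30, 0.25, 0.15),
                "slope": (-0.05, 0.0, -0.015, -0.020, 0.0, -0.08, -0.06)},
}

#: simulator stage-date conventions per crop: stage -> (anchor, offset days)
#: anchors: D1 (green-up onset), PEAK (max EVI), D3 (senescence onset),
#: D4 (senescence end)
STAGE_DEFS = {
    "corn": {"planted": ("D1", -12.0), "emerged": ("D1", 0.0),
             "silking": ("PEAK", 0.0), "dough": ("PEAK", 12.0),
             "dented": ("D3", 0.0), "mature": ("D4", 0.0),
             "harvested": ("D4", 14.0)},
    "soybean": {"planted": ("D1", -12.0), "emerged": ("D1", 0.0),
                "blooming": ("PEAK", 0.0), "setting_pods": ("PEAK", 12.0),
                "dropping_leaves": ("D3", 0.0), "mature": ("D4", 0.0),
                "harvested": ("D4", 14.0)},
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study area.

    Defaults describe a Corn-Belt-like scene: a 512x512 fine grid (30 m
    analogue) aggregated 16x to a 32x32 coarse grid (500 m analogue,
    pixel_area 25 ha), 35/35/30% corn/soybean/other, EVI observation
    noise sigma=0.02 and 5% missing composites.
    """

    seed: int = 0
    fine_shape: tuple[int, int] = (512, 512)
    factor: int = 16
    field_size_range: tuple[int, int] = (8, 40)
    proportions: dict = dc_field(default_factory=lambda: {
        "corn": 0.35, "soybean": 0.35, "other": 0.30})
    pheno: dict = dc_field(default_factory=lambda: {
        c: dict(DEFAULT_PHENO[c]) for c in CLASSES})
    #: mapping year -> uniform phenology shift in days (applied to all dates)
    year_shifts: dict = dc_field(default_factory=lambda: {2009: 0.0, 2010: 15.0,
                                                          2011: 5.0})
    #: west-east swing of the corn share (soybean moves oppositely),
    #: as a fraction of its base proportion; emulates the county-scale
    #: composition gradients of real agricultural landscapes
    spatial_gradient: float = 0.6
    #: north-south green-up gradient in days: crop transition dates run
    #: this many days later at the northern edge than at the southern
    #: edge, emulating the latitudinal progression of planting and
    #: green-up within a state
    pheno_gradient_days: float = 14.0
    #: standard deviation (days) of a smooth year-specific sub-state
    #: anomaly field added to crop transition dates; weather-driven
    #: phenology anomalies are regionally coherent but not uniform
    #: across a state, and differ between years
    anomaly_days: float = 2.0
    #: correlation length of the anomaly field, in coarse pixels
    anomaly_scale: float = 4.0
    evi_noise: float = 0.02
    band_noise: float = 0.004
    missing_rate: float = 0.05
    county_factor: int = 2
    pixel_area_ha: float = 25.0
    state: str = "IA"

    def __post_init__(self):
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if self.evi_noise < 0 or self.missing_rate < 0 or self.missing_rate >= 1:
            raise ValueError("invalid noise/missing configuration")


@dataclass
class SimulatedScene:
    """One simulated state-year with full ground truth."""

    year: int
    fine_labels: np.ndarray          # (H, W) class codes
    dates: np.ndarray                # (46,) composite start DOYs
    reflectance: np.ndarray          # (46, 7, Hc, Wc)
    quality: np.ndarray              # (46, 7, Hc, Wc) bool
    coverage: np.ndarray             # (3, Hc, Wc) exact percent targets
    zones: np.ndarray                # (Hc, Wc) county ids

    def pixel_series(self, i: int, j: int) -> ReflectanceSeries:
        return ReflectanceSeries(self.dates,
                                 self.reflectance[:, :, i, j],
                                 self.quality[:, :, i, j])


def _rng(config: SimulationConfig, *keys: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *[k & 0x7FFFFFFF for k in keys]])


def simulate_landscape(config: SimulationConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Rectangular field patches with classes assigned to match proportions.

    Rows and columns are cut into random intervals whose cross products
    form fields; fields are visited in random order and each is given the
    class currently furthest below its target area (weighted by a
    west-east corn/soybean composition gradient), so realized class
    fractions land within one field of the global targets while county
    composition varies spatially.
    """
    h, w = config.fine_shape
    if h < config.factor or w < config.factor:
        raise ValueError("fine grid smaller than one aggregation block")
    lo, hi = config.field_size_range

    def cuts(n):
        edges = [0]
        while edges[-1] < n:
            edges.append(min(n, edges[-1] + int(rng.integers(lo, hi + 1))))
        return np.array(edges)

    rows, cols = cuts(h), cuts(w)
    fields = [(r0, r1, c0, c1)
              for r0, r1 in zip(rows[:-1], rows[1:])
              for c0, c1 in zip(cols[:-1], cols[1:])]
    order = rng.permutation(len(fields))
    target = {c: config.proportions[c] * h * w for c in CLASSES}
    assigned = {c: 0.0 for c in CLASSES}
    labels = np.zeros((h, w), dtype=np.uint8)
    g = config.spatial_gradient
    for k in order:
        r0, r1, c0, c1 = fields[k]
        area = (r1 - r0) * (c1 - c0)
        u = 2.0 * ((c0 + c1) / (2.0 * w) - 0.5)   # -1 at west edge, +1 at east
        weight = {"corn": max(1.0 + g * u, 0.05),
                  "soybean": max(1.0 - g * u, 0.05), "other": 1.0}
        # sample with deficit-weighted probabilities: smooth gradient,
        # self-correcting global proportions
        score = np.array([max((target[c] - assigned[c]) / max(target[c], 1.0), 1e-9)
                          * weight[c] for c in CLASSES])
        cls = CLASSES[rng.choice(3, p=score / score.sum())]
        labels[r0:r1, c0:c1] = CLASS_CODES[cls]
        assigned[cls] += area
    return labels


def _draw_params(cls: str, config: SimulationConfig, shift: float,
                 rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    out = {}
    for name, (mu, sd) in config.pheno[cls].items():
        if name in ("d_i", "d_d"):
            mu = mu + shift
        out[name] = rng.normal(mu, sd, size=n)
    out["p"] = np.clip(out["p"], 0.015, 0.9)
    out["q"] = np.clip(out["q"], 0.015, 0.9)
    out["v_a"] = np.clip(out["v_a"], 0.02, 1.1)
    out["d_d"] = np.maximum(out["d_d"], out["d_i"] + 20.0)
    return out


def _bands_from_evi(cls: str, evi: np.ndarray, greenness: np.ndarray,
                    config: SimulationConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Band reflectances (..., 7) whose computed EVI equals ``evi``."""
    arch = BAND_ARCHETYPES[cls]
    base = np.asarray(arch["base"])
    slope = np.asarray(arch["slope"])
    g = np.clip(greenness, 0.0, 1.0)[..., None]
    bands = base + g * slope
    if config.band_noise > 0:
        noise = rng.normal(0.0, config.band_noise, size=bands.shape)
        noise[..., 1] = 0.0
        bands = bands + noise
    bands = np.clip(bands, 0.001, 1.0)
    red, blue = bands[..., 0], bands[..., 2]
    e = np.clip(evi, -0.5, 1.2)
    # invert the EVI formula for NIR: 2.5 (nir-red)/(nir + 6 red - 7.5 blue + 1) = e
    nir = (2.5 * red + e * (6.0 * red - 7.5 * blue + 1.0)) / (2.5 - e)
    bands[..., 1] = np.clip(nir, 0.001, 1.0)
    return bands


def simulate_pixel_series(cls: str, params: dict, config: SimulationConfig,
                          rng: np.random.Generator) -> ReflectanceSeries:
    """One pure pixel-year of 46 composites for a single class.

    ``params`` holds scalar double-sigmoid parameters (v_b, v_a, p, d_i,
    q, d_d).  EVI noise is injected before the band inversion, so the EVI
    recomputed from the bands carries exactly the configured noise; a
    random subset of composites is flagged bad at the missing rate.
    """
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}")
    t = COMPOSITE_DOYS.astype(float)
    clean = double_sigmoid(t, params["v_b"], params["v_a"], params["p"],
                           params["d_i"], params["q"], params["d_d"])
    evi = clean + rng.normal(0.0, config.evi_noise, size=t.shape)
    g = (clean - params["v_b"]) / max(params["v_a"], 1e-6)
    bands = _bands_from_evi(cls, evi, g, config, rng)
    bad = rng.random(len(t)) < config.missing_rate
    quality = np.ones_like(bands, dtype=bool)
    quality[bad, :] = False
    return ReflectanceSeries(t, bands, quality)


def simulate_scene(config: SimulationConfig, year: int) -> SimulatedScene:
    """Simulate one state-year: labels, coarse reflectance stack, truth.

    Coarse-pixel reflectance is the exact coverage-weighted mixture of the
    three class band trajectories, with per-pixel parameter draws from the
    year's (possibly shifted) class distributions.
    """
    if year not in config.year_shifts:
        raise ValueError(f"year {year} not configured")
    shift = config.year_shifts[year]
    rng = _rng(config, year)
    fine = simulate_landscape(config, rng)
    cov = aggregate_coverage(fine, config.factor)     # (3, Hc, Wc)
    hc, wc = cov.shape[1:]
    n = hc * wc
    t = COMPOSITE_DOYS.astype(float)
    nt = len(t)

    # latitudinal green-up offset, shared by all crops: +g/2 days at the
    # northern (first) row, -g/2 at the southern (last) row
    row_frac = (np.arange(hc) / max(hc - 1, 1))[:, None] * np.ones((1, wc))
    lat_offset = config.pheno_gradient_days * (0.5 - row_frac).ravel()
    # year-specific smooth anomaly field on top of the uniform shift
    lat_offset = lat_offset + _anomaly_field(hc, wc, config, rng).ravel()

    mix = np.zeros((n, nt, 7))
    frac = cov.reshape(3, n).T / 100.0                # (n, 3) corn/soy/other
    for ci, cls in enumerate(CLASSES):
        pars = _draw_params(cls, config, shift, rng, n)
        pars["d_i"] = pars["d_i"] + lat_offset
        pars["d_d"] = pars["d_d"] + lat_offset
        clean = double_sigmoid(t[None, :], pars["v_b"][:, None],
                               pars["v_a"][:, None], pars["p"][:, None],
                               pars["d_i"][:, None], pars["q"][:, None],
                               pars["d_d"][:, None])
        evi = clean + rng.normal(0.0, config.evi_noise, size=clean.shape)
        g = (clean - pars["v_b"][:, None]) / np.maximum(pars["v_a"][:, None], 1e-6)
        bands = _bands_from_evi(cls, evi, g, config, rng)   # (n, nt, 7)
        mix += frac[:, ci][:, None, None] * bands

    bad = rng.random((n, nt)) < config.missing_rate
    quality = np.ones((n, nt, 7), dtype=bool)
    quality[bad, :] = False

    reflectance = mix.reshape(hc, wc, nt, 7).transpose(2, 3, 0, 1)
    qual = quality.reshape(hc, wc, nt, 7).transpose(2, 3, 0, 1)
    zones = _county_zones(hc, wc, config.county_factor)
    return SimulatedScene(year=year, fine_labels=fine, dates=t,
                          reflectance=reflectance, quality=qual,
                          coverage=cov, zones=zones)


def _anomaly_field(hc: int, wc: int, config: SimulationConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean random field of date anomalies (days)."""
    if config.anomaly_days <= 0:
        return np.zeros((hc, wc))
    from scipy.ndimage import gaussian_filter

    white = rng.normal(size=(hc, wc))
    smooth = gaussian_filter(white, sigma=config.anomaly_scale, mode="reflect")
    smooth -= smooth.mean()
    sd = smooth.std()
    return smooth * (config.anomaly_days / sd) if sd > 0 else smooth


def _county_zones(hc: int, wc: int, county_factor: int) -> np.ndarray:
    rows = np.arange(hc) // county_factor
    cols = np.arange(wc) // county_factor
    ncol = int(cols.max()) + 1
    return (rows[:, None] * ncol + cols[None, :]).astype(np.int32)


def _stage_population(cls: str, config: SimulationConfig,
                      shift: float) -> dict[str, tuple[float, float]]:
    """Mean/sd of each stage-date population implied by the class params."""
    ph = config.pheno[cls]
    w = HALF_WIDTH_CONST
    d1 = ph["d_i"][0] + shift - w / ph["p"][0]
    peak = 0.5 * (ph["d_i"][0] + ph["d_d"][0]) + shift
    d3 = ph["d_d"][0] + shift - w / ph["q"][0]
    d4 = ph["d_d"][0] + shift + w / ph["q"][0]
    # population spread: parameter draw sd plus the latitudinal gradient
    # (uniform over +-g/2, variance g^2/12), the anomaly field, and a
    # 1-day survey blur
    grad_var = config.pheno_gradient_days**2 / 12.0 + config.anomaly_days**2
    sd_i = np.sqrt(ph["d_i"][1] ** 2 + grad_var) + 1.0
    sd_d = np.sqrt(ph["d_d"][1] ** 2 + grad_var) + 1.0
    anchors = {"D1": (d1, sd_i), "PEAK": (peak, sd_i),
               "D3": (d3, sd_d), "D4": (d4, sd_d)}
    out = {}
    for stage, (anchor, off) in STAGE_DEFS[cls].items():
        mu, sd = anchors[anchor]
        out[stage] = (mu + off, sd)
    return out


def simulate_progress_table(config: SimulationConfig,
                            years: Iterable[int] | None = None) -> ProgressTable:
    """Weekly cumulative progress percentages per state/year/crop/stage.

    Percentages are the normal CDF of the stage-date population implied by
    the class parameter distributions, evaluated at week-ending DOYs, so
    each stage's 50% date equals the population mean exactly.
    """
    years = list(years) if years is not None else sorted(config.year_shifts)
    week_doys = np.arange(92, 331, 7)
    rows = []
    for year in years:
        shift = config.year_shifts[year]
        for crop in ("corn", "soybean"):
            pops = _stage_population(crop, config, shift)
            for stage, (mu, sd) in pops.items():
                pct = 100.0 * norm.cdf((week_doys - mu) / sd)
                for doy, p in zip(week_doys, pct):
                    rows.append({"state": config.state, "year": year,
                                 "crop": crop, "stage": stage,
                                 "week_ending_doy": int(doy),
                                 "percent": float(round(p, 2))})
    df = pd.DataFrame(rows, columns=PROGRESS_COLUMNS)
    # rounding can produce tiny decreases at the tails; enforce monotonicity
    df["percent"] = df.groupby(["state", "year", "crop", "stage"])["percent"].cummax()
    return ProgressTable(df)
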