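"""Crop-progress processing: 50%-dates, interannual RMSD, training-year choice.

Weekly crop-progress tables report, per state/crop/stage, the cumulative
percentage of cropland that has reached the stage by each week's end.
Each stage's series is reduced to the day-of-year at which 50% of the crop
had reached the stage (linear interpolation between bracketing weeks).
Interannual phenological similarity between a mapping year v and a
candidate training year t is the root-mean-square deviation over all
shared progress items i (corn and soybean stages pooled)::

    RMSD(v, t) = sqrt( mean_i (X_iv - X_it)^2 )

and the candidate with the smallest RMSD is selected as the training year
("similar progress").  The "close year" control instead takes the year
immediately before the mapping year (the earliest mapping year borrows
the following year instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ProgressTable", "StageDates", "TrainingYearSelection",
           "fifty_percent_date", "stage_dates_from_table", "progress_rmsd",
           "select_training_year"]

PROGRESS_COLUMNS = ["state", "year", "crop", "stage", "week_ending_doy", "percent"]

#: back-extrapolation is clipped to first reported DOY minus this many days
BACKCAST_CLIP_DAYS = 7.0


@dataclass
class StageDates:
    """50%-progress DOYs for one (state, year), keyed by "crop:stage"."""

    state: str
    year: int
    dates: dict[str, float] = field(default_factory=dict)

    def shared_items(self, other: "StageDates") -> list[str]:
        return sorted(set(self.dates) & set(other.dates))


@dataclass
class TrainingYearSelection:
    mapping_year: int
    candidates: list[int]
    rmsd: dict[int, float]
    selected: int
    strategy: str


class ProgressTable:
    """Thin wrapper over the weekly progress DataFrame with validation."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in PROGRESS_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"progress table missing columns {missing}")
        self.df = df.copy()

    @classmethod
    def read_csv(cls, path) -> "ProgressTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def stage_dates(self, state: str, year: int) -> StageDates:
        return stage_dates_from_table(self, state, year)


def fifty_percent_date(doys: np.ndarray, percents: np.ndarray) -> float:
    """DOY at which a cumulative progress series crosses 50%.

    Linear interpolation between the weeks bracketing 50; exact DOY when a
    week reports exactly 50.  Returns NaN when the series never reaches
    50.  When the first report already exceeds 50, the date is
    back-extrapolated from the first two points and clipped to no more
    than 7 days before the first report.
    """
    doys = np.asarray(doys, dtype=float)
    percents = np.asarray(percents, dtype=float)
    if np.any(np.diff(percents) < 0):
        raise ValueError("cumulative percentages must be non-decreasing")
    if percents.max() < 50.0:
        return float("nan")
    if percents[0] > 50.0:
        if len(doys) >= 2 and percents[1] > percents[0]:
            slope = (doys[1] - doys[0]) / (percents[1] - percents[0])
            d = doys[0] - slope * (percents[0] - 50.0)
        else:
            d = doys[0]
        return float(max(d, doys[0] - BACKCAST_CLIP_DAYS))
    idx = int(np.argmax(percents >= 50.0))
    if percents[idx] == 50.0:
        return float(doys[idx])
    d0, d1 = doys[idx - 1], doys[idx]
    p0, p1 = percents[idx - 1], percents[idx]
    return float(d0 + (d1 - d0) * (50.0 - p0) / (p1 - p0))


def stage_dates_from_table(table: ProgressTable, state: str, year: int) -> StageDates:
    """All 50% dates for one state-year, corn and soybean stages pooled."""
    sub = table.df[(table.df.state == state) & (table.df.year == year)]
    out = StageDates(state=state, year=int(year))
    for (crop, stage), grp in sub.groupby(["crop", "stage"], sort=True):
        grp = grp.sort_values("week_ending_doy")
        d = fifty_percent_date(grp.week_ending_doy.to_numpy(),
                               grp.percent.to_numpy())
        if np.isfinite(d):
            out.dates[f"{crop}:{stage}"] = d
    return out


def progress_rmsd(a: StageDates, b: StageDates) -> float:
    """RMSD in days over progress items present in both years."""
    shared = a.shared_items(b)
    if not shared:
        raise ValueError(f"no shared progress items between {a.year} and {b.year}")
    diffs = np.array([a.dates[k] - b.dates[k] for k in shared])
    return float(np.sqrt(np.mean(diffs**2)))


def select_training_year(
    mapping_year: int,
    candidates: dict[int, StageDates] | list[int],
    strategy: str = "similar_progress",
    mapping_dates: StageDates | None = None,
) -> TrainingYearSelection:
    """Pick the training year for ``mapping_year``.

    similar_progress
        argmin over candidate RMSDs vs the mapping year's stage dates;
        ties broken toward the most recent year.
    close_year
        the year immediately preceding the mapping year; when the mapping
        year precedes every candidate, the earliest following year.
    """
    if strategy == "similar_progress":
        if not isinstance(candidates, dict) or mapping_dates is None:
            raise ValueError("similar_progress needs candidate StageDates and "
                             "the mapping year's StageDates")
        cand = {y: sd for y, sd in candidates.items() if y != mapping_year}
        if not cand:
            raise ValueError("no candidate years")
        rmsd = {y: progress_rmsd(mapping_dates, sd) for y, sd in cand.items()}
        # argmin; tie -> most recent year
        selected = min(sorted(rmsd, reverse=True), key=lambda y: rmsd[y])
        return TrainingYearSelection(mapping_year, sorted(cand), rmsd,
                                     selected, strategy)
    if strategy == "close_year":
        years = sorted(candidates if isinstance(candidates, list) else candidates.keys())
        years = [y for y in years if y != mapping_year]
        if not years:
            raise ValueError("no candidate years")
        prior = [y for y in years if y < mapping_year]
        selected = max(prior) if prior else min(years)
        return TrainingYearSelection(mapping_year, years, {}, selected, strategy)
    raise ValueError(f"unknown strategy {strategy!r}")
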