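"""Shared I/O: season windows, raster stacks (TIFF + JSON sidecar), tables.

Rasters are written as plain multi-band TIFF via :mod:`tifffile`, with a
JSON sidecar recording band names, composite dates and the no-data value.
Georeferencing is deliberately not handled: all spatial bookkeeping in this
package is in pixel/block coordinates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile

from .phenology import ReflectanceSeries

__all__ = ["SeasonWindow", "truncate_to_window", "write_raster", "read_raster",
           "NODATA"]

logger = logging.getLogger("phenomap")

#: no-data sentinel for float rasters
NODATA = -9999.0

#: length of one composite period in days
COMPOSITE_DAYS = 8
#: number of composites retained in early-season mode (the 28th product
#: ends on DOY 224)
EARLY_COMPOSITES = 28


@dataclass(frozen=True)
class SeasonWindow:
    """Observation window: the full year or the early-season subset.

    Early mode keeps composites whose start DOY does not exceed
    ``end_doy`` (default 224, the last day of the 28th 8-day product);
    DOY — not calendar date — is primary, so leap years use the same
    cutoff.
    """

    mode: Literal["full", "early"]
    end_doy: int = field(default=0)

    def __post_init__(self) -> None:
        if self.mode not in ("full", "early"):
            raise ValueError(f"unknown season mode {self.mode!r}")
        if self.end_doy == 0:
            object.__setattr__(
                self, "end_doy",
                366 if self.mode == "full" else EARLY_COMPOSITES * COMPOSITE_DAYS,
            )

    @property
    def n_composites(self) -> int:
        return self.end_doy // COMPOSITE_DAYS


FULL_WINDOW = SeasonWindow("full")
EARLY_WINDOW = SeasonWindow("early")


def truncate_to_window(series: ReflectanceSeries, window: SeasonWindow) -> ReflectanceSeries:
    """Drop composites starting after the window end; full mode is identity."""
    if window.mode == "full":
        return series
    keep = series.dates <= window.end_doy
    return ReflectanceSeries(series.dates[keep], series.bands[keep],
                             series.quality[keep])


def write_raster(path: str | Path, data: np.ndarray, *,
                 band_names: list[str] | None = None,
                 dates: list[int] | None = None,
                 nodata: float | None = NODATA,
                 extra: dict | None = None) -> None:
    """Write an array (bands-first for 3-D) as TIFF with a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.ascontiguousarray(data), photometric="minisblack")
    meta = {"shape": list(data.shape), "dtype": str(data.dtype), "nodata": nodata}
    if band_names is not None:
        meta["band_names"] = list(band_names)
    if dates is not None:
        meta["dates"] = [int(d) for d in dates]
    if extra:
        meta.update(extra)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a TIFF written by :func:`write_raster`; returns (array, sidecar)."""
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return data, meta
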