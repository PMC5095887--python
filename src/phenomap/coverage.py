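"""Coverage percentages from a fine-resolution crop-label raster.

A fine label grid (classes other/corn/soybean, encoded 0/1/5 echoing CDL
codes) is aggregated in square blocks to per-coarse-pixel coverage
percentages — the fuzzy regression targets — and thresholded into "pure"
pixels usable as hard-classification labels.
"""

from __future__ import annotations

import logging

import numpy as np

__all__ = ["CLASS_CODES", "CLASS_NAMES", "UNLABELED", "aggregate_coverage",
           "select_pure_pixels"]

logger = logging.getLogger("phenomap")

#: fine-raster class encoding (0=other, 1=corn, 5=soybean, echoing CDL)
CLASS_CODES = {"other": 0, "corn": 1, "soybean": 5}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}
#: hard-label sentinel for coarse pixels with no dominant class
UNLABELED = 255


def aggregate_coverage(fine: np.ndarray, factor: int) -> np.ndarray:
    """Blockwise class coverage, shape ``(3, H//factor, W//factor)``.

    Band order (corn%, soybean%, other%); each band in [0, 100] and the
    three sum to exactly 100.  Trailing rows/columns not filling a whole
    block are cropped with a warning.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    fine = np.asarray(fine)
    h, w = fine.shape
    hc, wc = h // factor, w // factor
    if hc == 0 or wc == 0:
        raise ValueError("raster smaller than one aggregation block")
    if (h % factor) or (w % factor):
        logger.warning("cropping %d trailing rows, %d trailing columns "
                       "not divisible by factor %d", h % factor, w % factor, factor)
        fine = fine[: hc * factor, : wc * factor]
    blocks = fine.reshape(hc, factor, wc, factor)
    out = np.empty((3, hc, wc), dtype=float)
    for i, cls in enumerate(("corn", "soybean")):
        counts = (blocks == CLASS_CODES[cls]).sum(axis=(1, 3))
        out[i] = counts * 100.0 / factor**2
    # remainder of the summed crop share keeps corn% + soybean% + other%
    # == 100 exactly in floating point (verified exhaustively per factor)
    out[2] = 100.0 - (out[0] + out[1])
    return out


def select_pure_pixels(coverage: np.ndarray, threshold: float = 75.0) -> np.ndarray:
    """Hard labels where one class covers strictly more than ``threshold``%.

    Returns a class-code raster with :data:`UNLABELED` where no class
    exceeds the threshold; those pixels are excluded from hard training.
    """
    if not 50.0 < threshold < 100.0:
        raise ValueError("threshold must lie in (50, 100)")
    corn, soy, other = coverage
    out = np.full(corn.shape, UNLABELED, dtype=np.uint8)
    out[corn > threshold] = CLASS_CODES["corn"]
    out[soy > threshold] = CLASS_CODES["soybean"]
    out[other > threshold] = CLASS_CODES["other"]
    return out
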