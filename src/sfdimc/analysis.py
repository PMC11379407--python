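"""Accuracy assessment for SFDI-derived maps and reflectance values.

Region-of-interest statistics (mean and quartiles over determined pixels,
with an omission rule once more than 2 percent of the ROI is
undetermined), mean absolute percent error against ground truth,
LED-spectrum-weighted averaging of spectral measurements, and the
wavelength-averaged summary tables comparing phase-function and
polarization combinations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "OMIT_THRESHOLD",
    "RoiResult",
    "roi_stats",
    "mape",
    "error_table",
    "spectral_weighted_average",
]

OMIT_THRESHOLD = 0.02  # undetermined fraction above which an ROI is omitted


@dataclass(frozen=True)
class RoiResult:
    """Summary of one property map over a region of interest."""

    mean: float
    q25: float
    q75: float
    undetermined_fraction: float

    @property
    def omitted(self) -> bool:
        return self.undetermined_fraction > OMIT_THRESHOLD


def roi_stats(
    values: np.ndarray,
    mask: Optional[np.ndarray] = None,
    roi: Optional[Tuple[int, int, int, int]] = None,
) -> RoiResult:
    """Mean and quartiles of a map over a rectangular ROI.

    ``roi`` is ``(row_start, row_stop, col_start, col_stop)`` in pixels
    (defaults to the full image); ``mask`` marks undetermined pixels, which
    are excluded from the statistics and drive the omission flag.
    Quartiles use linear interpolation between order statistics.
    """
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = ~np.isfinite(values)
    mask = np.asarray(mask, dtype=bool)
    if roi is not None:
        r0, r1, c0, c1 = roi
        if r0 < 0 or c0 < 0 or r1 > values.shape[0] or c1 > values.shape[1]:
            raise ValueError("ROI extends beyond the image")
        values = values[r0:r1, c0:c1]
        mask = mask[r0:r1, c0:c1]
    if values.size == 0:
        raise ValueError("empty ROI")
    frac = float(mask.mean())
    good = values[~mask]
    if good.size == 0:
        return RoiResult(mean=np.nan, q25=np.nan, q75=np.nan, undetermined_fraction=frac)
    return RoiResult(
        mean=float(good.mean()),
        q25=float(np.percentile(good, 25)),
        q75=float(np.percentile(good, 75)),
        undetermined_fraction=frac,
    )


def mape(measured, truth) -> float:
    """Mean absolute percent error, ``mean(|measured - truth| / truth) * 100``."""
    m = np.asarray(measured, dtype=float)
    t = np.asarray(truth, dtype=float)
    if m.shape != t.shape:
        raise ValueError("measured and truth must align")
    if np.any(t == 0.0):
        raise ValueError("truth values must be nonzero")
    return float(np.mean(np.abs(m - t) / np.abs(t)) * 100.0)


def error_table(results: pd.DataFrame) -> pd.DataFrame:
    """Wavelength-averaged error summary over SPF and polarization.

    ``results`` needs columns ``spf``, ``polarization``, ``channel``,
    ``quantity``, ``mape`` and optionally ``omitted``; omitted channels are
    excluded from the average over channels.  Returns a table with one row
    per SPF and one column per quantity-polarization pair.  A pure function
    of its input: rerunning on the same frame reproduces the table exactly.
    """
    required = {"spf", "polarization", "channel", "quantity", "mape"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results frame lacks columns: {sorted(missing)}")
    frame = results.copy()
    if "omitted" in frame.columns:
        frame = frame[~frame["omitted"].astype(bool)]
    table = frame.pivot_table(
        index="spf",
        columns=["quantity", "polarization"],
        values="mape",
        aggfunc="mean",
    )
    return table.sort_index(axis=1)


def spectral_weighted_average(spectrum, led_profile) -> float:
    """LED-spectrum-weighted average: ``sum(w s) / sum(w)``.

    ``spectrum`` and ``led_profile`` must be aligned on the same wavelength
    grid; weights must be non-negative and not all zero.
    """
    s = np.asarray(spectrum, dtype=float)
    w = np.asarray(led_profile, dtype=float)
    if s.shape != w.shape:
        raise ValueError("spectrum and LED profile grids are misaligned")
    if np.any(w < 0.0) or w.sum() == 0.0:
        raise ValueError("weights must be non-negative and not all zero")
    return float(np.sum(w * s) / np.sum(w))
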