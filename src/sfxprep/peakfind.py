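"""Bragg-peak candidate search and crystal hit classification.

The hit finder scans a corrected frame in row-major order for pixels above an
ADU threshold that are the maximum of a surrounding (2h+1)×(2h+1) box.  The
box background is estimated robustly: pixels whose signal-to-noise ratio
(x − mean)/std exceeds ``snr_background`` are stripped and the statistics
recomputed until stable.  Pixels in the box that then exceed ``snr_peak``
and are 8-connected to the seed form the candidate peak; candidates with at
least ``min_npix`` member pixels are recorded in a variable-row table with
their intensity-weighted centroid, seed index, maximum pixel value,
background-subtracted integrated intensity and pixel count.  An event is a
crystal *hit* when its peak count lies in a user-selected range.

Conventions: ties for the box maximum are resolved to the first pixel in
row-major order; boxes that would cross the frame edge are skipped; masked
pixels never seed a peak, never join one, and never enter box statistics;
pixels already belonging to an accepted peak cannot seed another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PeakFinderParams",
    "PEAK_DTYPE",
    "find_peaks",
    "count_peaks",
    "is_hit",
    "saturation_ratio",
    "SaturationStats",
    "hit_rate",
    "STD_FLOOR",
]

#: background standard deviation floor (ADU) for SNR tests
STD_FLOOR = 1e-6

#: one row per accepted Bragg-peak candidate
PEAK_DTYPE = np.dtype([
    ("centroid_row", np.float64),
    ("centroid_col", np.float64),
    ("center_index", np.int64),
    ("max_value", np.float64),
    ("integrated", np.float64),
    ("npix", np.int64),
])


@dataclass(frozen=True)
class PeakFinderParams:
    """Tunable knobs of the SNR peak finder.

    Defaults suit a quiet detector with a few-ADU noise floor; threshold and
    box size depend strongly on crystal size and beam intensity and should be
    revisited per experiment and sample.
    """

    pixel_threshold: float = 20.0
    box_half_width: int = 5
    snr_background: float = 3.0
    snr_peak: float = 3.0
    min_npix: int = 4
    hit_range: tuple[float, float] = (1.0, math.inf)
    saturation_threshold: float = 16000.0

    def __post_init__(self) -> None:
        if self.box_half_width < 1:
            raise ValueError("box_half_width must be >= 1")
        if self.min_npix < 1:
            raise ValueError("min_npix must be >= 1")
        if self.hit_range[0] > self.hit_range[1]:
            raise ValueError("hit_range lower bound exceeds upper bound")


def _background_stats(values: np.ndarray, snr: float) -> tuple[float, float]:
    """Iteratively strip high outliers and return background (mean, std)."""
    vals = values
    while vals.size:
        mean = float(vals.mean())
        std = float(vals.std())
        keep = (vals - mean) <= snr * max(std, STD_FLOOR)
        if keep.all():
            return mean, std
        if not keep.any():
            return mean, std
        vals = vals[keep]
    return 0.0, 0.0


def find_peaks(
    frame: np.ndarray,
    params: PeakFinderParams,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Locate Bragg-peak candidates; returns a structured :data:`PEAK_DTYPE` array.

    ``mask`` marks bad pixels (nonzero = bad); they are excluded from
    seeding, membership and background statistics.  Boxes that do not fit
    entirely inside the frame are skipped, not an error.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError(f"frame must be 2D, got shape {frame.shape}")
    nrows, ncols = frame.shape
    if mask is None:
        bad = np.zeros(frame.shape, dtype=bool)
    else:
        bad = np.asarray(mask).astype(bool)
        if bad.shape != frame.shape:
            raise ValueError("mask shape does not match frame shape")
    if not np.isfinite(frame[~bad]).all():
        raise ValueError("frame contains non-finite values on unmasked pixels")

    h = params.box_half_width
    used = np.zeros(frame.shape, dtype=bool)
    rows: list[tuple] = []

    cand_r, cand_c = np.nonzero((frame > params.pixel_threshold) & ~bad)
    for r, c in zip(cand_r.tolist(), cand_c.tolist()):
        if used[r, c]:
            continue
        if r - h < 0 or r + h >= nrows or c - h < 0 or c + h >= ncols:
            continue
        box = frame[r - h: r + h + 1, c - h: c + h + 1]
        box_good = ~bad[r - h: r + h + 1, c - h: c + h + 1]
        vals = box[box_good]
        vmax = vals.max()
        centre = frame[r, c]
        if centre < vmax:
            continue
        # tie-break: the first row-major box pixel attaining the maximum wins
        at_max = (box == vmax) & box_good
        first = np.transpose(np.nonzero(at_max))[0]
        if (first[0], first[1]) != (h, h):
            continue

        mean, std = _background_stats(vals, params.snr_background)
        std = max(std, STD_FLOOR)

        above = ((box - mean) / std > params.snr_peak) & box_good
        labels, _ = ndimage.label(above, structure=np.ones((3, 3), dtype=int))
        seed_label = labels[h, h]
        if seed_label == 0:
            continue
        member = labels == seed_label
        npix = int(member.sum())
        if npix < params.min_npix:
            continue

        mr, mc = np.nonzero(member)
        w = box[member] - mean
        wsum = float(w.sum())
        centroid_row = float(((mr + r - h) * w).sum() / wsum)
        centroid_col = float(((mc + c - h) * w).sum() / wsum)
        rows.append((
            centroid_row,
            centroid_col,
            r * ncols + c,
            float(box[member].max()),
            wsum,
            npix,
        ))
        used[r - h + mr, c - h + mc] = True

    return np.array(rows, dtype=PEAK_DTYPE)


def count_peaks(table: np.ndarray) -> int:
    """Number of Bragg-peak candidates, i.e. rows of the table."""
    return len(table)


def is_hit(n_peaks: int, hit_range: tuple[float, float]) -> bool:
    """True when the peak count lies in the inclusive ``hit_range``."""
    lo, hi = hit_range
    return lo <= n_peaks <= hi


@dataclass(frozen=True)
class SaturationStats:
    n_saturated: int
    n_total: int
    ratio: float  # NaN when the table is empty


def saturation_ratio(table: np.ndarray, saturation_threshold: float) -> SaturationStats:
    """Fraction of peaks whose brightest pixel exceeds the saturation level.

    An empty table yields a NaN ratio (undefined), never 0.
    """
    n_total = len(table)
    if n_total == 0:
        return SaturationStats(0, 0, math.nan)
    n_sat = int((table["max_value"] > saturation_threshold).sum())
    return SaturationStats(n_sat, n_total, n_sat / n_total)


def hit_rate(flags, window: int) -> float:
    """Fraction of hits among the most recent ``window`` events.

    With fewer events than ``window``, the fraction over all available events
    is returned; no events at all yields NaN.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    recent = list(flags)[-window:]
    if not recent:
        return math.nan
    return sum(bool(f) for f in recent) / len(recent)
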