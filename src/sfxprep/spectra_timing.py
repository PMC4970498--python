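"""Worked per-shot analysis chains: fluorescence spectra and timing-tool delays.

Fluorescence: a dispersive detector records single-photon events whose ADU
values fall in a narrow window (for the Fe Kβ region about 18–50 ADU at one
photon per pixel).  Pixels outside the window are zeroed and the region of
interest is projected onto the column axis, normalized to the number of
surviving pixels per column — the live spectrum of the target.

Timing tool: an optical spectrum is chirped across a camera; the FEL shot
burns a step into it whose spectral (column) position encodes the relative
FEL/laser arrival time.  The chain projects the signal band, subtracts a
local background band, normalizes against a reference (laser-only) trace,
convolves with an edge-matched kernel and reports the argmax column, which a
linear calibration turns into a femtosecond delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectrumChainParams",
    "TimingChainParams",
    "Spectrum",
    "fluorescence_spectrum",
    "timing_edge",
    "delay_correct",
]


@dataclass(frozen=True)
class SpectrumChainParams:
    """ADU acceptance window and detector region of interest.

    ``roi_rows``/``roi_cols`` are half-open (lo, hi) index intervals of the
    dispersive detector area.
    """

    adu_low: float = 18.0
    adu_high: float = 50.0
    roi_rows: tuple[int, int] | None = None
    roi_cols: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.adu_low < self.adu_high:
            raise ValueError("adu_low must be < adu_high")


@dataclass(frozen=True)
class TimingChainParams:
    """Signal/background row bands, laser-only reference trace and filter kernel."""

    signal_rows: tuple[int, int]
    background_rows: tuple[int, int]
    reference: np.ndarray = field(repr=False)
    kernel: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        s0, s1 = self.signal_rows
        b0, b1 = self.background_rows
        if max(s0, b0) < min(s1, b1):
            raise ValueError("signal and background row intervals must be disjoint")
        if (s1 - s0) != (b1 - b0):
            raise ValueError("signal and background intervals must have equal width")


@dataclass
class Spectrum:
    """Per-column spectrum values and the surviving-pixel counts behind them."""

    values: np.ndarray
    counts: np.ndarray


def fluorescence_spectrum(frame: np.ndarray, params: SpectrumChainParams) -> Spectrum:
    """Extract the single-photon fluorescence spectrum from a corrected frame.

    Pixels outside [adu_low, adu_high] are set to zero; within the region of
    interest each column's value is the sum of surviving pixels divided by
    their count.  Columns with no survivors are 0 with a recorded count of 0.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    rows = params.roi_rows or (0, frame.shape[0])
    cols = params.roi_cols or (0, frame.shape[1])
    if not (0 <= rows[0] < rows[1] <= frame.shape[0]
            and 0 <= cols[0] < cols[1] <= frame.shape[1]):
        raise ValueError(
            f"roi rows {rows} / cols {cols} outside frame of shape {frame.shape}"
        )
    roi = frame[rows[0]: rows[1], cols[0]: cols[1]]
    in_range = (roi >= params.adu_low) & (roi <= params.adu_high)
    counts = in_range.sum(axis=0)
    sums = np.where(in_range, roi, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, sums / counts, 0.0)
    return Spectrum(values=values, counts=counts.astype(np.int64))


def timing_edge(image: np.ndarray, params: TimingChainParams) -> int:
    """Column position of the FEL-induced spectral edge in a timing-tool image.

    Steps: (a) column-project the signal band and subtract the projected
    local-background band; (b) subtract the laser-only reference and divide
    by it; (c) convolve with the filter kernel (same-length, zero-padded);
    (d) return the argmax column, first index on ties.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("timing image must be 2D")
    s0, s1 = params.signal_rows
    b0, b1 = params.background_rows
    if not (0 <= s0 < s1 <= image.shape[0] and 0 <= b0 < b1 <= image.shape[0]):
        raise ValueError("signal/background rows outside the image")
    ref = np.asarray(params.reference, dtype=float)
    if ref.shape != (image.shape[1],):
        raise ValueError(
            f"reference length {ref.shape} does not match projection length "
            f"({image.shape[1]},)"
        )
    zero_cols = np.nonzero(ref == 0)[0]
    if zero_cols.size:
        raise ValueError(
            f"reference contains zeros at column(s) {zero_cols[:10].tolist()}"
        )

    s = image[s0:s1].sum(axis=0) - image[b0:b1].sum(axis=0)
    t = (s - ref) / ref
    c = np.convolve(t, np.asarray(params.kernel, dtype=float), mode="same")
    return int(np.argmax(c))


def delay_correct(
    edge_pixel: float,
    fs_per_pixel: float,
    nominal_delay: float,
    reference_pixel: float = 0.0,
) -> float:
    """Per-shot pump-probe delay (fs) from the timing-tool edge position.

    delay = nominal_delay + fs_per_pixel · (edge_pixel − reference_pixel).
    The calibration slope is an input measured elsewhere, never fitted here.
    """
    return nominal_delay + fs_per_pixel * (edge_pixel - reference_pixel)
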