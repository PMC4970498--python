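"""q-binned radial averaging and single-particle diagnostics.

Projecting an assembled image onto the radius axis produces artefacts at the
gaps between detector tiles: empty regions bias a naive projection.  The
radial average here instead histograms every covered, unmasked pixel's q
value with the pixel value as weight and normalizes each bin by its entry
count, so unpopulated regions simply contribute nothing.

For single-particle work the module also provides a size proxy — the spacing
of the first two nodes (minima) of the radial profile, inversely proportional
to particle size for sphere-like scatterers — plus Cartesian and polar
autocorrelations and the power spectrum used to separate single particles
from clusters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import BeamGeometry, GeometryMap, q_map

__all__ = [
    "RadialProfile",
    "radial_average",
    "find_nodes",
    "node_distance",
    "profile_node_distance",
    "autocorrelate_cartesian",
    "autocorrelate_polar",
    "power_spectrum",
]


@dataclass
class RadialProfile:
    """1D weighted q-histogram: bin edges (Å⁻¹), per-bin mean value, entry counts.

    ``values`` is NaN wherever ``counts`` is zero — empty bins are missing,
    never zero-filled.
    """

    q_edges: np.ndarray
    values: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != len(self.q_edges) - 1 or len(self.counts) != len(self.values):
            raise ValueError("profile arrays are inconsistent with the bin edges")

    @property
    def q_centers(self) -> np.ndarray:
        return 0.5 * (self.q_edges[:-1] + self.q_edges[1:])


def radial_average(
    frame: np.ndarray,
    geom: GeometryMap,
    beam: BeamGeometry,
    mask: np.ndarray | None = None,
    nbins: int = 100,
    q_range: tuple[float, float] | None = None,
) -> RadialProfile:
    """Geometry-aware radial average of a corrected frame.

    Each covered, unmasked raw pixel contributes its value, weighted into the
    uniform half-open q bin containing its q; per-bin values are the weighted
    sums divided by the entry counts.  Pixel order is irrelevant by
    construction.  All pixels masked → all-missing profile with a warning.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != geom.raw_shape:
        raise ValueError(f"frame shape {frame.shape} != raw layout {geom.raw_shape}")
    good = geom.covered
    if mask is not None:
        good = good & ~np.asarray(mask).astype(bool)

    q = q_map(geom, beam)
    if q_range is None:
        if good.any():
            q_range = (0.0, float(np.nanmax(q[good])) * (1 + 1e-12))
        else:
            q_range = (0.0, 1.0)
    if not q_range[1] > q_range[0]:
        raise ValueError(f"invalid q_range {q_range}")

    qs = q[good]
    ws = frame[good]
    wsum, edges = np.histogram(qs, bins=nbins, range=q_range, weights=ws)
    counts, _ = np.histogram(qs, bins=nbins, range=q_range)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, wsum / counts, np.nan)
    if not good.any():
        warnings.warn("all pixels masked: radial profile is entirely missing")
    return RadialProfile(q_edges=edges, values=values, counts=counts)


def find_nodes(
    trace: np.ndarray,
    search_range: tuple[int, int] | None = None,
    smooth: bool = False,
) -> np.ndarray:
    """Indices of strict local minima of a 1D trace, ascending.

    ``search_range`` restricts the reported indices to [lo, hi); ``smooth``
    applies a centred 3-point moving average first.  Traces shorter than 3
    have no interior minima.  NaN samples never qualify and never support a
    neighbour.
    """
    t = np.asarray(trace, dtype=float)
    if t.ndim != 1:
        raise ValueError("trace must be 1D")
    if t.size < 3:
        return np.array([], dtype=np.int64)
    if smooth:
        kernel = np.ones(3) / 3.0
        finite = np.isfinite(t)
        padded = np.where(finite, t, 0.0)
        norm = np.convolve(finite.astype(float), kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(norm > 0, np.convolve(padded, kernel, mode="same") / norm, np.nan)
    interior = np.arange(1, t.size - 1)
    ok = (t[interior] < t[interior - 1]) & (t[interior] < t[interior + 1])
    nodes = interior[ok]
    if search_range is not None:
        lo, hi = search_range
        nodes = nodes[(nodes >= lo) & (nodes < hi)]
    return nodes.astype(np.int64)


def node_distance(trace: np.ndarray, smooth: bool = False) -> float:
    """Spacing (in samples) of the first two nodes of a trace; NaN if < 2 nodes."""
    nodes = find_nodes(trace, smooth=smooth)
    if nodes.size < 2:
        return math.nan
    return float(nodes[1] - nodes[0])


def profile_node_distance(profile: RadialProfile, units: str = "bins", smooth: bool = False) -> float:
    """Node spacing of a radial profile in bin indices or in q (Å⁻¹)."""
    nodes = find_nodes(profile.values, smooth=smooth)
    if nodes.size < 2:
        return math.nan
    if units == "bins":
        return float(nodes[1] - nodes[0])
    if units == "q":
        centers = profile.q_centers
        return float(centers[nodes[1]] - centers[nodes[0]])
    raise ValueError(f"units must be 'bins' or 'q', got {units!r}")


def autocorrelate_cartesian(image: np.ndarray) -> np.ndarray:
    """Circular 2D autocorrelation via FFT; zero shift at index (0, 0).

    The zero-shift cell equals Σx² and the result is symmetric under point
    inversion (modulo the periodic wrap).  Boundary handling is periodic.
    """
    image = np.asarray(image, dtype=float)
    f = np.fft.fft2(image)
    return np.real(np.fft.ifft2(f * np.conj(f)))


def autocorrelate_polar(
    image: np.ndarray,
    center: tuple[float, float],
    nradii: int = 64,
    nangles: int = 180,
    rmax: float | None = None,
) -> np.ndarray:
    """Per-radius circular autocorrelation over the azimuth.

    The image is resampled onto an (nradii × nangles) polar grid by bilinear
    interpolation around ``center`` (row, col), then each radius row is
    autocorrelated circularly over the angle axis.  A circularly symmetric
    image therefore gives a flat angular autocorrelation at every radius; an
    n-fold symmetric one gives peaks every 2π/n of angular lag.
    """
    image = np.asarray(image, dtype=float)
    cr, cc = center
    if rmax is None:
        rmax = min(cr, cc, image.shape[0] - 1 - cr, image.shape[1] - 1 - cc)
    radii = np.linspace(0.0, rmax, nradii)
    angles = np.linspace(0.0, 2.0 * np.pi, nangles, endpoint=False)
    rr = radii[:, None] * np.ones_like(angles)[None, :]
    aa = np.ones_like(radii)[:, None] * angles[None, :]
    coords = np.stack([cr + rr * np.sin(aa), cc + rr * np.cos(aa)])
    polar = ndimage.map_coordinates(image, coords, order=1, mode="constant", cval=0.0)
    f = np.fft.fft(polar, axis=1)
    return np.real(np.fft.ifft(f * np.conj(f), axis=1))


def power_spectrum(image: np.ndarray) -> np.ndarray:
    """Squared modulus of the 2D DFT, zero frequency shifted to the centre."""
    image = np.asarray(image, dtype=float)
    return np.abs(np.fft.fftshift(np.fft.fft2(image))) ** 2
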