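"""Synthetic detector data with known ground truth.

Every input class the reduction chains consume can be generated here with a
recorded truth object, so the whole package is testable without downloads:
dark runs with per-pixel Gaussian statistics plus cosmic-like spikes, frames
with injected Gaussian Bragg spots, isotropic scattering rings, sphere
form-factor patterns with closed-form minima, timing-tool camera images with
a spectral step edge, and single-photon fluorescence frames.

All generators are pure functions of their parameters and a seed
(numpy ``default_rng``); generators needing several independent streams split
them from one ``SeedSequence`` spawned off the seed.  Defaults model a quiet
integrating pixel detector: pedestals of 50–150 ADU, noise of 1–5 ADU,
Bragg spots of 30–150 ADU on a 3 ADU background, one photon ≈ 30 ADU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import BeamGeometry, GeometryMap, build_geometry_map, GeometryPanel, q_map

__all__ = [
    "DarkRunTruth",
    "BraggTruth",
    "TimingTruth",
    "gen_dark_run",
    "gen_bragg_frame",
    "gen_ring_frame",
    "gen_sphere_frame",
    "gen_timing_image",
    "gen_fluorescence_frame",
    "simple_geometry",
    "simple_geometry_text",
]


def simple_geometry_text(shape: tuple[int, int], pixel_size: float = 1e-4,
                         center: tuple[float, float] | None = None) -> str:
    """CrystFEL geometry text for one axis-aligned panel.

    ``center`` is the beam position in pixel units (row, col); default is the
    frame centre.  Useful both as a parser fixture and as a quick real
    geometry for synthetic scattering frames.
    """
    nrows, ncols = shape
    if center is None:
        center = ((nrows - 1) / 2.0, (ncols - 1) / 2.0)
    cr, cc = center
    return (
        f"panel0/min_fs = 0\n"
        f"panel0/max_fs = {ncols - 1}\n"
        f"panel0/min_ss = 0\n"
        f"panel0/max_ss = {nrows - 1}\n"
        f"panel0/corner_x = {-cc}\n"
        f"panel0/corner_y = {-cr}\n"
        f"panel0/fs = +1.0x\n"
        f"panel0/ss = +1.0y\n"
        f"panel0/res = {1.0 / pixel_size}\n"
    )


def simple_geometry(shape: tuple[int, int], pixel_size: float = 1e-4,
                    center: tuple[float, float] | None = None) -> GeometryMap:
    """Single-panel :class:`GeometryMap` with the beam at ``center`` (pixels)."""
    nrows, ncols = shape
    if center is None:
        center = ((nrows - 1) / 2.0, (ncols - 1) / 2.0)
    cr, cc = center
    panel = GeometryPanel(
        name="panel0",
        min_fs=0, max_fs=ncols - 1, min_ss=0, max_ss=nrows - 1,
        fs_vec=(1.0, 0.0), ss_vec=(0.0, 1.0),
        corner_x=-cc, corner_y=-cr,
        pixel_size=pixel_size,
    )
    return build_geometry_map([panel])


@dataclass
class DarkRunTruth:
    """Generating parameters of a synthetic dark run."""

    mu: np.ndarray
    sigma: np.ndarray
    spike_mask: np.ndarray = field(repr=False)  # (n_frames, *shape) bool
    bad_pixels: np.ndarray = field(repr=False)  # bool map of 10x-offset pixels
    seed: int = 0


def gen_dark_run(
    shape: tuple[int, int] = (64, 64),
    mu_range: tuple[float, float] = (50.0, 150.0),
    sigma_range: tuple[float, float] = (1.0, 5.0),
    n_frames: int = 200,
    outlier_fraction: float = 0.001,
    bad_fraction: float = 0.0,
    spike_value: float = 1000.0,
    seed: int = 0,
) -> tuple[np.ndarray, DarkRunTruth]:
    """Dark frames: per-pixel Gaussian noise around a fixed pedestal.

    Per-pixel µ ~ U(mu_range) and σ ~ U(sigma_range) are drawn once; a
    fraction ``outlier_fraction`` of pixel-events is replaced by cosmic-like
    spikes (pedestal + ``spike_value``).  ``bad_fraction`` of pixels get a
    10× pedestal, emulating broken pixels for mask checks.
    """
    ss = np.random.SeedSequence(seed)
    rng_map, rng_noise, rng_spike = (np.random.default_rng(s) for s in ss.spawn(3))
    mu = rng_map.uniform(*mu_range, size=shape)
    sigma = rng_map.uniform(*sigma_range, size=shape)
    bad = np.zeros(shape, dtype=bool)
    if bad_fraction > 0:
        n_bad = max(1, int(round(bad_fraction * mu.size)))
        idx = rng_map.choice(mu.size, size=n_bad, replace=False)
        bad.ravel()[idx] = True
        mu = np.where(bad, mu * 10.0, mu)

    frames = mu[None] + rng_noise.normal(0.0, 1.0, size=(n_frames, *shape)) * sigma[None]
    spikes = rng_spike.random((n_frames, *shape)) < outlier_fraction
    frames = np.where(spikes, mu[None] + spike_value, frames)
    return frames, DarkRunTruth(mu=mu, sigma=sigma, spike_mask=spikes,
                                bad_pixels=bad, seed=seed)


@dataclass
class BraggTruth:
    """Injected-spot parameters of a synthetic Bragg frame."""

    centers: np.ndarray  # (n, 2) float (row, col)
    amplitudes: np.ndarray
    widths: np.ndarray  # (n, 2) float (sigma_row, sigma_col)
    background_sigma: float
    seed: int = 0


def gen_bragg_frame(
    shape: tuple[int, int] = (48, 48),
    n_peaks: int = 5,
    amplitude_range: tuple[float, float] = (30.0, 150.0),
    width_range: tuple[float, float] = (0.8, 1.5),
    background_sigma: float = 3.0,
    margin: int = 7,
    min_separation: float = 12.0,
    seed: int = 0,
) -> tuple[np.ndarray, BraggTruth]:
    """Frame with non-overlapping 2D Gaussian spots on Gaussian noise.

    Spot centres keep ``margin`` pixels from the edges (so the peak finder's
    box always fits) and ``min_separation`` pixels from each other (so no
    two spots share a box).
    """
    ss = np.random.SeedSequence(seed)
    rng_pos, rng_par, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))
    nrows, ncols = shape
    if n_peaks > 0 and (nrows <= 2 * margin or ncols <= 2 * margin):
        raise ValueError("frame too small for the requested margin")

    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_peaks:
        attempts += 1
        if attempts > 1000 * max(n_peaks, 1):
            raise ValueError("cannot place non-overlapping peaks; relax the parameters")
        r = rng_pos.uniform(margin, nrows - 1 - margin)
        c = rng_pos.uniform(margin, ncols - 1 - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_separation**2 for r0, c0 in centers):
            centers.append((r, c))

    amps = rng_par.uniform(*amplitude_range, size=n_peaks)
    widths = rng_par.uniform(*width_range, size=(n_peaks, 2))
    frame = rng_noise.normal(0.0, background_sigma, size=shape)
    rr, cc = np.mgrid[0:nrows, 0:ncols]
    for (r0, c0), a, (sr, sc) in zip(centers, amps, widths):
        frame += a * np.exp(-((rr - r0) ** 2 / (2 * sr**2) + (cc - c0) ** 2 / (2 * sc**2)))
    truth = BraggTruth(
        centers=np.array(centers).reshape(-1, 2),
        amplitudes=amps,
        widths=widths,
        background_sigma=background_sigma,
        seed=seed,
    )
    return frame, truth


def gen_ring_frame(
    geom: GeometryMap,
    beam: BeamGeometry,
    q0: float,
    width: float,
    value: float = 100.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Isotropic ring: pixels with q within q0 ± width set to ``value``.

    Optional Gaussian noise on top; pixels outside the ring are zero (plus
    noise).  Off-panel pixels are NaN.
    """
    q = q_map(geom, beam)
    frame = np.where(np.abs(q - q0) <= width, value, 0.0)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        frame = frame + rng.normal(0.0, noise_sigma, size=frame.shape)
    return np.where(geom.covered, frame, np.nan)


def gen_sphere_frame(
    geom: GeometryMap,
    beam: BeamGeometry,
    diameter: float,
    intensity: float = 1000.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Sphere form-factor pattern: I(q) = I₀·[3(sin qR − qR cos qR)/(qR)³]².

    ``diameter`` is in ångström (R = diameter/2), consistent with the Å⁻¹ q
    axis, so the first minimum sits at qR ≈ 4.493 (the first positive root
    of tan x = x) and doubling the diameter halves every minimum position.
    """
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    q = q_map(geom, beam)
    x = q * (diameter / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(x > 1e-8, 3.0 * (np.sin(x) - x * np.cos(x)) / x**3, 1.0)
    frame = intensity * f**2
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        frame = frame + rng.normal(0.0, noise_sigma, size=frame.shape)
    return np.where(geom.covered, frame, np.nan)


@dataclass
class TimingTruth:
    """Ground truth of a synthetic timing-tool image."""

    edge_col: int
    depth: float
    signal_rows: tuple[int, int]
    background_rows: tuple[int, int]
    seed: int = 0


def gen_timing_image(
    shape: tuple[int, int] = (64, 1024),
    edge_col: int = 512,
    depth: float = 0.3,
    noise_sigma: float = 0.0,
    signal_rows: tuple[int, int] = (8, 24),
    background_rows: tuple[int, int] = (40, 56),
    kernel_sigma: float = 3.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, TimingTruth]:
    """Timing-tool camera image with a step edge burnt into the spectrum.

    Returns (image, reference, kernel, truth).  The reference is the
    laser-only projection of the signal band (strictly positive, smooth);
    the signal band is the reference profile scaled down by ``depth`` from
    ``edge_col`` onward; the kernel is x·exp(−x²/2σ²), matched so the
    convolved normalized trace peaks at the edge.  ``noise_sigma`` is per
    pixel, in units of the row profile.
    """
    nrows, ncols = shape
    if not 0 <= edge_col < ncols:
        raise ValueError(f"edge_col {edge_col} outside the image width {ncols}")
    s0, s1 = signal_rows
    b0, b1 = background_rows
    if not (0 <= s0 < s1 <= nrows and 0 <= b0 < b1 <= nrows):
        raise ValueError("signal/background rows outside the image")

    cols = np.arange(ncols)
    # broad, strictly positive optical spectrum
    row_profile = 50.0 + 100.0 * np.exp(-((cols - ncols / 2.0) / (ncols / 3.0)) ** 2)
    step = 1.0 - depth * (cols >= edge_col)

    rng = np.random.default_rng(seed)
    image = np.zeros(shape)
    image[s0:s1] = row_profile * step
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, size=shape)
    reference = (s1 - s0) * row_profile

    x = np.arange(-int(3 * kernel_sigma), int(3 * kernel_sigma) + 1, dtype=float)
    kernel = x * np.exp(-(x**2) / (2.0 * kernel_sigma**2))
    truth = TimingTruth(edge_col=edge_col, depth=depth, signal_rows=signal_rows,
                        background_rows=background_rows, seed=seed)
    return image, reference, kernel, truth


def gen_fluorescence_frame(
    shape: tuple[int, int],
    rate_map: np.ndarray,
    adu_per_photon: float = 30.0,
    noise_sigma: float = 3.0,
    seed: int = 0,
) -> np.ndarray:
    """Single-photon fluorescence frame: Poisson photons plus Gaussian noise.

    ``rate_map`` is the per-pixel expected photon count (broadcastable to
    ``shape``); each photon deposits ``adu_per_photon`` ADU.
    """
    rate = np.broadcast_to(np.asarray(rate_map, dtype=float), shape)
    if (rate < 0).any():
        raise ValueError("photon rates must be >= 0")
    ss = np.random.SeedSequence(seed)
    rng_ph, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    photons = rng_ph.poisson(rate)
    return photons * adu_per_photon + rng_noise.normal(0.0, noise_sigma, size=shape)
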