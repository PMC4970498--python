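"""CrystFEL-style detector geometry: parsing, lab-frame assembly, q and resolution.

Multi-panel pixel detectors (CSPAD and relatives) deliver their data in a *raw
layout* that bears no resemblance to the physical arrangement of the panels
around the beam.  A plain-text geometry description maps each raw-layout slab
onto the laboratory frame through a corner position and two in-plane basis
vectors (the fast-scan and slow-scan directions).  This module parses that
description, assembles raw frames into lab-frame images by nearest-cell
placement, and converts detector radii into momentum transfer q and Bragg
d-spacing.

Conventions used throughout: raw and lab indices are 0-based and row-major;
the slow-scan index is the raw row, the fast-scan index the raw column; lab y
increases with row index; the direct beam pierces the lab frame at
(x, y) = (0, 0).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeometryPanel",
    "GeometryMap",
    "BeamGeometry",
    "GeometryError",
    "GeometryParseError",
    "parse_geometry",
    "assemble",
    "q_of",
    "resolution_of",
    "pixel_radius_map",
    "q_map",
    "resolution_map",
]


class GeometryError(ValueError):
    """Invalid or inconsistent geometry (overlap, collision, bad vectors)."""


class GeometryParseError(GeometryError):
    """Malformed geometry text; message names the panel and line."""


@dataclass(frozen=True)
class GeometryPanel:
    """One rectangular raw-layout slab and its placement in the lab frame.

    ``fs_vec``/``ss_vec`` are the lab-frame (x, y) displacements, in pixel
    units, produced by one step along the fast-scan / slow-scan axis.
    ``corner_x``/``corner_y`` locate the centre of the panel's first pixel
    (min_fs, min_ss), again in pixel units relative to the beam axis.
    ``pixel_size`` is metres per pixel (the reciprocal of the geometry file's
    ``res`` entry); ``coffset`` is an additive detector-distance offset.
    """

    name: str
    min_fs: int
    max_fs: int
    min_ss: int
    max_ss: int
    fs_vec: tuple[float, float]
    ss_vec: tuple[float, float]
    corner_x: float
    corner_y: float
    pixel_size: float
    coffset: float = 0.0

    def __post_init__(self) -> None:
        if self.max_fs < self.min_fs or self.max_ss < self.min_ss:
            raise GeometryError(
                f"panel {self.name!r}: max_fs/max_ss must be >= min_fs/min_ss"
            )
        if self.pixel_size <= 0:
            raise GeometryError(f"panel {self.name!r}: pixel_size must be > 0")
        fx, fy = self.fs_vec
        sx, sy = self.ss_vec
        cross = fx * sy - fy * sx
        if math.hypot(fx, fy) == 0 or math.hypot(sx, sy) == 0 or cross == 0:
            raise GeometryError(
                f"panel {self.name!r}: fs/ss vectors are degenerate "
                f"(zero or parallel): fs={self.fs_vec}, ss={self.ss_vec}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        """(n_ss, n_fs) slab shape."""
        return (self.max_ss - self.min_ss + 1, self.max_fs - self.min_fs + 1)


@dataclass
class GeometryMap:
    """Per-pixel lab-frame placement for a whole detector.

    ``x_map``/``y_map`` hold lab coordinates in metres for every
    panel-covered raw pixel and NaN elsewhere; ``coffset_map`` carries the
    per-pixel detector-distance offset.  ``lab_row``/``lab_col`` are the
    integer lab-frame cells each covered raw pixel is assembled into.
    """

    panels: list[GeometryPanel]
    raw_shape: tuple[int, int]
    lab_shape: tuple[int, int]
    x_map: np.ndarray
    y_map: np.ndarray
    coffset_map: np.ndarray
    lab_row: np.ndarray = field(repr=False)
    lab_col: np.ndarray = field(repr=False)

    @property
    def covered(self) -> np.ndarray:
        """Boolean map of panel-covered raw pixels."""
        return np.isfinite(self.x_map)


@dataclass(frozen=True)
class BeamGeometry:
    """Photon wavelength (ångström) and sample-detector distance (metres).

    The lab-frame origin (0, 0) is the direct-beam axis.
    """

    wavelength: float
    detector_distance: float

    def __post_init__(self) -> None:
        if not self.wavelength > 0:
            raise ValueError(f"wavelength must be > 0, got {self.wavelength}")
        if not self.detector_distance > 0:
            raise ValueError(
                f"detector_distance must be > 0, got {self.detector_distance}"
            )


# keys we understand inside a panel block
_PANEL_KEYS = {
    "fs", "ss", "corner_x", "corner_y",
    "min_fs", "max_fs", "min_ss", "max_ss",
    "res", "coffset",
}
_REQUIRED_KEYS = {"fs", "ss", "corner_x", "corner_y",
                  "min_fs", "max_fs", "min_ss", "max_ss", "res"}

_VEC_TOKEN = re.compile(r"([+-]?\d*\.?\d*(?:[eE][+-]?\d+)?)\s*([xyz])")


def _parse_axis_vector(value: str, panel: str, key: str, lineno: int) -> tuple[float, float]:
    """Parse a direction like ``+1.0x -0.002y`` into an (x, y) tuple."""
    comps = {"x": 0.0, "y": 0.0, "z": 0.0}
    matched = False
    for m in _VEC_TOKEN.finditer(value):
        coeff, axis = m.group(1), m.group(2)
        if coeff in ("", "+"):
            c = 1.0
        elif coeff == "-":
            c = -1.0
        else:
            c = float(coeff)
        comps[axis] += c
        matched = True
    if not matched:
        raise GeometryParseError(
            f"panel {panel!r}, line {lineno}: cannot parse {key} vector {value!r}"
        )
    if comps["z"] != 0.0:
        logger.warning(
            "panel %r: ignoring z component of %s vector (planar geometry only)",
            panel, key,
        )
    return (comps["x"], comps["y"])


def parse_geometry(text: str) -> GeometryMap:
    """Parse CrystFEL geometry-file text into a :class:`GeometryMap`.

    Supports the minimal panel dialect: ``NAME/KEY = VALUE`` lines with keys
    fs, ss, corner_x, corner_y, min_fs/max_fs/min_ss/max_ss, res and coffset.
    Bare ``KEY = VALUE`` lines set defaults inherited by every panel.  Unknown
    keys are ignored with a logged warning; a panel block missing a required
    key raises :class:`GeometryParseError` naming the panel and line.
    """
    defaults: dict[str, tuple[str, int]] = {}
    blocks: dict[str, dict[str, tuple[str, int]]] = {}

    for lineno, raw_line in enumerate(text.splitlines(), start=1):
        line = raw_line.split(";", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise GeometryParseError(f"line {lineno}: expected 'key = value': {raw_line!r}")
        key_part, value = (s.strip() for s in line.split("=", 1))
        if "/" in key_part:
            panel, key = key_part.split("/", 1)
            panel, key = panel.strip(), key.strip()
            if key not in _PANEL_KEYS:
                logger.warning("line %d: ignoring unknown panel key %r", lineno, key_part)
                continue
            blocks.setdefault(panel, {})[key] = (value, lineno)
        else:
            if key_part not in _PANEL_KEYS:
                logger.warning("line %d: ignoring unknown key %r", lineno, key_part)
                continue
            defaults[key_part] = (value, lineno)

    if not blocks:
        raise GeometryParseError("no panel blocks found in geometry text")

    panels: list[GeometryPanel] = []
    for name, entries in blocks.items():
        merged = dict(defaults)
        merged.update(entries)
        missing = _REQUIRED_KEYS - set(merged)
        if missing:
            raise GeometryParseError(
                f"panel {name!r}: missing required key(s) {sorted(missing)}"
            )

        def _num(key: str, cast=float):
            value, lineno = merged[key]
            try:
                return cast(value)
            except ValueError as exc:
                raise GeometryParseError(
                    f"panel {name!r}, line {lineno}: bad value for {key}: {value!r}"
                ) from exc

        fs_value, fs_line = merged["fs"]
        ss_value, ss_line = merged["ss"]
        panels.append(
            GeometryPanel(
                name=name,
                min_fs=_num("min_fs", int),
                max_fs=_num("max_fs", int),
                min_ss=_num("min_ss", int),
                max_ss=_num("max_ss", int),
                fs_vec=_parse_axis_vector(fs_value, name, "fs", fs_line),
                ss_vec=_parse_axis_vector(ss_value, name, "ss", ss_line),
                corner_x=_num("corner_x"),
                corner_y=_num("corner_y"),
                pixel_size=1.0 / _num("res"),
                coffset=_num("coffset") if "coffset" in merged else 0.0,
            )
        )

    return build_geometry_map(panels)


def build_geometry_map(panels: list[GeometryPanel]) -> GeometryMap:
    """Compute per-pixel lab coordinates and assembly targets from panels.

    Raises :class:`GeometryError` when panel slabs overlap in the raw layout
    or when two raw pixels would collide in one assembled lab cell.
    """
    n_ss = max(p.max_ss for p in panels) + 1
    n_fs = max(p.max_fs for p in panels) + 1
    raw_shape = (n_ss, n_fs)

    x_map = np.full(raw_shape, np.nan)
    y_map = np.full(raw_shape, np.nan)
    coffset_map = np.full(raw_shape, np.nan)
    owner = np.full(raw_shape, -1, dtype=np.int32)

    for idx, p in enumerate(panels):
        sl = (slice(p.min_ss, p.max_ss + 1), slice(p.min_fs, p.max_fs + 1))
        if (owner[sl] != -1).any():
            other = panels[int(owner[sl][owner[sl] != -1][0])].name
            raise GeometryError(
                f"panel {p.name!r} overlaps panel {other!r} in the raw layout"
            )
        owner[sl] = idx
        i_ss, i_fs = np.mgrid[0: p.max_ss - p.min_ss + 1, 0: p.max_fs - p.min_fs + 1]
        x_pix = p.corner_x + i_fs * p.fs_vec[0] + i_ss * p.ss_vec[0]
        y_pix = p.corner_y + i_fs * p.fs_vec[1] + i_ss * p.ss_vec[1]
        x_map[sl] = x_pix * p.pixel_size
        y_map[sl] = y_pix * p.pixel_size
        coffset_map[sl] = p.coffset

    covered = np.isfinite(x_map)
    # lab grid in pixel units: nearest-cell rounding relative to the global
    # minimum, one spare cell of margin on each side is unnecessary since the
    # grid is sized to the rounded extent itself
    px = np.full(raw_shape, np.nan)
    py = np.full(raw_shape, np.nan)
    for idx, p in enumerate(panels):
        sel = owner == idx
        px[sel] = x_map[sel] / p.pixel_size
        py[sel] = y_map[sel] / p.pixel_size

    col = np.rint(px[covered] - np.nanmin(px)).astype(np.int64)
    row = np.rint(py[covered] - np.nanmin(py)).astype(np.int64)
    lab_shape = (int(row.max()) + 1, int(col.max()) + 1)

    flat = row * lab_shape[1] + col
    if np.unique(flat).size != flat.size:
        n_coll = flat.size - np.unique(flat).size
        raise GeometryError(
            f"lab-frame assembly would place {n_coll} raw pixel(s) into "
            "already-occupied cells; geometry is not representable on an "
            "integer grid without loss"
        )

    lab_row = np.full(raw_shape, -1, dtype=np.int64)
    lab_col = np.full(raw_shape, -1, dtype=np.int64)
    lab_row[covered] = row
    lab_col[covered] = col

    return GeometryMap(
        panels=panels,
        raw_shape=raw_shape,
        lab_shape=lab_shape,
        x_map=x_map,
        y_map=y_map,
        coffset_map=coffset_map,
        lab_row=lab_row,
        lab_col=lab_col,
    )


def assemble(frame: np.ndarray, geom: GeometryMap, fill: float = np.nan) -> np.ndarray:
    """Place a raw-layout frame into the lab frame.

    Each covered raw pixel is written to the lab cell nearest its lab
    coordinate; uncovered cells carry ``fill``.  No pixel is duplicated or
    dropped, so the sum over mapped cells equals the sum over covered raw
    pixels.
    """
    frame = np.asarray(frame)
    if frame.shape != geom.raw_shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match raw layout {geom.raw_shape}"
        )
    out = np.full(geom.lab_shape, fill, dtype=float)
    covered = geom.covered
    out[geom.lab_row[covered], geom.lab_col[covered]] = frame[covered]
    return out


def q_of(radius, beam: BeamGeometry):
    """Momentum transfer q (Å⁻¹) at detector radius ``radius`` (metres).

    q = (4π/λ)·sin(½·arctan(r/d)) for elastic scattering; monotonically
    increasing in r with q(0) = 0.  Accepts scalars or arrays.
    """
    r = np.asarray(radius, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be >= 0")
    theta = 0.5 * np.arctan2(r, beam.detector_distance)
    q = (4.0 * np.pi / beam.wavelength) * np.sin(theta)
    return q if q.ndim else float(q)


def resolution_of(radius, beam: BeamGeometry):
    """Bragg d-spacing (Å) at detector radius ``radius`` (metres).

    d = λ / (2·sin(½·arctan(r/d))) = 2π / q; strictly decreasing in r.  A zero
    radius maps to +inf (unbounded resolution), not an error.
    """
    r = np.asarray(radius, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be >= 0")
    theta = 0.5 * np.arctan2(r, beam.detector_distance)
    with np.errstate(divide="ignore"):
        d = np.where(r > 0, beam.wavelength / (2.0 * np.sin(theta)), np.inf)
    return d if d.ndim else float(d)


def pixel_radius_map(geom: GeometryMap) -> np.ndarray:
    """Per-raw-pixel distance from the direct beam (metres); NaN off-panel."""
    return np.hypot(geom.x_map, geom.y_map)


def q_map(geom: GeometryMap, beam: BeamGeometry) -> np.ndarray:
    """Per-raw-pixel q (Å⁻¹), honouring per-panel coffset; NaN off-panel.

    The panel-local detector distance is the beam's global distance plus the
    panel coffset.
    """
    r = pixel_radius_map(geom)
    d = beam.detector_distance + np.where(
        np.isfinite(geom.coffset_map), geom.coffset_map, 0.0
    )
    theta = 0.5 * np.arctan2(r, d)
    return (4.0 * np.pi / beam.wavelength) * np.sin(theta)


def resolution_map(geom: GeometryMap, beam: BeamGeometry) -> np.ndarray:
    """Per-raw-pixel Bragg d-spacing (Å); +inf on the beam axis, NaN off-panel."""
    q = q_map(geom, beam)
    with np.errstate(divide="ignore"):
        return np.where(q > 0, 2.0 * np.pi / q, np.inf)
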