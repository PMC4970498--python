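"""Pixel-detector dark calibration: offset/noise maps, bad pixels, correction.

A dark run is a sequence of detector exposures taken without beam.  Each
pixel's mean over the run is its *offset* (pedestal) and the population
standard deviation its *noise*, both in ADU.  Cosmic-ray-like spikes are
removed by iterative outlier rejection: values further than ``n_outlier``
standard deviations from the running mean are discarded and the statistics
recomputed until the set of survivors is stable.

After training, the maps can be refined frame by frame, either cumulatively
(every frame weighted equally) or as an exponential moving average/standard
deviation that tracks slow drifts such as temperature-induced pedestal
shifts.  Bad pixels are flagged when their offset or noise falls outside
explicit or automatically determined boundaries, and corrections are applied
in two downstream dialects: dark-subtracted frames with bad pixels zeroed
(CrystFEL-style) or untouched raw values with bad pixels set to a negative
sentinel (nXDS-style).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "CalibrationSet",
    "train",
    "update",
    "detect_bad_pixels",
    "apply_correction",
    "stack_maps",
    "split_maps",
    "save_calibration",
    "save_calibration_series",
    "load_calibration",
    "subtract_common_mode_rows",
    "NOISE_FLOOR",
    "MAX_REJECTION_PASSES",
]

#: stand-in for a zero standard deviation in outlier tests (ADU); a perfectly
#: constant pixel would otherwise reject every subsequent value
NOISE_FLOOR = 1e-6
#: iterative outlier rejection is capped at this many passes
MAX_REJECTION_PASSES = 20


@dataclass
class CalibrationSet:
    """Pixel-wise dark-calibration state.

    ``offset``/``noise``/``counts``/``mask`` all share one detector shape;
    ``mask`` is 0 for good and 1 for bad pixels.
    """

    offset: np.ndarray
    noise: np.ndarray
    counts: np.ndarray
    mask: np.ndarray
    mode: str = "training"
    train_size: int = 0
    n_outlier: float = 4.0
    bounds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {self.offset.shape, self.noise.shape, self.counts.shape, self.mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"calibration maps have inconsistent shapes: {shapes}")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")
        if (self.noise < 0).any():
            raise ValueError("noise must be >= 0")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.offset.shape

    def copy(self) -> "CalibrationSet":
        return dataclasses.replace(
            self,
            offset=self.offset.copy(),
            noise=self.noise.copy(),
            counts=self.counts.copy(),
            mask=self.mask.copy(),
            bounds=dict(self.bounds),
        )


def _iterative_stats(values: np.ndarray, n_outlier: float, axis: int = 0):
    """Mean/std/count along ``axis`` with iterative n-sigma outlier rejection.

    Returns (mean, std, count, keep) where ``keep`` marks surviving samples.
    Convergence means a pass removed nothing; at most
    :data:`MAX_REJECTION_PASSES` passes are made.
    """
    values = np.asarray(values, dtype=float)
    keep = np.ones(values.shape, dtype=bool)
    mean = values.mean(axis=axis)
    std = values.std(axis=axis)
    for _ in range(MAX_REJECTION_PASSES):
        limit = n_outlier * np.maximum(std, NOISE_FLOOR)
        new_keep = keep & (np.abs(values - np.expand_dims(mean, axis)) <= np.expand_dims(limit, axis))
        # never discard the entire sample at a pixel
        cnt = new_keep.sum(axis=axis)
        if (cnt == 0).any():
            new_keep = np.where(np.expand_dims(cnt == 0, axis), keep, new_keep)
            cnt = new_keep.sum(axis=axis)
        if (new_keep == keep).all():
            break
        keep = new_keep
        s = np.where(keep, values, 0.0).sum(axis=axis)
        mean = s / cnt
        var = (np.where(keep, values - np.expand_dims(mean, axis), 0.0) ** 2).sum(axis=axis) / cnt
        std = np.sqrt(var)
    return mean, std, keep.sum(axis=axis), keep


def train(frames, n_outlier: float = 4.0) -> CalibrationSet:
    """Train offset/noise maps from a stack of dark frames.

    ``frames`` is an (n, rows, cols) array or sequence of 2D frames, n >= 2.
    Per pixel, values outside ``n_outlier`` standard deviations are discarded
    iteratively; the surviving values define the offset (mean), the noise
    (population standard deviation) and the contribution count.
    """
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3:
        raise ValueError("frames must stack to (n, rows, cols); got non-uniform shapes"
                         if stack.dtype == object else
                         f"frames must be 3-dimensional, got shape {stack.shape}")
    if stack.shape[0] < 2:
        raise ValueError(f"training requires at least 2 frames, got {stack.shape[0]}")

    mean, std, counts, _ = _iterative_stats(stack, n_outlier, axis=0)
    cal = CalibrationSet(
        offset=mean,
        noise=std,
        counts=counts.astype(np.int64),
        mask=np.zeros(mean.shape, dtype=np.uint8),
        mode="training",
        train_size=stack.shape[0],
        n_outlier=n_outlier,
    )
    return cal


def update(
    cal: CalibrationSet,
    frame: np.ndarray,
    scheme: str = "cumulative",
    alpha: float = 0.01,
    n_outlier: float | None = None,
) -> CalibrationSet:
    """Fold one new dark frame into trained maps.

    Pixels where ``|x − offset| > n_outlier·max(noise, floor)`` are skipped.
    ``cumulative`` gives every frame equal weight (Welford update of mean and
    population variance); ``exponential`` is a moving average with weight
    ``alpha`` on the newest frame so recent frames dominate:

        offset ← (1−α)·offset + α·x
        var    ← (1−α)·(var + α·(x − offset_old)²)

    Returns a new :class:`CalibrationSet`; the input is not modified.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != cal.shape:
        raise ValueError(f"frame shape {frame.shape} != calibration shape {cal.shape}")
    if scheme not in ("cumulative", "exponential"):
        raise ValueError(f"unknown update scheme {scheme!r}")
    if scheme == "exponential" and not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if n_outlier is None:
        n_outlier = cal.n_outlier

    out = cal.copy()
    good = np.abs(frame - cal.offset) <= n_outlier * np.maximum(cal.noise, NOISE_FLOOR)

    if scheme == "cumulative":
        n0 = cal.counts.astype(float)
        n1 = n0 + 1.0
        delta = frame - cal.offset
        new_mean = cal.offset + delta / n1
        # population variance via sum of squared deviations
        m2 = cal.noise**2 * n0 + delta * (frame - new_mean)
        out.offset = np.where(good, new_mean, cal.offset)
        out.noise = np.where(good, np.sqrt(np.maximum(m2, 0.0) / n1), cal.noise)
        out.counts = np.where(good, cal.counts + 1, cal.counts)
    else:
        var = cal.noise**2
        new_mean = (1.0 - alpha) * cal.offset + alpha * frame
        new_var = (1.0 - alpha) * (var + alpha * (frame - cal.offset) ** 2)
        out.offset = np.where(good, new_mean, cal.offset)
        out.noise = np.where(good, np.sqrt(new_var), cal.noise)
        out.counts = np.where(good, cal.counts + 1, cal.counts)
    out.mode = scheme
    return out


def detect_bad_pixels(cal: CalibrationSet, bounds="auto", n: float = 4.0) -> CalibrationSet:
    """Flag pixels whose offset or noise leaves its acceptance interval.

    ``bounds="auto"`` derives the intervals from the maps themselves: the mean
    and standard deviation of the offset map and of the noise map are computed
    with the same iterative outlier rejection used in training, and the
    boundaries are mean ± n·std for each map.  Explicit bounds are a mapping
    such as ``{"offset": (lo, hi), "noise": (lo, hi)}``; either entry may be
    omitted.  Returns a new CalibrationSet whose mask is 1 exactly on the
    offending pixels.  A degenerate map (all pixels identical) masks nothing.
    """
    out = cal.copy()
    if isinstance(bounds, str) and bounds == "auto":
        resolved = {}
        for name, values in (("offset", cal.offset), ("noise", cal.noise)):
            mean, std, _, _ = _iterative_stats(values.ravel(), n, axis=0)
            resolved[name] = (float(mean - n * std), float(mean + n * std))
    else:
        resolved = dict(bounds)

    bad = np.zeros(cal.shape, dtype=bool)
    for name, values in (("offset", cal.offset), ("noise", cal.noise)):
        if name in resolved:
            lo, hi = resolved[name]
            bad |= (values < lo) | (values > hi)
    out.mask = bad.astype(np.uint8)
    out.bounds = resolved
    return out


def apply_correction(
    frame: np.ndarray,
    cal: CalibrationSet,
    dialect: str = "crystfel",
    masked_value: float | None = None,
):
    """Correct a raw frame for one of the two downstream consumers.

    ``crystfel``: dark-subtracted (frame − offset) with masked pixels set to
    ``masked_value`` (default 0).  ``nxds``: raw pixel values untouched —
    bit-identical on unmasked pixels — with masked pixels set to a negative
    sentinel (default −1).
    """
    frame = np.asarray(frame)
    if frame.shape != cal.shape:
        raise ValueError(f"frame shape {frame.shape} != calibration shape {cal.shape}")
    bad = cal.mask.astype(bool)
    if dialect == "crystfel":
        fill = 0.0 if masked_value is None else masked_value
        out = frame.astype(float) - cal.offset
        out[bad] = fill
        return out
    if dialect == "nxds":
        fill = -1 if masked_value is None else masked_value
        if fill >= 0:
            raise ValueError("nxds dialect marks bad pixels with a negative value")
        out = frame.copy()
        out[bad] = fill
        return out
    raise ValueError(f"unknown dialect {dialect!r} (expected 'crystfel' or 'nxds')")


def stack_maps(cal: CalibrationSet) -> np.ndarray:
    """Stack offset, noise, counts and mask vertically into one 2D array."""
    return np.vstack([
        cal.offset,
        cal.noise,
        cal.counts.astype(float),
        cal.mask.astype(float),
    ])


def split_maps(stacked: np.ndarray, **meta) -> CalibrationSet:
    """Invert :func:`stack_maps`; height must be 4 × the map height."""
    stacked = np.asarray(stacked)
    if stacked.ndim != 2 or stacked.shape[0] % 4 != 0:
        raise ValueError(
            f"stacked maps must be 2D with height divisible by 4, got {stacked.shape}"
        )
    h = stacked.shape[0] // 4
    return CalibrationSet(
        offset=stacked[:h].copy(),
        noise=stacked[h: 2 * h].copy(),
        counts=np.rint(stacked[2 * h: 3 * h]).astype(np.int64),
        mask=np.rint(stacked[3 * h:]).astype(np.uint8),
        **meta,
    )


def save_calibration(cal: CalibrationSet, path) -> Path:
    """Write a calibration to HDF5 (/offset /noise /counts /mask + attributes)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name, data in (
            ("offset", cal.offset),
            ("noise", cal.noise),
            ("counts", cal.counts),
            ("mask", cal.mask),
        ):
            f.create_dataset(name, data=data, track_times=False)
        f.attrs["mode"] = cal.mode
        f.attrs["train_size"] = cal.train_size
        f.attrs["n_outlier"] = cal.n_outlier
        f.attrs["timestamp"] = _dt.datetime.now().isoformat()
    return path


def save_calibration_series(cal: CalibrationSet, directory, base: str = "darkcal") -> tuple[Path, Path]:
    """Write a timestamped calibration file plus a refreshed ``latest`` alias.

    The file name is derived from ``base`` and the current date/time; the
    alias ``<base>_latest.h5`` always points at (is a copy of the link to)
    the most recent file.  Returns (timestamped_path, alias_path).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stamp = _dt.datetime.now().strftime("%Y%m%d_%H%M%S_%f")
    path = directory / f"{base}_{stamp}.h5"
    while path.exists():  # same microsecond: disambiguate
        stamp += "x"
        path = directory / f"{base}_{stamp}.h5"
    save_calibration(cal, path)
    alias = directory / f"{base}_latest.h5"
    if alias.is_symlink() or alias.exists():
        alias.unlink()
    try:
        alias.symlink_to(path.name)
    except OSError:  # filesystem without symlink support
        import shutil

        shutil.copyfile(path, alias)
    return path, alias


def load_calibration(path, train_size: int | None = None, auto_mask_n: float = 4.0) -> CalibrationSet:
    """Read a calibration file written by :func:`save_calibration`.

    Offset and noise are required.  When the counts dataset is absent the
    counts are artificially set to the training size (attribute or
    ``train_size`` argument); when the mask is absent it is regenerated with
    automatic boundaries (:func:`detect_bad_pixels`).
    """
    with h5py.File(path, "r") as f:
        found = sorted(f.keys())
        missing = [k for k in ("offset", "noise") if k not in f]
        if missing:
            raise ValueError(
                f"calibration file {path} is missing dataset(s) {missing}; found {found}"
            )
        offset = f["offset"][()]
        noise = f["noise"][()]
        n_train = int(f.attrs.get("train_size", 0)) or (train_size or 0)
        counts = f["counts"][()] if "counts" in f else np.full(offset.shape, n_train, dtype=np.int64)
        mask = f["mask"][()].astype(np.uint8) if "mask" in f else None
        mode = str(f.attrs.get("mode", "training"))
        n_outlier = float(f.attrs.get("n_outlier", 4.0))

    cal = CalibrationSet(
        offset=offset,
        noise=noise,
        counts=np.asarray(counts, dtype=np.int64),
        mask=mask if mask is not None else np.zeros(offset.shape, dtype=np.uint8),
        mode=mode,
        train_size=n_train,
        n_outlier=n_outlier,
    )
    if mask is None:
        cal = detect_bad_pixels(cal, "auto", n=auto_mask_n)
    return cal


def subtract_common_mode_rows(frame: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Subtract the per-row median of unmasked pixels from each row.

    Convenience utility for correlated per-readout baseline shifts; this is a
    simple documented stand-in, not a full common-mode calibration chain.
    """
    frame = np.asarray(frame, dtype=float)
    if mask is None:
        med = np.median(frame, axis=1, keepdims=True)
    else:
        good = ~np.asarray(mask, dtype=bool)
        masked = np.where(good, frame, np.nan)
        with np.errstate(invalid="ignore"):
            med = np.nanmedian(masked, axis=1, keepdims=True)
        med = np.where(np.isfinite(med), med, 0.0)
    return frame - med
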